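"""End-to-end orchestration: generate/load -> preprocess -> analyse.

``run_pipeline`` drives synthetic generation (or loading a directory of
text spectra), the preprocessing chain, band analysis, the classifier suite
and the PLSR stage-trend analysis from one configuration mapping, and
writes a machine-readable JSON report plus CSV exports of every
figure-analogue.  ``validate_suite`` runs the package's internal contract
battery (normalisation contracts, permutation nulls, parameter recovery)
and reports pass/fail per check.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bands import (AMIDE_III_REGION, DEFAULT_AMIDE_III_PEAKS,
                    class_mean_spectrum, correlation_analysis, fit_region)
from .catalog import BAND_CATALOG, STAGE_CODING, default_profiles
from .chemometrics import (LinearSVM, PCALDAClassifier, SmallTreeEnsemble,
                           TreeClassifier, cross_validate)
from .io import read_dataset
from .preprocess import RamanPreprocessor
from .stagetrend import StageTrendPLSR
from .synth import GeneratorConfig, generate_study_dataset

__all__ = ["run_pipeline", "validate_suite", "default_config"]

MODELS = {
    "pca-lda": lambda seed: PCALDAClassifier(),
    "tree": lambda seed: TreeClassifier(random_state=seed),
    "ensemble": lambda seed: SmallTreeEnsemble(random_state=seed),
    "svm": lambda seed: LinearSVM(),
}


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "generator": {"two_class": False},
        "preprocess": {},
        "analysis": {"bands": True, "classify": True, "stagetrend": True},
        "cv": {"k_folds": 10, "repetitions": 5},
    }


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _build_dataset(cfg: dict, seed: int):
    gen = cfg.get("generator") or {}
    input_dir = cfg.get("input_dir")
    if input_dir and gen.get("enabled", True) and "cells_per_class" in gen:
        raise ValueError("give either a generator config or input_dir")
    if input_dir:
        return read_dataset(input_dir)
    classes = None
    if gen.get("two_class"):
        classes = ["SW480", "SW620"]
    profiles = default_profiles(contrast=gen.get("contrast", 1.0),
                                classes=classes)
    config = GeneratorConfig(
        profiles=profiles,
        cells_per_class=gen.get("cells_per_class"),
        seed=gen.get("seed", seed))
    return generate_study_dataset(config)


def run_pipeline(cfg: dict, out_dir=None) -> dict:
    """Execute every enabled stage; returns (and optionally writes) the
    run report."""
    seed = int(cfg.get("seed", 0))
    report = {"version": __version__, "seed": seed,
              "config_hash": _config_hash(cfg), "stages": {}}
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    try:
        dataset = _build_dataset(cfg, seed)
        report["stages"]["data"] = {
            "n_cells": len(dataset.cells),
            "classes": sorted({c["class"] for c in dataset.cells}),
        }
        pre = RamanPreprocessor(**(cfg.get("preprocess") or {}))
        result = pre.process(dataset)
        report["stages"]["preprocess"] = {
            "n_processed": len(result.chemo_set),
            "n_skipped": len(result.skipped),
            "skipped": result.skipped,
            "params": pre.get_params(),
        }
        analysis = cfg.get("analysis") or {}
        X = result.matrix
        y = result.labels
        wn = result.chemo_set.wavenumbers
        if analysis.get("bands", True):
            report["stages"]["bands"] = _bands_stage(result, out)
        if analysis.get("classify", True):
            report["stages"]["classify"] = _classify_stage(
                X, y, wn, cfg, seed, out)
        if analysis.get("stagetrend", True):
            # stage-trend biomarkers are read on the Amide-I-normalised
            # scale; SNV would rescale away common-mode lipid loss
            report["stages"]["stagetrend"] = _stagetrend_stage(
                result.band_set.matrix(), result.band_set.labels,
                result.band_set.wavenumbers, cfg, out)
    except Exception as exc:  # noqa: BLE001 - partial report on failure
        report["error"] = f"{type(exc).__name__}: {exc}"
    if out:
        (out / "report.json").write_text(json.dumps(report, indent=1,
                                                    default=str))
    return report


def _bands_stage(result, out):
    sec = {}
    band_set = result.band_set
    classes = band_set.classes
    means = {}
    for c in classes:
        mean, sd = class_mean_spectrum(band_set, c)
        means[c] = mean
    fits = fit_region(means, AMIDE_III_REGION, DEFAULT_AMIDE_III_PEAKS,
                      share_across=True)
    table = pd.concat(
        [f.to_frame().assign(cell_line=c) for c, f in fits.items()])
    sec["amide_iii"] = table.to_dict(orient="records")
    corr = correlation_analysis(
        band_set.matrix(), band_set.wavenumbers,
        report_subset=[b.center for b in BAND_CATALOG
                       if 730 <= b.center <= 3100])
    sec["correlated_pairs"] = corr.reported_pairs[:50]
    if out:
        table.to_csv(out / "amide_iii_bands.csv", index=False)
        pd.DataFrame(corr.reported_pairs,
                     columns=["wavenumber_1", "wavenumber_2", "r"]
                     ).to_csv(out / "correlated_pairs.csv", index=False)
        mean_df = pd.DataFrame(
            {c: m.intensities for c, m in means.items()},
            index=band_set.wavenumbers)
        mean_df.to_csv(out / "class_mean_spectra.csv",
                       index_label="wavenumber")
    return sec


def _classify_stage(X, y, wn, cfg, seed, out):
    cv_cfg = cfg.get("cv") or {}
    k = cv_cfg.get("k_folds", 10)
    reps = cv_cfg.get("repetitions", 5)
    sec = {}
    pair_mask = np.isin(y, ["SW480", "SW620"])
    scopes = []
    if pair_mask.sum() and len(set(y[pair_mask])) == 2:
        scopes.append(("two_class", X[pair_mask], y[pair_mask]))
    if len(set(y)) > 2:
        scopes.append(("all_classes", X, y))
    for scope_name, Xs, ys in scopes:
        scope = {}
        for name, make in MODELS.items():
            if scope_name == "all_classes" and name != "pca-lda":
                continue  # the multi-class model of record is PCA/LDA
            model = make(seed)
            if hasattr(model, "wavenumbers"):
                model.set_params(wavenumbers=wn)
            res = cross_validate(model, Xs, ys, k=k, reps=reps, seed=seed)
            scope[name] = {
                "accuracy_mean": res.accuracy_mean,
                "accuracy_se": res.accuracy_se,
                "confusion": np.asarray(res.confusion).tolist(),
                "classes": res.classes,
                "protocol": res.protocol,
            }
        sec[scope_name] = scope
    if out:
        (out / "classification.json").write_text(
            json.dumps(sec, indent=1))
    return sec


def _stagetrend_stage(X, y, wn, cfg, out):
    mask = np.isin(y, list(STAGE_CODING))
    if len(set(y[mask])) < 3:
        return {"skipped": "fewer than 3 staged classes present"}
    st_cfg = cfg.get("stagetrend") or {}
    model = StageTrendPLSR(
        n_components=st_cfg.get("n_components", 10),
        alpha=st_cfg.get("alpha", 0.01)).fit(X[mask], y[mask])
    sec = {
        "selected_components": model.selected_,
        "pairwise_p": model.pairwise_p_.tolist(),
        "stage_codes": model.stage_codes_,
    }
    if out:
        model.weights_frame(wn).to_csv(out / "plsr_weights.csv", index=False)
        model.scores_frame().to_csv(out / "plsr_scores.csv", index=False)
        model.report().to_csv(out / "plsr_summary.csv", index=False)
    return sec


def validate_suite(cfg: dict | None = None, fast: bool = True) -> dict:
    """Contract battery runnable from the CLI: each check returns pass/fail.

    ``fast`` shrinks the dataset so the battery runs in seconds; the pytest
    suite exercises the same contracts at larger sizes.
    """
    cfg = cfg or {}
    seed = int(cfg.get("seed", 0))
    n = 24 if fast else 80
    checks = {}

    profiles = default_profiles(classes=["SW480", "SW620"])
    config = GeneratorConfig(profiles=profiles,
                             cells_per_class={"SW480": n, "SW620": n},
                             seed=seed)
    dataset = generate_study_dataset(config)
    result = RamanPreprocessor().process(dataset)

    m = result.band_set.matrix()
    wn = result.band_set.wavenumbers
    am = (wn >= 1600) & (wn <= 1690)
    checks["amide_i_max_unity"] = bool(
        np.allclose(m[:, am].max(axis=1), 1.0, atol=1e-9))
    Xc = result.matrix
    checks["snv_rows"] = bool(
        np.allclose(Xc.mean(axis=1), 0, atol=1e-9)
        and np.allclose(Xc.std(axis=1, ddof=1), 1, atol=1e-9))
    checks["excision"] = bool(
        not np.any((wn > 1750) & (wn < 2800)))

    truth = dataset.truth
    fitted = np.array([result.adjustment_factors[c["cell_id"]]
                       for c in dataset.cells])
    true_a = np.array([truth[c["cell_id"]]["background_scale"]
                       for c in dataset.cells])
    rel_err = np.abs(fitted - true_a) / true_a
    checks["adjustment_factor_recovery"] = bool(np.mean(rel_err) < 0.05)

    y = result.labels
    rng = np.random.default_rng(seed)
    yp = rng.permutation(y)
    res = cross_validate(PCALDAClassifier(), Xc, yp, k=5, reps=2, seed=seed)
    half = 50.0
    se = max(res.accuracy_se, 1e-6)
    checks["permutation_null"] = bool(
        abs(res.accuracy_mean - half) <= 3 * se + 5.0)

    leaky = cross_validate(PCALDAClassifier(), Xc, yp, k=5, reps=2,
                           seed=seed, leaky_pca=True)
    # the default (nested) CV must sit at chance on permuted labels; the
    # leaky variant may only ever look better, never worse, than nested
    checks["leaky_vs_nested_gap_pct"] = float(
        leaky.accuracy_mean - res.accuracy_mean)
    checks["no_leakage_probe"] = bool(
        abs(res.accuracy_mean - half) <= 3 * se + 5.0)

    checks["all_passed"] = all(
        v for v in checks.values() if isinstance(v, bool))
    return checks
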
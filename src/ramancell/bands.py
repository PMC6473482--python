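"""Band-level analysis of normalised spectra.

Class mean/variability spectra, Gaussian decomposition of the Amide III,
Amide I and CH-stretch regions (with peak positions and widths shared across
cell lines, per-class amplitudes), scalar band-intensity readouts, and the
p-value-filtered Pearson correlation matrix used for peak assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Minimizer, Parameters
from scipy import stats

from .catalog import BandSpec
from .spectra import ProcessedSpectrum, SpectrumSet

__all__ = [
    "BandFit", "CorrelationResult", "class_mean_spectrum", "fit_region",
    "band_intensity", "correlation_analysis",
    "AMIDE_III_REGION", "AMIDE_I_REGION", "CH_REGION",
    "DEFAULT_AMIDE_III_PEAKS", "DEFAULT_AMIDE_I_PEAKS", "DEFAULT_CH_PEAKS",
]

# Region definitions (the Amide III band proper spans ~1230-1300 cm-1; the
# fit window is widened so the flanking cytochrome/CH bands do not distort
# the shared-width optimisation).
AMIDE_III_REGION = (1200.0, 1320.0)
AMIDE_I_REGION = (1600.0, 1700.0)
CH_REGION = (2800.0, 3100.0)

# initial peak positions/widths for the shared-parameter fits
DEFAULT_AMIDE_III_PEAKS = [
    BandSpec(1230, 10, "beta-sheet"),
    BandSpec(1248, 11, "disordered"),
    BandSpec(1270, 10, "alpha+beta"),
    BandSpec(1300, 10, "alpha-helix"),
]
DEFAULT_AMIDE_I_PEAKS = [
    BandSpec(1630, 10, "beta-sheet"),
    BandSpec(1655, 12, "alpha-helix"),
    BandSpec(1675, 10, "beta-sheet/turn"),
    BandSpec(1690, 9, "disordered"),
]
DEFAULT_CH_PEAKS = [
    BandSpec(2850, 14, "CH2 symmetric"),
    BandSpec(2885, 14, "CH2 asymmetric"),
    BandSpec(2930, 16, "CH3 symmetric"),
    BandSpec(2960, 14, "CH3 asymmetric"),
    BandSpec(3060, 12, "aromatic =CH"),
]


@dataclass
class BandFit:
    """Gaussian decomposition of one region for one class."""

    region: tuple
    peaks: list = field(default_factory=list)  # (center, sigma, amp, label)
    shared_constraints: bool = False
    goodness: float = 0.0                      # residual sum of squares

    def amplitude(self, label_or_center) -> float:
        for c, s, a, lab in self.peaks:
            if lab == label_or_center or c == label_or_center:
                return a
        raise KeyError(f"no fitted peak {label_or_center!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.peaks,
                            columns=["center", "sigma", "amplitude",
                                     "assignment"])


def class_mean_spectrum(spectrum_set: SpectrumSet, class_label: str):
    """Channelwise mean and sample standard deviation for one class."""
    sel = [s for s in spectrum_set if s.class_label == class_label]
    if not sel:
        raise ValueError(f"unknown class {class_label!r}")
    if len(sel) < 2:
        raise ValueError("need at least 2 spectra for a variability spectrum")
    mat = np.vstack([s.intensities for s in sel])
    mean = ProcessedSpectrum(
        spectrum_set.wavenumbers, mat.mean(axis=0),
        excised_region=sel[0].excised_region, class_label=class_label,
        cell_id=f"mean_{class_label}")
    sd = mat.std(axis=0, ddof=1)
    return mean, sd


def _gauss_sum(w, centers, sigmas, amps):
    out = np.zeros_like(w)
    for c, s, a in zip(centers, sigmas, amps):
        out = out + a * np.exp(-0.5 * ((w - c) / s) ** 2)
    return out


def fit_region(mean_specs, region, init_peaks,
               share_across: bool = True,
               center_window: float = 10.0,
               sigma_bounds: tuple = (0.3, 3.0)):
    """Fit a sum of Gaussians to one spectral region of class mean spectra.

    Parameters
    ----------
    mean_specs : ProcessedSpectrum or dict[str, ProcessedSpectrum]
        One mean spectrum, or one per class.  With ``share_across`` (the
        default, and the convention for multi-class fits) peak centres and
        widths are global parameters optimised jointly over all classes while
        amplitudes are per class.
    region : (lo, hi) wavenumber window.
    init_peaks : list of BandSpec initial positions/widths.
    center_window : float
        Half-width (cm-1) of the box constraint around each initial centre.
    sigma_bounds : (lo, hi)
        Multiplicative bounds on each width relative to its initial value.

    Returns a dict class -> :class:`BandFit` (or a single BandFit when one
    spectrum is passed).
    """
    single = isinstance(mean_specs, ProcessedSpectrum)
    specs = {"_": mean_specs} if single else dict(mean_specs)
    if not init_peaks:
        raise ValueError("need at least one initial peak")
    lo, hi = region
    data = {}
    for name, sp in specs.items():
        m = (sp.wavenumbers >= lo) & (sp.wavenumbers <= hi)
        if m.sum() < 3 * len(init_peaks):
            raise ValueError(f"region {region} not covered by spectrum")
        data[name] = (sp.wavenumbers[m], sp.intensities[m])

    params = Parameters()
    for j, pk in enumerate(init_peaks):
        params.add(f"c{j}", value=pk.center,
                   min=pk.center - center_window,
                   max=pk.center + center_window,
                   vary=True)
        params.add(f"s{j}", value=pk.width,
                   min=pk.width * sigma_bounds[0],
                   max=pk.width * sigma_bounds[1], vary=True)
    names = list(data)
    for gi, name in enumerate(names):
        w, y = data[name]
        guess = max(float(y.max()), 1e-3) / len(init_peaks)
        for j in range(len(init_peaks)):
            suffix = f"g{gi}_a{j}"
            if share_across or gi == 0:
                params.add(suffix, value=guess, min=0.0)
            else:
                params.add(suffix, value=guess, min=0.0)
    if not share_across and len(names) > 1:
        # independent fits per class: centres/widths get per-class copies
        return {name: fit_region(specs[name], region, init_peaks,
                                 share_across=True,
                                 center_window=center_window,
                                 sigma_bounds=sigma_bounds)
                for name in names}

    def residual(p):
        res = []
        centers = [p[f"c{j}"] for j in range(len(init_peaks))]
        sigmas = [p[f"s{j}"] for j in range(len(init_peaks))]
        for gi, name in enumerate(names):
            w, y = data[name]
            amps = [p[f"g{gi}_a{j}"] for j in range(len(init_peaks))]
            res.append(y - _gauss_sum(w, centers, sigmas, amps))
        return np.concatenate(res)

    out = Minimizer(residual, params).least_squares()
    if not out.success:
        raise RuntimeError(
            f"region fit did not converge: {out.message}; "
            f"residual RSS {float(np.sum(out.residual ** 2)):.3g}")
    p = out.params
    fits = {}
    for gi, name in enumerate(names):
        w, y = data[name]
        centers = [p[f"c{j}"].value for j in range(len(init_peaks))]
        sigmas = [p[f"s{j}"].value for j in range(len(init_peaks))]
        amps = [p[f"g{gi}_a{j}"].value for j in range(len(init_peaks))]
        rss = float(np.sum((y - _gauss_sum(w, centers, sigmas, amps)) ** 2))
        fits[name] = BandFit(
            region=region,
            peaks=[(c, s, a, pk.assignment) for c, s, a, pk in
                   zip(centers, sigmas, amps, init_peaks)],
            shared_constraints=len(names) > 1, goodness=rss)
    return fits["_"] if single else fits


def band_intensity(spec: ProcessedSpectrum, center: float,
                   half_width: float = 4.0) -> float:
    """Mean normalised intensity over [center - hw, center + hw]."""
    m = (spec.wavenumbers >= center - half_width) & \
        (spec.wavenumbers <= center + half_width)
    if not m.any():
        raise ValueError(
            f"window {center}+-{half_width} cm-1 lies in an excised or "
            "truncated region")
    return float(spec.intensities[m].mean())


@dataclass
class CorrelationResult:
    """Pearson correlation over wavenumbers with the p > 1e-4 filter."""

    wavenumbers: np.ndarray
    r_matrix: np.ndarray
    p_matrix: np.ndarray
    filtered_r: np.ndarray
    reported_pairs: list          # (w_i, w_j, r) sorted by |r| descending
    constant_channels: list = field(default_factory=list)

    def pair_r(self, w1: float, w2: float) -> float:
        i = int(np.argmin(np.abs(self.wavenumbers - w1)))
        j = int(np.argmin(np.abs(self.wavenumbers - w2)))
        return float(self.filtered_r[i, j])


def correlation_analysis(matrix: np.ndarray, wavenumbers: np.ndarray,
                         p_threshold: float = 1e-4,
                         r_threshold: float = 0.3,
                         report_subset=None) -> CorrelationResult:
    """Filtered correlation matrix of the preprocessed data.

    Pearson r between every pair of wavenumber channels across cells;
    entries with two-sided p > ``p_threshold`` are set to zero and only
    pairs with |r| > ``r_threshold`` are reported.  ``report_subset`` limits
    the reported pair list to the channels nearest the given wavenumbers
    (e.g. catalogue band centres) -- the full matrices are always computed.
    """
    X = np.asarray(matrix, float)
    n, m = X.shape
    if n < 3:
        raise ValueError("need at least 3 cells")
    sd = X.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    Xs = X - X.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xs.T @ Xs) / n / np.outer(X.std(axis=0), X.std(axis=0))
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    filtered = np.where(p > p_threshold, 0.0, r)
    if report_subset is not None:
        idx = np.unique([int(np.argmin(np.abs(wavenumbers - w)))
                         for w in report_subset])
    else:
        idx = np.arange(m)
    pairs = []
    for ii in range(idx.size):
        for jj in range(ii + 1, idx.size):
            i, j = idx[ii], idx[jj]
            if abs(filtered[i, j]) > r_threshold:
                pairs.append((float(wavenumbers[i]), float(wavenumbers[j]),
                              float(filtered[i, j])))
    pairs.sort(key=lambda x: -abs(x[2]))
    return CorrelationResult(
        wavenumbers=np.asarray(wavenumbers, float), r_matrix=r, p_matrix=p,
        filtered_r=filtered, reported_pairs=pairs,
        constant_channels=constant.tolist())
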
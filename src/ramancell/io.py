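"""Plain-text spectrum I/O.

One file per cell per acquisition window, two whitespace-separated columns
(wavenumber cm-1, intensity), "#"-prefixed header lines carrying metadata --
the dialect of a WiRE-style text export.  A dataset is a directory per
experiment containing cell files, ``background_*.txt`` and ``silicon.txt``,
with an optional ``truth.json`` sidecar written by the generator.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .spectra import RawSpectrum
from .synth import RawDataset

__all__ = ["write_spectrum", "read_spectrum", "write_dataset", "read_dataset"]


def write_spectrum(s: RawSpectrum, path, descending: bool = False) -> None:
    path = Path(path)
    w, y = s.wavenumbers, s.intensities
    if descending:
        order = np.argsort(w)[::-1]
    else:
        order = np.argsort(w)
    with open(path, "w") as fh:
        fh.write(f"# cell_id: {s.cell_id}\n")
        fh.write(f"# experiment_id: {s.experiment_id}\n")
        fh.write(f"# class: {s.class_label}\n")
        fh.write(f"# window: {s.window_id}\n")
        for wi, yi in zip(w[order], y[order]):
            fh.write(f"{wi:.4f}\t{yi:.8g}\n")


def read_spectrum(path) -> RawSpectrum:
    path = Path(path)
    meta = {"cell_id": "", "experiment_id": "", "class": "", "window": "1"}
    w, y = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.replace(",", " ").split()
            w.append(float(parts[0]))
            y.append(float(parts[1]))
    return RawSpectrum(np.array(w), np.array(y),
                       window_id=int(meta.get("window", 1) or 1),
                       cell_id=meta["cell_id"],
                       experiment_id=meta["experiment_id"],
                       class_label=meta["class"]).ascending


def write_dataset(ds: RawDataset, out_dir, descending: bool = False) -> None:
    """Write every cell/background/silicon spectrum plus the truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for exp_id, exp in ds.experiments.items():
        d = out / exp_id
        d.mkdir(exist_ok=True)
        write_spectrum(exp["silicon"], d / "silicon.txt", descending)
        for win in (1, 2):
            for k, bg in enumerate(exp["backgrounds"][win]):
                write_spectrum(bg, d / f"background_{k}_w{win}.txt", descending)
    for cell in ds.cells:
        d = out / cell["experiment_id"]
        for win in (1, 2):
            write_spectrum(cell[f"w{win}"],
                           d / f"{cell['cell_id']}_w{win}.txt", descending)
    truth = _jsonable(ds.truth)
    (out / "truth.json").write_text(json.dumps(truth, indent=1))


def read_dataset(in_dir) -> RawDataset:
    """Load a directory-per-experiment dataset written by `write_dataset`
    (or hand-assembled in the same layout)."""
    root = Path(in_dir)
    experiments, cells = {}, []
    for d in sorted(p for p in root.iterdir() if p.is_dir()):
        exp_id = d.name
        silicon = read_spectrum(d / "silicon.txt") \
            if (d / "silicon.txt").exists() else None
        bgs = {1: [], 2: []}
        for win in (1, 2):
            for p in sorted(d.glob(f"background_*_w{win}.txt")):
                bgs[win].append(read_spectrum(p))
        experiments[exp_id] = {"backgrounds": bgs, "silicon": silicon,
                               "shift": None}
        by_cell: dict[str, dict] = {}
        for p in sorted(d.glob("*_w1.txt")) + sorted(d.glob("*_w2.txt")):
            if p.name.startswith(("background_", "silicon")):
                continue
            s = read_spectrum(p)
            rec = by_cell.setdefault(s.cell_id or p.stem.rsplit("_w", 1)[0], {
                "cell_id": s.cell_id, "experiment_id": exp_id or s.experiment_id,
                "class": s.class_label})
            rec[f"w{s.window_id}"] = s
        for rec in by_cell.values():
            if "w1" in rec and "w2" in rec:
                cells.append(rec)
    truth = {}
    if (root / "truth.json").exists():
        truth = json.loads((root / "truth.json").read_text())
    return RawDataset(cells=cells, experiments=experiments, truth=truth)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
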
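"""Preprocessing chain for raw two-window single-cell Raman spectra.

Ordered stages: cosmic-ray despiking, silicon-based wavenumber calibration,
vertical zero-offset, scaled background subtraction (quartz substrate
removal), Savitzky-Golay smoothing, window stitching, truncation to
730-3100 cm-1, asymmetric-least-squares baseline correction, excision of the
band-free 1750-2800 cm-1 region, and Amide-I normalisation.  The
chemometrics branch additionally caps the CH window at 3000 cm-1 and applies
per-spectrum standard normal variate scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator

from .spectra import ProcessedSpectrum, RawSpectrum, SpectrumSet
from .synth import SILICON_PEAK, RawDataset

__all__ = [
    "BackgroundModel", "RamanPreprocessor", "PreprocessResult",
    "despike", "calibrate_axis", "silicon_shift", "zero_offset",
    "subtract_background", "smooth", "baseline_correct", "stitch_windows",
    "truncate_excise", "normalize_amide1", "snv", "preprocess_dataset",
]

TRUNCATE_RANGE = (730.0, 3100.0)
EXCISE_RANGE = (1750.0, 2800.0)
CHEMO_UPPER = 3000.0
AMIDE_I_WINDOW = (1600.0, 1690.0)


# ---------------------------------------------------------------- despiking

def despike(s: RawSpectrum, z_threshold: float = 8.0):
    """Remove single-channel cosmic-ray spikes.

    A channel is flagged when the modified z-score of the second difference
    exceeds ``z_threshold`` *and* the channel itself stands out from the
    5-point running median by the same factor; flagged channels are replaced
    by that local median.  The two-criterion rule keeps the immediate
    neighbours of a spike (whose second differences are also inflated) and
    sharp genuine bands untouched.

    Returns the cleaned spectrum and the sorted list of flagged indices.
    """
    y = s.intensities
    if y.size < 5:
        raise ValueError("despike needs at least 5 channels")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")
    d2 = np.zeros_like(y)
    d2[1:-1] = y[:-2] - 2 * y[1:-1] + y[2:]
    # one-sided second differences so edge-channel spikes are catchable
    d2[0] = y[0] - 2 * y[1] + y[2]
    d2[-1] = y[-1] - 2 * y[-2] + y[-3]
    span = float(y.max() - y.min())
    floor = 1e-3 * span + 1e-12
    scale_d2 = max(_mad_sigma(d2), floor)
    z = np.abs(d2 - np.median(d2)) / scale_d2 * 1.0
    local = median_filter(y, size=5, mode="nearest")
    r = y - local
    scale_r = max(_mad_sigma(r), floor)
    # a cosmic spike is one channel wide: its residual must dominate both
    # neighbours' residuals, which a sharp genuine band never does
    ar = np.abs(r)
    neigh = np.zeros_like(ar)
    neigh[1:] = ar[:-1]
    neigh[:-1] = np.maximum(neigh[:-1], ar[1:])
    flags = (z > z_threshold) & (ar > z_threshold * scale_r) \
        & (ar > 3.0 * neigh)
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return s, []
    out = y.copy()
    out[idx] = local[idx]
    return s.with_intensities(out), idx.tolist()


def _mad_sigma(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


# -------------------------------------------------------------- calibration

def silicon_shift(silicon: RawSpectrum) -> float:
    """Axis correction delta = 520.5 - parabolic peak of the silicon line."""
    s = silicon.ascending
    y, w = s.intensities, s.wavenumbers
    i = int(np.argmax(y))
    prominence = y[i] - np.median(y)
    if prominence <= max(5 * _mad_sigma(y), 1e-12):
        raise ValueError("no detectable silicon peak")
    if i == 0 or i == y.size - 1:
        raise ValueError("silicon peak at spectrum edge")
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    frac = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
    step = 0.5 * (w[i + 1] - w[i - 1])
    peak = w[i] + frac * step
    return SILICON_PEAK - peak


def calibrate_axis(s: RawSpectrum, silicon: RawSpectrum) -> RawSpectrum:
    """Shift the wavenumber axis so the silicon line sits at 520.5 cm-1."""
    return s.with_axis(s.wavenumbers + silicon_shift(silicon))


# ------------------------------------------------------------- zero offset

def zero_offset(s: RawSpectrum) -> RawSpectrum:
    """Translate vertically so the minimum intensity is zero."""
    return s.with_intensities(s.intensities - s.intensities.min())


# ------------------------------------------------- background subtraction

@dataclass
class BackgroundModel:
    """Average cell-free background on the raw grid of one window."""

    mean_background: RawSpectrum
    n_spectra: int = 1
    adjustment_factor_window: tuple = (430.0, 530.0)

    def __post_init__(self) -> None:
        if self.n_spectra < 1:
            raise ValueError("n_spectra must be >= 1")

    @classmethod
    def from_spectra(cls, backgrounds, window=(430.0, 530.0),
                     z_threshold: float = 8.0) -> "BackgroundModel":
        """Despike, zero-offset and average a set of background spectra."""
        cleaned = []
        for bg in backgrounds:
            d, _ = despike(bg.ascending, z_threshold)
            cleaned.append(zero_offset(d))
        grid = cleaned[0].wavenumbers
        mean = np.mean([c.intensities for c in cleaned], axis=0)
        return cls(RawSpectrum(grid, mean,
                               window_id=cleaned[0].window_id,
                               cell_id="background_mean"),
                   n_spectra=len(cleaned), adjustment_factor_window=window)


def subtract_background(s: RawSpectrum, bg: BackgroundModel,
                        factor: float | None = None,
                        residual_tol: float = 0.05):
    """Subtract the scaled mean background from a cell spectrum.

    The adjustment factor ``a`` is the least-squares scale of the mean
    background against the spectrum over the quartz-band window (default
    430-530 cm-1); a local linear term is co-fitted there so that residual
    fluorescence and the earlier vertical translation do not bias the scale.
    When ``factor`` is given (e.g. for the CH window, which does not cover
    the quartz band) the fit is skipped and that factor is applied.

    Returns ``(corrected spectrum, a, mean |residual| in the window)``.
    """
    s = s.ascending
    w = s.wavenumbers
    bg_y = np.interp(w, bg.mean_background.ascending.wavenumbers,
                     bg.mean_background.ascending.intensities)
    a = factor
    if a is None:
        lo, hi = bg.adjustment_factor_window
        if lo < w[0] or hi > w[-1]:
            raise ValueError(
                f"adjustment window {lo}-{hi} outside spectrum range")
        m = (w >= lo) & (w <= hi)
        x = (w[m] - lo) / (hi - lo)
        A = np.column_stack([bg_y[m], np.ones(m.sum()), x])
        coef, *_ = np.linalg.lstsq(A, s.intensities[m], rcond=None)
        a = float(coef[0])
    out = s.intensities - a * bg_y
    lo, hi = bg.adjustment_factor_window
    m = (w >= lo) & (w <= hi)
    resid = float(np.mean(np.abs(out[m] - np.mean(out[m])))) if m.any() \
        else float("nan")
    if np.isfinite(resid):
        ref = max(float(np.abs(a * bg_y[m]).max()), 1e-12)
        if resid / ref > residual_tol:
            warnings.warn(
                f"quartz window residual {resid:.3g} exceeds {residual_tol:.0%}"
                " of the subtracted background", stacklevel=2)
    return s.with_intensities(out), a, resid


# ---------------------------------------------------------------- smoothing

def smooth(s: RawSpectrum, window_pts: int = 11, polyorder: int = 3
           ) -> RawSpectrum:
    """Savitzky-Golay smoothing; length preserved."""
    if window_pts % 2 == 0 or window_pts <= polyorder:
        raise ValueError("window_pts must be odd and > polyorder")
    if window_pts >= s.intensities.size:
        raise ValueError("window_pts must be smaller than the spectrum")
    return s.with_intensities(
        savgol_filter(s.intensities, window_pts, polyorder))


# ------------------------------------------------------ baseline correction

def asls_baseline(y: np.ndarray, lam: float = 1e5, p_asym: float = 0.01,
                  max_iter: int = 50, tol: float = 1e-6) -> np.ndarray:
    """Iterative asymmetric penalized least-squares baseline (Eilers style).

    Minimises sum_i w_i (y_i - z_i)^2 + lam * sum (Delta^2 z)^2 with
    asymmetric weights w_i = p for y_i > z_i and 1 - p otherwise, solved as a
    banded symmetric system; iteration stops when the weights converge.
    """
    y = np.asarray(y, float)
    n = y.size
    if n < 4:
        return np.zeros_like(y)
    d0 = np.full(n, 6.0)
    d0[[0, -1]] = 1.0
    d0[[1, -2]] = 5.0
    d1 = np.full(n - 1, -4.0)
    d1[[0, -1]] = -2.0
    d2 = np.ones(n - 2)
    ab = np.zeros((3, n))
    ab[0, 2:] = lam * d2
    ab[1, 1:] = lam * d1
    w = np.ones(n)
    z = y
    converged = False
    for _ in range(max_iter):
        ab[2, :] = w + lam * d0
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p_asym, 1.0 - p_asym)
        if np.mean(np.abs(w_new - w)) < tol:
            converged = True
            w = w_new
            break
        w = w_new
    if not converged:
        warnings.warn("baseline weights did not converge; returning best "
                      "estimate", stacklevel=2)
    return z


def baseline_correct(s: RawSpectrum, lam: float = 1e5, p_asym: float = 0.01,
                     max_iter: int = 50):
    """Subtract the asymmetric-least-squares baseline estimate.

    Returns ``(corrected spectrum, baseline array)``.
    """
    z = asls_baseline(s.intensities, lam=lam, p_asym=p_asym,
                      max_iter=max_iter)
    return s.with_intensities(s.intensities - z), z


# ----------------------------------------------------------------- stitching

def stitch_windows(w1: RawSpectrum, w2: RawSpectrum,
                   max_gap_channels: float = 2.0) -> RawSpectrum:
    """Merge the fingerprint and CH windows into one monotone spectrum.

    Overlapping channels are averaged after the CH window is offset so the
    two windows agree in mean intensity on the overlap; abutting windows are
    concatenated.  A gap wider than ``max_gap_channels`` grid steps is an
    error.
    """
    if w1.cell_id != w2.cell_id:
        raise ValueError("windows belong to different cells")
    a, b = w1.ascending, w2.ascending
    if a.wavenumbers[0] > b.wavenumbers[0]:
        a, b = b, a
    step = float(np.median(np.diff(a.wavenumbers)))
    tol = 0.5 * step
    gap = b.wavenumbers[0] - a.wavenumbers[-1]
    if gap > max_gap_channels * step + tol:
        raise ValueError(
            f"gap of {gap:.1f} cm-1 between windows exceeds "
            f"{max_gap_channels} channels")
    ov_a = np.flatnonzero(a.wavenumbers >= b.wavenumbers[0] - tol)
    ov_b = np.flatnonzero(b.wavenumbers <= a.wavenumbers[-1] + tol)
    ya = a.intensities.copy()
    yb = b.intensities.copy()
    if ov_a.size and ov_b.size:
        offset = float(np.mean(ya[ov_a]) - np.mean(yb[ov_b]))
        yb += offset
        n_ov = min(ov_a.size, ov_b.size)
        merged_w = np.concatenate([
            a.wavenumbers[: ov_a[0]],
            0.5 * (a.wavenumbers[ov_a[:n_ov]] + b.wavenumbers[ov_b[:n_ov]]),
            b.wavenumbers[ov_b[n_ov - 1] + 1:]])
        merged_y = np.concatenate([
            ya[: ov_a[0]],
            0.5 * (ya[ov_a[:n_ov]] + yb[ov_b[:n_ov]]),
            yb[ov_b[n_ov - 1] + 1:]])
    else:
        merged_w = np.concatenate([a.wavenumbers, b.wavenumbers])
        merged_y = np.concatenate([ya, yb])
    return RawSpectrum(merged_w, merged_y, window_id=1,
                       cell_id=w1.cell_id, experiment_id=w1.experiment_id,
                       class_label=w1.class_label)


# ------------------------------------------------------ truncation/excision

def _truncate(s: RawSpectrum, lo: float, hi: float,
              grid_step: float = 1.0) -> RawSpectrum:
    """Restrict to [lo, hi] on the canonical analysis grid (closed ends)."""
    s = s.ascending
    if s.wavenumbers[0] > lo + 1e-9 or s.wavenumbers[-1] < hi - 1e-9:
        raise ValueError(
            f"spectrum {s.wavenumbers[0]:.0f}-{s.wavenumbers[-1]:.0f} does "
            f"not cover the retained range [{lo}, {hi}]")
    grid = lo + grid_step * np.arange(int(round((hi - lo) / grid_step)) + 1)
    y = np.interp(grid, s.wavenumbers, s.intensities)
    return RawSpectrum(grid, y, window_id=s.window_id, cell_id=s.cell_id,
                       experiment_id=s.experiment_id,
                       class_label=s.class_label)


def truncate_excise(s: RawSpectrum,
                    retained=TRUNCATE_RANGE,
                    excised=EXCISE_RANGE,
                    grid_step: float = 1.0) -> ProcessedSpectrum:
    """Truncate to [730, 3100] cm-1 and drop the open interval (1750, 2800).

    Interval endpoints are closed: channels at exactly 730, 1750, 2800 and
    3100 cm-1 are retained.
    """
    t = _truncate(s, retained[0], retained[1], grid_step)
    lo, hi = excised
    keep = (t.wavenumbers <= lo) | (t.wavenumbers >= hi)
    return ProcessedSpectrum(
        t.wavenumbers[keep], t.intensities[keep], excised_region=(lo, hi),
        cell_id=s.cell_id, experiment_id=s.experiment_id,
        class_label=s.class_label)


# ------------------------------------------------------------ normalisation

def normalize_amide1(ps: ProcessedSpectrum,
                     window=AMIDE_I_WINDOW) -> ProcessedSpectrum:
    """Scale so the Amide I peak (max over 1600-1690 cm-1) equals one."""
    m = (ps.wavenumbers >= window[0]) & (ps.wavenumbers <= window[1])
    if not m.any():
        raise ValueError("Amide I window not present in spectrum")
    peak = float(ps.intensities[m].max())
    if peak <= 0:
        raise ValueError("non-positive Amide I maximum")
    out = ps.copy_with(ps.intensities / peak)
    out.log_step("normalize_amide1", window=window, peak=peak)
    return out


def snv(ps: ProcessedSpectrum) -> ProcessedSpectrum:
    """Standard normal variate: per-spectrum mean 0, sample sd 1."""
    y = ps.intensities
    if y.size < 2:
        raise ValueError("SNV needs at least 2 channels")
    sd = float(y.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance spectrum")
    out = ps.copy_with((y - y.mean()) / sd)
    out.log_step("snv")
    return out


# ------------------------------------------------------------ full pipeline

@dataclass
class PreprocessResult:
    """Both branches of the preprocessing chain plus per-cell diagnostics."""

    band_set: SpectrumSet       # Amide-I normalised, 730-1750 u 2800-3100
    chemo_set: SpectrumSet      # SNV rows, 730-1750 u 2800-3000
    adjustment_factors: dict    # cell_id -> fitted quartz scale a
    skipped: list               # (cell_id, reason)

    @property
    def matrix(self) -> np.ndarray:
        return self.chemo_set.matrix()

    @property
    def labels(self) -> np.ndarray:
        return self.chemo_set.labels


class RamanPreprocessor(BaseEstimator):
    """Configurable preprocessing chain applied cell by cell.

    Parameters mirror the individual stage functions; the chain order is
    fixed.  ``process`` consumes a :class:`~ramancell.synth.RawDataset` and
    returns a :class:`PreprocessResult`.
    """

    def __init__(self, despike_z: float = 8.0, enable_despike: bool = True,
                 sg_window: int = 11, sg_polyorder: int = 3,
                 asls_lam: float = 1e5, asls_p: float = 0.01,
                 asls_max_iter: int = 50,
                 adjustment_window: tuple = (430.0, 530.0),
                 grid_step: float = 1.0):
        self.despike_z = despike_z
        self.enable_despike = enable_despike
        self.sg_window = sg_window
        self.sg_polyorder = sg_polyorder
        self.asls_lam = asls_lam
        self.asls_p = asls_p
        self.asls_max_iter = asls_max_iter
        self.adjustment_window = adjustment_window
        self.grid_step = grid_step

    # -- single cell ------------------------------------------------------
    def process_cell(self, w1: RawSpectrum, w2: RawSpectrum,
                     bg1: BackgroundModel, bg2: BackgroundModel,
                     delta: float = 0.0):
        """Run the chain on one cell; returns (band spectrum, chemo
        spectrum, fitted adjustment factor)."""
        provenance = []
        if self.enable_despike:
            w1, f1 = despike(w1, self.despike_z)
            w2, f2 = despike(w2, self.despike_z)
            provenance.append({"step": "despike", "z": self.despike_z,
                               "flagged": [f1, f2]})
        w1 = w1.with_axis(w1.wavenumbers + delta)
        w2 = w2.with_axis(w2.wavenumbers + delta)
        provenance.append({"step": "calibrate", "delta": delta})
        w1, w2 = zero_offset(w1), zero_offset(w2)
        provenance.append({"step": "zero_offset"})
        w1, a, _ = subtract_background(w1, bg1)
        w2, _, _ = subtract_background(w2, bg2, factor=a)
        provenance.append({"step": "subtract_background", "factor": a})
        w1 = smooth(w1, self.sg_window, self.sg_polyorder)
        w2 = smooth(w2, self.sg_window, self.sg_polyorder)
        provenance.append({"step": "smooth", "window": self.sg_window,
                           "polyorder": self.sg_polyorder})
        merged = stitch_windows(w1, w2)
        provenance.append({"step": "stitch"})
        trunc = _truncate(merged, *TRUNCATE_RANGE, self.grid_step)
        provenance.append({"step": "truncate", "range": TRUNCATE_RANGE})
        corrected, _ = baseline_correct(trunc, self.asls_lam, self.asls_p,
                                        self.asls_max_iter)
        provenance.append({"step": "baseline", "lam": self.asls_lam,
                           "p": self.asls_p})
        lo, hi = EXCISE_RANGE
        keep = (corrected.wavenumbers <= lo) | (corrected.wavenumbers >= hi)
        ps = ProcessedSpectrum(
            corrected.wavenumbers[keep], corrected.intensities[keep],
            excised_region=EXCISE_RANGE, cell_id=w1.cell_id,
            experiment_id=w1.experiment_id, class_label=w1.class_label,
            provenance=provenance + [{"step": "excise", "range": EXCISE_RANGE}])
        band_spec = normalize_amide1(ps)
        chemo_keep = band_spec.wavenumbers <= CHEMO_UPPER
        chemo = ProcessedSpectrum(
            band_spec.wavenumbers[chemo_keep],
            band_spec.intensities[chemo_keep],
            excised_region=EXCISE_RANGE, cell_id=ps.cell_id,
            experiment_id=ps.experiment_id, class_label=ps.class_label,
            provenance=list(band_spec.provenance)
            + [{"step": "truncate_chemo", "upper": CHEMO_UPPER}])
        chemo = snv(chemo)
        return band_spec, chemo, a

    # -- whole dataset ----------------------------------------------------
    def process(self, dataset: RawDataset) -> PreprocessResult:
        band_specs, chemo_specs, factors, skipped = [], [], {}, []
        exp_cache: dict[str, tuple] = {}
        for exp_id, exp in dataset.experiments.items():
            delta = 0.0
            if exp.get("silicon") is not None:
                delta = silicon_shift(exp["silicon"])
            bgs = exp["backgrounds"]
            bg1 = BackgroundModel.from_spectra(
                bgs[1], window=self.adjustment_window,
                z_threshold=self.despike_z)
            bg2 = BackgroundModel.from_spectra(
                bgs[2], window=self.adjustment_window,
                z_threshold=self.despike_z)
            # background grids share the experiment's shift: calibrate them
            bg1.mean_background = bg1.mean_background.with_axis(
                bg1.mean_background.wavenumbers + delta)
            bg2.mean_background = bg2.mean_background.with_axis(
                bg2.mean_background.wavenumbers + delta)
            exp_cache[exp_id] = (delta, bg1, bg2)
        for cell in dataset.cells:
            delta, bg1, bg2 = exp_cache[cell["experiment_id"]]
            try:
                band_spec, chemo, a = self.process_cell(
                    cell["w1"], cell["w2"], bg1, bg2, delta)
            except Exception as exc:  # noqa: BLE001 - skip & log bad cells
                skipped.append((cell["cell_id"], str(exc)))
                continue
            band_specs.append(band_spec)
            chemo_specs.append(chemo)
            factors[cell["cell_id"]] = a
        if not band_specs:
            raise ValueError("no cell survived preprocessing")
        return PreprocessResult(
            band_set=SpectrumSet(band_specs),
            chemo_set=SpectrumSet(chemo_specs),
            adjustment_factors=factors, skipped=skipped)


def preprocess_dataset(dataset: RawDataset, **params) -> PreprocessResult:
    """Functional wrapper around :class:`RamanPreprocessor`."""
    return RamanPreprocessor(**params).process(dataset)
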
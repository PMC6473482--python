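"""Synthetic single-cell Raman dataset generator.

Emulates a two-window confocal Raman acquisition of live single cells on a
quartz substrate: per-cell band amplitudes drawn log-normally around a
cell-line profile (with shared latent factors producing correlated band
families), a low-order polynomial fluorescence baseline, a broad quartz
substrate band near 480 cm-1 mixed in with a per-cell scale factor, additive
Gaussian detector noise, Poisson-distributed single-channel cosmic-ray
spikes, and a per-experiment wavenumber mis-calibration that a silicon
reference spectrum lets the preprocessing undo.

Every random draw flows from one integer seed through ``numpy`` seed
sequences, so identical configurations are bit-identical across runs.  A
truth record keeps the latent amplitudes, baselines, spike positions and
background mixing coefficients for parameter-recovery tests downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import (BAND_CATALOG, DEFAULT_CELL_COUNTS, default_profiles)
from .spectra import RawSpectrum

__all__ = [
    "CellLineProfile", "InstrumentModel", "GeneratorConfig", "RawDataset",
    "generate_cell_spectrum", "generate_background_spectrum",
    "generate_silicon_spectrum", "generate_study_dataset",
]

SILICON_PEAK = 520.5      # cm-1, calibration target
SILICON_SIGMA = 3.0       # cm-1, apparent width of the Si line
QUARTZ_CENTER = 480.0     # cm-1
QUARTZ_SIGMA = 45.0       # broad substrate band

# share of the amplitude variance carried by the group latent factor
_GROUP_WEIGHT = 0.65


@dataclass
class CellLineProfile:
    """Mean band amplitudes and their fluctuation structure for one line."""

    name: str
    bands: list                      # list[BandSpec]
    amplitudes: np.ndarray           # mean amplitude per band, Amide I ~ 1
    amplitude_cv: np.ndarray         # per-band coefficient of variation
    covariance_groups: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, float))
        self.amplitude_cv = np.broadcast_to(
            np.asarray(self.amplitude_cv, float), self.amplitudes.shape).copy()
        if len(self.bands) == 0:
            raise ValueError("profile needs at least one band")
        if len(self.bands) != self.amplitudes.size:
            raise ValueError("bands and amplitudes length mismatch")
        if np.any(self.amplitudes < 0):
            raise ValueError("mean amplitudes must be >= 0")
        if np.any(self.amplitude_cv < 0):
            raise ValueError("amplitude_cv must be >= 0")
        n = len(self.bands)
        for g in self.covariance_groups:
            if any(not 0 <= i < n for i in g):
                raise ValueError("covariance group index out of range")

    def draw_amplitudes(self, rng: np.random.Generator) -> np.ndarray:
        """Log-normal per-cell amplitudes with one latent factor per group."""
        sigma = np.log1p(self.amplitude_cv)  # ~cv for small cv
        z = rng.standard_normal(self.amplitudes.size)
        group_of = np.full(self.amplitudes.size, -1)
        for gi, g in enumerate(self.covariance_groups):
            for i in g:
                group_of[i] = gi
        zg = rng.standard_normal(max(len(self.covariance_groups), 1))
        w = _GROUP_WEIGHT
        latent = np.where(
            group_of >= 0,
            w * zg[group_of] + np.sqrt(1 - w * w) * z,
            z)
        return self.amplitudes * np.exp(sigma * latent)


@dataclass
class InstrumentModel:
    """Acquisition geometry and noise model of the emulated spectrometer."""

    window1: tuple = (300.0, 1800.0)
    window2: tuple = (1800.0, 3200.0)
    grid_step: float = 1.0
    miscalibration_shift: float = 0.0   # cm-1 offset of the raw axis
    noise_sd: float = 0.02              # additive Gaussian noise, Amide I = 1
    cosmic_rate: float = 0.5            # expected spikes per window
    baseline_coeffs: tuple = (0.30, 0.25, -0.10)  # poly in x=(w-300)/2900
    quartz_amplitude: float = 2.0

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.cosmic_rate < 0:
            raise ValueError("cosmic_rate must be >= 0")
        if self.window1[1] < self.window2[0]:
            raise ValueError("windows must abut or overlap at the junction")

    def grid(self, window: int) -> np.ndarray:
        lo, hi = self.window1 if window == 1 else self.window2
        n = int(round((hi - lo) / self.grid_step))
        return lo + self.grid_step * np.arange(n + 1)

    def baseline(self, w: np.ndarray, scale: float = 1.0) -> np.ndarray:
        x = (np.asarray(w) - 300.0) / 2900.0
        c = self.baseline_coeffs
        return scale * sum(ci * x ** i for i, ci in enumerate(c))

    def quartz(self, w: np.ndarray) -> np.ndarray:
        return self.quartz_amplitude * np.exp(
            -0.5 * ((np.asarray(w) - QUARTZ_CENTER) / QUARTZ_SIGMA) ** 2)


@dataclass
class GeneratorConfig:
    """Full study-dataset recipe; defaults reproduce the emulated study."""

    profiles: list = None
    cells_per_class: dict = None
    instrument: InstrumentModel = None
    background_scale_factor: float = 1.0  # true mean quartz mixing coefficient
    background_scale_cv: float = 0.10     # per-cell spread of the coefficient
    baseline_scale_cv: float = 0.15       # per-cell fluorescence variability
    miscalibration_sd: float = 1.5        # per-experiment axis shift, cm-1
    cells_per_experiment: int = 82        # 79-85 cells measured per session
    backgrounds_per_experiment: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profiles is None:
            self.profiles = default_profiles()
        if self.cells_per_class is None:
            self.cells_per_class = {
                p.name: DEFAULT_CELL_COUNTS.get(p.name, 80)
                for p in self.profiles}
        if self.instrument is None:
            self.instrument = InstrumentModel()
        if self.background_scale_factor <= 0:
            raise ValueError("background_scale_factor must be > 0")
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValueError("duplicate class names in profiles")
        for n, c in self.cells_per_class.items():
            if c < 1:
                raise ValueError(f"cells_per_class[{n}] must be >= 1")


def _band_sum(w: np.ndarray, bands, amps: np.ndarray) -> np.ndarray:
    out = np.zeros_like(w, dtype=float)
    for b, a in zip(bands, amps):
        out += a * np.exp(-0.5 * ((w - b.center) / b.width) ** 2)
    return out


def _inject_cosmics(y: np.ndarray, rate: float, rng: np.random.Generator):
    """Single-channel positive spikes, 10-50x the local signal level."""
    n_spikes = rng.poisson(rate)
    pos = rng.integers(0, y.size, size=n_spikes)
    mult = rng.uniform(10.0, 50.0, size=n_spikes)
    for p, m in zip(pos, mult):
        local = max(abs(y[p]), 0.1)
        y[p] += m * local
    return y, np.sort(pos).tolist()


def generate_cell_spectrum(profile: CellLineProfile,
                           instrument: InstrumentModel,
                           seed,
                           background_scale: float = 1.0,
                           baseline_scale: float = 1.0,
                           return_truth: bool = False,
                           **meta):
    """Synthesize the two acquisition windows of one cell.

    The same latent band amplitudes feed both windows; the raw axis is the
    ideal grid while the physics is evaluated at ``w - miscalibration_shift``,
    so every feature appears shifted by ``+miscalibration_shift`` on the raw
    axis, exactly as an uncalibrated spectrometer would report it.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    amps = profile.draw_amplitudes(rng)
    shift = instrument.miscalibration_shift
    windows, spikes = [], []
    for win in (1, 2):
        w = instrument.grid(win)
        w_true = w - shift
        y = _band_sum(w_true, profile.bands, amps)
        y += instrument.baseline(w_true, baseline_scale)
        y += background_scale * instrument.quartz(w_true)
        y += rng.normal(0.0, instrument.noise_sd, size=w.size)
        y, pos = _inject_cosmics(y, instrument.cosmic_rate, rng)
        spikes.append(pos)
        windows.append(RawSpectrum(
            w, y, window_id=win, class_label=profile.name, **meta))
    if return_truth:
        truth = {"amplitudes": amps, "background_scale": background_scale,
                 "baseline_scale": baseline_scale,
                 "spikes": {"window1": spikes[0], "window2": spikes[1]},
                 "shift": shift}
        return windows[0], windows[1], truth
    return windows[0], windows[1]


def generate_background_spectrum(instrument: InstrumentModel, seed,
                                 window: int = 1,
                                 baseline_scale: float = 1.0,
                                 quartz_scale: float = 1.0,
                                 **meta) -> RawSpectrum:
    """A cell-free spectrum: quartz band + fluorescence baseline + noise."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    w = instrument.grid(window)
    w_true = w - instrument.miscalibration_shift
    y = instrument.baseline(w_true, baseline_scale)
    y += quartz_scale * instrument.quartz(w_true)
    y += rng.normal(0.0, instrument.noise_sd, size=w.size)
    return RawSpectrum(w, y, window_id=window, **meta)


def generate_silicon_spectrum(shift: float,
                              instrument: InstrumentModel | None = None
                              ) -> RawSpectrum:
    """Noise-free silicon reference line, apparent peak at 520.5 + shift."""
    if abs(shift) >= 20:
        raise ValueError("silicon axis shift must satisfy |shift| < 20 cm-1")
    if instrument is None:
        instrument = InstrumentModel()
    w = instrument.grid(1)
    y = 100.0 * np.exp(-0.5 * ((w - SILICON_PEAK - shift) / SILICON_SIGMA) ** 2)
    return RawSpectrum(w, y, window_id=1, cell_id="silicon")


@dataclass
class RawDataset:
    """Raw two-window spectra grouped into experiments, plus ground truth."""

    cells: list            # list of dicts: {"w1", "w2", "cell_id", ...}
    experiments: dict      # exp_id -> {"backgrounds": {1: [...], 2: [...]},
                           #            "silicon": RawSpectrum, "shift": float}
    truth: dict            # cell_id -> truth record; plus "config" entry

    def __len__(self) -> int:
        return len(self.cells)


def generate_study_dataset(config: GeneratorConfig) -> RawDataset:
    """Generate the full labelled study dataset with per-experiment
    backgrounds, silicon references and a truth record per cell."""
    root = np.random.SeedSequence(config.seed)
    cells, experiments, truth = [], {}, {}
    profile_by_name = {p.name: p for p in config.profiles}
    exp_counter = 0
    for name, count in config.cells_per_class.items():
        profile = profile_by_name[name]
        n_exp = max(1, int(np.ceil(count / config.cells_per_experiment)))
        sizes = np.full(n_exp, count // n_exp)
        sizes[: count - sizes.sum()] += 1
        for size in sizes:
            exp_id = f"exp{exp_counter:02d}"
            exp_counter += 1
            ss = root.spawn(1)[0]
            rng = np.random.default_rng(ss)
            shift = float(rng.normal(0.0, config.miscalibration_sd))
            shift = float(np.clip(shift, -5.0, 5.0))
            instrument = InstrumentModel(
                window1=config.instrument.window1,
                window2=config.instrument.window2,
                grid_step=config.instrument.grid_step,
                miscalibration_shift=shift,
                noise_sd=config.instrument.noise_sd,
                cosmic_rate=config.instrument.cosmic_rate,
                baseline_coeffs=config.instrument.baseline_coeffs,
                quartz_amplitude=config.instrument.quartz_amplitude)
            silicon = generate_silicon_spectrum(shift, instrument)
            bgs = {1: [], 2: []}
            for k in range(config.backgrounds_per_experiment):
                b_base = float(rng.lognormal(0.0, config.baseline_scale_cv))
                b_quartz = float(rng.lognormal(0.0, 0.03))
                for win in (1, 2):
                    bgs[win].append(generate_background_spectrum(
                        instrument, rng, window=win,
                        baseline_scale=b_base, quartz_scale=b_quartz,
                        experiment_id=exp_id, cell_id=f"background_{k}"))
            experiments[exp_id] = {
                "backgrounds": bgs, "silicon": silicon, "shift": shift}
            for j in range(size):
                cell_id = f"{name}_{exp_id}_c{j:03d}"
                a_cell = config.background_scale_factor * float(
                    rng.lognormal(0.0, config.background_scale_cv))
                b_cell = float(rng.lognormal(0.0, config.baseline_scale_cv))
                w1, w2, t = generate_cell_spectrum(
                    profile, instrument, rng,
                    background_scale=a_cell, baseline_scale=b_cell,
                    return_truth=True,
                    cell_id=cell_id, experiment_id=exp_id)
                cells.append({"cell_id": cell_id, "experiment_id": exp_id,
                              "class": name, "w1": w1, "w2": w2})
                truth[cell_id] = t
    truth["_config"] = {
        "seed": config.seed,
        "cells_per_class": dict(config.cells_per_class),
        "background_scale_factor": config.background_scale_factor,
        "band_centers": [b.center for b in config.profiles[0].bands],
    }
    return RawDataset(cells=cells, experiments=experiments, truth=truth)
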
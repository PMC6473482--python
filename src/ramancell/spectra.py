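"""In-memory containers for single-cell Raman spectra.

A cell is measured in two acquisition windows (fingerprint 300-1800 cm-1 and
CH-stretch 1800-3200 cm-1); each window is a :class:`RawSpectrum`.  After the
preprocessing chain the stitched, truncated, excised spectrum becomes a
:class:`ProcessedSpectrum`, and a labelled collection of those forms a
:class:`SpectrumSet`, the feature matrix for chemometrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["RawSpectrum", "ProcessedSpectrum", "SpectrumSet"]


@dataclass
class RawSpectrum:
    """One acquisition window of one cell: wavenumber axis plus intensities.

    Parameters
    ----------
    wavenumbers : array of float
        Raman shift axis in cm-1, strictly monotone.
    intensities : array of float
        Detector counts (arbitrary units), same length as ``wavenumbers``.
    window_id : int
        1 for the fingerprint window, 2 for the CH-stretch window.
    cell_id, experiment_id, class_label : str
        Free-text metadata.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    window_id: int = 1
    cell_id: str = ""
    experiment_id: str = ""
    class_label: str = ""

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("wavenumbers and intensities must have equal length")
        if self.wavenumbers.size < 2:
            raise ValueError("a spectrum needs at least 2 channels")
        d = np.diff(self.wavenumbers)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber axis must be strictly monotone")

    @property
    def ascending(self) -> "RawSpectrum":
        if self.wavenumbers[0] < self.wavenumbers[-1]:
            return self
        return replace(self, wavenumbers=self.wavenumbers[::-1].copy(),
                       intensities=self.intensities[::-1].copy())

    def with_intensities(self, y: np.ndarray) -> "RawSpectrum":
        return replace(self, intensities=np.asarray(y, dtype=float))

    def with_axis(self, w: np.ndarray) -> "RawSpectrum":
        return replace(self, wavenumbers=np.asarray(w, dtype=float))


@dataclass
class ProcessedSpectrum:
    """A stitched spectrum on the analysis grid with the silent region excised.

    ``wavenumbers`` are restricted to [730, 1750] u [2800, 3100] cm-1 (the
    chemometrics branch further caps the upper window at 3000 cm-1); the
    removed mid-region is recorded in ``excised_region``.  ``provenance`` is
    the ordered list of (step, parameters) applied to reach this state.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    excised_region: tuple[float, float] = (1750.0, 2800.0)
    cell_id: str = ""
    experiment_id: str = ""
    class_label: str = ""
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        lo, hi = self.excised_region
        inside = (self.wavenumbers > lo) & (self.wavenumbers < hi)
        if np.any(inside):
            raise ValueError(
                f"channels inside the excised region ({lo}, {hi}) cm-1")

    def log_step(self, step: str, **params) -> None:
        self.provenance.append({"step": step, **params})

    def copy_with(self, y: np.ndarray) -> "ProcessedSpectrum":
        out = replace(self, intensities=np.asarray(y, dtype=float))
        out.provenance = list(self.provenance)
        return out


class SpectrumSet:
    """Labelled collection of processed spectra sharing one analysis grid."""

    def __init__(self, spectra: list[ProcessedSpectrum]):
        if not spectra:
            raise ValueError("empty spectrum set")
        grid = spectra[0].wavenumbers
        for s in spectra[1:]:
            if s.wavenumbers.shape != grid.shape or not np.allclose(
                    s.wavenumbers, grid):
                raise ValueError("all spectra must share one wavenumber grid")
        self.spectra = spectra
        self.wavenumbers = grid

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.class_label for s in self.spectra])

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.spectra:
            seen.setdefault(s.class_label, None)
        return list(seen)

    def matrix(self) -> np.ndarray:
        """Cells x wavenumbers intensity matrix."""
        return np.vstack([s.intensities for s in self.spectra])

    def subset(self, classes) -> "SpectrumSet":
        keep = set(classes)
        sel = [s for s in self.spectra if s.class_label in keep]
        if not sel:
            raise ValueError(f"no spectra with class in {sorted(keep)}")
        return SpectrumSet(sel)

    def to_frame(self) -> pd.DataFrame:
        """Feature matrix as a DataFrame with metadata columns first."""
        df = pd.DataFrame(self.matrix(),
                          columns=[f"{w:.1f}" for w in self.wavenumbers])
        meta = pd.DataFrame({
            "cell_id": [s.cell_id for s in self.spectra],
            "experiment_id": [s.experiment_id for s in self.spectra],
            "class": [s.class_label for s in self.spectra],
        })
        return pd.concat([meta, df], axis=1)
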
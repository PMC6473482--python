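"""Band catalogue and default cell-line profiles.

The catalogue lists the Raman bands resolvable in averaged live single-cell
spectra of the five lines studied (SW480, SW620, HL60, HT29, HCT116) with
their standard literature assignments.  Per-class amplitude profiles encode
the qualitative biochemical differences between the lines: nucleic-acid and
bonded-phosphate bands (782/810 cm-1) ordered HL60 > HCT116 > SW620 > HT29 >
SW480; lactate (1725 cm-1) rising and CH2 stretch (2850 cm-1) falling with
colorectal adenocarcinoma stage; SW620 richer than SW480 in beta-sheet,
alpha-helix, saccharide and double-bond bands while SW480 carries more
disordered protein structure and overall CH-stretch intensity.

Amplitudes are relative to the Amide I peak (= 1 after normalisation).  The
numeric contrast values are the package's versioned calibration constants:
they were calibrated once so that the default synthetic datasets reach the
classification accuracies reported for the real data, and are not meant to
be edited per run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BandSpec", "BAND_CATALOG", "CLASS_NAMES", "DEFAULT_CELL_COUNTS",
           "default_profiles", "STAGE_CODING", "COVARIANCE_GROUPS"]


@dataclass(frozen=True)
class BandSpec:
    """A single Raman band: Gaussian centre/width plus its assignment."""

    center: float  # cm-1
    width: float   # Gaussian sigma, cm-1
    assignment: str = ""

    def __post_init__(self) -> None:
        if not 300.0 <= self.center <= 3200.0:
            raise ValueError(f"band centre {self.center} outside 300-3200 cm-1")
        if self.width <= 0:
            raise ValueError("band width must be positive")


# centre, sigma, assignment, base amplitude (Amide I alpha-helix = 0.85)
_CATALOG_ROWS = [
    (748, 6, "cytochrome C", 0.25),
    (782, 6, "DNA/RNA pyrimidine ring breathing", 0.30),
    (810, 6, "phosphodiester / bonded phosphate", 0.18),
    (828, 6, "phosphate / tyrosine", 0.18),
    (855, 7, "proline, hydroxyproline", 0.20),
    (885, 7, "lactate / saccharide", 0.12),
    (898, 7, "saccharide", 0.10),
    (936, 8, "C-C backbone stretch, alpha-helix", 0.15),
    (1001, 4, "phenylalanine ring breathing", 0.45),
    (1095, 9, "DNA PO2- backbone", 0.18),
    (1128, 7, "cytochrome C / C-N stretch", 0.22),
    (1157, 7, "carotenoid / conjugated C=C", 0.12),
    (1175, 7, "cytochrome C", 0.12),
    (1230, 10, "Amide III beta-sheet", 0.25),
    (1248, 11, "Amide III disordered", 0.28),
    (1270, 10, "Amide III alpha+beta", 0.25),
    (1300, 10, "Amide III alpha-helix / CH2 twist", 0.30),
    (1310, 7, "cytochrome C", 0.18),
    (1338, 9, "DNA / CH deformation", 0.30),
    (1438, 10, "CH2 deformation (lipid)", 0.45),
    (1448, 9, "CH2/CH3 deformation (protein)", 0.50),
    (1517, 6, "carotenoid", 0.10),
    (1556, 8, "C=C stretch / tryptophan", 0.12),
    (1585, 7, "cytochrome C", 0.20),
    (1605, 7, "phenylalanine / tyrosine", 0.15),
    (1630, 10, "Amide I beta-sheet", 0.45),
    (1655, 12, "Amide I alpha-helix", 0.85),
    (1675, 10, "Amide I beta-sheet / turn", 0.45),
    (1690, 9, "Amide I disordered", 0.25),
    (1725, 10, "C=O stretch, lactate/ester", 0.10),
    (2850, 14, "CH2 symmetric stretch (lipid)", 1.20),
    (2885, 14, "CH2 asymmetric stretch", 1.40),
    (2930, 16, "CH3 symmetric stretch (protein)", 2.20),
    (2960, 14, "CH3 asymmetric stretch", 1.20),
    (3060, 12, "aromatic =CH stretch", 0.25),
]

BAND_CATALOG: list[BandSpec] = [
    BandSpec(c, w, a) for c, w, a, _ in _CATALOG_ROWS]

BASE_AMPLITUDES = np.array([r[3] for r in _CATALOG_ROWS])

CLASS_NAMES = ["SW480", "SW620", "HL60", "HT29", "HCT116"]

# per-class counts of the emulated study
DEFAULT_CELL_COUNTS = {
    "SW480": 163, "SW620": 167, "HL60": 89, "HT29": 190, "HCT116": 71}

# Duke stage codes for the colorectal adenocarcinoma lines:
# B primary -> 1, C primary -> 2, C metastasis -> 3.
STAGE_CODING = {"SW480": 1, "HT29": 2, "SW620": 3}

# Bands whose per-cell amplitudes co-fluctuate through a shared latent
# factor (index into BAND_CATALOG): the cytochrome-C resonance series, the
# nucleic-acid/phosphate series and the lipid CH series.
COVARIANCE_GROUPS = {
    "cytochrome": [748, 1128, 1175, 1310, 1585],
    "nucleic": [782, 810, 828, 1095, 1338],
    "lipid": [1438, 2850, 2885],
}

# Per-class amplitude multipliers (calibration constants, see module
# docstring).  Rows follow _CATALOG_ROWS; columns follow CLASS_NAMES.
_CLASS_CONTRAST = {
    748:  (1.05, 1.05, 0.70, 1.30, 0.75),
    782:  (0.85, 1.18, 1.55, 1.02, 1.35),
    810:  (0.85, 1.18, 1.55, 1.02, 1.35),
    828:  (0.88, 1.15, 1.45, 1.02, 1.30),
    855:  (0.90, 1.15, 0.75, 1.30, 1.00),
    885:  (0.90, 1.25, 0.85, 1.10, 1.40),
    898:  (0.90, 1.25, 0.80, 1.10, 1.40),
    936:  (0.95, 1.10, 0.70, 1.35, 0.80),
    1001: (0.85, 1.00, 1.20, 0.88, 1.18),
    1095: (0.88, 1.15, 1.45, 1.30, 1.25),
    1128: (1.00, 1.10, 1.00, 1.25, 0.85),
    1157: (0.90, 1.15, 0.75, 1.45, 1.00),
    1175: (1.00, 1.08, 1.00, 1.25, 0.88),
    1230: (0.85, 1.25, 1.30, 0.90, 0.80),
    1248: (1.15, 0.90, 0.95, 1.12, 1.18),
    1270: (1.10, 0.95, 1.10, 1.45, 1.15),
    1300: (1.05, 1.20, 0.70, 0.95, 0.95),
    1310: (1.00, 1.08, 1.00, 1.25, 0.85),
    1338: (0.90, 1.12, 1.30, 1.25, 1.20),
    1438: (0.90, 1.20, 1.35, 1.00, 0.95),
    1448: (1.05, 0.95, 1.20, 1.30, 1.00),
    1517: (0.90, 1.15, 0.75, 1.45, 1.00),
    1556: (0.85, 1.20, 0.95, 1.00, 1.00),
    1585: (1.00, 1.08, 1.00, 1.25, 0.85),
    1605: (0.95, 1.05, 1.35, 1.40, 1.05),
    1630: (0.90, 1.15, 1.20, 0.78, 0.85),
    1655: (1.00, 1.00, 1.00, 1.00, 1.00),
    1675: (1.10, 0.90, 1.05, 1.00, 1.05),
    1690: (1.15, 0.90, 0.95, 1.30, 1.20),
    1725: (0.90, 1.40, 0.90, 1.15, 1.60),
    2850: (1.25, 0.92, 1.15, 1.05, 0.60),
    2885: (1.15, 1.00, 1.35, 1.05, 0.85),
    2930: (1.30, 0.85, 1.20, 1.10, 1.15),
    2960: (1.25, 0.85, 1.30, 1.05, 1.25),
    3060: (1.00, 1.05, 1.40, 1.35, 0.75),
}

# per-band coefficient of variation of the per-cell amplitudes; the Amide I
# sub-bands vary less because spectra are later normalised to that peak and
# protein content is the within-class anchor
DEFAULT_AMPLITUDE_CV = 0.36
AMIDE_I_CV = 0.12
_AMIDE_I_CENTERS = {1630, 1655, 1675, 1690}


def _group_indices() -> list[list[int]]:
    centers = [b.center for b in BAND_CATALOG]
    return [[centers.index(c) for c in members]
            for members in COVARIANCE_GROUPS.values()]


def default_profiles(contrast: float = 1.0, classes=None):
    """Build the default :class:`~ramancell.synth.CellLineProfile` list.

    Parameters
    ----------
    contrast : float
        Scale applied to the between-class log-amplitude differences.
        1.0 gives the calibrated study profiles; 0.0 collapses all classes
        onto the shared base profile (a class-null dataset).
    classes : sequence of str, optional
        Subset/order of class names; defaults to all five lines.
    """
    from .synth import CellLineProfile

    if classes is None:
        classes = CLASS_NAMES
    cv = np.full(len(BAND_CATALOG), DEFAULT_AMPLITUDE_CV)
    for i, b in enumerate(BAND_CATALOG):
        if b.center in _AMIDE_I_CENTERS:
            cv[i] = AMIDE_I_CV
    groups = _group_indices()
    profiles = []
    for name in classes:
        j = CLASS_NAMES.index(name)
        mult = np.array([_CLASS_CONTRAST[b.center][j] for b in BAND_CATALOG])
        amps = BASE_AMPLITUDES * np.power(mult, contrast)
        profiles.append(CellLineProfile(
            name=name, bands=list(BAND_CATALOG), amplitudes=amps,
            amplitude_cv=cv.copy(), covariance_groups=[list(g) for g in groups]))
    return profiles


def band_index(center: float) -> int:
    """Index into BAND_CATALOG of the band whose centre equals ``center``."""
    for i, b in enumerate(BAND_CATALOG):
        if b.center == center:
            return i
    raise KeyError(f"no catalogue band at {center} cm-1")
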
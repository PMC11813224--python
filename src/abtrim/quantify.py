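"""Standard-curve calibration and light/heavy peptide mass bookkeeping.

Coproduct concentrations are read off internal-standard response-ratio
standard curves (synthetic peptide standards spiked with a fixed insulin
internal standard; the response ratio analyte/insulin is linear in
concentration over the calibrated range).  Concentrations inverting below
the lowest standard are censored at that standard, never extrapolated.

The light/heavy channel design uses substrate grown on natural-abundance
vs. uniformly ¹³C/¹⁵N-labelled media, so every product peptide appears at
two masses separated exactly by nC·Δ(¹³C−¹²C) + nN·Δ(¹⁵N−¹⁴N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence, Union

import numpy as np
from pyteomics import mass as _ptmass
from scipy import stats

from .values import Censored

__all__ = [
    "StandardCurve",
    "PeptideSpecies",
    "ElementalComposition",
    "fit_standard_curve",
    "invert_curve",
    "internal_standard_ratio",
    "peptide_composition",
    "monoisotopic_mass",
    "heavy_mass_shift",
    "assign_channel",
    "DEFAULT_MASS_TOLERANCE_DA",
]

# Monoisotopic atomic masses (Da), standard NIST/IUPAC values.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}
DELTA_13C = 13.0033548378 - MONOISOTOPIC_MASS["C"]
DELTA_15N = 15.0001088982 - MONOISOTOPIC_MASS["N"]

#: Ion mass extraction width (Da) of the LC-MS/MS acquisition; used as the
#: default window for channel assignment.
DEFAULT_MASS_TOLERANCE_DA = 0.02

Labeling = Literal["light", "uniform_13C15N"]


@dataclass(frozen=True)
class PeptideSpecies:
    """A quantified peptide coproduct and its isotope-labelling state."""

    id: str
    sequence: str
    labeling: Labeling = "light"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.sequence) - set("ACDEFGHIKLMNPQRSTVWY")
        if bad:
            raise ValueError(f"non-canonical residues in {self.sequence!r}: {sorted(bad)}")


@dataclass(frozen=True)
class ElementalComposition:
    """Element counts of a neutral peptide (residues + one water)."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for element in ("C", "H", "N", "O", "S"):
            if getattr(self, element) < 0:
                raise ValueError(f"negative count for element {element}")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            *(getattr(self, e) + getattr(other, e) for e in ("C", "H", "N", "O", "S"))
        )


def peptide_composition(sequence: str) -> ElementalComposition:
    """Elemental composition of a linear peptide (sum of residues + H₂O)."""
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    try:
        comp = _ptmass.Composition(sequence=sequence)
    except Exception as exc:
        raise ValueError(f"cannot parse peptide sequence {sequence!r}") from exc
    extra = set(comp) - {"C", "H", "N", "O", "S"}
    if extra:
        raise ValueError(f"unsupported elements {sorted(extra)} in {sequence!r}")
    return ElementalComposition(**{e: comp.get(e, 0) for e in ("C", "H", "N", "O", "S")})


def monoisotopic_mass(
    comp: ElementalComposition, labeling: Labeling = "light"
) -> float:
    """Neutral monoisotopic mass in Da.

    ``uniform_13C15N`` assumes every carbon is ¹³C and every nitrogen ¹⁵N
    (substrate grown with ¹³C-glucose and ¹⁵NH₄Cl as sole C and N sources).
    """
    light = sum(getattr(comp, e) * MONOISOTOPIC_MASS[e] for e in ("C", "H", "N", "O", "S"))
    if labeling == "light":
        return light
    if labeling == "uniform_13C15N":
        return light + comp.C * DELTA_13C + comp.N * DELTA_15N
    raise ValueError(f"unknown labeling {labeling!r}")


def heavy_mass_shift(sequence: str) -> float:
    """Mass difference (Da) between heavy and light forms of a peptide."""
    comp = peptide_composition(sequence)
    return comp.C * DELTA_13C + comp.N * DELTA_15N


def assign_channel(
    observed_mass: float,
    species: PeptideSpecies,
    tolerance: float = DEFAULT_MASS_TOLERANCE_DA,
) -> Literal["light", "heavy", "unassigned"]:
    """Assign an observed neutral mass to the light or heavy channel.

    Picks the nearer of the two theoretical masses if it lies within
    ``tolerance``; an exact tie (possible only for peptides with no C or N,
    which cannot occur) or neither mass in range gives ``unassigned``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    comp = peptide_composition(species.sequence)
    d_light = abs(observed_mass - monoisotopic_mass(comp, "light"))
    d_heavy = abs(observed_mass - monoisotopic_mass(comp, "uniform_13C15N"))
    if d_light > tolerance and d_heavy > tolerance:
        return "unassigned"
    if d_light == d_heavy:
        return "unassigned"
    return "light" if d_light < d_heavy else "heavy"


# ---------------------------------------------------------------------------
# Standard curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares calibration of response ratio against concentration.

    ``log_scale`` indicates the fit was done on log10-transformed axes
    (a piecewise-linear alternative for wide calibration ranges).
    """

    analyte: str
    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    r_squared: float
    lowest_standard: float
    log_scale: bool = False


def fit_standard_curve(
    points: Sequence[tuple[float, float]],
    analyte: str = "",
    force_origin: bool = False,
    log_scale: bool = False,
) -> StandardCurve:
    """Fit response_ratio = slope·concentration + intercept by OLS.

    ``force_origin`` pins the intercept at zero; ``log_scale`` fits
    log10(ratio) against log10(concentration) instead.  Requires at least
    three points at distinct, strictly positive concentrations.
    """
    pts = tuple((float(c), float(r)) for c, r in points)
    if len(pts) < 3:
        raise ValueError("a standard curve needs at least 3 points")
    conc = np.array([p[0] for p in pts])
    resp = np.array([p[1] for p in pts])
    if np.any(conc <= 0):
        raise ValueError("standard concentrations must be strictly positive")
    if np.unique(conc).size < 2:
        raise ValueError("standard concentrations must not all coincide")

    x, y = (np.log10(conc), np.log10(resp)) if log_scale else (conc, resp)
    if log_scale and np.any(resp <= 0):
        raise ValueError("log-scale fit requires strictly positive responses")

    if force_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        residual = y - slope * x
        total = np.sum((y - y.mean()) ** 2)
        r_squared = 1.0 - float(np.sum(residual**2) / total) if total > 0 else 1.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r_squared = float(fit.rvalue**2)

    return StandardCurve(
        analyte=analyte,
        points=pts,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        lowest_standard=float(conc.min()),
        log_scale=log_scale,
    )


def invert_curve(
    curve: StandardCurve, response_ratio: float
) -> Union[float, Censored]:
    """Concentration (nM) for a response ratio, censored below the lowest standard.

    The detection limit is the lowest calibration standard of *this* curve;
    anything inverting below it is reported as ``Censored(lowest_standard)``
    rather than an extrapolated number.
    """
    if curve.slope == 0:
        raise ValueError("cannot invert a flat standard curve (slope = 0)")
    if curve.log_scale:
        if response_ratio <= 0:
            return Censored(curve.lowest_standard)
        conc = 10.0 ** ((math.log10(response_ratio) - curve.intercept) / curve.slope)
    else:
        conc = (response_ratio - curve.intercept) / curve.slope
    if conc < curve.lowest_standard:
        return Censored(curve.lowest_standard)
    return float(conc)


def internal_standard_ratio(analyte_response: float, is_response: float) -> float:
    """Dimensionless analyte/internal-standard response ratio."""
    if is_response <= 0:
        raise ValueError("internal-standard response must be positive")
    return float(analyte_response) / float(is_response)
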
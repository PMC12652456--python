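"""Reference tannin assay: tannic-acid standard curve and the
spectrophotometric tannin formula.

The assay reads absorbance at 525 nm, converts it to tannic-acid
concentration c (mg/mL) through a fitted standard curve, and computes

    T (%) = (2*c / m) * 100 * 100 / (100 - H)

where m is the sample mass (mg) and H the sample moisture (%).  2c/m is the
tannin dry-mass fraction (the factor 2 folds in the 20 mL extraction
volume), x100 converts to percent, and 100/(100-H) corrects to dry basis.
Replicate absorbances are averaged before curve inversion; with a linear
curve the order of averaging is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StandardCurve",
    "TanninAssay",
    "fit_standard_curve",
    "tannin_from_assay",
    "average_replicates",
]


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line absorbance = slope * c + intercept at 525 nm."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("standard curve slope must be nonzero")

    def concentration(self, absorbance: float) -> float:
        """Invert the curve: tannic-acid concentration (mg/mL)."""
        return (absorbance - self.intercept) / self.slope


@dataclass(frozen=True)
class TanninAssay:
    """One sample's assay record (replicate absorbances at 525 nm)."""

    absorbances: tuple[float, ...]
    mass_mg: float
    moisture_pct: float = 0.0

    def __post_init__(self) -> None:
        if len(self.absorbances) == 0:
            raise ValueError("at least one replicate absorbance required")
        if self.mass_mg <= 0:
            raise ValueError("sample mass must be positive")
        if not 0 <= self.moisture_pct < 100:
            raise ValueError("moisture must lie in [0, 100)")


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """OLS fit of absorbance on concentration from (c, A) calibration points."""
    if len(points) < 2:
        raise ValueError("need at least 2 calibration points")
    c = np.array([p[0] for p in points], float)
    a = np.array([p[1] for p in points], float)
    if np.ptp(c) == 0 or np.ptp(a) == 0:
        raise ValueError("degenerate calibration points (constant c or absorbance)")
    slope, intercept = np.polyfit(c, a, 1)
    return StandardCurve(float(slope), float(intercept))


def average_replicates(values) -> float:
    """Arithmetic mean of replicate measurements."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("no replicate values")
    return float(values.mean())


def tannin_from_assay(curve: StandardCurve, assay: TanninAssay) -> float:
    """Tannin content T (%) from a standard curve and an assay record."""
    absorbance = average_replicates(assay.absorbances)
    c = curve.concentration(absorbance)
    return (2.0 * c / assay.mass_mg) * 100.0 * 100.0 / (100.0 - assay.moisture_pct)
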
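"""Size-exclusion chromatography calibration and oligomeric-state calling.

A SEC column is calibrated by ordinary least squares of log10(mass in kDa)
on elution volume (ml).  Apparent masses follow from the line; the oligomer
call divides by the monomer mass and rounds to the nearest integer.  An
apparent mass far below the monomer flags interaction with the column matrix
(a lectin binding the dextran resin elutes anomalously late).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SECCalibration",
    "OligomerCall",
    "BIORAD_STANDARD_MASSES_KDA",
    "fit_calibration",
    "estimate_mass",
    "call_oligomer",
]

#: Bio-Rad gel-filtration standard masses (kDa): thyroglobulin, gamma-globulin,
#: ovalbumin, myoglobin, vitamin B12.
BIORAD_STANDARD_MASSES_KDA: tuple[float, ...] = (670.0, 158.0, 44.0, 17.0, 1.35)


@dataclass(frozen=True)
class SECCalibration:
    """log10(kDa) = intercept + slope × elution_ml."""

    slope: float
    intercept: float
    r_squared: float
    standards: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if len(self.standards) < 2:
            raise ValueError("need at least 2 standards")

    @property
    def elution_range(self) -> tuple[float, float]:
        volumes = [v for _, v in self.standards]
        return min(volumes), max(volumes)


@dataclass(frozen=True)
class OligomerCall:
    estimated_mass: float
    monomer_mass: float
    ratio: float
    n_mer: int
    matrix_interaction_flag: bool


def fit_calibration(standards) -> SECCalibration:
    """OLS of log10(mass kDa) on elution volume over (mass, elution) pairs."""
    pairs = [(float(m), float(v)) for m, v in standards]
    if len({v for _, v in pairs}) < 2:
        raise ValueError("need at least 2 distinct elution volumes to calibrate")
    masses = np.array([m for m, _ in pairs])
    volumes = np.array([v for _, v in pairs])
    if np.any(masses <= 0):
        raise ValueError("standard masses must be positive")
    fit = stats.linregress(volumes, np.log10(masses))
    r2 = float(fit.rvalue ** 2) if np.isfinite(fit.rvalue) else 1.0
    if fit.slope >= 0:
        warnings.warn("calibration slope is non-negative; check standards", stacklevel=2)
    return SECCalibration(slope=float(fit.slope), intercept=float(fit.intercept),
                          r_squared=min(r2, 1.0), standards=tuple(pairs))


def estimate_mass(cal: SECCalibration, elution_ml: float) -> float:
    """Apparent mass (kDa) at an elution volume: 10^(intercept + slope·V)."""
    lo, hi = cal.elution_range
    span = hi - lo
    if span > 0 and not (lo - 0.2 * span <= elution_ml <= hi + 0.2 * span):
        warnings.warn(f"elution {elution_ml} ml is outside the calibrated range "
                      f"[{lo}, {hi}] ml by more than 20%", stacklevel=2)
    return 10.0 ** (cal.intercept + cal.slope * elution_ml)


def call_oligomer(estimated_mass: float, monomer_mass: float) -> OligomerCall:
    """Oligomeric state from apparent vs monomer mass.

    ``n_mer`` is the nearest integer (ties round up, never below 1); an
    apparent mass under half the monomer flags matrix interaction.
    """
    if estimated_mass <= 0 or monomer_mass <= 0:
        raise ValueError("masses must be positive")
    ratio = estimated_mass / monomer_mass
    n_mer = max(1, math.floor(ratio + 0.5))
    return OligomerCall(estimated_mass=estimated_mass, monomer_mass=monomer_mass,
                        ratio=ratio, n_mer=n_mer,
                        matrix_interaction_flag=estimated_mass < 0.5 * monomer_mass)
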
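"""Travelling-wave ion mobility CCS calibration and normalization.

Travelling-wave drift times have no closed-form relation to collision
cross section (CCS); they are calibrated externally against ions of known
helium CCS.  The standard protocol, adopted here:

1. correct each drift time for m/z-dependent transit outside the mobility
   cell:  t' = t - c * sqrt(m/z) / 1000   (c is the instrument's enhanced
   duty-cycle delay coefficient, conventionally 1.41; t in ms, m/z in Th)
2. reduce each reference CCS by charge and reduced mass with the drift
   gas:  CCS' = CCS / (z * sqrt(1/mu)),  mu = m*m_He/(m + m_He)
3. fit the power law  ln CCS' = ln A + B ln t'  by least squares.

An analyte CCS then follows as  CCS = A t'^B * z * sqrt(1/mu).

Reported uncertainties combine the replicate SD with a 3% calibration
term in quadrature, and cross-homolog comparison uses the
molecular-weight-normalized CCS = CCS / mass (A^2/Da): a 1:1 complex as
compact as its equal-mass components has a normalized CCS half theirs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import linregress
from sklearn.base import BaseEstimator, RegressorMixin

from ._constants import HELIUM_MASS_DA, PROTON_MASS_DA
from .errors import CalibrationError

__all__ = [
    "CalibrantEntry",
    "CCSCalibration",
    "CCSMeasurement",
    "TWIMSCalibrator",
    "fit_ccs_calibration",
    "ccs_from_drift",
    "normalized_ccs",
    "ccs_uncertainty",
]

#: minimum number of calibrant ions for a trustworthy power-law fit
MIN_CALIBRANTS = 5

#: fractional calibration uncertainty folded into every CCS measurement
CALIBRATION_FRACTION = 0.03

#: conventional duty-cycle delay coefficient (ms per sqrt(Th), /1000)
DEFAULT_DEAD_TIME_COEFF = 1.41


@dataclass(frozen=True)
class CalibrantEntry:
    """A calibrant ion: mass (Da), charge, drift time (ms), helium CCS (A^2)."""

    mass: float
    charge: int
    drift_time: float
    reference_ccs: float

    def __post_init__(self) -> None:
        if min(self.mass, self.charge, self.drift_time, self.reference_ccs) <= 0:
            raise ValueError("all calibrant fields must be positive")


@dataclass(frozen=True)
class CCSCalibration:
    """Fitted power-law mapping from corrected drift time to reduced CCS."""

    A: float  # scale (A^2 per ms^B, on the reduced scale)
    B: float  # exponent
    dead_time_coeff: float
    r_squared: float
    gas_mass: float = HELIUM_MASS_DA

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0:
            raise CalibrationError("power-law coefficients must be positive")


@dataclass(frozen=True)
class CCSMeasurement:
    """Species-level CCS with combined uncertainty and MW normalization."""

    species: str
    charge: int
    ccs: float  # A^2
    uncertainty: float  # A^2; >= 3% of ccs by construction
    normalized_ccs: float  # A^2/Da


def _reduced_mass(mass: float, gas_mass: float) -> float:
    return mass * gas_mass / (mass + gas_mass)


def _corrected_drift(
    drift: float | np.ndarray, mass, charge, dead_time_coeff: float
) -> np.ndarray:
    mz = (np.asarray(mass, dtype=float) + np.asarray(charge) * PROTON_MASS_DA) / np.asarray(
        charge
    )
    return np.asarray(drift, dtype=float) - dead_time_coeff * np.sqrt(mz) / 1000.0


class TWIMSCalibrator(BaseEstimator, RegressorMixin):
    """Power-law TWIMS CCS calibration as a scikit-learn estimator.

    ``fit(X, y)`` takes ``X`` of shape (n, 3) with columns
    (mass_da, charge, drift_ms) and ``y`` the reference helium CCS (A^2);
    ``predict(X)`` maps analyte (mass, charge, drift) rows to CCS.

    Attributes after ``fit``: ``A_``, ``B_``, ``r_squared_``,
    ``calibration_``.
    """

    def __init__(
        self,
        dead_time_coeff: float = DEFAULT_DEAD_TIME_COEFF,
        gas_mass: float = HELIUM_MASS_DA,
    ):
        self.dead_time_coeff = dead_time_coeff
        self.gas_mass = gas_mass

    def fit(self, X, y) -> "TWIMSCalibrator":
        X = np.asarray(X, dtype=float)
        ccs_ref = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must have columns (mass_da, charge, drift_ms)")
        if X.shape[0] != ccs_ref.size:
            raise ValueError("X and y must have equal length")
        if X.shape[0] < MIN_CALIBRANTS:
            raise CalibrationError(
                f"need at least {MIN_CALIBRANTS} calibrants, got {X.shape[0]}"
            )
        mass, charge, drift = X.T
        t_prime = _corrected_drift(drift, mass, charge, self.dead_time_coeff)
        if np.any(t_prime <= 0):
            raise CalibrationError("non-positive corrected drift time in calibrants")
        mu = _reduced_mass(mass, self.gas_mass)
        ccs_reduced = ccs_ref / (charge * np.sqrt(1.0 / mu))
        res = linregress(np.log(t_prime), np.log(ccs_reduced))
        A = float(np.exp(res.intercept))
        B = float(res.slope)
        if B <= 0:
            raise CalibrationError(f"non-positive fitted exponent B = {B:.3g}")
        self.A_ = A
        self.B_ = B
        self.r_squared_ = float(res.rvalue**2)
        self.calibration_ = CCSCalibration(
            A=A,
            B=B,
            dead_time_coeff=self.dead_time_coeff,
            r_squared=self.r_squared_,
            gas_mass=self.gas_mass,
        )
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must have columns (mass_da, charge, drift_ms)")
        return np.array(
            [
                ccs_from_drift(d, int(z), m, self.calibration_)
                for m, z, d in X
            ]
        )


def fit_ccs_calibration(calibrants: Sequence[CalibrantEntry], **kwargs) -> CCSCalibration:
    """Fit the drift -> CCS power law from a calibrant table."""
    X = [(c.mass, c.charge, c.drift_time) for c in calibrants]
    y = [c.reference_ccs for c in calibrants]
    return TWIMSCalibrator(**kwargs).fit(X, y).calibration_


def ccs_from_drift(
    drift: float, z: int, mass: float, calib: CCSCalibration
) -> float:
    """Analyte CCS (A^2): A t'^B * z * sqrt(1/mu); increasing in drift."""
    if z < 1:
        raise ValueError("charge must be a positive integer")
    t_prime = float(_corrected_drift(drift, mass, z, calib.dead_time_coeff))
    if t_prime <= 0:
        raise CalibrationError(
            f"corrected drift {t_prime:.4g} ms <= 0 (dead-time correction too large)"
        )
    mu = _reduced_mass(mass, calib.gas_mass)
    return calib.A * t_prime**calib.B * z * math.sqrt(1.0 / mu)


def normalized_ccs(ccs: float, mass: float) -> float:
    """Molecular-weight-normalized CCS (A^2/Da) for cross-homolog comparison."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if ccs <= 0:
        raise ValueError("CCS must be positive")
    return ccs / mass


def ccs_uncertainty(replicate_ccs: Sequence[float]) -> tuple[float, float]:
    """Mean CCS and total uncertainty: sqrt(SD^2 + (3% of mean)^2).

    The replicate SD (sample SD, n-1; zero for a single replicate) is
    combined in quadrature with the 3% calibration term, so the total is
    never below 3% of the mean.
    """
    vals = np.asarray(list(replicate_ccs), dtype=float)
    if vals.size == 0:
        raise ValueError("empty replicate list")
    mean = float(vals.mean())
    sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else 0.0
    total = math.sqrt(sd**2 + (CALIBRATION_FRACTION * mean) ** 2)
    return mean, total
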
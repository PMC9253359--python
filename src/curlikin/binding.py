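"""Calibrated native-MS Kd inference for a 1:1 protein-protein complex.

For the dissociation equilibrium P1P2 <=> P1 + P2 (P1 = CsgA, P2 =
alpha-synuclein), the dissociation constant follows from the calibrated
abundance ratio R = Ab(P1P2)/Ab(P1) = [P1P2]eq/[P1]eq and the initial
concentrations:

    Kd = [P1]eq [P2]eq / [P1P2]eq = [P2]0 / R - [P1]0 / (1 + R)

using the 1:1 mass balances [P1]0 = [P1]eq (1 + R) and
[P2]0 = [P2]eq + [P1P2]eq.

Because the two free proteins ionize with different efficiencies, raw MS
intensities are first converted to concentration scale through per-protein
response calibrations (signal vs known concentration, line through the
origin).  The complex's own response is not separately measurable; by
default it is taken equal to the response of P1, which keeps R a
like-for-like intensity ratio of the two species sharing the denominator
protein.  An independent closed-form equilibrium solver provides the
forward oracle used to validate the inference round trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import CalibrationError, MassBalanceError, SaturationError

__all__ = [
    "ResponseCalibration",
    "ResponseCalibrator",
    "TitrationReplicate",
    "KdEstimate",
    "fit_response_calibration",
    "abundance_ratio",
    "kd_from_ratio",
    "equilibrium_complex",
    "aggregate_kd",
    "estimate_kd",
]


@dataclass(frozen=True)
class ResponseCalibration:
    """Linear ionization-response calibration: abundance = slope * conc + intercept."""

    slope: float  # abundance units per uM
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError(f"non-positive calibration slope {self.slope}")

    def to_concentration(self, abundance: float) -> float:
        """Invert the calibration: measured abundance -> concentration (uM)."""
        return (abundance - self.intercept) / self.slope


class ResponseCalibrator(BaseEstimator, RegressorMixin):
    """Fits the per-protein signal-vs-concentration line.

    ``fit_intercept=False`` (default) forces the line through the origin:
    zero concentration gives zero signal.  The free-intercept mode is a
    diagnostic for background signal.

    Attributes after ``fit``: ``slope_``, ``intercept_``, ``r_squared_``,
    and ``calibration_`` (an immutable :class:`ResponseCalibration`).
    """

    def __init__(self, fit_intercept: bool = False):
        self.fit_intercept = fit_intercept

    def fit(self, X, y) -> "ResponseCalibrator":
        conc = np.asarray(X, dtype=float).reshape(-1)
        ab = np.asarray(y, dtype=float).reshape(-1)
        if conc.shape != ab.shape:
            raise ValueError("X and y must have equal length")
        if conc.size < 3:
            raise CalibrationError("need at least 3 calibration points")
        if np.any(conc <= 0):
            raise ValueError("calibration concentrations must be positive")

        if self.fit_intercept:
            A = np.column_stack([conc, np.ones_like(conc)])
            coef, *_ = np.linalg.lstsq(A, ab, rcond=None)
            slope, intercept = float(coef[0]), float(coef[1])
        else:
            slope = float(conc @ ab / (conc @ conc))
            intercept = 0.0
        if slope <= 0:
            raise CalibrationError(f"non-positive fitted slope {slope:.3g}")

        pred = slope * conc + intercept
        ss_res = float(np.sum((ab - pred) ** 2))
        ss_tot = float(np.sum((ab - ab.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

        self.slope_ = slope
        self.intercept_ = intercept
        self.r_squared_ = r2
        self.calibration_ = ResponseCalibration(slope, intercept, r2)
        return self

    def predict(self, X) -> np.ndarray:
        conc = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * conc + self.intercept_


@dataclass(frozen=True)
class TitrationReplicate:
    """One titration replicate: initial concentrations and corrected abundances."""

    p1_0: float  # uM, CsgA
    p2_0: float  # uM, alpha-synuclein
    ab_p1: float  # corrected free-P1 abundance
    ab_complex: float  # corrected complex abundance

    def __post_init__(self) -> None:
        if self.p1_0 <= 0 or self.p2_0 <= 0:
            raise ValueError("initial concentrations must be positive")
        if self.ab_p1 < 0 or self.ab_complex < 0:
            raise ValueError("abundances must be non-negative")

    @property
    def r(self) -> float:
        """Abundance ratio R = Ab(P1P2)/Ab(P1)."""
        if self.ab_p1 == 0:
            raise SaturationError("free-P1 abundance is zero; R undefined")
        return self.ab_complex / self.ab_p1


@dataclass(frozen=True)
class KdEstimate:
    """Per-replicate Kd values with plain mean and sample SD."""

    values: tuple[float, ...]  # uM
    mean: float
    sd: float  # NaN when n == 1
    n: int


def fit_response_calibration(
    points: Sequence[tuple[float, float]], fit_intercept: bool = False
) -> ResponseCalibration:
    """Least-squares response line from (concentration uM, abundance) points."""
    conc, ab = zip(*points)
    return ResponseCalibrator(fit_intercept=fit_intercept).fit(conc, ab).calibration_


def abundance_ratio(
    ab_p1_raw: float,
    ab_complex_raw: float,
    calib_p1: ResponseCalibration | None = None,
    calib_complex: ResponseCalibration | None = None,
) -> float:
    """Calibrated abundance ratio R = Ab(P1P2)/Ab(P1), concentration scale.

    The complex response defaults to the P1 response (``calib_complex``
    None), in which case the calibration cancels exactly and R equals the
    raw intensity ratio.  With no calibrations at all, unit response is
    assumed.
    """
    if ab_p1_raw < 0 or ab_complex_raw < 0:
        raise ValueError("abundances must be non-negative")
    if ab_p1_raw == 0:
        raise SaturationError("free-P1 abundance is zero; R undefined")
    if calib_complex is None:
        calib_complex = calib_p1
    p1 = calib_p1.to_concentration(ab_p1_raw) if calib_p1 else ab_p1_raw
    cx = calib_complex.to_concentration(ab_complex_raw) if calib_complex else ab_complex_raw
    if p1 <= 0:
        raise SaturationError("corrected free-P1 abundance is non-positive")
    return cx / p1


def kd_from_ratio(r: float, p1_0: float, p2_0: float) -> float:
    """Kd (uM) from the abundance ratio and initial concentrations.

    Kd = p2_0/r - p1_0/(1 + r); requires the implied free-P2 concentration
    [P2]eq = p2_0 - r*p1_0/(1+r) to be positive.
    """
    if r <= 0:
        raise ValueError(f"abundance ratio must be positive, got {r}")
    if p1_0 <= 0 or p2_0 <= 0:
        raise ValueError("initial concentrations must be positive")
    complex_eq = r * p1_0 / (1.0 + r)
    p2_eq = p2_0 - complex_eq
    if p2_eq <= 0:
        raise MassBalanceError(
            f"implied [P2]eq = {p2_eq:.4g} uM <= 0: the complex abundance "
            f"exceeds what [P2]0 = {p2_0} uM can supply under the 1:1 mass balance"
        )
    return p2_0 / r - p1_0 / (1.0 + r)


def equilibrium_complex(
    kd: float, p1_0: float, p2_0: float
) -> tuple[float, float, float]:
    """Closed-form 1:1 equilibrium: ([P1P2]eq, [P1]eq, [P2]eq) in uM.

    The physical root of the binding quadratic:
    [P1P2]eq = ((p1_0+p2_0+kd) - sqrt((p1_0+p2_0+kd)^2 - 4 p1_0 p2_0)) / 2.
    Serves as the independent forward oracle for the ratio-based inference.
    """
    if kd < 0:
        raise ValueError("Kd must be non-negative")
    if p1_0 <= 0 or p2_0 <= 0:
        raise ValueError("initial concentrations must be positive")
    s = p1_0 + p2_0 + kd
    disc = s * s - 4.0 * p1_0 * p2_0
    if disc < 0:  # impossible for valid inputs
        raise ArithmeticError("negative discriminant in binding quadratic")
    cx = (s - math.sqrt(disc)) / 2.0
    return cx, p1_0 - cx, p2_0 - cx


def aggregate_kd(replicates: Sequence[float]) -> KdEstimate:
    """Arithmetic mean and sample SD (n-1 denominator) of per-replicate Kds."""
    vals = tuple(float(v) for v in replicates)
    if not vals:
        raise ValueError("empty replicate list")
    arr = np.array(vals)
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else float("nan")
    return KdEstimate(values=vals, mean=float(arr.mean()), sd=sd, n=arr.size)


def estimate_kd(
    replicates: Sequence[TitrationReplicate],
) -> KdEstimate:
    """Per-replicate Kd via the ratio equation, aggregated over replicates."""
    return aggregate_kd(
        [kd_from_ratio(rep.r, rep.p1_0, rep.p2_0) for rep in replicates]
    )
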
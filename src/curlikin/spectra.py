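"""Charge-state peak assignment and oligomer quantification in native spectra.

Native nESI mass spectra of intrinsically disordered proteins show broad
charge-state envelopes (monomers typically 5+ to 26+ in the m/z window
100-8000).  Monomer, homodimer and 1:1 heterocomplex species are assigned
by matching local intensity maxima to their expected m/z

    m/z(M, z) = (M + z * m_H) / z,   m_H = 1.00728 Da

and the dimer share is quantified as

    % dimer = 100 * sum(dimer areas) / (sum(monomer areas) + sum(dimer areas))

summed over all assigned charge states, with no per-charge ionization
correction.  Where a dimer charge state 2z coincides exactly in m/z with
the monomer at z, the observed intensity cannot be apportioned from the
m/z dimension alone (the ion-mobility dimension used experimentally to
separate them is summarized here as an ambiguity flag), so coincident
assignments are flagged and excluded from both sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._constants import PROTON_MASS_DA
from .errors import CurlikinError

__all__ = [
    "MassSpectrum",
    "SpeciesDefinition",
    "PeakAssignment",
    "OligomerQuant",
    "expected_mz",
    "assign_peaks",
    "percent_dimer",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class MassSpectrum:
    """A centroid/profile spectrum as parallel m/z (Th) and intensity arrays."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class SpeciesDefinition:
    """A protein species observable in the spectrum.

    ``order`` is the oligomeric order (1 monomer, 2 dimer); ``components``
    lists the constituent monomer labels (heterocomplexes allowed) and for
    complexes the mass must equal the sum of component masses — callers
    constructing complexes from monomer definitions get this for free.
    """

    name: str
    mass: float  # average mass, Da
    order: int = 1
    components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.order < 1:
            raise ValueError("oligomeric order must be >= 1")
        if not self.components:
            object.__setattr__(self, "components", (self.name,) * self.order)
        if len(self.components) != self.order:
            raise ValueError("components must have length equal to order")


@dataclass(frozen=True)
class PeakAssignment:
    """One (species, charge) attribution to an observed peak."""

    species: str
    charge: int
    expected_mz: float
    observed_mz: float
    area: float
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area must be non-negative")


@dataclass(frozen=True)
class OligomerQuant:
    """Dimer share of the summed assigned monomer + dimer signal."""

    percent_dimer: float
    monomer_area: float
    dimer_area: float


def expected_mz(mass: float, z: int) -> float:
    """Positive-mode m/z of an ion of average mass ``mass`` carrying z protons."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if int(z) != z or z < 1:
        raise ValueError(f"charge must be a positive integer, got {z}")
    return (mass + z * PROTON_MASS_DA) / z


def _charge_range(env) -> range:
    """Accept (z_min, z_max) tuples or objects with z_min/z_max attributes."""
    if hasattr(env, "z_min"):
        return range(int(env.z_min), int(env.z_max) + 1)
    lo, hi = env
    return range(int(lo), int(hi) + 1)


def _local_sigma(spec: MassSpectrum, apex: int, fallback: float) -> float:
    """Peak width (Gaussian sigma) from half-maximum crossings around an apex."""
    y = spec.intensity
    x = spec.mz
    half = y[apex] / 2.0
    left = right = None
    i = apex
    while i > 0:
        if y[i - 1] <= half:
            # linear interpolation of the crossing
            f = (y[i] - half) / (y[i] - y[i - 1])
            left = x[i] - f * (x[i] - x[i - 1])
            break
        i -= 1
    i = apex
    while i < y.size - 1:
        if y[i + 1] <= half:
            f = (y[i] - half) / (y[i] - y[i + 1])
            right = x[i] + f * (x[i + 1] - x[i])
            break
        i += 1
    if left is None or right is None:
        return fallback
    return (right - left) / _FWHM_TO_SIGMA


def _integrate(spec: MassSpectrum, lo: float, hi: float) -> float:
    sel = (spec.mz >= lo) & (spec.mz <= hi)
    if sel.sum() < 2:
        return 0.0
    return float(np.trapezoid(spec.intensity[sel], spec.mz[sel]))


def assign_peaks(
    spectrum: MassSpectrum,
    species: Sequence[SpeciesDefinition],
    envelopes: Mapping[str, object],
    tolerance: float = 0.5,
) -> list[PeakAssignment]:
    """Attribute observed peaks to (species, charge) pairs.

    For every species and every charge in its envelope, the local intensity
    maximum within ``tolerance`` Th of the expected m/z is located; a
    candidate is accepted only if that maximum is a genuine local apex of
    the full spectrum (an argmax pinned to the tolerance-window edge means
    the true peak lies outside the window).  The peak area is integrated
    by the trapezoid rule over +/- 3 sigma around the apex, with sigma
    estimated from the local half-maximum width.

    When two expected positions claim the same observed apex, the nearer
    expected m/z receives the assignment, flagged ``ambiguous``; the other
    candidates are dropped with a warning.  Returns an empty list (with a
    warning) when nothing can be assigned.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if spectrum.mz.size == 0:
        raise CurlikinError("empty spectrum")

    y = spectrum.intensity
    mz = spectrum.mz
    n = mz.size

    # candidate apex per (species, charge)
    candidates: list[tuple[SpeciesDefinition, int, float, int]] = []
    for sp in species:
        if sp.name not in envelopes:
            continue
        for z in _charge_range(envelopes[sp.name]):
            exp = expected_mz(sp.mass, z)
            if exp < mz[0] - tolerance or exp > mz[-1] + tolerance:
                warnings.warn(
                    f"expected m/z {exp:.2f} for {sp.name} {z}+ outside grid; skipped",
                    stacklevel=2,
                )
                continue
            sel = np.nonzero(np.abs(mz - exp) <= tolerance)[0]
            if sel.size == 0:
                continue
            apex = int(sel[np.argmax(y[sel])])
            if apex == 0 or apex == n - 1:
                continue
            if y[apex] <= 0 or y[apex] < y[apex - 1] or y[apex] < y[apex + 1]:
                continue  # window edge or non-apex: true peak is elsewhere
            candidates.append((sp, z, exp, apex))

    # group by claimed apex; nearest expected m/z wins, ties go to the
    # first-listed species; any contention marks the winner ambiguous
    by_apex: dict[int, list[tuple[SpeciesDefinition, int, float, int]]] = {}
    for cand in candidates:
        by_apex.setdefault(cand[3], []).append(cand)

    out: list[PeakAssignment] = []
    for apex, group in sorted(by_apex.items()):
        group.sort(key=lambda c: abs(c[2] - mz[c[3]]))
        sp, z, exp, _ = group[0]
        ambiguous = len(group) > 1
        if ambiguous:
            losers = ", ".join(f"{c[0].name} {c[1]}+" for c in group[1:])
            warnings.warn(
                f"peak at m/z {mz[apex]:.2f} also claimed by {losers}; "
                f"assigned to {sp.name} {z}+ and flagged ambiguous",
                stacklevel=2,
            )
        sigma = _local_sigma(spectrum, apex, fallback=tolerance)
        area = _integrate(spectrum, mz[apex] - 3 * sigma, mz[apex] + 3 * sigma)
        out.append(
            PeakAssignment(
                species=sp.name,
                charge=z,
                expected_mz=exp,
                observed_mz=float(mz[apex]),
                area=area,
                ambiguous=ambiguous,
            )
        )

    if not out:
        warnings.warn("no peaks assigned for any species", stacklevel=2)
    out.sort(key=lambda a: (a.species, a.charge))
    return out


def percent_dimer(
    assignments: Sequence[PeakAssignment],
    monomer_label: str,
    dimer_label: str,
) -> OligomerQuant:
    """Dimer percentage from summed assigned peak areas.

    Ambiguous assignments (monomer/dimer m/z coincidences) are excluded
    from both sums.  Raises on zero total area.
    """
    mono = sum(
        a.area for a in assignments if a.species == monomer_label and not a.ambiguous
    )
    dim = sum(
        a.area for a in assignments if a.species == dimer_label and not a.ambiguous
    )
    total = mono + dim
    if total <= 0:
        raise CurlikinError(
            f"zero total assigned area for {monomer_label!r}/{dimer_label!r}"
        )
    return OligomerQuant(
        percent_dimer=100.0 * dim / total,
        monomer_area=float(mono),
        dimer_area=float(dim),
    )
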
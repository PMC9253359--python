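"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here under
controlled conditions: sigmoidal ThT traces, native nESI spectra of
monomer/dimer/heterocomplex mixtures, Kd titration abundance tables,
travelling-wave mobility datasets, and consistent multi-homolog panels.
Each generator is a pure function of its parameters and an integer seed
(no global random state), and stores the generating truth in metadata so
estimator round-trip tests can assert recovery.

Defaults mirror the experimental conditions of the study system: ThT read
every 20 min for 48 h; m/z window 100-8000; disordered-monomer charge
envelopes spanning 5+ to 26+; heterocomplex charges 9+ to 11+; titrations
at two concentration pairs in triplicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._constants import PROTON_MASS_DA
from .binding import equilibrium_complex
from .kinetics import SigmoidParams, ThTTrace, sigmoid
from .mobility import (
    DEFAULT_DEAD_TIME_COEFF,
    CalibrantEntry,
    CCSCalibration,
    _reduced_mass,
)
from .spectra import MassSpectrum, SpeciesDefinition, expected_mz

__all__ = [
    "NoiseModel",
    "ChargeEnvelope",
    "HomologTruth",
    "TitrationDataset",
    "MobilityDataset",
    "HomologPanel",
    "generate_tht_trace",
    "generate_mass_spectrum",
    "generate_titration_dataset",
    "generate_mobility_dataset",
    "generate_homolog_panel",
]

#: plate reader interval: one read every 20 min
DEFAULT_INTERVAL_H = 1.0 / 3.0
DEFAULT_DURATION_H = 48.0

#: instrument m/z window
DEFAULT_MZ_RANGE = (100.0, 8000.0)
DEFAULT_MZ_STEP = 0.25


@dataclass(frozen=True)
class NoiseModel:
    """Seeded noise specification applied by the generators.

    ``kind`` is one of ``none``, ``additive-gaussian`` (sd in signal
    units) or ``multiplicative-gaussian`` (sd as a fraction of the value).
    Identical seeds give bitwise-identical output.
    """

    kind: str = "none"
    sd: float = 0.0
    seed: int = 0

    _KINDS = ("none", "additive-gaussian", "multiplicative-gaussian")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"noise kind must be one of {self._KINDS}")
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls()

    @classmethod
    def additive(cls, sd: float, seed: int = 0) -> "NoiseModel":
        return cls("additive-gaussian", sd, seed)

    @classmethod
    def multiplicative(cls, sd: float, seed: int = 0) -> "NoiseModel":
        return cls("multiplicative-gaussian", sd, seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Perturb ``values``; a fresh generator is seeded unless one is passed."""
        if self.kind == "none" or self.sd == 0.0:
            return np.asarray(values, dtype=float).copy()
        if rng is None:
            rng = np.random.default_rng(self.seed)
        values = np.asarray(values, dtype=float)
        if self.kind == "additive-gaussian":
            return values + rng.normal(0.0, self.sd, size=values.shape)
        return values * (1.0 + rng.normal(0.0, self.sd, size=values.shape))


@dataclass(frozen=True)
class ChargeEnvelope:
    """Discretized Gaussian charge-state envelope over integer charges.

    Broad envelopes (e.g. 5+ to 26+) are the native-MS hallmark of
    intrinsically disordered proteins; no physical functional form is
    implied, a renormalized Gaussian over [z_min, z_max] centred at
    ``z_mode`` with spread ``width`` simply reproduces the qualitative
    shape.
    """

    z_min: int
    z_max: int
    z_mode: int | None = None
    width: float = 3.0

    def __post_init__(self) -> None:
        if self.z_mode is None:
            object.__setattr__(self, "z_mode", (self.z_min + self.z_max) // 2)
        if not (1 <= self.z_min <= self.z_mode <= self.z_max):
            raise ValueError("require 1 <= z_min <= z_mode <= z_max")
        if self.width <= 0:
            raise ValueError("envelope width must be positive")

    def charges(self) -> np.ndarray:
        return np.arange(self.z_min, self.z_max + 1)

    def weights(self) -> np.ndarray:
        z = self.charges().astype(float)
        w = np.exp(-0.5 * ((z - self.z_mode) / self.width) ** 2)
        return w / w.sum()


def generate_tht_trace(
    params: SigmoidParams,
    duration_h: float = DEFAULT_DURATION_H,
    interval_h: float = DEFAULT_INTERVAL_H,
    noise: NoiseModel = NoiseModel.none(),
    metadata: Mapping | None = None,
) -> ThTTrace:
    """Sigmoidal ThT trace sampled on a regular grid, plus optional noise.

    The noiseless value at time t is y0 + a/(1 + exp(-(t - x0)/k)); the
    grid starts at t = 0 and ends at ``duration_h`` inclusive.  Ground
    truth is recorded in the trace metadata.
    """
    if duration_h <= 0 or interval_h <= 0:
        raise ValueError("duration and interval must be positive")
    n = int(round(duration_h / interval_h))
    if n < 1:
        raise ValueError("grid is empty")
    time = np.linspace(0.0, n * interval_h, n + 1)
    clean = sigmoid(time, params.y0, params.a, params.x0, params.k)
    meta = dict(metadata or {})
    meta["truth"] = {
        "y0": params.y0,
        "a": params.a,
        "x0": params.x0,
        "k": params.k,
        "lag_time": params.lag_time,
        "noise": (noise.kind, noise.sd, noise.seed),
    }
    return ThTTrace(time=time, fluorescence=noise.apply(clean), metadata=meta)


def _species_response(sp: SpeciesDefinition, response: Mapping[str, float]) -> float:
    # mean of the component monomers' response factors: a homodimer
    # inherits its monomer's factor, a heterocomplex an intermediate one
    return float(np.mean([response.get(c, 1.0) for c in sp.components]))


def generate_mass_spectrum(
    abundances: Mapping[str, float],
    species: Sequence[SpeciesDefinition],
    envelopes: Mapping[str, ChargeEnvelope],
    response: Mapping[str, float] | None = None,
    peak_width: float = 2.0,
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE,
    mz_step: float = DEFAULT_MZ_STEP,
    noise: NoiseModel = NoiseModel.none(),
) -> MassSpectrum:
    """Sum-of-Gaussians nESI spectrum of a species mixture.

    Each species contributes one area-normalized Gaussian (sigma =
    ``peak_width`` Th) per charge state, weighted by its renormalized
    charge envelope, with total species area equal to
    mole_fraction x response factor.  Peaks whose centre falls outside
    the m/z grid are truncated with a warning.  Isotopic fine structure
    is not modelled (unresolved at protein masses).
    """
    import warnings

    if not abundances:
        raise ValueError("empty abundance map")
    if peak_width <= 0:
        raise ValueError("peak_width must be positive")
    if any(v < 0 for v in abundances.values()):
        raise ValueError("mole fractions must be non-negative")
    response = dict(response or {})
    by_name = {sp.name: sp for sp in species}

    lo, hi = mz_range
    mz = np.arange(lo, hi + mz_step / 2, mz_step)
    intensity = np.zeros_like(mz)
    norm = 1.0 / (peak_width * math.sqrt(2.0 * math.pi))
    for name, fraction in abundances.items():
        if fraction == 0.0:
            continue
        sp = by_name[name]
        env = envelopes[name]
        amp = fraction * _species_response(sp, response)
        for z, w in zip(env.charges(), env.weights()):
            centre = expected_mz(sp.mass, int(z))
            if centre < lo or centre > hi:
                warnings.warn(
                    f"{name} {z}+ at m/z {centre:.1f} outside window {mz_range}; truncated",
                    stacklevel=2,
                )
            intensity += amp * w * norm * np.exp(
                -0.5 * ((mz - centre) / peak_width) ** 2
            )
    intensity = noise.apply(intensity)
    np.clip(intensity, 0.0, None, out=intensity)
    return MassSpectrum(mz=mz, intensity=intensity)


@dataclass
class TitrationDataset:
    """Raw titration abundances with their generating truth."""

    table: pd.DataFrame  # replicate, p1_0_uM, p2_0_uM, ab_p1, ab_complex, ab_p2
    true_kd: float  # uM
    response: dict  # per-protein response factors used


def generate_titration_dataset(
    true_kd: float,
    conc_pairs: Sequence[tuple[float, float]] = ((10.0, 10.0), (20.0, 20.0)),
    response: Mapping[str, float] | None = None,
    noise: NoiseModel = NoiseModel.none(),
    replicates: int = 3,
) -> TitrationDataset:
    """Equilibrium titration abundances from a ground-truth Kd.

    For each concentration pair the 1:1 equilibrium is solved exactly,
    species concentrations are converted to raw abundances via the
    per-protein response factors (``p1``, ``p2``; the complex reports with
    the response of P1), then perturbed by noise.  Defaults reproduce the
    experimental design: two concentration pairs, triplicates.
    """
    if true_kd <= 0:
        raise ValueError(
            "true_kd must be positive (Kd = 0 saturates the limiting protein "
            "and leaves the abundance ratio undefined)"
        )
    if replicates < 1:
        raise ValueError("need at least one replicate")
    resp = {"p1": 1.0, "p2": 1.0}
    resp.update(response or {})
    rng = np.random.default_rng(noise.seed)

    rows = []
    rep_id = 0
    for p1_0, p2_0 in conc_pairs:
        if p1_0 <= 0 or p2_0 <= 0:
            raise ValueError("concentrations must be positive")
        cx, p1_eq, p2_eq = equilibrium_complex(true_kd, p1_0, p2_0)
        for _ in range(replicates):
            raw = np.array(
                [
                    resp["p1"] * p1_eq,
                    resp["p1"] * cx,  # complex reports with P1's response
                    resp["p2"] * p2_eq,
                ]
            )
            raw = noise.apply(raw, rng=rng)
            rows.append(
                {
                    "replicate": rep_id,
                    "p1_0_uM": p1_0,
                    "p2_0_uM": p2_0,
                    "ab_p1": raw[0],
                    "ab_complex": raw[1],
                    "ab_p2": raw[2],
                }
            )
            rep_id += 1
    return TitrationDataset(
        table=pd.DataFrame(rows), true_kd=true_kd, response=dict(resp)
    )


@dataclass
class MobilityDataset:
    """Calibrant and analyte drift-time tables with generating truth."""

    calibrants: list[CalibrantEntry]
    analytes: pd.DataFrame  # species, mass_da, charge, drift_ms, true_ccs_A2
    calibration: CCSCalibration  # the generating (true) power law


def _drift_from_ccs(
    ccs: float, mass: float, charge: int, calib: CCSCalibration
) -> float:
    """Invert the calibration transform: true CCS -> raw drift time (ms)."""
    mu = _reduced_mass(mass, calib.gas_mass)
    ccs_reduced = ccs / (charge * math.sqrt(1.0 / mu))
    t_prime = (ccs_reduced / calib.A) ** (1.0 / calib.B)
    mz = (mass + charge * PROTON_MASS_DA) / charge
    return t_prime + calib.dead_time_coeff * math.sqrt(mz) / 1000.0


def generate_mobility_dataset(
    species: Sequence[tuple[SpeciesDefinition, float, Sequence[int]]],
    calib: tuple[float, float] = (400.0, 0.55),
    dead_time_coeff: float = DEFAULT_DEAD_TIME_COEFF,
    calibrant_ccs: Sequence[tuple[float, int, float]] | None = None,
    noise: NoiseModel = NoiseModel.none(),
) -> MobilityDataset:
    """Drift times for analytes and calibrants from a known power law.

    ``species`` is a list of (definition, true CCS in A^2, charge list);
    ``calib`` the generating (A, B); ``calibrant_ccs`` a list of
    (mass_da, charge, reference_ccs_A2) — defaults to eight calibrant ions
    spanning 1000-4500 A^2, comfortably bracketing protein monomer and
    dimer cross sections.  Drift times are obtained by inverting the
    calibration transform, so a noiseless dataset round-trips the fit
    exactly.  Noise (if any) perturbs drift times only.
    """
    A, B = calib
    if A <= 0 or B <= 0:
        raise ValueError("power-law coefficients must be positive")
    if calibrant_ccs is None:
        calibrant_ccs = [
            (8000.0, 5, 1000.0),
            (12000.0, 7, 1500.0),
            (16000.0, 9, 2000.0),
            (20000.0, 10, 2500.0),
            (26000.0, 12, 3100.0),
            (32000.0, 13, 3600.0),
            (40000.0, 15, 4100.0),
            (48000.0, 16, 4500.0),
        ]
    if len(calibrant_ccs) < 5:
        raise ValueError("need at least 5 calibrants to span the analyte range")
    truth = CCSCalibration(
        A=A, B=B, dead_time_coeff=dead_time_coeff, r_squared=1.0
    )
    rng = np.random.default_rng(noise.seed)

    cals = []
    for mass, z, ccs_ref in calibrant_ccs:
        drift = _drift_from_ccs(ccs_ref, mass, z, truth)
        drift = float(noise.apply(np.array([drift]), rng=rng)[0])
        cals.append(CalibrantEntry(mass, z, drift, ccs_ref))

    rows = []
    for sp, true_ccs, charges in species:
        if true_ccs <= 0:
            raise ValueError("true CCS must be positive")
        for z in charges:
            drift = _drift_from_ccs(true_ccs, sp.mass, int(z), truth)
            drift = float(noise.apply(np.array([drift]), rng=rng)[0])
            rows.append(
                {
                    "species": sp.name,
                    "mass_da": sp.mass,
                    "charge": int(z),
                    "drift_ms": drift,
                    "true_ccs_A2": true_ccs,
                }
            )
    return MobilityDataset(
        calibrants=cals, analytes=pd.DataFrame(rows), calibration=truth
    )


@dataclass(frozen=True)
class HomologTruth:
    """Ground truth for one homolog in a synthetic panel."""

    label: str
    sigmoid: SigmoidParams
    dimer_fraction: float  # mole fraction of dimer at 0 h, in [0, 1]
    dimer_ccs: float  # A^2
    mass: float  # monomer average mass, Da

    def __post_init__(self) -> None:
        if not 0.0 <= self.dimer_fraction <= 1.0:
            raise ValueError("dimer mole fraction must lie in [0, 1]")
        if self.mass <= 0 or self.dimer_ccs <= 0:
            raise ValueError("mass and CCS must be positive")


@dataclass
class HomologPanel:
    """One consistent synthetic dataset per homolog, truth retained."""

    truth: tuple[HomologTruth, ...]
    tht: dict[str, list[ThTTrace]]
    spectra: dict[str, MassSpectrum]
    species: dict[str, tuple[SpeciesDefinition, SpeciesDefinition]]
    envelopes: dict[str, dict[str, ChargeEnvelope]]
    mobility: MobilityDataset
    usable_for_correlation: bool


# study-condition envelope defaults: disordered monomers 5+..26+, dimers
# shifted up in charge as larger ions; dimer envelope kept clear of exact
# monomer m/z coincidences is NOT imposed — the assigner must handle them
MONOMER_ENVELOPE = ChargeEnvelope(z_min=5, z_max=26, z_mode=12, width=4.0)
DIMER_ENVELOPE = ChargeEnvelope(z_min=11, z_max=19, z_mode=15, width=2.0)


def generate_homolog_panel(
    truth: Sequence[HomologTruth],
    noise: NoiseModel = NoiseModel.none(),
    tht_replicates: int = 3,
) -> HomologPanel:
    """Consistent ThT + spectrum + mobility data for a homolog panel.

    Requires unique labels; a panel of fewer than 3 homologs is generated
    but flagged unusable for correlation analysis.  All randomness derives
    from ``noise.seed``; sub-seeds are drawn deterministically per homolog
    and data type.
    """
    labels = [t.label for t in truth]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate homolog labels")
    root = np.random.default_rng(noise.seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=(len(truth), 3))

    tht: dict[str, list[ThTTrace]] = {}
    spectra: dict[str, MassSpectrum] = {}
    species_map: dict[str, tuple[SpeciesDefinition, SpeciesDefinition]] = {}
    envelope_map: dict[str, dict[str, ChargeEnvelope]] = {}
    mob_species = []
    for i, t in enumerate(truth):
        tht[t.label] = [
            generate_tht_trace(
                t.sigmoid,
                noise=replace(noise, seed=int(sub_seeds[i, 0]) + rep),
                metadata={"condition": t.label, "replicate": rep},
            )
            for rep in range(tht_replicates)
        ]
        mono = SpeciesDefinition(name=f"{t.label}-monomer", mass=t.mass, order=1)
        dim = SpeciesDefinition(
            name=f"{t.label}-dimer",
            mass=2 * t.mass,
            order=2,
            components=(f"{t.label}-monomer",) * 2,
        )
        species_map[t.label] = (mono, dim)
        envs = {mono.name: MONOMER_ENVELOPE, dim.name: DIMER_ENVELOPE}
        envelope_map[t.label] = envs
        spectra[t.label] = generate_mass_spectrum(
            abundances={
                mono.name: 1.0 - t.dimer_fraction,
                dim.name: t.dimer_fraction,
            },
            species=[mono, dim],
            envelopes=envs,
            noise=replace(noise, seed=int(sub_seeds[i, 1])),
        )
        mob_species.append((dim, t.dimer_ccs, list(DIMER_ENVELOPE.charges())))

    mobility = generate_mobility_dataset(
        mob_species, noise=replace(noise, seed=int(sub_seeds[-1, 2]))
    )
    return HomologPanel(
        truth=tuple(truth),
        tht=tht,
        spectra=spectra,
        species=species_map,
        envelopes=envelope_map,
        mobility=mobility,
        usable_for_correlation=len(truth) >= 3,
    )
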
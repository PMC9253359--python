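# curlikin

Quantitative analysis of bacterial functional-amyloid biophysics: a tested,
reusable pipeline for studying how curli-type CsgA amyloid homologs from the
gut microbiome aggregate and how they interact with the Parkinson's-disease
protein α-synuclein.

Slow-aggregating CsgA homologs accumulate more dimeric species at time zero
and adopt more compact dimer conformations, and these properties track their
ability to accelerate α-synuclein aggregation. `curlikin` implements the
analysis layer needed to measure all of this from plate-reader and native
ion-mobility mass-spectrometry (IM-MS) data — and ships a synthetic-data
module that generates every input with known ground truth, so each estimator
is validated by exact round trips.

## What it computes

**ThT aggregation kinetics** (`curlikin.kinetics`). Thioflavin-T time courses
are fitted with the empirical sigmoid

```
y(t) = y0 + a / (1 + exp(-(t - x0)/k))
```

(`y0` baseline, `a` amplitude, `x0` midpoint in h, `k` apparent growth time
constant in h), and the lag phase is extracted by the tangent construction
`t_lag = x0 - 2k`.

**Native-MS oligomer quantification** (`curlikin.spectra`). Charge-state
peaks of monomer, homodimer and 1:1 heterocomplex species are assigned from
`m/z = (M + z·1.00728)/z`, integrated, and summarized as
`% dimer = 100 · Σ dimer areas / (Σ monomer + Σ dimer areas)`. Exact
monomer/dimer m/z coincidences (dimer at charge 2z on top of monomer at z)
are flagged ambiguous and excluded from both sums.

**Calibrated Kd inference** (`curlikin.binding`). For the 1:1 dissociation
equilibrium `P1P2 ⇌ P1 + P2` the dissociation constant follows from the
calibrated abundance ratio `R = Ab(P1P2)/Ab(P1)`:

```
Kd = [P2]0/R − [P1]0/(1 + R)
```

with per-protein ionization-response calibrations (signal vs concentration)
correcting for unequal ionization efficiency, and a closed-form equilibrium
solver as the independent oracle.

**CCS calibration and normalization** (`curlikin.mobility`). Travelling-wave
drift times are calibrated against reference helium collision cross sections
via the standard dead-time-corrected power law
`ln Ω' = ln A + B ln t'`, with `Ω' = Ω/(z√(1/μ))` the charge/reduced-mass
reduced CCS. Uncertainties combine the replicate SD with a 3% calibration
term in quadrature; cross-homolog comparison uses the molecular-weight
normalized CCS (Ω/mass, Å²/Da).

**Repeat-motif scanning** (`curlikin.motifs`). CsgA-type sequences are
scanned for the 12-residue curli consensus Q-X4-N-X5-Q (overlapping matches
reported; abutting repeats may share the boundary Q), plus global-alignment
percent identity between homologs.

**Orchestration** (`curlikin.workflow`). `run_pipeline` runs
simulate → kinetics → spectra → binding → mobility → motifs → correlate on a
homolog panel and reports Spearman correlations of lag time with % dimer and
with normalized CCS.

## Worked example

```python
from curlikin import (SigmoidParams, generate_tht_trace, fit_sigmoid,
                      equilibrium_complex, kd_from_ratio, aggregate_kd)

# lag phase of a noiseless sigmoidal trace (20-min reads over 48 h)
fit = fit_sigmoid(generate_tht_trace(SigmoidParams(y0=0, a=1, x0=3.5, k=0.5)))
print(fit.lag_time)            # 2.4999999999620652  -> 2.5 h

# Kd round trip at one titration condition (10/10 uM)
cx, p1_eq, p2_eq = equilibrium_complex(489.0, 10.0, 10.0)
r = cx / p1_eq
print(round(cx, 4), round(r, 6))        # 0.1965 0.020048
print(kd_from_ratio(r, 10.0, 10.0))     # 489.0000000000348

# replicate aggregation: plain mean and sample SD
est = aggregate_kd([489, 298, 429, 551, 412])
print(est.mean, round(est.sd, 1))       # 435.8 94.5
```

The full synthetic demo (five homologs spanning fast to slow aggregation,
2% multiplicative noise):

```bash
curlikin run --seed 1 --out-dir demo_out
```

prints

```
    label     lag_h  percent_dimer  normalized_ccs
homolog-A  0.495590       1.308791        0.115101
homolog-B  1.499664       2.630263        0.110806
homolog-C  2.518295       5.361035        0.105742
homolog-D  5.489360       8.123998        0.100333
homolog-E 10.011782      11.631096        0.096010

Spearman lag vs %dimer        : +1.000
Spearman lag vs normalized CCS: -1.000
n homologs                    : 5

Kd (1:1 complex): 407.3 +/- 14.8 uM (n=6)
```

Slow aggregators (long `lag_h`) carry more dimer and a more compact
(smaller) normalized CCS — the configuration the correlation stage is
designed to detect — and the Kd estimate recovers the synthetic ground
truth (416 µM) within the noise of six replicates. Note the reported
`percent_dimer` is the assigned-signal share after excluding ambiguous
monomer/dimer coincidences, a rank-preserving but slightly biased estimate
of the generating mole fraction (see `docs/methods.md`).

The CLI also exposes each stage separately (`curlikin simulate ...`,
`curlikin kinetics fit`, `curlikin spectra assign`, `curlikin kd estimate`,
`curlikin ccs calibrate|measure`, `curlikin motifs scan`).

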
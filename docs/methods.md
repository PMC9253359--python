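# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of each `curlikin` stage. It describes what the code
does and why; every number quoted here is computed by the test suite or
the demo pipeline, not asserted from elsewhere.

## Aggregation kinetics

Amyloid assembly monitored by ThT fluorescence is modelled with the
four-parameter logistic `y(t) = y0 + a/(1 + exp(-(t - x0)/k))`. This is an
empirical description of nucleation-limited growth — no mechanistic
(secondary-nucleation / elongation-moment) model is fitted, deliberately:
the quantities of interest downstream are the lag phase and an apparent
growth constant, for which the logistic is the field's workhorse.

**Lag time.** Several lag definitions circulate; we use the tangent
construction: the tangent at the inflection point `(x0, y0 + a/2)` has
slope `a/(4k)` and intersects the baseline `y = y0` at `t_lag = x0 − 2k`.
This is the conventional choice for ThT kinetics and keeps lag, midpoint
and growth constant mutually consistent. Negative lags are reported as-is
(they signal near-instant aggregation), never clamped.

**Fitting.** Trust-region least squares (`scipy.optimize.curve_fit`) with
initialization `y0 ← min(y)`, `a ← range(y)`, `x0 ← time of first
half-rise`, `k ← span/10`, and bounds `a, k > 0`. Traces need ≥ 8 points.
A trace whose dynamic range is below 5× a robust noise scale
(`1.4826·median|Δy|/√2`, which ignores the smooth sigmoid's contribution)
is rejected as transition-free rather than fitted; note that a pure-noise
trace's range hovers near this threshold (≈ 4–5 σ for tens of points), so
borderline flat traces may occasionally pass the gate and then fail to
converge — both paths raise. Replicates are summarized as mean ± SEM
(sample SD/√n; undefined and reported as NaN for n = 1).

On noiseless synthetic traces, parameters are recovered to < 1e-5 relative
error across `x0 ∈ [1, 40] h`, `k ∈ [0.1, 5] h`; with 2% (of amplitude)
additive noise and triplicates, the mean lag stays within ±0.5 h of truth
for lags between 0.5 and 12 h.

## Spectrum simulation and oligomer quantification

**Forward model.** A spectrum is a sum of area-normalized Gaussians
(σ = `peak_width`, default 2 Th — instrument-limited width at native
protein masses; isotopic structure is unresolved there and not modelled),
one per (species, charge), on the default instrument window m/z 100–8000.
Charge envelopes of disordered proteins are broad and have no accepted
functional form; we use a renormalized Gaussian over integer charges in
`[z_min, z_max]`. Species area equals mole fraction × response factor; a
multi-subunit species' response factor is the mean of its components'
(a homodimer therefore inherits its monomer's factor). Masses are average
masses; the charge carrier is a proton at 1.00728 Da.

**Assignment.** For each expected position, the local intensity maximum
within ±tolerance (default 0.5 Th) must be a genuine apex of the full
spectrum — an argmax pinned to the window edge means the real peak lies
outside and the candidate is dropped. Peak width σ is measured from the
half-maximum crossings and the area integrated by the trapezoid rule over
±3σ.

**% dimer.** Summed assigned dimer area over summed monomer + dimer area,
across all assigned charge states, with no per-charge ionization
correction (none is identifiable from a single spectrum). Exact
monomer/dimer coincidences — the dimer at charge 2z shares the monomer's
m/z at z — cannot be apportioned from the m/z dimension alone; the
ion-mobility dimension that separates them experimentally is represented
here only as an ambiguity flag, and flagged peaks are excluded from both
sums. Consequence: with the realistic default envelopes (monomer 5+–26+,
dimer 11+–19+) four dimer charges coincide with monomer charges and the
quantified share is a *biased but strictly monotone* estimate of the
generating mole fraction (e.g. 11.6% quantified at 16% generated in the
demo panel) — rank correlations across a panel are unaffected. With
coincidence-free envelopes the share recovers the mole fraction to
< 0.5% absolute, which is what the fold-change tests use.

## Kd inference

P1 is the curli subunit (CsgA), P2 is α-synuclein. From the 1:1 mass
balances, `Kd = [P2]0/R − [P1]0/(1+R)` with
`R = Ab(P1P2)/Ab(P1) = [P1P2]eq/[P1]eq`. The independent oracle is the
closed-form physical root of the binding quadratic,
`[P1P2]eq = (s − √(s² − 4·[P1]0·[P2]0))/2`, `s = [P1]0+[P2]0+Kd`; oracle →
ratio → inference is an algebraic identity and round-trips to machine
precision across Kd ∈ [1, 10⁴] µM (a property test, not a tolerance
judgment).

**Response calibration.** Per-protein least-squares line through the
origin (zero concentration ⇒ zero signal; free-intercept mode available
for background diagnostics), over the 5–40 µM working range. The complex's
own ionization response is not measurable; it defaults to P1's response,
which keeps R a like-for-like ratio of two species sharing the denominator
protein — under this policy the calibration cancels from R exactly, and Kd
is invariant to rescaling both proteins' response factors by any common
constant (tested).

**Aggregation.** Plain arithmetic mean and sample SD (n−1). For the
replicate set {489, 298, 429, 551, 412} µM this gives 435.8 ± 94.5 µM.
With 5% multiplicative abundance noise and six replicates across the
(10,10) and (20,20) µM concentration pairs, the mean estimate stays within
15% of the generating truth.

## CCS calibration

The travelling-wave drift-time → CCS mapping has no first-principles form;
the standard external-calibration protocol is implemented: drift times
corrected for m/z-dependent transit (`t' = t − c·√(m/z)/1000` ms, with the
duty-cycle coefficient c = 1.41 by default, configurable), reference
helium CCS values reduced by charge and ion–He reduced mass
(`Ω' = Ω·√μ/z`), and `ln Ω'` regressed on `ln t'`. At least 5 calibrants
are required and should span the analyte range; the bundled synthetic
calibrant set (8 ions, 1000–4500 Å²) brackets protein monomer and dimer
cross sections. The synthetic generator produces drift times by inverting
this exact transform, so the forward model is self-consistent by
construction and noiseless data refit (A, B) and every analyte CCS to
machine precision — which is precisely what those round-trip tests are
entitled to show (they validate the pipeline's algebra, not the vendor's
unpublished constants).

Uncertainty = `√(SD² + (0.03·mean)²)`: replicate scatter combined in
quadrature with a 3% calibration term ("SD plus an additional ±3%" is
ambiguous between addition and quadrature; quadrature is the standard
error-propagation rule and is flagged in reports). Species-level CCS is
the unweighted mean over observed charge states. Normalized CCS = Ω/mass
(Å²/Da, unit made explicit); a 1:1 complex as compact as its equal-mass
components therefore shows half their normalized value.

## Motif scanning and identity

The curli consensus Q-X4-N-X5-Q is a fixed 12-residue window (Q at offset
0, N at 5, Q at 11; X positions accept any residue including the ambiguity
code X). All overlapping windows are reported — adjacent curli repeats can
abut and share the boundary glutamine — with a greedy non-overlapping
post-filter available that permits exactly that one-residue sharing. The
scanner is property-tested against an exhaustive window oracle on 10⁴
random 200-mers.

Percent identity uses Needleman–Wunsch global alignment (match +1,
mismatch 0, linear gap −1) with identity = identical pairs / alignment
length (gaps included). Published identity figures for curli homologs come
from different aligners with different objectives; these values are for
within-package comparison only.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (parameters, seed); one integer seed per
call, sub-seeds drawn deterministically inside composite generators — no
global state. Defaults encode the experimental design: ThT read every
20 min for 48 h; m/z window 100–8000; monomer envelopes 5+–26+;
heterocomplex charges 9+–11+; titrations at (10,10) and (20,20) µM in
triplicate; calibration standards at 5–40 µM. Noise is additive or
multiplicative Gaussian; real nESI spray/transmission noise structure is
unpublished, so the multiplicative default (2% in the demo, 5% for
titration abundances) is a modelling choice, not data-derived.

Not emulated: chemical baselines and detector saturation, in-source
dissociation of the complex, arrival-time distributions of co-drifting
conformer families (per-charge mean CCS only), isotope structure, vendor
file formats. Passing tests therefore demonstrate correctness of the
estimators under the stated noise models, not robustness to every
instrument artifact.

The demo panel (`workflow.demo_panel_truth`) is five synthetic homologs
with lags 0.5–10 h spanning the range reported across curli homologs, with
dimer fraction increasing and normalized dimer CCS decreasing monotonically
in lag; it encodes the qualitative biological claim (slow aggregators ⇒
more dimer, more compact dimers) so the correlation stage has a known sign
to recover. The demo titration ground truth is 416 µM, the affinity scale
of the α-synuclein–CsgA complex. The demo sequences are constructed
curli-like repeat proteins (labelled `synthetic-curli-*`), not real CsgA
sequences.

## Problem sizes

Default analyses are intentionally small: spectra of ~32k grid points,
panels of 5 homologs × 3 replicates, 6-replicate titrations, 8-calibrant
mobility fits. The full test suite, including the 10⁴-sequence motif
oracle and the Monte-Carlo noise checks, completes in a few seconds on one
CPU.

## Known limitations

- Only the 1:1 binding model is implemented (no 2:1 or cooperative
  binding; no in-source-dissociation correction), matching the observed
  complex stoichiometry.
- % dimer uses areas summed over charge states with no per-charge
  correction; whether heights or areas, and which charge states, best
  match any particular published value is unknowable without the raw
  spectra.
- The printed panel average for the replicate Kd set it ships as a worked
  example (435.8 ± 94.5 µM from five replicates) is the plain arithmetic
  summary; no weighting scheme is applied.
- Correlations are reported without p-values: homolog panels of n ≈ 5 are
  far too small for hypothesis testing.
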
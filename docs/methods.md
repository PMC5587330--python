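# Methods

## Forward model of the bench circuit

The circuit is a closed extracorporeal loop: pump → upstream ("mixed
venous") mixing chamber → up to five parallel membrane oxygenators plus
shunt tubes → downstream ("arterial") mixing chamber → pump. Each
oxygenator is treated as a single ideal compartment: the outlet perfusate is
in complete diffusion equilibrium with the sweep gas, and the sweep gas
enters free of inert gas (open sweep circuit, full washout). Under those
assumptions the steady-state retention of a gas with Ostwald partition
coefficient λ in a unit ventilated at V and perfused at Q is the Farhi
relation

    r(λ, V/Q) = λ / (λ + V/Q),

exactly 1 for an unventilated unit. The circuit retention is the
perfusion-weighted mixture of the unit outlets plus the shunted fraction:

    R_j = q_s + Σ_i q_i · λ_j / (λ_j + V_i/Q_i),

where q_s is the shunt-flow fraction and q_i the perfusate-flow fraction of
unit i. The preset ("reference") shunt is measured flow arithmetic:
shunted flow over total flow; a unit with zero sweep flow counts as shunt.
Bypassing k of 5 equal-flow units therefore presets shunt k/5 exactly.

Pressures are carried in arbitrary consistent units — only retention ratios
enter the inversion. For synthetic samples with realistic absolute levels,
the closed-circuit steady state balances continuous infusion against
elimination, giving upstream level ∝ infusion_rate / (total_flow · (1 −
R_j)). A full-shunt circuit (every unit bypassed) has no elimination path
and no steady state; the generator refuses it, while the plain flow
arithmetic still handles it.

Not modelled: equilibration transients (every sample is at steady state),
temperature dependence of λ, heat exchange, O₂/CO₂ transfer, inert-gas loss
through tubing. Deviations from ideal-compartment behaviour are the job of
the noise model, not the physics.

## Gas panels

The classical six-gas panel (SF6, krypton, desflurane, enflurane, diethyl
ether, acetone) spans more than four decades of λ. Published λ values for
the specific bench perfusates are not available, so the package ships
literature-typical defaults at ~38 °C in a versioned data file
(`src/migetsim/data/gas_panels.yaml`):

| gas | blood | saline |
|-----|-------|--------|
| SF6 | 0.0055 | 0.005 |
| KR  | 0.045 | 0.06 |
| DES | 0.45 | 0.225 |
| ENF | 1.9 | 0.78 |
| DEE | 12.0 | 13.0 |
| AC  | 300.0 | 330.0 |

Every coefficient is overridable per experiment. This is deliberate: the
pipeline's correctness is established by forward–inverse *consistency*,
which holds for any strictly ordered, consistent panel; absolute λ accuracy
matters only when comparing against externally measured retentions.

## Inversion

Retentions are converted to a perfusion distribution over a fixed V/Q grid:
compartment 0 at V/Q = 0 (shunt) and 49 log-spaced compartments on
[0.005, 100] by default. Grid bounds follow conventional MIGET practice;
the published analysis states only the compartment count (50) and the shunt
definition. The grid endpoints are pinned exactly to the configured bounds
so that log-spacing round-off cannot push the lowest ventilated compartment
below the shunt threshold.

The solve minimises

    ‖W (R − A q)‖² + Z ‖D q‖²   s.t.  q ≥ 0,  Σ q = 1,

with kernel A[j,k] = λ_j/(λ_j + vq_k), per-gas residual weights W (default
uniform 1.0, which keeps the reported RSS directly comparable across
samples), and D taking second differences over the ventilated compartments
only — shunt is a genuine point mass at V/Q = 0 and must not be penalised
against its neighbours. The unit-sum constraint is enforced by appending a
row weighted at 100 × max(W), followed by exact renormalisation; this keeps
the solver a single `scipy.optimize.nnls` call while guaranteeing a
probability vector. If NNLS hits its iteration limit the fit falls back to
a bounded least-squares solve and is flagged `converged=False` rather than
raising.

Reported quantities per sample:

* **MM-S (derived shunt)** — recovered perfusion summed over compartments
  with V/Q strictly below 0.005 (with the default grid, exactly the V/Q = 0
  compartment; a compartment sitting exactly at 0.005 is excluded).
* **RSS** — the *unweighted* Σ_j (R_j − Â_j q)² on the normalised solution,
  on the [0, 1] retention scale. Instrument software conventionally weights
  residuals by inverse measurement SD before summing, which inflates RSS by
  roughly the squared inverse SD; published RSS quality figures (counts
  below 5 and 10) are therefore on a different scale and are not
  numerically comparable to this package's RSS. `rss_quality` computes
  below-threshold fractions for any chosen thresholds.

### Smoothing weight

The default enforced-smoothing weight is Z = 40, the conventional MIGET
choice, exposed in config and logged on every inversion. Two consequences
worth knowing:

* With six gases and fifty compartments the system is underdetermined, so
  smoothing (not the data) selects among near-exact fits. At Z = 40 the
  noiseless round trip on the bench configurations recovers preset shunt
  within 0.017 (worst case, k = 1) at RSS ≈ 1e-4–3e-3.
* Forward–inverse *consistency* of the kernel and solver is a separate
  question from regularisation policy, and is assessed with Z = 0: there
  the noiseless round trip recovers shunt within 2e-4 at RSS below 4e-7 for
  every preset setting. The consistency tests in the suite use Z = 0 for
  this reason; all noisy-pipeline results use the default Z = 40.

Increasing Z never decreases RSS (regularisation trades fit for
smoothness); this monotonicity is asserted in the tests. Retentions outside
[0, 1] are clipped before solving, with a warning.

### Numerical cross-check

On small grids (≤ 6 compartments) the production solver is verified against
an exact brute-force oracle: exhaustive enumeration of all 2ⁿ−1 support
sets, each solved through its sum-constrained KKT system; the best feasible
face solution is the exact global optimum of the constrained problem.
(A dense grid search over the probability simplex — the more obvious
brute-force oracle — cannot certify 1e-3 per-fraction agreement here: the
kernel's adjacent columns are nearly collinear, the objective has flat
valleys, and nested grid refinement stalls far from the optimum.) Observed
agreement: ≤ 5e-5 per fraction over random retention vectors.

## Synthetic studies

`StudyDesign` defaults reproduce the bench experiment's structure: settings
{0, 0.2, 0.4, 0.6, 0.8} (k of 5 units bypassed), 2 duplicates per setting,
both perfusates, visited in seeded-random order (order does not affect a
steady-state model but is recorded for fidelity). Two error sources:

* **flow-meter error** (default 1% relative SD, the stated meter accuracy):
  each "measured" flow is the true flow × Normal(1, 0.01); the reference
  shunt IVLM-S is computed from measured flows, as on the bench, while the
  physics uses true flows.
* **retention noise** (default 2% relative SD): multiplicative
  Normal(1, 0.02) per gas and duplicate, clipped to [0, 1]. No published
  retention-error model exists; 2% is chosen as a plausible aggregate of
  sampling and spectrometry error such that the synthetic study lands in
  the neighbourhood of the bench agreement statistics, and it is a plain
  config knob, not hard-coded.

What the generator does *not* emulate: hematocrit effects beyond the λ
panel switch, inert-gas loss through tubing, temperature drift, handling
and sampling errors, or any systematic instrument bias. Passing synthetic
tests therefore demonstrates that the *pipeline* is self-consistent and
robust to the modelled noise — not that a physical instrument would achieve
the same agreement. Notably, the synthetic study at default noise gives
slopes ≈ 0.98–1.0 and |bias| ≲ 0.02, tighter than the bench study's
published slope 0.87 / bias −0.085 (blood); the residual gap is exactly the
un-modelled systematic error discussed above, and the published values are
bracketed only loosely (slope within [0.85, 1.05], |bias| < 0.06 over
seeds).

## Agreement statistics

* **Regression**: OLS of MM-S on IVLM-S (statsmodels), duplicates entering
  as individual points.
* **Bland–Altman**: differences d = MM-S − IVLM-S (negative bias reads as
  MIGET underestimating the reference), limits of agreement at bias ±
  2·SD — exactly 2, not 1.96, matching the study convention.
* **Duplicate CV**: per-setting SD/mean of duplicate MM-S values, settings
  with duplicate mean below 0.01 excluded (CV diverges at zero shunt),
  pooled as the root mean square of per-setting CVs and reported in
  percent. The pooling rule and floor are explicit, configurable choices:
  no single convention reproduces published overall CVs exactly, since the
  original pooling is unstated.

## Re-analysis of the deposited bench data

`read_s1_csv` ingests a CSV export of the deposited bench dataset through a
configurable column mapping (the export layout is not standardised), and
`migetsim validate --s1-mapping` runs the agreement stage on it. The
dataset itself is not redistributed with the package; the corresponding
test in `tests/test_acceptance.py` requires it at `data/s1/s1_pairs.csv`
and fails in its absence.

## Interchange and reproducibility

All tables are plain CSV written with 6 significant digits (documented
round-trip precision); configs are YAML layered over package defaults.
Every CLI command writes a `manifest.yaml` (command, package version, full
config including seed) alongside its outputs, sufficient to regenerate them
bit-identically. All randomness flows from a single `numpy` generator
seeded by the design seed.

## Problem sizes in the test suite

Desk-scale throughout: round trips use the five bench configurations;
oracle equivalence uses 20 random retention vectors on 3–6-compartment
grids; noise-model checks use 1000 duplicates of one setting; the pipeline
sweeps use 20 seeds per condition (each study = 10 samples per perfusate).
The full suite runs in a few seconds on one core.

## Known limitations

* Retention-only inversion: with no excretion data the ventilation
  distribution and deadspace are not identifiable and are not reported.
* The exact compartment bounds, weighting and smoothing weight of the
  original instrument software are unreported; numerical equality with its
  per-sample shunt values is not expected, only statistical agreement.
* The RSS scale differs from instrument-weighted RSS (see above).
* λ defaults are literature values, not measured for the specific
  perfusates.
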
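# Methods

## Model and assumptions

The package implements two-stage (Dorfman) pooled screening for
quantitative chemical conformity testing. Its assumptions:

- **Independent conformity.** Each sample conforms to the limit
  independently with probability q (the qualification rate). The
  expected-workload formula N/n = (1 − q^K) + 1/K counts one pooled
  test per group plus K confirmations whenever the group is flagged,
  and treats stage-2 confirmations as definitive.
- **Negligible analytic false positives at stage 1.** For intentional
  additives (plasticizers are dosed at percent levels), the
  probability that measurement scatter alone pushes an all-conforming
  pool past the decision limit is far below q^K and is dropped from
  the closed form. The simulator measures it instead of assuming it.
- **Worst-case attribution.** A pooled result cannot localize the
  analyte, so the verdict assumes it all came from the lightest
  sub-sample: W_max = c·V·D/m_min. This makes the pooled pass
  decision conservative by construction — with exact measurement the
  false-negative rate is structurally zero, which the test suite
  asserts.
- **Uncertainty guard band.** The limit is shrunk to
  L_cor = L·(1 − U_rel/100)/I before comparison, so a pool passes only
  when even a worst-case-attributed, worst-case-biased measurement
  would conform. U_rel is the relative expanded uncertainty (coverage
  factor k = 2 ≈ 95 %) and, for sum limits, the maximum over member
  analytes. The alternative algebraic reading L·(1 − U_rel/(100·I)) is
  available as `mode="divide_uncertainty"` on `corrected_limit` and
  `judge_pool`; the default was chosen for consistency with the
  placement of I in the K_max budget, and note that under the default
  the per-analyte comparison already implies the sum bound
  (I·L_cor = L·(1 − U_rel/100)).

## Parameters that matter

| Parameter | Units | Default | Why |
|---|---|---|---|
| q | fraction | user input | Expected qualification rate; pooling refused below 0.70, where no K saves work |
| F (safety factor) | – | 0.8 | Empirical headroom for inter-laboratory variability; enters the K_max numerator |
| K cap | samples | 10 | Practical homogenization/handling bound on group size |
| k (coverage factor) | – | 2 | ~95 % expanded uncertainty under normality |
| nominal sub-sample mass | g | 0.1 | Routine weighing target; masses outside ±10 % are flagged because unequal masses inflate W_max through m_min |
| extract volume | mL/g | 25 | Solvent volume per gram of pooled sample in the bundled workflow |

Uncertainty budgets combine five relative components (mass, volume,
standard solution, recovery, precision) in quadrature; further sources
can be folded in via `extra`. Full precision is kept internally;
percentages round to 1 dp and workload cells to 3 dp only at report
time, using round-half-up to match how laboratory tables are printed.

## Numerical choices

- K_opt is found by exhaustive search over an integer range (default
  [2, 100]); ties break toward the smaller K, which puts fewer samples
  at risk per retest round. The range upper bound is far past the
  workload optimum for any q ≥ 0.7.
- K_max floors its ratio; an epsilon of 1e-9 is added before flooring
  so exact-integer ratios are not floored down by float representation.
- A plan with 2 ≤ K_max ≤ 3 carries a warning: the sensitivity margin
  is thin and conservative practice may prefer individual testing.
  (The three-substance worked scenario — DNOP/DINP/DIDP with a
  65 mg/kg worst LOQ — computes K_max = 3 and is exactly such a case.)
- W_max = L_cor passes (inclusive comparison).
- Degenerate inputs: empty pools, K < 2, non-positive masses/limits
  and uncertainties ≥ 100 % raise validation errors naming the field.

## Simulation design

The Monte-Carlo module verifies a design end to end rather than the
formulas in isolation: draw true concentrations, pool, measure with
noise, judge, retest flagged pools, and count.

**Concentration model.** Non-conforming samples (probability 1 − q)
draw uniformly from 10 000–300 000 mg/kg — plasticizers are
intentional additives at 1–30 % w/w, so non-conformity means gross
presence, not marginal exceedance. Conforming samples are exact
zeros, with an optional mixture fraction drawing 50–100 mg/kg to
model low-level carry-over. That mixture exists to probe the known
failure mode of worst-case attribution: many individually-conforming
low-level members can push W_max past L_cor and force unnecessary
retests, which the suite asserts as a directional property.

**Noise model.** The analysis only specifies an expanded uncertainty,
not a distribution, so measured pooled concentrations default to
c·(1 + ε) with ε ~ Normal(0, u_rel/100) clipped at −1 (concentrations
stay nonnegative); a lognormal family with matched relative SD is
available. u_rel here is the *standard* relative uncertainty
(U_rel/k).

**Censoring.** When enabled, a pooled measurement whose implied
mass-weighted mean sample concentration c·V·D/m_total falls below the
method LOQ reports as zero. This is the mechanism by which oversized
groups (K > K_max) produce false negatives, and the suite demonstrates
exactly that.

**Bookkeeping.** Batches split into ⌊n/K⌋ pools; the n mod K
remainder is tested individually by default (a short-pool mode
exists). Stage-2 retests are error-free by default, matching the
workload formula's accounting; a noisy-retest mode exists but is off.
False positives are counted per all-conforming pool sent to retest;
false negatives per non-conforming sample cleared. Repetition means
are reported with normal-approximation 95 % CI half-widths.

**Problem sizes.** Verification runs use batches of 10⁵ samples and
20–50 repetitions, which pins tests-per-sample to ±0.001 at 3
Monte-Carlo standard errors — tight enough to separate adjacent
quick-reference cells. Unit-level checks use batches of 2 000–20 000.

## What the synthetic generator does not emulate

Real screening streams have serially correlated non-conformity
(products arrive in lots from shared suppliers), matrix-dependent
recovery, and a continuous spectrum of intermediate concentrations.
The generator draws i.i.d. samples with a two-(or three-)component
concentration mixture and applies a single relative noise scale.
Passing simulations therefore validate the model's internal
consistency — workload arithmetic, conservatism of the worst-case
bound, sensitivity bookkeeping — not field performance on any
particular product stream. Estimating q itself from historical data
is out of scope; it is a user-supplied input.

## Known limitations and discrepancies

- The marginal three-substance scenario is reported by the formula as
  K_max = 3, while conservative practice (and the source validation
  study of this workflow) treats such a case as not applicable and
  tests individually. The planner computes the value and attaches the
  thin-margin warning rather than silently refusing.
- Published reference tables for the routine seven-phthalate method
  are reproduced with F = 1 as K_max = 18 (per-substance limit, I = 1)
  and K_max = 4 (four-substance sum, I = 4); reports elsewhere that
  transpose these two values against I are a labeling slip, and the
  package does not reproduce the transposition.
- The bundled spiked-pool validation fixtures aggregate each pool's
  blank portion into one sub-sample because per-portion blank masses
  were not recorded; this reconstruction makes m_min the positive
  portion's mass and reproduces the published reference rows within
  ±1 mg/kg (the published rows mix rounding and truncation).
- Strictly two-stage Dorfman pooling only: no array, matrix, or
  multi-stage schemes.
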
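# Methods

This note documents the model implemented in `carestrat`, the choices
made where the design was genuinely open, the numerics, and the limits
of what the synthetic experiments can show.

## Decision model

A hospital chooses one treatment plan per patient per condition over a
decision period (the packaged examples use three months). Uncertainty —
in plan costs and in each plan's mean readmission probability — is
represented by a finite scenario set Ω with weights p(ω) summing to 1;
the packaged generator uses equal weights, as no experiment here calls
for unequal ones. The objective is the scenario-expected treatment cost
plus an expected-penalty term, and each condition carries a chance
constraint: the per-patient average of the selected plans' readmission
probabilities must stay below the target θ_c with confidence β_c.

### Deterministic equivalent

The realized readmission probability of a selected plan is modelled as
Gaussian with mean μ̂ and variance λ_c·μ̂, independent across patients.
Writing m = Σ_p μ̂ for the selected mean-sum, the selected total is
N(m, λ_c·m), so the chance constraint is equivalent to the deterministic
cap m ≤ μ*_c, with μ*_c the unique positive root of

    θ_c|P_c| − μ* = sqrt(λ_c μ*)·Φ⁻¹(β_c).

Substituting s = √μ* gives s² + √λ_c·z·s − θ_c|P_c| = 0 whose two roots
have product −θ_c|P_c| < 0; exactly one is positive, so the closed form
is unambiguous. The implementation also carries a bracketed Brent
root-finder used as a consistency check (agreement to 1e-10 relative),
and a Monte-Carlo oracle that simulates the *untruncated* Gaussian model
exactly as the derivation assumes and verifies the coverage of boundary
selections. At β = 0.5 the cap equals θ_c|P_c| exactly; β < 0.5 is
supported (the closed form remains valid) although practical use ranges
over 50–98%.

Two notational points are resolved deliberately. The variance scale λ_c
is used exactly as a variance multiplier (variance = λ_c·μ̂), which is
what makes the standardization in the equivalence argument correct, even
though the quantity is conventionally *named* a coefficient of
variation. And the cap constraint's coefficients are the scenario's
realized means μ̂ — the only reading under which the equivalence holds
per scenario.

## Scenario generator

The generator defines the study conditions and is not a tuning surface.
Per (condition, scenario):

* **Patient baselines.** Each patient draws a baseline readmission rate
  from a Gaussian centred on the hospital's condition mean μ_c with
  coefficient of variation λ_c (sd = λ_c·μ_c, default λ_c = 0.25),
  resampled into (0.001, 0.999). The CV parameterization is the
  package's choice: with the variance-scale reading (sd = √(λ μ) ≈ 0.23
  at μ ≈ 0.21) truncation would bias the baseline mean upward by ~0.07
  and patient baselines would no longer track the hospital's observed
  rate, defeating the generator's purpose. The chance-constraint
  machinery itself keeps variance = λ·μ̂ throughout.
* **Tier structure.** Each plan's mean μ̂ is the baseline times a
  multiplier drawn uniformly per (patient, plan) from its tier's range —
  defaults Tier 1 (0.4, 0.7), Tier 2 (0.7, 1.0), Tier 3 (1.0, 1.3) —
  then clipped into the probability bounds. The ranges are a design
  choice (no published distribution links plans to baselines); they
  anchor Tier 2 at roughly the hospital's current practice, make Tier 1
  a genuine improvement and Tier 3 mildly worse, and are configurable.
* **Costs.** Plan costs are i.i.d. draws from the condition's triangular
  distribution (the min/mode/max triples of the packaged instances come
  from published fair-price ranges), sorted descending across the plan
  index so Tier 1 is most expensive. Sorting realizes the
  cost-vs-effectiveness anti-correlation without inventing a joint
  distribution.
* **Reproducibility.** One named substream per (condition index,
  scenario index) derives from the single seed, so appending conditions
  or scenarios never reshuffles existing draws.

The scenario count is sized by the standard precision bound
n > (z_{α/2})² s²/ε². With the reported pilot variances ($156,721.15 and
$81,246.64 over 25 scenarios), 99% confidence and ε = $150, the bound
gives 47 and 24; the experiments use 50 scenarios throughout. The pilot
draws behind those variances are treated as given inputs, not
reproduced.

What the generator does **not** emulate: correlation across conditions
or across patients, risk adjustment, cost–effectiveness correlation
beyond the tier ordering, and any real hospital's plan menu. Passing
tests therefore demonstrate correctness of the optimization and the
qualitative cost/readmission trade-off, not calibrated dollar
predictions for a specific hospital.

## Solver

The model decomposes exactly into independent (condition, scenario)
cells — the objective is separable and no constraint couples cells — and
each cell is a multiple-choice knapsack (MCKP): one plan per patient,
minimize cost, subject to Σ μ̂ ≤ μ*_c. Cells are solved exactly:

1. Shortcuts: if the per-patient cheapest plans meet the cap the cell is
   unconstrained; if even the per-patient minimum μ̂ sum exceeds it the
   cell is infeasible (reported with its violating margin — and used
   as the necessary-and-sufficient screen in the β* feasibility search,
   which therefore needs no solves).
2. Otherwise a branch and bound: per-patient dominance pruning, a
   Lagrangian dual bound by bisection on the multiplier with a greedy
   slack-filling incumbent, reduction to the core of plans whose
   reduced-cost excess is below the duality gap, then depth-first search
   with the convex-hull LP bound, branching on the LP's single
   fractional patient. On the packaged instances (≤ 132 patients × 10
   plans) cells solve in ~1 ms.
3. A MILP backend (HiGHS through `scipy.optimize.milp`) serves as
   fallback if the search exceeds its node budget and as an independent
   cross-check in the tests. The MILP gap is pinned to zero: the
   default relative gap accepts provably suboptimal incumbents.

Tolerances: the knapsack cap is enforced to 1e-9 absolute; search
pruning uses 1e-9 relative to the incumbent (below that, alternative
optima are floating-point plateaus). Among cost-optimal assignments ties
break toward low plan indices; the refinement solve that enforces this
runs on small instances and whenever exact cost duplicates exist — at
production scale costs are continuous draws and ties have probability
zero.

## Economics

The expected penalty is EP(β) = Σ_c (1−β_c)·R_c·Penalty with cost shares
R_c = |P_c|ā_c / Σ|P_ĉ|ā_ĉ and ā_c the analytic triangular mean
(min+mode+max)/3 — the penalty model is defined on the hospital's cost
model, not on a particular draw. Baselines are Σ|P_c|ā_c (no policy) and
that plus the full annual penalty. The annual penalty passes through
unprorated to the decision period: no proration rule is published, and
keeping the figure annual makes EP directly comparable with the annual
baseline. The packaged dollar penalties are assumptions — only
percentage penalties (1.35% and 0.2%) are published for the example
hospitals — set at $620,000 for hospital A (consistent with the ~$0.62M
gap between its published with- and without-penalty cost levels) and
$49,000 for hospital B (A's figure scaled by the penalty percentages and
the baseline-cost ratio).

Reported summaries: the scenario-averaged mean readmission rate is
normalized per patient (divide by |P_c|) so it is directly comparable
with θ_c and the hospitals' observed rates; the raw mean-sum is exposed
as an auxiliary quantity. Tier shares are scenario-probability-weighted
percentages of patients per tier and sum to 100 per condition.
Single-condition sweeps hold the other conditions at their highest
feasible grid level by default, configurable.

## Target validation

The penalty rule compares a hospital's excess readmission ratio (ERR) to
its peer group's *median*; the optimization model targets the peer
group's *mean readmission probability*, which maps onto treatment
decisions. The validation module labels each (peer group, condition)
stratum record with actual = ERR > stratum median and predicted =
probability > stratum mean — strict inequalities, so a hospital exactly
at the threshold is not penalized — pools per peer group, and reports
confusion-matrix accuracy and misclassification (which sum to 100% by
construction). Flags are computed per (group, condition) and pooled per
group; the stratum mean is unweighted by default with a case-weighted
option. Strata with fewer than two records are excluded and flagged.

Reproducing the published per-peer-group accuracies requires the actual
public supplemental file; the module reads that CSV layout directly and
otherwise ships a synthetic generator (lognormal ERR around 1, Gaussian
copula with correlation ρ to the readmission probability, mapped
affinely into a plausible range). Note that even at ρ = 1 a mean-based
and a median-based split need not select identical records in finite
samples; the perfect-concordance check therefore uses a symmetric
fixture (evenly spaced ERRs, probability affine in ERR) where mean and
median splits provably coincide.

## Problem sizes used in the shipped experiments

Both packaged hospitals are solved with 50 scenarios over the default
confidence grid 0.50–0.95 in steps of 0.05 plus 0.98. The Monte-Carlo
equivalence checks use 200,000 draws per configuration (MC standard
error ~0.0009 at β = 0.8); the generator's distributional checks use
2,000 scenarios of a single small condition; the synthetic validation
tables use 2,000 hospitals. Exactness of the assignment solver is
checked against exhaustive enumeration on hundreds of small random
instances and against the proven-optimal MILP on medium ones.

## Known limitations

* Single-period model: no multi-year performance window, no dynamics.
* No coupling constraints (shared budgets or staff across conditions).
* The Gaussian response model admits values outside [0, 1]; the
  equivalence is exact for the model, and the generator's truncation
  (realism) is deliberately *not* applied inside the coverage oracle.
  The discrepancy is negligible at the parameter ranges used.
* ERR risk-adjustment internals are out of scope; ERR values are inputs.
* β* is defined per-scenario (every scenario must be feasible), the
  conservative reading; an average-case variant would be laxer.
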
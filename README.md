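# carestrat

Chance-constrained care-strategy optimization for hospitals operating
under readmission-penalty programs.

## The problem

Under the U.S. Hospital Readmission Reduction Program (HRRP), CMS
penalizes hospitals whose 30-day readmission performance for six
conditions (AMI, PN, HF, HK, COPD, CABG) is worse than their peer
group's. A hospital that wants to avoid the penalty must decide, for
every patient of every condition, which treatment plan to fund.
Effective plans (Tier 1: transition coaches, intensive follow-up) cost
more and lower the readmission probability; cheap plans (Tier 3:
medication reconciliation) cost less and lower it little — and even
then, every patient's response is uncertain.

`carestrat` is a decision-support tool for healthcare operations teams
that formalizes this trade-off as a scenario-based stochastic program
with probabilistic constraints, and solves it exactly.

## The model

For condition *c*, patients *p* ∈ *P_c*, plans *k* ∈ *K_c* and scenarios
ω with probabilities *p*(ω), choose binary assignments *x_pkc*(ω) (one
plan per patient) minimizing

```
min  Σ_ω p(ω) Σ_c Σ_p Σ_k a_pkc(ω) x_pkc(ω)  +  EP(β)
```

subject to, for each condition and scenario, the chance constraint

```
P( Σ_p Σ_k μ_pkc(ω) x_pkc(ω) / |P_c|  ≤  θ_c )  ≥  β_c ,
```

where θ_c is the target rate (the peer-group mean), β_c a hospital-chosen
confidence level, and each selected plan's realized readmission
probability is Gaussian, μ ~ N(μ̂, λ_c μ̂). Because the variance of the
selected sum is λ_c times its mean, the chance constraint has an exact
deterministic equivalent: Σ μ̂ ≤ μ*_c, where μ*_c is the unique positive
root of

```
θ_c |P_c| − μ*  =  sqrt(λ_c μ*) · Φ⁻¹(β_c),
```

available in closed form via the quadratic in √μ*. Each (condition,
scenario) cell is then a multiple-choice knapsack, solved exactly by a
Lagrangian-core branch and bound (with a HiGHS MILP fallback). The
expected penalty EP(β) = Σ_c (1−β_c) R_c · Penalty apportions the annual
penalty by condition cost shares R_c = |P_c| ā_c / Σ |P_ĉ| ā_ĉ.

A separate module validates the use of the peer-group *mean readmission
probability* as a stand-in target for the program's *median excess
readmission ratio (ERR)* rule, via per-peer-group confusion matrices.

## Worked example

Two example hospitals ship with the package: `A`, a low performer
penalized on five of six conditions, and `B`, a high performer penalized
only on AMI.

```python
import carestrat as cs

spec = cs.example_spec("A")
scen = cs.generate_scenarios(spec, 50, cs.GeneratorSettings(seed=1))
sol = cs.solve_dem(scen, cs.BetaVector.uniform(spec, 0.8), spec)
print(f"objective  ${sol.objective:,.0f}")
print(f"treatment  ${sol.expected_treatment_cost:,.0f}")
print(f"penalty    ${sol.expected_penalty:,.0f}")
print({c: round(r, 4) for c, r in cs.mean_readmission_summary(sol, spec).items()})
```

prints

```
objective  $5,846,911
treatment  $5,722,911
penalty    $124,000
{'AMI': 0.138, 'PN': 0.14, 'HF': 0.1885, 'HK': 0.0483, 'COPD': 0.162, 'CABG': 0.1196}
```

At 80% confidence the optimal strategy costs $5.85M against a
with-penalty baseline of $7.87M, and drives AMI's expected readmission
rate to 13.8% — below both the hospital's current 21.2% and the 15.97%
peer-group target. HK, already far below its target, stays on all-Tier-3
plans at its unconstrained minimum.

The same workflow is available from the shell:

```bash
carestrat sweep --spec src/carestrat/data/hospital_a.yaml \
    --seed 1 --scenarios 50 --out out/
```

which writes `out/sweep.csv` with one row per confidence level: expected
cost, expected penalty, objective, both baselines, and per-condition
mean readmission rates and tier shares. Subcommands `generate`, `solve`
and `validate-target` cover the other stages.

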
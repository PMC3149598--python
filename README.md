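# crctdesign

Design calculations for cluster randomised controlled trials (CRCTs)
when the number of clusters is **fixed**.

Standard CRCT sample-size formulae fix the cluster size *m* and solve
for the number of clusters *k* — implicitly assuming clusters can be
added at will.  In health-service evaluations the constraint usually
runs the other way: the clusters are the midwifery teams, general
practices or villages that exist, so *k* is fixed and only recruitment
*within* clusters can grow.  Because the variance of the estimated
difference,

    var(d_C) = 2 σ² · VIF / (k·m),      VIF = 1 + ((cv²+1)·m − 1)·ρ,

approaches the floor `2σ²ρ(cv²+1)/k` as *m* grows (ρ the intra-cluster
correlation, cv the coefficient of variation of cluster sizes), some
designs are infeasible at *any* cluster size.  `crctdesign` is for the
trial statistician facing that situation.  It computes:

- **feasibility** — the check `n_I · ρ · (cv²+1) < k`, where `n_I` is
  the per-arm size under individual randomisation;
- **cluster size** — for feasible designs, the closed form
  `n_C = n_I(1−ρ) / (1 − n_I ρ (cv²+1)/k)`, rounded up to a multiple of
  *k*, with `m = n_C / k`;
- **MDD** — the minimum detectable difference at the target power as
  *m* → ∞, `d_MDD = (z_{α/2}+z_β)·√(2σ²ρ(cv²+1)/k)`; for binary
  outcomes the variance depends on the limiting proportion, so the MDD
  is the upper root of a quadratic in π₂;
- **MAP** — the maximum achievable power for a stated difference,
  `Φ(|d| / √(2σ²ρ(cv²+1)/k) − z_{α/2})`;
- an **advisor** that walks the full workflow and emits concrete
  remediation suggestions for infeasible designs; and
- a **Monte-Carlo validator** (random-intercept and beta-binomial
  generators, cluster-mean z-test) that checks the analytic power
  empirically.

Continuous and binary outcomes are supported (binary via the pooled
variance `σ² = (π₁(1−π₁)+π₂(1−π₂))/2`), with equal or unequal cluster
sizes.  See `docs/methods.md` for formulas, rounding conventions and
limitations.

## Worked example

A region has 40 midwifery teams (k = 20 per arm) and wants to raise
6-week breastfeeding rates from 40% to 50% at 80% power.  Reported ICCs
in comparable trials span 0.005–0.07:

```python
from crctdesign import EffectSpec, TestParams, advise

effect = EffectSpec.binary(0.4, 0.5)
test = TestParams(alpha=0.05, power=0.80)
print(advise(effect, test, k=20, rho=0.07).to_text())
```

```
Design: detect 40% vs 50%, alpha=0.05 (two-sided), power=80%
Clusters per arm k=20, ICC rho=0.07, cluster-size cv=0
(a) individual randomisation: n_I = 385 per arm
(b) feasibility: n_I*rho*(cv^2+1) = 26.95 >= k = 20 -> NOT feasible
(d-i) maximum achievable power: 67.5% (supremum as cluster size -> infinity)
(d-ii) minimum detectable difference: 0.12 (raw 0.1160)
suggestion [reduce_power]: power is bounded by the MAP 67.5%, a supremum never attained at finite cluster size; choose a target strictly below it
suggestion [raise_difference]: raise the target to 40% vs 52% (MDD 0.12): m = 189 per cluster
```

At ICC 0.07 the 10-point increase is undetectable at 80% power with 20
clusters per arm, full stop: power is capped at 67.5% however large the
clusters, and the smallest increase detectable at 80% power is 12
percentage points (requiring 189 per cluster).  At ICC 0.005 the same
design is comfortably feasible with 22 individuals per cluster
(n_C = 440 per arm).  The same calculations are available from the
shell:

```sh
crctdesign cluster-size --pi1 0.4 --pi2 0.5 --k 20 --icc 0.005
# n_I = 385 per arm (individual randomisation)
# n_C = 440 per arm, m = 22 per cluster, total = 880
crctdesign mdd --pi1 0.4 --k 20 --icc 0.07
# MDD = 0.12 (raw 0.115991; pi2 limits 0.2894, 0.5160)
```

Other subcommands: `feasibility`, `power`, `detectable-diff`, `map`,
`advise` (`--json` for machine output), `table1`, `grid`, `validate`
(Monte-Carlo).  Flags can be preloaded from a `key=value` config file
via `--config`; `cluster-size` exits with code 3 when the design is
infeasible.  The `examples/` scripts show the library API for the
workflow, the limit grids and the Monte-Carlo check.

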
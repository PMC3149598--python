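# Methods

## The design problem

Cluster randomised controlled trials (CRCTs) randomise intact groups —
midwifery teams, general practices, villages — rather than individuals.
Standard CRCT sample-size formulae fix the cluster size m and solve for
the number of clusters k, implicitly assuming clusters can be added at
will.  In service-delivery evaluations the opposite constraint is
typical: k is fixed by how many units exist or agree to take part, and
only the recruitment *within* each cluster can grow.  `crctdesign`
solves that inverted problem: given k, how large must clusters be — and,
when no finite cluster size suffices, what is the minimum detectable
difference (MDD) and the maximum achievable power (MAP)?

All calculations assume two equal-sized parallel arms, common variance
across arms, two-sided tests, and normal approximations throughout; for
binary outcomes the variance of a difference of proportions is the
pooled approximation `sigma^2 = (pi1(1-pi1) + pi2(1-pi2)) / 2`.

## Core formulas

With `z_a = Phi^-1(1 - alpha/2)` and `z_b = Phi^-1(power)`:

* Individual randomisation, per arm:
  `n_I = (z_a + z_b)^2 * 2 sigma^2 / d^2` (reported as `ceil(n_I)`).
* Design effect for clusters of (average) size m with intra-cluster
  correlation rho and cluster-size coefficient of variation cv:
  `VIF = 1 + ((cv^2 + 1) m - 1) rho`.
* Fixed k, solving `n_C = n_I * VIF(m)` with `m = n_C / k` gives the
  closed form

      n_C = n_I (1 - rho) / (1 - n_I rho (cv^2 + 1) / k),

  with `n_I` **unrounded**; `n_C` is then rounded up to a multiple of k.
* Precision bound: the variance of the estimated difference,
  `2 sigma^2 VIF / (k m)`, decreases in m but only to the limit
  `2 sigma^2 rho (cv^2 + 1) / k` (the m -> infinity limit of the two
  expressions above).  Hence the feasibility condition
  `n_I rho (cv^2 + 1) < k`, strictly: at equality the required cluster
  size is infinite.
* MDD at fixed power: `d_MDD = (z_a + z_b) sqrt(2 sigma^2 rho (cv^2+1)/k)`.
* MAP at fixed difference:
  `1 - beta_MAP = Phi(|d| / sqrt(2 sigma^2 rho (cv^2+1)/k) - z_a)`.
* Binary MDD: because the pooled variance depends on the unknown
  limiting proportion pi2, the MDD solves a quadratic
  `a pi2^2 + b pi2 + c = 0` with `w = rho (cv^2+1)(z_a+z_b)^2 / k`,
  `a = -(1+w)`, `b = 2 pi1 + w`, `c = w pi1 - pi1^2 (1+w)`, derived from
  the defining relation `d^2 = w (pi1(1-pi1) + pi2(1-pi2))`.  The upper
  root is the smallest detectable increase, the lower root the smallest
  detectable decrease; they bracket pi1, and by construction the MAP
  evaluated at a root equals the target power exactly.

MAP and MDD are suprema/infima over the cluster size: no finite m
attains them, which is why the advisor flags a "reduce power to the
MAP" suggestion as unattainable unless a positive safety margin is
requested.

## Numerical conventions

These conventions are load-bearing; changing any of them changes
borderline integer results.

* **Full-precision z-values.** 1.959964..., 0.841621..., never 1.96/0.84.
  Two-decimal z-values shift n_I for 40% vs 50% at 90% power from 515
  to 514, for example.
* **n_I enters the fixed-k closed form unrounded.**  Rounding it first
  changes the 40% vs 52% per-cluster size from 189 to 190.  The
  feasibility *product* shown in reports uses the rounded (integer)
  n_I — the number a reader recomputes by hand (385 x 0.005 = 1.925) —
  while the feasibility boolean and the solver guard use the unrounded
  value, which is the exact condition for the closed form's denominator
  to be positive.  The two can disagree only within one unit of the
  boundary.
* **Ceiling rounding.**  Per-arm totals round up to a multiple of k (or
  of m when solving for k).  MDD proportions are quoted rounded *up* at
  two decimal places: conservative, and the only convention consistent
  with quoting 0.14 for a raw MDD of 0.1341.
* **Equality is infeasible.**  `n_I rho (cv^2+1) = k` requires an
  infinite cluster size and raises the same structured error as the
  strictly infeasible region, carrying the full feasibility report.
* **Negative ICCs are rejected.**  The design-effect framework models
  variance inflation; rho lies in [0, 1), cv in [0, inf).
* **Binary MDD root validity.**  Only the upper root (detectable
  increase) must lie in [pi1, 1); for small baselines with large w the
  lower root legitimately falls below 0 — no decrease is then
  detectable — and is reported as-is rather than treated as an error.

## Tunable parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `alpha` | two-sided significance level | 0.05 | conventional |
| `power` | target power 1 - beta | 0.80 | conventional |
| `cv` | cluster-size coefficient of variation (SD/mean) | 0 | equal clusters unless stated |
| `power_margin` (advisor) | gap below the MAP for the reduced-power suggestion | 0 | report the bound itself; any attainable target must sit strictly below it |
| `difference_granularity` (advisor) | step for the raised-difference suggestion | 0.01 | one percentage point (binary) / 0.01 standardised units |
| grid ICC step | resolution of the reporting grids | 0.005 | package choice; fine enough to show the MAP/MDD curvature over ICC 0-0.1 |

## Monte-Carlo validator

The analytic formulas rest on normal approximations; the `simulate`
module tests them empirically rather than taking them on faith.

*Generator.*  Continuous outcomes follow a random-intercept model: a
cluster effect with variance `rho sigma^2` plus individual noise with
variance `(1-rho) sigma^2`, so the total variance is sigma^2 and the
within-cluster correlation is exactly rho.  Binary outcomes are
beta-binomial: cluster probabilities drawn from a beta with mean pi and
ICC rho on the proportion scale, then Bernoulli individuals.  A single
master seed plus per-replicate `SeedSequence(seed, r)` substreams make
every replicate reproducible independently of execution order.

*Analysis.*  Each replicate is analysed with the two-sample z-test on
cluster means, the variance estimated from the dispersion of the
cluster means — deliberately the same normal-theory variance structure
the closed forms assume, not a mixed model.  With k = 20 clusters per
arm the z critical value is slightly liberal relative to a t reference
(empirical type-I error near 0.057 rather than 0.050); this is a known
property of the normal-theory analysis at moderate k, visible in the
validator's output and within its Monte-Carlo error bands.  At k = 5
the degradation is material, which is one reason designs with fewer
than 5 clusters per arm trigger an advisory warning.

*What the simulations show — and do not.*  Agreement of empirical and
analytic power under this generator confirms the algebra and the
normal-approximation accuracy at the simulated (k, m, rho); it does not
validate the model against real trials, where cluster sizes are
informative, ICCs are estimated with error, and outcomes are not
exactly normal or beta-binomial.  Default problem sizes (2,000
replicates for power checks, 5,000 for null calibration, 400 at
m = 2,000 for the MAP ceiling) keep each check to seconds while holding
Monte-Carlo standard errors below one percentage point.

## Known inconsistencies in the published example

The breastfeeding worked example this package reproduces contains two
arithmetic slips, which the package documents but does not reproduce:

* It states that 90% power "would require 519 individuals per arm",
  yet its own feasibility arithmetic and table use 515.  The pooled
  variance approximation gives 514.9 -> **515**; 519 corresponds to an
  unpooled (Fleiss-style) variance formula that is never stated.  This
  package uses the pooled variance everywhere, hence 515.
* Its discussion says that with 15 clusters per arm and ICC 0.05 the
  achievable power for 40% vs 50% "is limited to about 62%".  The MAP
  formula with the pooled variance gives 0.6965; no variance convention
  we tried reproduces 62%.  The package reports the formula value.

## Limitations

Equal arms and equal variances only; no continuity correction, exact
binomial tests, or one-sided modes; unequal cluster sizes enter only
through the cv approximation of the design effect (an exact size-list
computation is not provided, though `cv_of_sizes` converts a planned
list to its cv); no cost-based trade-off between k and m; the
Monte-Carlo analysis model is the cluster-mean z-test, not GEE or a
mixed model.  Normal approximations degrade for small k, small m, and
proportions near 0 or 1.
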
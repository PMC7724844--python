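# Methods

## Scope and structure

`plucksim` links three layers: (i) a regression-tree analysis that finds
the lesion-prevalence cut-offs associated with changes in wean-to-finish
average daily gain (ADG) across a cohort of farrow-to-finish farms;
(ii) a deterministic weekly herd-flow + enterprise-budget model of a
728-sow farm, parameterised per lesion scenario; (iii) a Monte Carlo
risk layer with rank-correlated inputs and stochastic-dominance
comparison. The raw 56-farm cohort behind the default parameterisation
is not public; a synthetic-cohort generator reproduces its published
statistical structure so that the whole pipeline is runnable and
testable end to end.

## Synthetic cohort

Three clusters (17 / 29 / 10 farms) with cluster means ± SD for pleurisy
(3.9 ± 4.94, 7.5 ± 6.17, 38.8 ± 7.55 %) and lung scars (2.8 ± 3.32,
18.7 ± 8.34, 19.3 ± 12.1 %), ADG levels 760 / 725 / 671 g/day, and
per-cluster (min, mean, max) ranges for nine performance indicators.

* Lesions are truncated normals clipped to [0, 100] **and** to the
  cluster's side of the relevant cut-off (< 25 / ≥ 25 % pleurisy,
  < 8 / ≥ 8 % scars). The underlying location is solved numerically so
  the *post-truncation* mean equals the published cluster mean —
  truncating a normal centred on the published mean would bias the
  sample mean upward by 1–2 percentage points in the heavily truncated
  clusters.
* Performance indicators are modified-PERT draws (shape 4) on
  (min, max) with the mode solved in closed form so the distribution
  mean equals the published mean. The PERT is the one bounded unimodal
  family fully determined by the three published numbers.
* Within-cluster ADG SD is not published; the default is 20 g/day,
  comfortably below the 35 and 54 g between-cluster gaps, and
  configurable. Lesions with no published cluster structure
  (pneumonia-like lesions, abscesses, pericarditis, milk spots) use one
  cohort-wide distribution — plausible abattoir-survey levels chosen
  once — so they carry no signal about ADG by construction.
* Indicators are sampled independently within a farm; no joint
  farm-level structure is published (correlation enters separately in
  the risk layer).
* One master seed; per-cluster streams are spawned deterministically, so
  identical (spec, seed) gives byte-identical CSV output.

What passing tests on this cohort do **not** show: real farms have
correlated indicators, non-PERT marginals, measurement error in lesion
scoring, and clusters that are not cleanly separated at the cut-offs.
Tree-recovery results quantify what the method does under the published
cluster structure, not its power on arbitrary field data.

## Regression tree

Standard least-squares CART: every predictor and every midpoint between
consecutive distinct values is scanned; the split minimising the summed
within-child SSE wins, subject to both children keeping ≥ `min_leaf`
rows (default 10, so a node needs ≥ 20 rows to split — the published
"minimum of 10 farms to create a branch and/or a leaf" read as a
constraint on both). Rows with `x < threshold` go left, matching
cut-offs phrased as "< 25%" / "≥ 8%". Ties break on column order, then
lower threshold, for determinism. Growth uses no complexity pre-pruning;
all pruning is post hoc.

Cost-complexity pruning is weakest-link: per internal node
g(t) = (SSE(t) − SSE(T_t)) / (|T_t| − 1); collapsing the minimal-g nodes
repeatedly yields the nested subtree sequence with strictly increasing
penalties α. The cp table reports, per subtree, the penalty, the rpart-
style normalised cp (α / root SSE), resubstitution relative error, and
k-fold cross-validated error: fold trees are grown on the training
portion and evaluated after pruning at the geometric mean of adjacent
α values. The operating penalty is the one with least cross-validated
error (not the 1-SE rule); fold assignment is a seeded unstratified
permutation, default k = 10. `xstd` is a delta-method standard error of
the summed per-observation squared errors. Missing values and surrogate
splits are not supported.

A one-way ANOVA (equivalently the squared two-sample t test) is reported
for each retained split; zero within-group variance with distinct means
is reported as F = ∞, p = 0.

A note on recovery: across seeds the SSE-optimal root occasionally picks
scars first or places the pleurisy boundary inside the low-cluster
support (verified identical to an independent CART implementation), so
structural-recovery tests use a majority-over-seeds criterion rather
than every-seed assertions. Over 100 default cohorts: 3-leaf pruned tree
79%, pleurisy root 91%, boundary inside the cluster gap 72%, scars
second 90%, significant ANOVA at both splits 98%.

## Herd flow

Steady-state weekly operation: each week the same number of sows is
served, farrows and weans, so annual totals are 52 identical weekly
flows and week 1 equals week 52 (the model represents one representative
year of an ongoing farm, not a start-up transient).

The farrowing flow is derived from the sow reproductive cycle:
gestation 115 d + lactation 28 d + wean-to-service 5 d + re-service at
(1/farrowing rate − 1) × 21 d + 8.29 nonproductive days, giving
litters/sow/year = 365.25 / cycle. The nonproductive-days constant is
calibrated once so the benchmark scenario (farrowing rate 89.3%)
reproduces its published 2.30 litters/sow/year; the other scenarios then
land within 0.5% of their published pigs-sold figures and preserve the
published scenario ordering. Setting `litters_per_sow_year` explicitly
bypasses the cycle (farrowings/week = herd × lsy / 52).

Stage mortalities (piglet, weaner, finisher — percentages per stage) are
applied as one survival factor per stage; deaths are assumed uniform
through the stage, so pigs that die are credited half the stage's feed
and days. Replacement gilts are home-reared: annual demand = herd ×
(culling + sow mortality)/100, withdrawn from the finisher pool
(maiden gilts are carried from 24 to 32 weeks of age in the weekly
inventory). Culled sows are sold; dead sows go to disposal. Fractional
animals are permitted in flows; nothing is rounded before reporting.
Stage durations are rounded up to whole weeks for the housing inventory
only; feed and sale arithmetic uses exact days. Housing-capacity limits,
batch variability and sow parity structure are out of scope.

## Growth and feed

Gompertz growth BW(t) = W₀·exp[μ₀(1 − e^{−Dt})/D]. Each scenario is
anchored at (28 d, 7 kg) and (sale age, 110.8 kg), where sale age =
28 + (110.8 − 7)·1000/ADG days, with the asymptote fixed at 230 kg
(typical of modern genotypes; results are insensitive because only the
7–110.8 kg span is used). With the asymptote fixed the parameters have a
closed form, and the curve inversion at the 19 and 38 kg transfer
weights is likewise closed-form; anchor residuals are < 10⁻⁶ kg by
construction.

Slaughter age in whole weeks uses a ceiling rule by default (pigs are
sold in weekly batches the first week they are at or above target
weight): 760 → 24 wk, 725 → 25 wk. At 671 g/day the exact age is 26.10
weeks; ceiling gives 27 while the published age is 26 — no single
rounding rule reproduces all three published ages, so the rule is
configurable ("ceil", "nearest", "exact") and the discrepancy is
documented rather than resolved.

Feed demand is deliberately not a nutrient-requirement system (energy /
amino-acid equations and least-cost diet formulation are out of scope).
Each growing stage uses feed = a·(kg gained) + b·(pig-days): a growth
term plus a maintenance/time term. The time term is essential — the
weight spans are identical across scenarios, so a pure kg-gain model
could never make slower herds eat more total feed, which is the
dominant published effect. The (a, b) pairs for the weaner and finisher
diets are solved exactly (2 scenarios × 2 unknowns) so the 760 and
671 g/day benchmark herds reproduce their published annual tonnages;
creep and link feeds are flat per-weaned-pig allowances and sow feeds
flat per-sow-year, from the same benchmark. All coefficients live in
`FeedDemandParams` and are ordinary config values.

## Economics

The profit & loss account mirrors the published structure: two sales
lines, twelve variable-cost lines, eight fixed-cost lines; gross margin
= sales − variable costs, net profit = gross margin − fixed costs, with
per-pig (÷ pigs sold) and per-kg (÷ kg meat sold) views. Lines are
rounded to cents and totals are exact Decimal sums, so the account
identities hold to the cent for any input. The 1.5% condemnation rate is
applied to carcass kg before pricing (whole-carcass loss), which
reproduces the published meat tonnage. Default prices are calibrated
from published annual-line / quantity ratios (pork 1.6191 €/kg, cull
sows 120 €/head, feed 234–922 €/t by diet, gilts 161.91 €/head);
disposal is priced per head via representative carcass weights (4 /
22.5 / 74.4 / 230 kg) times one €/kg rate. Fixed costs are a flat
schedule shared across scenarios (the published fixed total, 665,117
€/year, is consistent only with equal loan interest in all columns, so
an apparently divergent value in one published column is treated as a
typo). Cash-flow budget, balance sheet and tax are out of scope.

## Risk analysis

Each scenario's eight biological parameters (farrowing rate, born alive,
culling, four mortalities, dressing) are modified-PERT distributions on
their published (min, mean, max) triples. Litters/sow/year is *derived*
from the sampled farrowing rate through the reproductive cycle, so it is
not an independent stochastic input at defaults. Pork and the six feed
prices are PERT triples at ±15% around the calibrated 2017 levels (the
underlying monthly 2013–2017 series is not published); one annual draw
per price per iteration, and price draws are shared across scenarios
within an iteration (common market conditions — the natural
common-random-numbers design for cross-scenario comparison). Sampling is
plain Monte Carlo, 10,000 iterations by default.

Rank correlation between the biological inputs is induced by
Iman–Conover reordering: van der Waerden scores, decorrelated and
rotated by the Cholesky factor of the target (Spearman converted to
normal-score Pearson via 2·sin(πρ/6), eigenvalue-clipped to PSD),
then each data column is rearranged to the score ranks — marginals are
preserved exactly. The default target matrix is estimated from a default
synthetic cohort (self-contained; overridable), as the real farm-record
matrix is not published. Iterations with infeasible outcomes (gilt
demand exceeding finisher output) are counted and reported, never
silently dropped; the published ranges cannot actually produce one.

Absolute simulated means/SDs are not comparable to the published risk
table — the fitted input distributions, correlation matrix and the
historical price series behind it are not published. The reproducible
properties are the mean ordering (LPLSC > LPHSC > HP), first-order
dominance of the low-lesion scenario, and the loss-probability ordering.

## Dominance

Verdicts are computed on the merged empirical grid: FOSD needs
F_A ≤ F_B everywhere (tolerance 10⁻¹²) with strict inequality somewhere
(threshold 10⁻⁹); SOSD compares running integrals of the step CDFs,
computed exactly (sum of F × grid gaps, equal to the expected shortfall
E[max(0, x − X)]) rather than by trapezoid, which would be biased on a
step function. Strict SOSD of the mid scenario over the high-pleurisy
scenario holds only in part of the seeds: the mid scenario's published
input ranges are the widest, its simulated minimum is the worst, and a
worse extreme left tail defeats the strict integral condition even when
the rest of the CDF dominates — consistent with the published minima,
where the mid scenario's minimum profit is far below the high-pleurisy
one. The implementation keeps the strict definition rather than a
"most of the distribution" relaxation.

## Problem sizes and determinism

Default runs: 56-farm cohorts, 52-week years, 10,000 Monte Carlo
iterations per scenario, 10-fold cross-validation, 20 cohort seeds for
structural-recovery summaries. The deterministic pipeline is vectorised
over iterations, so a full three-scenario risk run takes well under a
minute. Every random quantity flows from a single master seed through
spawned generator streams; identical seeds give identical outputs, and
all derived seeds stay below 2³¹.

## Known limitations

* The herd model is an expectation model: no batch-to-batch variability,
  no housing constraints, no parity effects.
* Feed coefficients are calibrated aggregates, not nutrient physiology;
  they are valid near the calibrated operating range (650–800 g/day,
  7–110.8 kg) and should be re-calibrated for other systems.
* Price levels are single-year calibrations with symmetric ±15% ranges;
  no seasonality or time-series structure.
* Lesion scenarios differ in their full biological profile, not lesions
  alone; the tree identifies association, not causation, and the
  simulated deltas inherit that caveat.
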
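# Methods

## The polling estimator

`profilepoll` implements a maximum-likelihood *profile* analysis of
under-five stunting in complex-survey data. A profile is a conjunction of
one category value per variable in a chosen covariate subset — for example
*(child > 1 year, rural residence, mother has no schooling, home delivery,
mother ≥ 145 cm)*. With survey weights `w_s`, a binary outcome
`g_s ∈ {0, 1}` (stunted / not) and the integer-coded profile `c_s` of
record `s`, the weighted empirical joint distribution of `(g, c)` has cell
masses

```
m_gc = Σ_{s : g_s = g, c_s = c} w_s
```

from which the estimator reports, for the outcome group `g = 1`:

* **conditional frequency** `P(g | c) = m_gc / Σ_g' m_g'c`,
* **coverage** of a profile `c`: `m_gc / m_g`, the weighted share of the
  outcome group that matches `c`,
* **edge** of the winning profile over the runner-up: the ratio of their
  scores under the ranking convention in force.

Some formulations normalise every mass by the size of the complete-case
sample; because that constant is shared by all cells it cancels in every
reported ratio, so `profilepoll` keeps raw weight sums (tested by a
metamorphic equivalence check).

### Two ranking conventions

The literature on this estimator is ambiguous about what the "winner" is,
and both readings are useful, so both are implemented behind one flag:

* `coverage-rank` (default): the winner is the profile with the largest
  mass *within* the stunted group — the profile covering the most stunted
  children — and the edge is the ratio of the top two coverages. This is
  the reading consistent with statements of the form "24 % of all stunted
  children are associated with the winning profile".
* `conditional-rank`: the winner maximises `P(g | c)` — the profile whose
  members are most likely to be stunted — and the edge is the ratio of the
  top two conditional probabilities.

Every result records which convention produced it. Ties are broken
lexicographically on the profile's category values and flagged; the edge is
exactly 1 iff the top two are tied.

### Support threshold

`min_cell` (default 25 unweighted records per candidate cell) excludes
thin profiles from the ranking. Without it, a single-record profile with
`P(g|c) = 1` trivially wins under `conditional-rank`. The coverage
*denominator* always includes every observed profile, so the threshold
filters candidates without redefining the outcome group.

## Subset search

All `C(n, k)` unordered k-variable subsets of the candidate set are polled
(`k = 5` by default; with the standard 11 candidates this is 462 analyses
per stratum). "Subsets" are unordered because a profile is an order-free
conjunction. Within each stratum (national = all records; otherwise one
administrative division, division labels taken from the data) the per-subset
results are ranked; the default rule is **coverage-then-edge** (coverage
descending, ties by edge descending, then lexicographic subset order), with
`edge-then-coverage` and a `coverage × log(edge)` product rule available.
Coverage ranks first because it is the primary selection criterion;
the ranking is a deterministic total order, so two runs on the same data are
byte-identical.

Complete cases are re-selected per subset (listwise deletion on exactly the
five variables entering that analysis plus HAZ), so each of the 462
analyses keeps its own maximal sample rather than sharing a single global
complete-case set. This maximises per-analysis n at the cost of slightly
different samples across subsets.

## Stunting classification and prevalence

HAZ is consumed as provided (recomputing z-scores from raw height/age
against a growth standard is out of scope). Severity follows the WHO
convention with boundary values assigned to the less severe class (strict
`<`): severe `HAZ < -3`, moderate `-3 ≤ HAZ < -2`, total = severe ∪
moderate. Weighted prevalence is `Σ w·1[outcome] / Σ w`, reported with
unweighted n per stratum; no design-effect confidence intervals are
computed (out of scope). District prevalences can be banded for mapping
into `[0, .30]`, `(.30, .40)`, `[.40, .50)`, `[.50, 1]` — the outer bands
inclusive to match their "≤ 30 %" / "≥ 50 %" labels, the middle boundaries
half-open to avoid overlap.

## Recoding conventions

* Child age: "> 1 year" means strictly more than 12 months; exactly 12
  months codes as `<=1y`.
* Education years: 0 = none, 1–5 = primary, ≥ 6 = secondary+ (standard DHS
  cut points).
* Mother's BMI: < 18.5 underweight, 18.5–25 normal, ≥ 25 overweight+.
* Mother's height: < 145 cm vs ≥ 145 cm; mother's age at birth: < 20,
  20–34, ≥ 35.
* Weights are used as-is; every downstream statistic is a ratio and hence
  invariant to a global rescale (tested to 1e-12).

## Univariate screening

Per candidate variable: weighted stunting prevalence per category plus one
Pearson chi-square test of independence on the weighted 2×K table rescaled
so its grand total equals the unweighted n. Weights shape the cell
proportions without inflating the evidence; no Rao–Scott design correction
is applied because screening is a gate into the subset search, not an
inferential endpoint. The candidate-set builder combines the p-threshold
with explicit force-inclusions (a variable can enter on policy grounds
despite a weak univariate signal) and exclusions (the stratifier is
excluded by default since polling runs within strata).

## Synthetic data generator

The generator emulates the *shape* of a DHS children's-recode extract, not
any real survey's joint distribution:

* 11 coded categorical covariates with configurable marginals. The
  defaults are illustrative values flavoured after a mid-1990s
  rural-majority Bangladesh composition (70 % rural, 60 % of mothers with
  no schooling, 75 % home deliveries); they are not estimates from data.
* Stunting from a logistic model: `logit p = logit(baseline) +
  Σ log(multiplier)` over planted profiles the record matches
  (baseline default 0.36).
* HAZ drawn conditionally on the indicator — stunted uniform on `[-5, -2)`
  (severe on `[-5, -3)` with probability `severe_fraction`, default 0.35),
  non-stunted uniform on `[-2, 2]`. The pipeline only thresholds HAZ, so
  matching the threshold semantics suffices and keeps the generator
  transparent; generated HAZ has no realistic within-class shape.
* Weights constant or lognormal (σ = 0.35 default); a two-stage structure
  (division by configurable shares → cluster → district by round-robin over
  clusters); optional MCAR missingness per covariate; optional positive
  pairwise dependence via a Gaussian copula (a shared latent normal mixed
  into each variable's latent draw), which preserves every marginal
  exactly.

Everything is reproducible from a single integer seed, and a *truth
manifest* records the planted profiles so recovery tests have ground truth.

### What the recovery study shows — and what it does not

The standard recovery scenario plants one 5-variable profile (child > 1 y,
rural, mother no education, home delivery, mother ≥ 145 cm) at risk
multiplier 3 over baseline 0.36, n = 5000, and checks that the exhaustive
search under `coverage-rank` returns exactly that subset and those values.
The planted profile sits at the *modal* category of each planted variable.
That is not a convenience: coverage-rank polling targets the most massive
cell of the stunted group, so a profile planted at rare categories is not
the coverage winner even at strongly elevated risk — prevalent-but-modest
risk combinations dominate rare-but-strong ones by construction. Passing
recovery therefore demonstrates that the search machinery finds the
coverage-optimal profile, not that polling identifies arbitrary causal risk
factors. The generator also omits several features of real DHS data
(design-informative weights correlated with covariates, spatial
autocorrelation beyond cluster labels, realistic HAZ distributions), so
passing tests on synthetic data does not certify estimates on a real
survey.

## Numerical choices

* Cell accumulation is `np.bincount` over a mixed-radix integer coding of
  the subset's categories, giving exact agreement with naive dictionary
  counting (same summation order per cell).
* Ties: relative tolerance 1e-12 on the ranking score; tied pairs get edge
  exactly 1.0.
* Degenerate inputs: fewer than two supported profiles raises an
  insufficient-support error, which the search counts and skips; an empty
  stratum yields an empty, diagnosable result rather than a crash; a
  profile never observed raises an undefined-profile error in
  `conditional_frequency`.
* Problem sizes in the test-suite and acceptance studies (n = 5000 surveys,
  20 seeds, 50 randomized oracle datasets of n ≤ 1000) were chosen as the
  smallest sizes at which the sampling error of every checked quantity is
  an order of magnitude below its assertion margin.

## Known limitations

* No design-based variance estimation (weights are used for point
  estimates only).
* Exhaustive search scales as `C(n, k)`; it is intended for candidate sets
  of roughly a dozen variables, as in its motivating application.
* Per-subset complete-case selection means two subsets' results can rest
  on slightly different samples when missingness is non-trivial.
* The chi-square screening p-values ignore the survey design and should be
  read as descriptive ordering, not inference.
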
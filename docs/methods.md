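# Methods

## Setting and model

The package derives an ordinal 0–6 risk-of-suicide/self-harm scale from
item-level screener records.  The dependent measure is a single clinician
rating of "danger to self", coded 0 (minimal) to 4 (very severe or
imminent), present on screener-type records only.  Predictors are the
screener's binary/ordinal items, restricted to those judged clinically
admissible: demographic variables (age, sex) and school-related items are
excluded by the item dictionary's `admissible` flags, because symptom and
behaviour items are preferable carriers of any age- or sex-related risk and
not all screened children attend school.  One engineered predictor is
available alongside the raw items: the Depression Symptoms Scale (DSS), the
sum of nine depression-symptom item codes.  Which nine items constitute the
DSS is configuration, not code — the shipped default is a placeholder list
`dss_01…dss_09`.

### Tree growth

The regression tree treats the 0–4 rating as an interval target and uses
its unweighted node mean as the node statistic.  A candidate split sends
`item ≤ t` left, for every item and every threshold with both children at
or above the minimum leaf size; candidates are ranked by the reduction in
the sum of squared deviations,

    ΔSSE = n_L n_R / n · (ȳ_L − ȳ_R)² ,

with ties broken lexicographically on (item code, threshold) so the ranking
is independent of record order.  For a fixed node this ordering is the
F-statistic ordering; an optional F-test significance floor with a
Bonferroni adjustment over the node's candidate pairs is available and off
by default (the default floor is simply ΔSSE > 0).  Growth is best-first:
the frontier leaf with the strongest available split is expanded until the
terminal-node budget is reached.  Defaults: 20 terminal nodes (the size of
the published tree), minimum leaf 50 (~0.08% of a 60k cohort — the size
implied by the rarest published group, chosen because small cells were an
explicit derivation concern), no depth limit.

The published derivation was analyst-guided: the analyst saw ranked split
options and sometimes chose below the top rank.  That interactivity is
replayed, not live — an override map from node id to item code forces the
choice at named nodes, and node ids are assigned in creation order so a
replay is exactly reproducible.  Binary splits only: multiway splits would
make the over-branching notion (a *sibling pair* sharing a group)
ill-defined.

### Collapse to the ordinal scale

Terminal-node mean ratings, weighted by node size, are clustered into at
most k = 7 groups.  In one dimension the optimal weighted k-means partition
is contiguous on the sorted distinct values, so the package solves the
problem exactly by dynamic programming (O(m²k) over m distinct means) —
deterministic and seed-free, unlike Lloyd iteration, which is retained only
as a test cross-check.  Labels 0…k−1 are assigned in ascending
weighted-mean order, making the labels an ordinal scale by construction.
When fewer than 7 distinct means survive, the scale simply has fewer levels
(7 is a design target, not a guarantee).

An internal node whose two terminal children fall in the same group is
over-branched: it adds tree complexity without changing anyone's scale
level.  Finalization iterates {cluster → flag → prune the deepest flagged
node → re-cluster} until no flags remain.  Each prune removes one terminal
node, so the iteration terminates in at most the initial leaf count; an
optional hook may substitute an alternative split instead of pruning.
Re-clustering is done from scratch after every prune (the conservative
reading of "repeat the process"); weights are taken to be node record
counts.

### Scoring

The finalized algorithm serializes to JSON (tree, node→group map, per-group
statistics, DSS definition, item-dictionary hash).  Scoring traverses the
tree, computing the DSS on the fly where a split references it.  Missing
items follow the package-wide policy: the default recodes a missing value
to 0 ("not exhibited" — screener items record observed problems, so absence
of evidence is coded as absence) and flags the path step as imputed; a
strict mode raises naming the item and node.  There are no surrogate
splits.  Because the rating is never a predictor, full-assessment records
score identically to screener records — the deployment case the scale
exists for.

### Evaluation

* **Concordance** C = P(score₊ > score₋) + ½ P(score₊ = score₋) by weighted
  counting over score values; equals the trapezoidal area under the
  empirical ROC over cut-points (verified as a test invariant).  The
  published validation used a multinomial-regression C whose exact
  construction is unspecified; this package's primary C is the binary
  concordance against a configurable dichotomy (default severe+ ≥ 3), with
  the understanding that published headline values are reference points,
  not bit-targets.
* **Cut-point diagnostics**: sensitivity = P(level ≥ c | outcome+),
  specificity = P(level < c | outcome−), PPV/NPV from the same weighted
  2×2; undefined cells (no positives, no flagged records) are reported as
  missing, never 0.
* **Odds ratios** vs level 0: crude 2×2 ad/bc with Wald CI on the log
  scale and a Haldane–Anscombe 0.5 correction (flagged) on zero cells; or a
  proportional-odds (cumulative-logit) model of the 0–4 rating on level
  dummies via statsmodels, for unweighted cohorts.  The default in
  `level_summary` is crude 2×2 because it is weight-aware; neither method
  reproduces the published per-level ORs exactly, whose regression
  specification is not recoverable.
* **Outcome dichotomies**: mild+ ≥ 1, moderate+ ≥ 2, severe+ ≥ 3 on the 0–4
  rating — three nested outcomes on a five-level rating whose back-computed
  prevalences (~32.5%, ~13.3%, ~2.9%) are mutually consistent.  All
  configurable.
* Reporting precision follows the published tables: percentages and ORs to
  one decimal, C to three.  The level-6/level-0 mean-risk ratio is reported
  at one decimal (inputs carry printed precision) with half-up integer
  rounding, giving 28.5 → 29.

## Synthetic cohorts

The generator emulates the derivation setting, not the instrument's
psychometrics.  Ground truth is a planted tree whose leaves carry latent
risks η; the rating is an ordered logit around η:

    P(Y ≥ j) = expit((η − θ_j) / s),  j = 1…4,

with strictly increasing thresholds θ and logistic noise scale s (s = 0
gives the deterministic threshold rule, used for exact-recovery tests; the
model gives closed-form cell probabilities for oracle checks).  Defaults
were chosen once to mirror the study conditions: n up to 60,414; ~49.8%
male; age bands ≤7 / 8–11 / ≥12 with weights (0.15, 0.33, 0.52), giving
mean age ≈ 11.8 on the 4–18 range; a five-leaf planted tree over
ideation/attempt/family-burden items plus a DSS split, with latents
(−3, −2, −0.5, 0.6, 1.5) and θ = (−1.2, 0.2, 2.2, 3.6) calibrated to ≈3%
severe+ and ≈33% mild+ prevalence, matching the prevalences implied by the
published tables.  Items not referenced by the planted tree (including the
nine DSS items) are drawn through a Gaussian copula sharing a latent
symptom factor (r = 0.2) so split ranking competes against correlated
distractors.  Optional slopes add an age trend to the latent risk and/or to
planted item prevalences for subgroup experiments.  A single seeded
generator drives everything; identical configuration and seed give
byte-identical cohort CSVs.

What the generator does *not* emulate: the real instrument's factor
structure, item reliabilities, repeated assessments of the same child, or
informative missingness.  Passing recovery tests therefore demonstrate that
the pipeline recovers planted structure under realistic marginals and
noise — not that the shipped defaults reproduce the real cohort's tree.

The published-strata fixture is data, not simulation: seven levels with
sample shares (46.3, 12.8, 14.2, 13.7, 6.6, 5.7, 0.8)%, mean ratings
(0.08, 0.30, 0.62, 0.85, 1.44, 1.74, 2.28) and severe+ fractions
(0.1, 1.1, 1.5, 3.3, 9.5, 19.5, 42.6)%, encoded as two weighted
pseudo-records per level.  Printed shares sum to 100.1%; the fixture
renormalizes to 1 and records the discrepancy.  Cut-point metrics are
functions of exactly these ingredients, so the fixture reconstructs every
printed severe-row diagnostic within input-rounding tolerance (±1
percentage point on sensitivity/specificity, ±0.2 on PPV/NPV).

## Numerical choices and degenerate inputs

Split-strength ties break lexicographically; best-first expansion ties
break on the lower node id.  The clustering DP aggregates duplicate means
before solving so boundaries never divide equal values, which guarantees
strictly increasing group means; singleton segment costs are exactly zero
(no cancellation residue).  k greater than the number of distinct means
degrades to singletons with a warning.  Conservation (child ns summing to
the parent; means combining to the parent mean within 1e-9 relative) is
asserted by a checker used in tests.  Pure nodes, empty cohorts, one-class
outcomes, zero-weight levels and empty strata all have defined behaviour
(no split / validation error / explicit error / blank row with warning /
omission with warning respectively).

## Problem sizes in tests and the acceptance script

Oracle-equivalence suites run ≥500 random instances per numeric (≤200
records × ≤5 items for split ranking; ≤40 nodes, k ≤ 7 for clustering;
n ≤ 200 for concordance).  Recovery experiments use n = 20,000 with a
4,000-record hold-out; the study-scale demonstration uses n = 60,414 with a
fresh 2,117-record validation cohort, the sizes of the original samples.
These sizes keep the whole battery to a few seconds while leaving
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The published tree's actual splits and thresholds are not public; the
  package reproduces the methodology and the printed stratum-level
  diagnostics, not Figure-level structure.
* Cumulative-logit odds ratios do not accept fractional weights (the
  underlying model has no weight support); crude 2×2 covers weighted
  fixtures.
* No cost-complexity pruning, cross-validation tree selection, multiway
  splits, or surrogate-split handling of missingness.
* The scale is decision support: no care-planning logic is included, by
  design.
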
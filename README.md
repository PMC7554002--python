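# risktree

Derivation, deployment and validation of compact ordinal risk-stratification
scales for suicide and self-harm screening in children's mental-health
services.

## The problem

Intake screeners used in children's mental-health systems collect ~100
binary/ordinal symptom and behaviour items plus a single clinician rating of
"danger to self" (0 = minimal … 4 = very severe or imminent).  The
comprehensive follow-up assessment shares most items but *not* that rating —
so services need an algorithm that predicts the clinician's risk judgement
from items available in both instruments.  `risktree` implements the
scale-construction methodology end to end:

1. **Tree growth** (`risktree.tree`) — a binary regression tree over
   clinically admissible items predicts the 0–4 rating; candidate splits
   `x ≤ t` are ranked by the reduction in the sum of squared deviations,
   ΔSSE = n_L n_R / n · (ȳ_L − ȳ_R)², best-first, with minimum-leaf,
   depth, terminal-node-budget and significance-floor stopping rules, and a
   deterministic override map replaying analyst-guided split choices.
2. **Scale collapse** (`risktree.collapse`) — terminal-node mean ratings,
   weighted by node size, are clustered into at most 7 ordered groups by
   *exact* dynamic-programming 1-D weighted k-means (optimal clusters are
   contiguous in one dimension).  Splits whose two terminal children share a
   group ("over-branched") are pruned, deepest first, and clustering is
   repeated until the tree is parsimonious.
3. **Scoring** (`risktree.scoring`) — the finalized algorithm (tree + group
   map + nine-item Depression Symptoms Scale definition) routes new records
   to levels 0–6 with a full audit path; records lacking the rating score
   identically since it is never a predictor.
4. **Evaluation** (`risktree.evaluation`) — level summaries (% of sample,
   mean rating, % severe+, odds ratios vs level 0 with Wald CIs, crude 2×2
   or cumulative-logit), concordance C = P(score₊ > score₋) + ½P(tie),
   sensitivity/specificity/PPV/NPV cut-point tables, age/sex subgroup and
   diagnosis-flag breakdowns — all weight-aware.
5. **Synthetic cohorts** (`risktree.cohort`) — planted-tree generators with
   an ordered-logit outcome model for end-to-end recovery experiments, and a
   weighted fixture encoding the published seven-stratum derivation table so
   printed diagnostics are reproducible in closed form.

## Worked example

```python
from risktree import SEVERE_PLUS, cutpoint_table, level_summary, \
    mean_risk_ratio, round_half_up, table1_fixture

frame = table1_fixture()          # published strata as weighted pseudo-records
print(cutpoint_table(frame, dichotomies=(SEVERE_PLUS,)).round(1))
summary = level_summary(frame)
print(mean_risk_ratio(summary), round_half_up(mean_risk_ratio(summary)))
```

prints

```
    outcome  cut  sensitivity  specificity  ppv  npv
severe_plus    1         98.4         47.6  5.4 99.9
severe_plus    2         93.6         60.6  6.7 99.7
severe_plus    3         86.4         75.0  9.4 99.5
severe_plus    4         70.9         88.7 15.9 99.0
28.5 29
```

Reading: dichotomizing the 0–6 scale at 3+ identifies severe-or-imminent
risk with ~86% sensitivity and ~75% specificity; the more sensitive 2+ cut
(~94%/61%) is the kind of threshold preferred when missing a high-risk child
is costlier than a false positive.  The top scale level carries ~29× the
mean clinician-rated risk of the bottom level.  The `examples/` scripts walk
through simulation, derivation, scoring with audit paths, and the full
evaluation battery; a thin CLI (`risktree simulate|fixture|derive|score|evaluate`)
wraps the same functions for shell use.

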
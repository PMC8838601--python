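# Methods

## Problem and model

A forum message either mentions an impact of disease/treatment on the
author's health-related quality of life or it does not; an impacted message
concerns one or more of five dimensions (physical, psychic, activity,
relational, financial). The classifier mirrors the two-step annotation
protocol as a *gated hierarchy*: a stage-1 binary detector for any impact,
and five stage-2 binary models evaluated only on impact-flagged messages. At
prediction time the gate is strict: if the stage-1 probability falls below
the decision threshold, every dimension flag is false and no dimension
probability is emitted.

All models consume the same fixed 25-feature inventory (lexical-field
scores, sentiment counts, grammar, conjugation, structure). The lexical
scores are the load-bearing features: counts of dimension-specific patient
expressions harvested during annotation (`build_lexicon_from_annotations`)
or shipped as fixtures. Counting is token-boundary anchored, non-overlapping
and leftmost-longest, so a lexicon holding both "mal" and "mal au dos"
scores a text containing "mal au dos" once.

## Training procedure and defaults

Per model, in order:

1. **Normalization** — median imputation then division by the per-feature
   training maximum, fit on training rows only. Imputation precedes scaling
   because the median is defined on the raw scale. Applied to unseen data,
   values may exceed 1 and are clipped back into [0, 1], keeping the
   documented unit-interval contract everywhere.
2. **Feature selection** — classic SFFS: greedily add the feature that
   maximizes mean cross-validated AUC, then repeatedly remove any already
   selected feature (never the one just added) whose removal strictly
   improves the score. Stratified 5-fold CV, ties broken by inventory order,
   stop at no improvement or `sffs_max_features` (default 6 — the planted
   signal concentrates in few features, and small subsets keep the selection
   auditable). Selection uses a lightweight boosting learner (50 rounds,
   depth 3) so the selected set reflects feature value rather than
   hyperparameter luck.
3. **Grid search** — exhaustive 5-fold CV over the boosting knobs, same
   folds for every point, ties to the first point in iteration order. The
   default grid is deliberately compact (learning rate {0.1, 0.3} × rounds
   {50, 100} × depth {2, 4}); `FULL_GRID` exposes the wide 216-point grid
   over all six knobs (learning rate, rounds, depth, min child weight, min
   split loss, L1) for users with time to spend. The compact default keeps a
   full hierarchical fit at n ≈ 1400 in the tens of seconds while losing
   essentially nothing on well-separated data.
4. **SMOTE** — applied to the rare dimensions (default activity, relational,
   financial; k = 5 neighbors, reduced when the minority is tiny). Synthetic
   rows are convex combinations of a minority row and one of its k nearest
   minority neighbors; originals are preserved verbatim and the minority is
   raised exactly to the majority count. Oversampling happens *inside* CV
   training folds only — oversampling before splitting leaks synthetic
   copies into validation folds and inflates CV AUC. When a fold's minority
   drops below 2 samples the fold trains without oversampling; fold counts
   are capped at the minority class size so every validation fold contains
   both classes.
5. **Final fit** on the full training rows (oversampled once for SMOTE
   dimensions) with the winning hyperparameters.

Stage-2 models train on the impacted-labeled subset (configurable via
`stage2_on_impacted`), matching the prediction-time gate: the dimension
model only ever scores messages the gate lets through. A dimension with
fewer than two positive (or negative) training labels is *untrainable*: its
predictions are fixed to false and the rest of the hierarchy is unaffected.
The decision threshold defaults to 0.5 and is configurable.

Determinism: a single training seed spawns per-stage seeds; folds, SMOTE
draws, and XGBoost (single-thread, `hist`) are all seeded, so identical
inputs and seed give bit-identical models and prediction files.

## Metrics

Sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), F = harmonic mean of
precision and recall (0 when both are 0; a zero denominator raises a named
error rather than silently returning 0). AUC is the Mann–Whitney pair
statistic with ties counted ½, computed from average ranks; the ROC curve
sweeps distinct scores and its trapezoidal integral equals the pair
statistic exactly. Dimension-level evaluation counts gated-out messages as
negative predictions with score 0 — the end-to-end behavior a user sees —
rather than conditioning on the gate.

Cohen's kappa is computed per label from the 2×2 table; when the expected
agreement is 1 (both raters constant and identical, e.g. a dimension absent
from the whole subset) kappa is reported as 0 by convention.

## Synthetic corpus generator

The generator emulates the statistical structure the pipeline assumes, with
defaults chosen as the study conditions: n = 1399 messages; impact
prevalence 0.58 with dimension prevalences 0.31/0.37/0.25/0.13/0.04;
lognormal message lengths matching mean 905 / SD 1041 characters; an
expected 2.0 planted expressions per positive dimension (Poisson, floored at
1 so a positive flag always has evidence); stray expressions in negative
dimensions at rate 0.02; one drug/disease dictionary term per message.

Mechanics: impact is Bernoulli(0.58); given impact, each dimension is
Bernoulli(p_dim/0.58), redrawn until at least one is positive (so impact ⇔
at least one dimension). Impacted messages open with a first-person framing
sentence and carry their planted expressions in first-person templates;
filler sentences, expression templates and the term dictionary are mutually
disjoint from the dimension lexicons by construction, so at zero noise the
lexical score of a dimension equals exactly the planted count. Texts are
emitted already normalized, making recorded spans directly indexable.

What the generator does *not* emulate: realistic French syntax and spelling
noise, dimension co-occurrence structure (dimensions are independent given
impact — only marginal prevalences are modeled; a correlation hook would
slot into the conditional draw), topic drift, thread/reply structure, and
the weak, distributed lexical evidence of real patient language. Passing
tests therefore demonstrate that the machinery recovers signal that is
present and obeys its contracts — not that real-forum performance would
match; on real text the expression lexicons are far from exhaustive and the
near-perfect synthetic scores should not be extrapolated.

The conditioning on ≥1 positive dimension inflates dimension marginals by a
factor ≈ 1.07 relative to the nominal prevalences; at n = 1399 the realized
counts remain within three binomial standard deviations of the nominal
expectations, which is the contract the tests check.

## Numerical and design choices

- Approximate term matching uses a length-scaled Levenshtein budget (0 edits
  below 5 characters, ≤1 at 5–9, ≤2 at ≥10): short names would otherwise
  false-positive pervasively; overlaps resolve leftmost-longest then
  lowest-distance, the deterministic concordancer convention.
- The 70:30 split takes `|train| = ⌊0.7·n⌋` (1399 → 979/420), unstratified
  uniform at a given seed; a stratified variant was considered and left out
  because the default corpus is large enough that label proportions are
  stable across the split.
- Deduplication is exact on normalized text — auditable, no fuzzy threshold
  to tune.
- The morphological tagger is a closed-list rule tagger (pronoun person,
  present/imparfait finite forms, infinitive list, participle suffixes).
  Suffix rules overgenerate on nouns ending in -é; counts are therefore
  noisy-but-deterministic covariates, adequate for the count-level features
  used here. The tagging contract is pluggable for a statistical tagger.
- "Who is writing" is operationalized as counts of first-person singular and
  plural pronoun tokens.
- HTML entity decoding happens once per normalization call; the function is
  idempotent except on text containing doubly-encoded entities.
- Tie-breaking everywhere (SFFS candidates, grid points, overlapping
  mentions) prefers the earlier item in a fixed documented order, making
  every pipeline stage reproducible bit-for-bit.

## Problem sizes used in the shipped checks

Unit tests run on corpora of 20–220 messages; the end-to-end check trains on
the full default study (n = 1399, 979 training / 420 validation) and the
determinism check retrains twice at n = 250; the selection-recovery check
runs 20 replicates at n = 400 with 2 informative features among 10. These
sizes were chosen so the whole suite completes in a few minutes while every
contract is exercised at, or above, the scale it is stated for.

## Known limitations

- Lexical features are literal token-sequence matches; no lemmatization or
  inflectional expansion, so lexicon coverage drives recall.
- The sentiment fixture lexicons are small open stand-ins with the same
  eight categories and file shape as a licensed psycholinguistic dictionary
  export; swap in a licensed export for real studies.
- The SVM family exposes margin scores (not calibrated probabilities) to the
  AUC computation; threshold-based flags are only meaningful for
  probability-producing families.
- Kappa utilities cover two raters and binary labels only; no weighted or
  multi-rater generalization.
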
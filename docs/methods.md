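# Methods

This note documents the statistical procedures, the synthetic-data model that
exercises them, the numerical choices made where the design was genuinely
open, and the limits of what the test suite demonstrates.

## Cohort model and weekly protocol

A cohort is a set of participants with a binary gender label (the
questionnaire instrument behind this design offered only two options — a
stated limitation, not an endorsement) observed over a contiguous window of
weeks. All indicators — mobility, network, interaction — are computed per
week and averaged per individual over the weeks in which they are defined;
undefined weeks are skipped, not zero-filled, so sparse data does not drag
averages toward zero. Participants with three active weeks or fewer are
excluded (`min_active_weeks = 4`). "Active week" is not externally defined;
here a week counts as active if the participant has at least one interaction
record in any channel or at least one location observation — the most
permissive reading. Weeks are indexed 0..N−1 from a Monday-aligned start
date, avoiding ISO-week year-boundary ambiguity.

All five channels are stored as undirected weekly graphs; calls and texts
additionally keep a directed event list (initiator, receiver, weight, call
duration), used only for initiator/duration statistics. Structural metrics
are computed on the undirected graphs.

## Effect sizes

`r = (μ_male − μ_female)/σ_p` with the n−1 pooled SD. The subsampling
protocol draws ⌊n_g/2⌋ items *without replacement* from each class,
independently across 1000 iterations, one RNG substream per indicator.
Design choices:

* **⌊n/2⌋** for odd class sizes (601 → 300): "half" with no stated rounding
  rule.
* **Significance criterion**: the central 90% percentile interval of the
  subsample distribution excluding zero. This is the only construction fully
  determined by what the source analysis displays (5/95 percentile bars and
  a two-tailed test with no named statistic). Its operating characteristics
  are worth stating plainly: with half-size sampling without replacement the
  band half-width at n = 166/601 is ≈ 1.645·√(1/165 + 1/598) ≈ 0.145, while
  a null cohort's realized effect has SD √(1/166 + 1/601) ≈ 0.088, so the
  criterion flags a true-zero effect about 10% of the time. That boundary
  (|r| ≈ 0.145) is exactly where the published significance calls flip
  (−0.149 significant; 0.143, −0.118, 0.095 not), which is strong evidence
  this is the right construction. The raw `r_samples` are exposed so stricter
  criteria can be applied downstream.

## Entropies

Location entropy uses the natural log (the defining formula writes an
unqualified log; the base is exposed and cancels in effect-size comparisons);
interaction entropy uses base 2 as its formula specifies. Zero-probability
terms contribute zero; empty distributions are missing, not zero.

## Network metrics

Degree counts all neighbors, including outside-cohort alters when present;
gender-dependent metrics (same-gender fraction, motifs) use labeled
participants only. Betweenness is the unnormalized sum over unordered pairs
of the fraction of shortest paths through a node, computed by igraph's exact
Brandes implementation and verified in the tests against a hand-written
all-pairs-BFS path-counting oracle. Triads are closed triangles only.
Weekly metrics are averaged over the weeks in which the participant has at
least one contact in the channel; a participant with no activity at all in a
channel gets missing values there, which is how channel-level data loss
reaches the imputation stage.

## Permutation null

Gender labels are permuted uniformly over nodes (counts conserved exactly),
topology fixed; ensemble size defaults to 2E. p-values use strict counting
(k/n, so p = 0 is representable); an add-one corrected mode exists but is off
by default. Dyad-level homophily is reported both as mean per-node
same-gender fraction (per gender) and as raw dyad counts, since either
reading is defensible. For triad counts the engine enumerates triangles once
and gathers labels per permutation; above 500k triangles it switches to a
trace(A_g³)/6 matrix identity for the all-female/all-male counts with
mixed = total − FFF − MMM (the two paths are verified equal in the tests).
The pipeline caps the ensemble at `min(2E, 2000)` and aggregates graphs over
4-week (monthly) windows by default; both are configuration options, chosen
to keep dense-channel runs at desk scale.

## Imputation

Features are z-standardized before the overlap distance so trait scores and
entropies contribute comparably (the distance as defined is scale-sensitive
and the source procedure is silent on scaling). Ties at the k-th neighbor
break by ascending participant id, making results independent of row order.
A feature observed by no neighbor falls back to the cohort mean with a
logged warning, guaranteeing a complete table for the classifier. A
participant comparable to no one is a hard error.

## Classification protocol

Female is the positive class. Hyperparameter grids are shipped as published;
the logistic-regression C grid prints the value 1 twice, so it is shipped as
printed plus 0.1 (the likely intent). Selection uses the same 10 stratified
folds for scoring and selection (mean held-out AUC and F1, harmonic mean);
fold aggregation is the unweighted mean. Random baselines: AUC 0.5;
F1 = prevalence p, since a classifier predicting positive with probability p
has expected precision and recall both p. Ensemble sizes default to 1000
trees and are exposed (`n_estimators`) for desk-scale runs, which use 200.

## Synthetic-data model

The generator's defaults are the study conditions:

* **166 women / 601 men, 36 weeks.**
* **Trait effects**: the published signed effect sizes (male − female,
  pooled-SD units), with unit variance in both groups so planted effects are
  exactly pooled-SD units: neuroticism −0.635, conscientiousness −0.436,
  agreeableness −0.259, extraversion −0.118, openness 0.143, stress −0.451,
  self-esteem 0.423, narcissism 0.349 (rivalry 0.334, admiration 0.241),
  locus of control −0.157, satisfaction −0.149, loneliness 0.095.
* **Channel densities**: weekly edge probability p solves
  1 − (1−p)⁴ = published monthly active-dyad fraction — proximity 0.12
  (→ 40% monthly), Facebook friendship 0.0063 (→ 2.5%), Facebook feed and
  texts 0.002 (→ 0.8%), calls 0.0015 (→ 0.6%).
* **Homophily** h per channel (same-gender dyads accepted ∝ 1+h, mixed
  ∝ 1−h): 0.20 proximity, 0.25 online, 0.15 telecom — moderate values of our
  choosing (no numeric dyadic preference is published); triad homophily
  emerges from the dyadic mechanism and is measured, never planted.
* **Call durations**: log-normal (σ = 0.8) with means 117 s (M→F),
  114.56 s (F–F), 71.52 s (M–M) as published; F→M is not published and is
  set to 95 s, between F–F and M–M, consistent with women having longer
  calls regardless of initiator.
* **Weights**: shifted Poisson per gender-pair class; texts lean female
  (FF 4, FM 2.5, MM 1.5 mean messages) to plant the reported text-volume
  difference. Poisson weights and log-normal durations are distributional
  conveniences — no forms are published.
* **Locations**: weekly support size 1 + Poisson, symmetric Dirichlet time
  fractions; female profile (12 locations, α = 1.0) vs male (10, α = 0.7)
  plants the women-higher unique-location and entropy effects.
* **Missingness**: per-category MCAR at 5% — back-solved from 21.5% of
  participants missing at least one of five channels, 1 − (1−q)⁵ = 0.215 →
  q ≈ 0.047 — applied to the raw tables (trait rows blanked; location and
  interaction rows of masked participants dropped).

One root seed is spawned into documented substreams (traits, locations,
missingness, one per channel), so each component is independently
reproducible and fixtures are byte-identical per seed.

What the generator does *not* emulate: temporal autocorrelation of edges
(weeks are independent), degree heterogeneity beyond the homophily mechanism,
gender-asymmetric homophily (h is symmetric; the real pattern of
female-homophilous online ties vs male-homophilous calls cannot be planted),
community structure from class schedules, and informative missingness.
Passing tests therefore demonstrate correctness of the estimators under the
planted model, not fidelity of any real-data finding.

A consequence worth noting: under a 78/22 imbalance the per-node same-gender
fraction separates the genders almost mechanically (≈ 0.78 for men vs ≈ 0.22
for women under random mixing), so the synthetic classification AUC
saturates near 1.0 — comfortably above the 0.75 sanity floor the tests
assert, and not comparable to real-data performance, where noise and
missingness bite harder.

## Problem sizes in tests and the acceptance script

Study-scale n (166/601) is kept wherever the claim depends on it (effect
recovery, baselines, classification floor); week counts are reduced (1–16)
and ensembles trimmed (n_perm ≤ 2E with caps, 200 trees) where volume only
adds runtime. Effect-size recovery is averaged over 8 generator seeds: a
single 166/601 cohort realizes a planted effect only to ±0.09 (one SE), so a
single-seed comparison at ±0.10 would mostly measure the cohort draw.
Oracle checks (betweenness, motifs, KNN, exhaustive permutation nulls) are
exact on small instances by construction.

## Known limitations

* The percentile significance criterion has a ~10% type-I rate by
  construction (see above); it is reported, not corrected.
* The permutation engine permutes labels only; no degree-preserving
  (configuration-model) null is provided.
* Monthly aggregation for homophily and the 2E ensemble size interact: on
  very dense channels the capped ensemble widens Monte-Carlo error on z.
* The imputer is distance-based only; no model-based (EM/MICE) alternative.
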
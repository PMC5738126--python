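# gendernet

Tools for studying **gender differences in multi-channel behavioral cohorts**:
personality questionnaires, mobility traces, and social interaction networks
(person-to-person proximity, online friendship and feed activity, calls and
texts) observed weekly over an academic year. The package targets the setting
of a heavily imbalanced university cohort (166 women, 601 men — 78% male) and
provides the statistical machinery such an analysis needs, end to end, plus a
synthetic cohort generator so every stage is testable without access to any
private participant data.

## What it computes

**Subsampled effect sizes.** Class imbalance inflates naive two-sample
statistics, so indicators are compared by drawing 1000 random half-size
subsamples without replacement from each class and computing the pooled-SD
standardized mean difference on each pair:

```
r = (μ(x_male) − μ(x_female)) / σ_p ,
σ_p² = ((n₁−1)σ²(x₁) + (n₂−1)σ²(x₂)) / (n₁ + n₂ − 2)
```

Negative r means women score higher. An indicator is *significant* when the
5–95% percentile band of the 1000 subsample values excludes zero.

**Behavioral entropies.** Location entropy `H_u = −Σ_l P_u(l) log P_u(l)`
over a participant's weekly relative time distribution across places, and
interaction entropy `S_u = −Σ_i P_u(i) log₂ P_u(i)` over the share of their
interactions going to each contact, both computed weekly and averaged.

**Permutation-null homophily tests.** On networks, subsampling would destroy
structure, so gender labels are randomly permuted over nodes (topology fixed,
gender counts conserved; default ensemble size 2E for E edges). Same-gender
neighbor fractions, dyad motifs (FF/MM/FM) and triangle motifs
(FFF/MMM/mixed) are recomputed per realization, and the observation is
summarized by `z = (x − μ(x̃))/σ(x̃)` and one-sided permutation p-values.

**Overlap-distance KNN imputation.** Participants missing more than two of
the five feature categories are removed; remaining gaps are filled from the
k = 7 nearest neighbors under the mean absolute difference over the mutually
observed features, `d_uv = (1/|L_uv|) Σ_{i∈L_uv} |x_i(u) − x_i(v)|`.

**Gender classification.** Five scikit-learn families (logistic regression,
SVC, random forest, gradient boosting, AdaBoost) tuned over their published
grids with 10-fold stratified CV, selecting by the harmonic mean of
mean-over-folds F1 (female = positive class) and ROC-AUC, reported against
imbalance-aware random baselines (AUC 0.5, F1 = prevalence ≈ 0.22) together
with random-forest feature importances.

**Synthetic cohorts.** `gendernet.synthetic_cohort` plants all of the above:
gender-shifted unit-variance trait scores, Dirichlet location profiles,
channel networks with a dyadic homophily parameter h (same-gender dyads
accepted ∝ 1+h, mixed ∝ 1−h), gender-pair call-duration means, and
per-category MCAR missingness. Defaults follow the study conditions; see
`docs/methods.md`.

## Worked example

```python
import pandas as pd
from gendernet import GeneratorConfig, generate, subsample_comparison, homophily_test

data = generate(GeneratorConfig(seed=7, n_weeks=8))   # 166 F / 601 M, study defaults
genders = pd.Series(data.cohort.genders())

xm = data.traits.loc[genders == "M", "neuroticism"]
xf = data.traits.loc[genders == "F", "neuroticism"]
dist = subsample_comparison(xm, xf, n_subsamples=1000, seed=7)
print(f"neuroticism effect size: mean r = {dist.mean_r:+.3f} "
      f"[{dist.p5:+.3f}, {dist.p95:+.3f}], significant = {dist.significant}")

graph = data.networks["proximity"].weekly_graphs[0].subgraph(data.cohort.ids)
result = homophily_test(graph, n_perm=2000, seed=7)
for name in ("dyads_FF", "triads_FFF"):
    r = result[name]
    print(f"{name}: observed = {r.observed:.0f}, z = {r.z:+.2f}, "
          f"p(greater) = {r.p_value('greater'):.4f}")
```

prints

```
neuroticism effect size: mean r = -0.622 [-0.776, -0.482], significant = True
dyads_FF: observed = 1929, z = +5.05, p(greater) = 0.0000
triads_FFF: observed = 2325, z = +6.85, p(greater) = 0.0000
```

The planted neuroticism shift of −0.635 pooled SDs is recovered with a
percentile band well clear of zero, and the planted proximity homophily
(h = 0.2) surfaces as a strong excess of female–female dyads and female-only
triangles against the permutation null.

The same stages run from the shell:

```
gendernet generate --seed 7 --out cohort/
gendernet homophily --in cohort/ --channel proximity --n-perm 2000 --seed 7 --out homophily.json
gendernet run --out rundir/        # full pipeline with a manifest
```

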
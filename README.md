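# coresig

Cohort-specific case/control expression signatures selected from a curated
pan-disease gene pool.

Many complex disorders — schizophrenia is the motivating case — have
accumulated large, poorly overlapping pools of literature-reported risk
genes. `coresig` tests whether such a pool can serve as a reusable feature
space: within each case/control brain-expression cohort it selects a small,
cohort-specific gene subset from the pool, measures how well that subset
separates cases from controls, and quantifies how stable the selected
subsets are across cohorts.

## Method

For one cohort with expression matrix restricted to the pool genes:

1. **Ranking.** Pool genes are ranked either by **SRVS** (sparse
   representation-based variable selection: the centered ±1 label vector is
   regressed on random gene subsets with an ℓ1 penalty,
   `min_w (1/2n)‖y − Zw‖² + λ‖w‖₁`, and each gene's score is its mean
   absolute coefficient over the subsets that contained it; descending
   order) or by per-gene one-way **ANOVA** between the two classes
   (`F = MS_between / MS_within` with (1, N−2) d.f.; ascending p).
2. **Classification.** For n = 1, 2, …, the top-n gene vector is scored by
   Euclidean nearest-centroid classification under leave-one-out (LOO)
   cross-validation, with per-fold training-set z-scoring. The
   classification ratio is `CR = #correct / #total`, and the best
   classifier is the smallest n attaining the maximum CR.
3. **Significance.** A gene-set permutation test draws random same-size
   gene sets from the measured genes and reports
   `p = #(CR_random ≥ CR_observed) / runs` (default 5,000 runs; zero
   counts are reported as `< 1/runs`). Random-gene baseline curves
   (mean CR of 300 random n-gene sets) give the chance-level reference.
4. **Cross-study comparison.** Selected gene sets from every
   (cohort, method) pair are compared by Jaccard similarity
   (`|A∩B| / |A∪B|`, diagonal zeroed); cohort factors (brain region,
   ethnicity, method) are tested against the similarity values with a
   main-effects N-way ANOVA (sequential Type-I sums of squares); and
   per-cohort CRs are aggregated into cross-study means/SDs with Welch
   t-tests between methods.

A fully seeded synthetic-data module generates cohorts with planted
informative genes so every stage is testable without any download.

## Worked example

```python
from coresig import (CohortSpec, SRVSConfig, anova_scores, cr_curve,
                     generate_dataset, permutation_pvalue, select_best)

spec = CohortSpec(n_cases=40, n_controls=40, n_genome=200, n_pool=200,
                  n_informative=20, effect_size=1.5, seed=1)
dataset, truth = generate_dataset(spec)
ranked = anova_scores(dataset)
best = select_best(cr_curve(dataset, ranked, n_max=200), ranked)
perm = permutation_pvalue(dataset, k=best.best_n, observed_cr=best.max_cr,
                          runs=500, seed=2)
print(f"best_n={best.best_n} max_cr={best.max_cr:.4f} p={perm.reported}")
```

prints

```
best_n=7 max_cr=1.0000 p=<2.00e-3
```

i.e. the 7 top-ranked genes classify all 80 samples correctly under LOO,
and none of 500 random 7-gene sets did as well (p below 1/500). The same
workflow is available from the shell:

```
coresig simulate --out sim/ --seed 1
coresig run --expression sim/sim01_expression.tsv \
            --labels sim/sim01_labels.tsv --pool sim/sim01_pool.txt \
            --out run/ --seed 1
coresig summarize --out summary.json
```

`coresig summarize` (with no `--results-table`) aggregates the bundled
per-cohort results of a published 14-cohort schizophrenia brain-expression
study and prints, per method, the cross-study mean ± SD classification
ratio and the mean permutation p-value:

```
SRVS: CR = 83.16 +/- 12.79, mean perm p <= 6.27e-03
ANOVA: CR = 82.36 +/- 8.61, mean perm p <= 5.00e-04
POOL_ALL: CR = 63.19 +/- 8.09, mean perm p 4.09e-01
```

The pattern these numbers show: small cohort-specific subsets of the pool
classify far better than the whole pool, whose advantage over random gene
sets of equal size is negligible.

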
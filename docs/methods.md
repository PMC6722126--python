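# Methods

## Model and workflow

`coresig` operates on a preprocessed (log-like scale) gene-symbol ×
sample expression matrix with binary case/control labels, restricted to a
curated pool of disease-associated genes before any selection. The working
assumption is that only a small, cohort-dependent subset of the pool
separates a given cohort's cases from controls, so the pipeline selects a
per-cohort subset, validates it by leave-one-out (LOO) classification, and
asks across cohorts how accurate and how stable those subsets are.

Stages per cohort: trim to the pool → rank genes (SRVS and/or one-way
ANOVA) → LOO CR curve over top-n vectors → select the best classifier →
gene-set permutation significance → random-gene baseline curve. Across
cohorts: Jaccard similarity of selected sets, a factor ANOVA on the
similarity values, and summary statistics of the per-cohort CRs.

## SRVS ranking

SRVS is specified here as: for each of `iterations` rounds, draw
`subset_size` gene indices uniformly without replacement; z-score each
gene column over all samples (zero-variance genes become all-zero columns,
so their coefficients are exactly zero); regress the centered ±1 label
vector on the subset with an ℓ1 penalty,
`min_w (1/2n)‖y − Zw‖² + λ‖w‖₁`, solved by coordinate descent to
tolerance 1e-8; accumulate `|w_g|` for each sampled gene. The final score
is the accumulated weight divided by the number of times the gene was
sampled; unsampled genes score 0 with a warning, and a warning is emitted
when `iterations × subset_size < 5 × n_genes` (thin coverage).

Parameters and defaults:

* `iterations = 1000` — enough for each of ~1,000 pool genes to be sampled
  ~20 times at the default subset size.
* `subset_size = min(n_samples − 2, ⌈n_genes/10⌉)` — keeps each regression
  under-determined-but-solvable and the per-round cost low.
* `l1_penalty` — if unset, chosen from a 10-point logarithmic grid spanning
  three decades below λ_max (the smallest penalty that zeroes every
  coefficient), by maximizing the LOO CR of the top-10 genes of a
  reduced-iteration (≤100 rounds) preliminary pass; grid points whose
  preliminary pass zeroes every score are skipped, and ties keep the
  larger (sparser) penalty. The choice is logged.
* The subset stream depends only on the seed and the gene count, so scores
  are invariant under sample reordering.

These internals (uniform subsets, per-column z-scoring, mean-absolute-
coefficient score) are this package's own fixed specification of the SRVS
idea; other variants (residual-bounded ℓ1 programs, unnormalized
accumulators) exist and would rank somewhat differently.

## ANOVA ranking

Per gene, a two-group one-way fixed-effects ANOVA:
`F = SS_between / (SS_within/(N−2))`, p from F(1, N−2). The ranking score
stored alongside p is −log10 p; ordering is by ascending p with
lexicographic tie-breaks. Degenerate genes: zero within-group variance
with equal class means → p = 1; with unequal means → the smallest positive
double (logged). p-values are used only as ranking scores, so no
multiple-testing correction is applied.

## Classification

"Euclidean multivariate classification" is implemented as nearest class
centroid: within each LOO fold, every gene is z-scored with the training
fold's mean/SD (ddof = 1), centroids are the training class means, and the
left-out sample takes the class with the smaller Euclidean distance. An
exact distance tie goes to the larger training class, then to control. A
1-nearest-neighbor alternative is available (`classifier="nn1"`). Per-fold
standardization prevents single high-variance genes from dominating
distances and makes the CR invariant under per-gene affine rescaling.

The CR curve evaluates the top-n vectors of a ranking computed **once on
the full dataset** — deliberately reproducing the evaluated workflow's
ordering of steps (rank, then cross-validate), which leaks selection
information into the LOO estimate. `nested_cr_curve` provides the
leakage-free variant (re-rank within every fold) for sensitivity analysis;
it is not the default. The best classifier is the smallest n attaining the
curve's maximum.

## Permutation test and baselines

The permutation test draws `runs` (default 5,000) random gene sets of the
observed classifier's size from the genes measured in the supplied dataset
(pass the trimmed dataset to restrict the universe to the pool) and
reports `p = #(CR ≥ CR_observed)/runs` — the plain fraction, not
(count+1)/(runs+1), so a zero count is reported as the censored string
`"<2.00e-4"` at 5,000 runs; the conventional estimator is available via
`estimator="plus_one"`. Each run uses an independent RNG stream keyed by
(seed, run index), so the result is identical for any worker count.
Baseline curves average the LOO CR of `reps` (default 300) random n-gene
sets per n.

## Cross-study stage

Jaccard similarities are assembled over all (cohort, method) pairs with
the diagonal forced to 0. The factor ANOVA on similarity uses, by default,
**all** matrix cells (including the zeroed diagonal), each labeled with
its row study's factors — for a 14-cohort × 2-method collection this gives
784 observations and a total d.f. of 783; `cells="offdiag-upper"` gives
the statistically cleaner variant restricted to the strictly upper
triangle. Factors observed at a single level are dropped before fitting.
Sums of squares are sequential (Type I) in the given factor order, via an
ordinary least-squares fit of main effects only.

Cross-study summaries report per-method mean and sample SD of CR on the
percent scale (cohorts whose values all lie in [0, 1] are rescaled ×100,
logged), the mean permutation p with censored entries `"<x"` contributing
their upper bound x, and both Welch and paired t-tests between each method
pair's CR vectors (the Welch test is the primary report).

## Synthetic data

The generator emulates preprocessed microarray brain cohorts: per gene a
Gaussian baseline with mean ~ U(6, 10) and SD ~ U(0.5, 1.5) (log2-like
units), informative genes' case means shifted by `effect_size` within-class
SDs, optional equicorrelated blocks (shared-factor construction), and
cohort metadata for the cross-study stage. Defaults (40+40 samples, 200
pool genes of 1,000 measured, 20 informative, shift 1.5 SD) describe a
mid-range two-class cohort within the 25–200-sample, ~600–1,500-pool-gene
regime the pipeline targets. Multi-cohort collections share one genome and
pool; each cohort's informative set takes fraction `overlap` from a common
core, with the cohort-specific remainder pairwise disjoint.

What the generator does **not** emulate: probe-level structure, batch and
platform effects, heavy-tailed or count-distributed noise, label noise, and
confounding between class and metadata. Passing tests on this model show
the machinery is correct and well calibrated under Gaussian assumptions,
not that real cohorts will reach comparable accuracies.

## Bundled reference tables

Two small TSVs ship with the package: per-cohort best-classifier results
(CR %, selected gene counts, permutation p-values with censored entries as
`"<x"`) and cohort descriptors (sample sizes, measured pool genes, brain
region, population) for a published 14-cohort schizophrenia
brain-expression study. They feed the results-fixture input mode so the
summarize stage can be exercised against published numbers without
downloading the underlying GEO series. Selected gene-count entries whose
printed source is typographically ambiguous were resolved to the most
plausible reading; those counts do not enter any summary statistic.

## Numerical choices and test scales

* Ranking ties (equal score or p) break lexicographically by symbol;
  equal-CR ties in best-n selection take the smallest n; exact distance
  ties take the majority class, then control.
* Lasso coordinate descent tolerance 1e-8; permutation CR comparison uses
  `CR ≥ observed − 1e-12` to absorb float fuzz (both sides are exact
  count/total ratios).
* Probe-to-symbol collapse is arithmetic mean by default
  (`max_variance` keeps the most variable probe); rows with any
  non-finite value are dropped, not imputed.
* Null calibration is checked at 200 replicates × 200 permutation runs on
  40+40-sample cohorts; signal recovery at 10 seeds of the canonical
  condition with 500 permutation runs — sizes chosen to make the binomial
  check informative while keeping the default suite quick.

## Known limitations

* The non-nested default CR curve overstates absolute accuracy; treat CRs
  as comparative between methods evaluated identically, not as unbiased
  generalization estimates.
* The permutation test conditions on the observed classifier size and the
  measured-gene universe; it does not account for the search over n.
* The factor ANOVA on all matrix cells double-counts each unordered pair
  and includes structural zeros; it mirrors the evaluated workflow's
  convention rather than a recommended design (use `offdiag-upper` for
  inference).
* Censored permutation p-values averaged at their bounds make the reported
  mean an upper bound, not an estimate.
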
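"""Per-gene ranking of pool genes within one cohort.

Two ranking schemes are provided:

* **SRVS** (sparse representation-based variable selection): the +/-1 class
  label is repeatedly regressed on random fixed-size gene subsets with an
  l1 penalty; each gene accumulates the absolute value of its coefficient,
  and its score is the mean absolute coefficient over the times it was
  sampled. Genes are ranked by descending score.
* **ANOVA**: a one-way fixed-effects ANOVA between the two classes per
  gene; genes are ranked by ascending p-value (the stored ranking score is
  -log10 p).

Both rankings are deterministic: ties are broken lexicographically by gene
symbol, and the SRVS subset stream depends only on the seed and the number
of genes.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso

from .data_io import ExpressionDataset

logger = logging.getLogger(__name__)

SRVS = "SRVS"
ANOVA = "ANOVA"
POOL_ALL = "POOL_ALL"
RANDOM = "RANDOM"


@dataclass
class RankedGeneList:
    """Scores and a deterministic ordering from one ranking method."""

    method: str
    scores: dict[str, float]
    order: tuple[str, ...]
    pvalues: dict[str, float] | None = None

    def top(self, n: int) -> tuple[str, ...]:
        if n < 1 or n > len(self.order):
            raise ValueError(f"n must be in 1..{len(self.order)}, got {n}")
        return self.order[:n]

    def __len__(self) -> int:
        return len(self.order)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, self.method, self.scores[g], rank)
                for rank, g in enumerate(self.order, start=1)]
        return pd.DataFrame(rows, columns=["gene_symbol", "method", "score", "rank"])


@dataclass
class SRVSConfig:
    """Tunables of the SRVS ranking.

    ``subset_size`` defaults to ``min(n_samples - 2, ceil(n_genes / 10))``;
    ``l1_penalty`` (the lasso alpha, on sklearn's 1/(2n) least-squares
    scale) defaults to a 10-point logarithmic grid search maximizing the
    leave-one-out classification ratio of the top-10 genes of a short
    preliminary pass.
    """

    iterations: int = 1000
    subset_size: int | None = None
    l1_penalty: float | None = None
    seed: int | None = None

    def resolve_subset_size(self, n_genes: int, n_samples: int) -> int:
        if self.subset_size is not None:
            m = self.subset_size
        else:
            m = min(n_samples - 2, math.ceil(n_genes / 10))
            m = max(m, 1)
        if m > n_genes:
            raise ValueError(f"subset_size {m} exceeds number of genes {n_genes}")
        return m


def _standardized_design(dataset: ExpressionDataset) -> np.ndarray:
    """Samples x genes matrix with z-scored columns; zero-variance genes
    become all-zero columns (their coefficients are necessarily zero)."""
    X = dataset.values().T.astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    Z = np.zeros_like(X)
    ok = sd > 0
    Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return Z


def _ordered(scores: dict[str, float], descending: bool) -> tuple[str, ...]:
    sign = -1.0 if descending else 1.0
    return tuple(sorted(scores, key=lambda g: (sign * scores[g], g)))


def srvs_scores(dataset: ExpressionDataset, config: SRVSConfig | None = None) -> RankedGeneList:
    """Rank pool genes by SRVS score.

    For each of ``config.iterations`` rounds, ``subset_size`` gene indices
    are drawn uniformly without replacement; an l1-penalized least-squares
    regression of the centered +/-1 label vector on the standardized
    expression of those genes is solved by coordinate descent
    (tolerance 1e-8), and each sampled gene accumulates the absolute value
    of its coefficient. The final score is accumulator / times-sampled.
    """
    config = config or SRVSConfig()
    dataset.require_two_per_class()
    genes = dataset.gene_symbols
    n_genes, n_samples = dataset.n_genes, dataset.n_samples
    m = config.resolve_subset_size(n_genes, n_samples)
    if config.iterations * m < 5 * n_genes:
        logger.warning(
            "SRVS coverage is thin: iterations*subset_size=%d < 5*n_genes=%d; "
            "some genes may be sampled rarely or never",
            config.iterations * m, 5 * n_genes)

    Z = _standardized_design(dataset)
    y = dataset.label_vector()
    y = y - y.mean()

    lam = config.l1_penalty
    if lam is None:
        lam = _select_penalty(dataset, Z, y, config)
        logger.info("SRVS l1_penalty selected by grid search: %.6g", lam)

    seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    acc = np.zeros(n_genes)
    cnt = np.zeros(n_genes, dtype=int)
    model = Lasso(alpha=lam, fit_intercept=False, tol=1e-8, max_iter=100_000)
    for _ in range(config.iterations):
        idx = rng.choice(n_genes, size=m, replace=False)
        model.fit(Z[:, idx], y)
        acc[idx] += np.abs(model.coef_)
        cnt[idx] += 1

    never = int((cnt == 0).sum())
    if never:
        logger.warning("SRVS: %d gene(s) never sampled; their score is 0", never)
    score_values = acc / np.maximum(cnt, 1)
    scores = {g: float(s) for g, s in zip(genes, score_values)}
    return RankedGeneList(SRVS, scores, _ordered(scores, descending=True))


def _select_penalty(dataset: ExpressionDataset, Z: np.ndarray, y: np.ndarray,
                    config: SRVSConfig) -> float:
    """Pick the lasso penalty from a 10-point log grid spanning three
    decades below the smallest penalty that zeroes every coefficient,
    by maximizing the LOO classification ratio of the top-10 genes of a
    short SRVS pass. Ties go to the larger (sparser) penalty."""
    from .classification import loo_cr  # local import to avoid a cycle

    n = Z.shape[0]
    lam_max = float(np.max(np.abs(Z.T @ y)) / n)
    if lam_max <= 0:
        return 1e-3
    grid = np.logspace(np.log10(lam_max), np.log10(lam_max) - 3, 10)
    quick_iters = min(100, config.iterations)
    best_lam, best_cr = float(grid[-1]), -1.0
    for lam in grid:  # descending; ties keep the larger (sparser) penalty
        quick = SRVSConfig(iterations=quick_iters, subset_size=config.subset_size,
                           l1_penalty=float(lam), seed=config.seed)
        ranking = srvs_scores(dataset, quick)
        if max(ranking.scores.values()) <= 0:
            continue  # penalty zeroed every coefficient; ranking is vacuous
        top = ranking.top(min(10, len(ranking)))
        cr = loo_cr(dataset, top)
        logger.debug("penalty grid: lambda=%.4g top-10 LOO CR=%.4f", lam, cr)
        if cr > best_cr:
            best_lam, best_cr = float(lam), cr
    return best_lam


def anova_scores(dataset: ExpressionDataset) -> RankedGeneList:
    """Rank genes by one-way two-group ANOVA p-value (ascending).

    F = between-group mean square / within-group mean square with
    (1, N-2) degrees of freedom. Degenerate genes: zero within-group
    variance with equal class means gives p = 1; zero within-group
    variance with different means gives the smallest positive double.
    """
    dataset.require_two_per_class()
    X = dataset.values()
    is_case = dataset.is_case
    nc, nk = int(is_case.sum()), int((~is_case).sum())
    N = nc + nk
    Xc, Xk = X[:, is_case], X[:, ~is_case]
    mc, mk = Xc.mean(axis=1), Xk.mean(axis=1)
    grand = X.mean(axis=1)
    ssb = nc * (mc - grand) ** 2 + nk * (mk - grand) ** 2
    ssw = ((Xc - mc[:, None]) ** 2).sum(axis=1) + ((Xk - mk[:, None]) ** 2).sum(axis=1)

    tiny = np.nextafter(0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ssb / (ssw / (N - 2))
    p = stats.f.sf(F, 1, N - 2)

    zero_w = ssw <= 0
    if zero_w.any():
        same = zero_w & (ssb <= 0)
        diff = zero_w & (ssb > 0)
        F = np.where(same, 0.0, F)
        p = np.where(same, 1.0, p)
        F = np.where(diff, np.inf, F)
        p = np.where(diff, tiny, p)
        if diff.any():
            logger.warning("ANOVA: %d gene(s) with zero within-group variance "
                           "and nonzero class difference; p set to smallest "
                           "positive value", int(diff.sum()))
    p = np.clip(p, tiny, 1.0)

    genes = dataset.gene_symbols
    pvalues = {g: float(v) for g, v in zip(genes, p)}
    scores = {g: float(-np.log10(pvalues[g])) for g in genes}
    order = tuple(sorted(genes, key=lambda g: (pvalues[g], g)))
    return RankedGeneList(ANOVA, scores, order, pvalues=pvalues)


def write_scores_tsv(rankings: Sequence[RankedGeneList], path) -> None:
    """Write one or more rankings as a TSV: gene_symbol, method, score, rank."""
    pd.concat([r.to_frame() for r in rankings], ignore_index=True).to_csv(
        path, sep="\t", index=False)
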
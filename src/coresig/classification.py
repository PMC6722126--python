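"""Euclidean nearest-centroid classification under leave-one-out (LOO)
cross-validation, and selection of the best top-n gene vector.

For every LOO fold, each gene is standardized with the training fold's mean
and standard deviation, class centroids are the training means in the
selected gene subspace, and the left-out sample is assigned to the class
with the smaller Euclidean distance. An exact distance tie goes to the
class with more training samples, then to control. The classification
ratio (CR) is the fraction of correctly classified subjects.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data_io import ExpressionDataset
from .ranking import POOL_ALL, RankedGeneList

logger = logging.getLogger(__name__)


def classification_ratio(correct: int, total: int) -> float:
    """CR = correctly classified subjects / total subjects."""
    if total <= 0:
        raise ValueError("total must be positive")
    if correct < 0 or correct > total:
        raise ValueError(f"correct must be in 0..{total}, got {correct}")
    return correct / total


def _loo_predictions_centroid(X: np.ndarray, is_case: np.ndarray) -> np.ndarray:
    """Vectorized LOO nearest-centroid predictions.

    X is genes x samples; returns a boolean array (True = predicted case).
    Training-fold standardization uses ddof=1; zero-variance genes within a
    fold contribute nothing to the distance.
    """
    k, n = X.shape
    S = X.sum(axis=1, keepdims=True)
    Q = (X ** 2).sum(axis=1, keepdims=True)
    n_tr = n - 1
    mu = (S - X) / n_tr                      # training mean per fold, (k, n)
    ss = Q - X ** 2                          # training sum of squares
    var = (ss - n_tr * mu ** 2) / (n_tr - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    ok = sd > 0
    inv_sd = np.where(ok, 1.0 / np.where(ok, sd, 1.0), 0.0)

    z_test = (X - mu) * inv_sd               # left-out sample, standardized

    case_f = is_case.astype(float)
    S_case = X[:, is_case].sum(axis=1, keepdims=True)
    S_ctrl = S - S_case
    m_case = case_f.sum() - case_f           # training class sizes per fold, (n,)
    m_ctrl = (n - case_f.sum()) - (1.0 - case_f)
    if (m_case < 1).any() or (m_ctrl < 1).any():
        raise ValueError("need >= 2 samples per class for LOO classification")

    cent_case = (S_case - case_f[None, :] * X - m_case[None, :] * mu) \
        / m_case[None, :] * inv_sd
    cent_ctrl = (S_ctrl - (1.0 - case_f)[None, :] * X - m_ctrl[None, :] * mu) \
        / m_ctrl[None, :] * inv_sd

    d2_case = ((z_test - cent_case) ** 2).sum(axis=0)
    d2_ctrl = ((z_test - cent_ctrl) ** 2).sum(axis=0)

    pred = d2_case < d2_ctrl
    tie = d2_case == d2_ctrl
    if tie.any():
        # majority training class wins a tie; an exact size tie -> control
        pred = np.where(tie, m_case > m_ctrl, pred)
    return pred


def _loo_predictions_nn1(X: np.ndarray, is_case: np.ndarray) -> np.ndarray:
    """1-nearest-neighbor alternative in the same standardized space."""
    k, n = X.shape
    pred = np.zeros(n, dtype=bool)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        Xt = X[:, train]
        mu = Xt.mean(axis=1)
        sd = Xt.std(axis=1, ddof=1)
        ok = sd > 0
        inv = np.where(ok, 1.0 / np.where(ok, sd, 1.0), 0.0)
        Zt = (Xt - mu[:, None]) * inv[:, None]
        z = (X[:, i] - mu) * inv
        d2 = ((Zt - z[:, None]) ** 2).sum(axis=0)
        j = int(np.argmin(d2))
        pred[i] = is_case[train][j]
    return pred


def _loo_cr_matrix(X: np.ndarray, is_case: np.ndarray,
                   classifier: str = "centroid") -> float:
    if classifier == "centroid":
        pred = _loo_predictions_centroid(X, is_case)
    elif classifier == "nn1":
        pred = _loo_predictions_nn1(X, is_case)
    else:
        raise ValueError(f"unknown classifier: {classifier!r}")
    return classification_ratio(int((pred == is_case).sum()), len(is_case))


def loo_cr(dataset: ExpressionDataset, gene_subset: Sequence[str],
           classifier: str = "centroid") -> float:
    """Leave-one-out classification ratio of a gene subset. Deterministic."""
    dataset.require_two_per_class()
    X = dataset.values(list(gene_subset))
    return _loo_cr_matrix(X, dataset.is_case, classifier)


@dataclass
class CRCurve:
    """Classification ratio of the top-n gene vectors for n = 1..n_max."""

    n_values: tuple[int, ...]
    cr_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.n_values) != len(self.cr_values):
            raise ValueError("n_values and cr_values must have equal length")
        if len(self.n_values) == 0:
            raise ValueError("empty CR curve")

    def cr_at(self, n: int) -> float:
        return self.cr_values[self.n_values.index(n)]


@dataclass
class ClassifierResult:
    """The best top-n gene vector for one cohort and method."""

    method: str
    gene_vector: tuple[str, ...]
    best_n: int
    max_cr: float
    curve: CRCurve
    permutation: object | None = None
    baseline: object | None = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "best_n": self.best_n,
            "max_cr": self.max_cr,
            "gene_vector": list(self.gene_vector),
            "curve": {"n": list(self.curve.n_values),
                      "cr": list(self.curve.cr_values)},
        }
        if self.permutation is not None:
            d["permutation"] = self.permutation.to_dict()
        if self.baseline is not None:
            d["baseline"] = self.baseline.to_dict()
        return d


def cr_curve(dataset: ExpressionDataset, ranking: RankedGeneList,
             n_max: int | None = None, classifier: str = "centroid") -> CRCurve:
    """LOO CR of the top-n genes of a ranking for n = 1..n_max.

    The ranking is computed once on the full dataset before
    cross-validation (the workflow evaluated here ranks first, then
    cross-validates); see :func:`nested_cr_curve` for the leakage-free
    variant that re-ranks within every fold.
    """
    dataset.require_two_per_class()
    if n_max is None:
        n_max = len(ranking)
    if n_max > dataset.n_genes or n_max > len(ranking):
        raise ValueError(f"n_max {n_max} exceeds available genes")
    X_full = dataset.values(list(ranking.order[:n_max]))
    is_case = dataset.is_case
    crs = [_loo_cr_matrix(X_full[:n], is_case, classifier)
           for n in range(1, n_max + 1)]
    return CRCurve(tuple(range(1, n_max + 1)), tuple(crs))


def nested_cr_curve(dataset: ExpressionDataset,
                    rank_fn: Callable[[ExpressionDataset], RankedGeneList],
                    n_max: int, classifier: str = "centroid") -> CRCurve:
    """Leakage-free CR curve: ranking is recomputed on every training fold
    and the left-out sample is classified with that fold's top-n genes."""
    dataset.require_two_per_class()
    n = dataset.n_samples
    correct = np.zeros(n_max, dtype=int)
    samples = dataset.sample_ids
    for i, sid in enumerate(samples):
        train_ids = samples[:i] + samples[i + 1:]
        train = ExpressionDataset(dataset.expr[train_ids].copy(),
                                  dataset.labels.loc[train_ids].copy(),
                                  dict(dataset.metadata))
        ranking = rank_fn(train)
        for j in range(min(n_max, len(ranking))):
            genes = list(ranking.order[:j + 1])
            Xt = train.values(genes)
            x = dataset.expr.loc[genes, sid].to_numpy(dtype=float)
            pred = _classify_one(Xt, train.is_case, x)
            correct[j] += int(pred == (dataset.labels[sid] == "case"))
    crs = tuple(classification_ratio(int(c), n) for c in correct)
    return CRCurve(tuple(range(1, n_max + 1)), crs)


def _classify_one(X_train: np.ndarray, is_case: np.ndarray, x: np.ndarray) -> bool:
    mu = X_train.mean(axis=1)
    sd = X_train.std(axis=1, ddof=1)
    ok = sd > 0
    inv = np.where(ok, 1.0 / np.where(ok, sd, 1.0), 0.0)
    Z = (X_train - mu[:, None]) * inv[:, None]
    z = (x - mu) * inv
    c_case = Z[:, is_case].mean(axis=1)
    c_ctrl = Z[:, ~is_case].mean(axis=1)
    d2c = ((z - c_case) ** 2).sum()
    d2k = ((z - c_ctrl) ** 2).sum()
    if d2c == d2k:
        return int(is_case.sum()) > int((~is_case).sum())
    return bool(d2c < d2k)


def select_best(curve: CRCurve, ranking: RankedGeneList) -> ClassifierResult:
    """Best dataset-specific classifier: the smallest n attaining the
    maximum CR of the curve; its gene vector is the ranking's top n."""
    crs = np.asarray(curve.cr_values)
    best_idx = int(np.argmax(crs))  # argmax returns the first (smallest n) maximum
    best_n = curve.n_values[best_idx]
    return ClassifierResult(
        method=ranking.method,
        gene_vector=ranking.top(best_n),
        best_n=best_n,
        max_cr=float(crs[best_idx]),
        curve=curve,
    )


def pool_classifier(dataset: ExpressionDataset,
                    classifier: str = "centroid") -> ClassifierResult:
    """The pan-signature classifier: every (trimmed) pool gene at once."""
    genes = tuple(dataset.gene_symbols)
    cr = loo_cr(dataset, genes, classifier)
    curve = CRCurve((len(genes),), (cr,))
    return ClassifierResult(POOL_ALL, genes, len(genes), cr, curve)
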
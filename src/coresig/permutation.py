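"""Permutation significance of an observed classifier CR, and random-gene
CR baselines.

The permutation test asks how often a randomly selected gene set of the
same size reaches an equal or higher LOO classification ratio than the
observed classifier. By default p = count / runs, so a result with zero
qualifying runs is reported as "< 1/runs" (e.g. "<2.00e-4" at 5,000 runs);
the (count+1)/(runs+1) estimator is available via ``estimator="plus_one"``.

Each run draws its genes from an independent RNG stream keyed by the run
index, so results are identical for any degree of parallelism given the
same seed.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classification import _loo_cr_matrix
from .data_io import ExpressionDataset

logger = logging.getLogger(__name__)


def format_pvalue(p: float) -> str:
    """Compact scientific notation without a padded exponent: 2.00e-4."""
    s = f"{p:.2e}"
    return re.sub(r"e([+-])0*(\d)", r"e\1\2", s)


@dataclass
class PermutationResult:
    runs: int
    better_or_equal: int
    p_value: float
    reported: str
    seed: int

    def __post_init__(self) -> None:
        if not (0 <= self.better_or_equal <= self.runs):
            raise ValueError("count must be in 0..runs")

    def to_dict(self) -> dict:
        return {"runs": self.runs, "better_or_equal": self.better_or_equal,
                "p_value": self.p_value, "reported": self.reported,
                "seed": self.seed}


@dataclass
class BaselineCurve:
    """Mean LOO CR of random n-gene sets, the chance-level reference."""

    n_values: tuple[int, ...]
    mean_cr: tuple[float, ...]
    reps: int
    seed: int

    def to_dict(self) -> dict:
        return {"n": list(self.n_values), "mean_cr": list(self.mean_cr),
                "reps": self.reps, "seed": self.seed}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("n\tmean_cr\n")
            for n, cr in zip(self.n_values, self.mean_cr):
                fh.write(f"{n}\t{cr!r}\n")


def _run_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def permutation_pvalue(dataset: ExpressionDataset, k: int, observed_cr: float,
                       runs: int = 5000, seed: int = 0,
                       estimator: str = "fraction",
                       classifier: str = "centroid") -> PermutationResult:
    """Fraction of random k-gene sets whose LOO CR >= observed_cr.

    The gene universe is every gene measured in ``dataset`` (pass a
    pool-trimmed dataset to restrict it). Deterministic given the seed.
    """
    if not (0.0 <= observed_cr <= 1.0):
        raise ValueError("observed_cr must be in [0, 1]")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    n_universe = dataset.n_genes
    if k < 1 or k > n_universe:
        raise ValueError(f"k must be in 1..{n_universe}, got {k}")
    dataset.require_two_per_class()
    X = dataset.values()
    is_case = dataset.is_case
    threshold = observed_cr - 1e-12
    count = 0
    for run in range(runs):
        idx = _run_rng(seed, run).choice(n_universe, size=k, replace=False)
        if _loo_cr_matrix(X[idx], is_case, classifier) >= threshold:
            count += 1
    if estimator == "fraction":
        p = count / runs
    elif estimator == "plus_one":
        p = (count + 1) / (runs + 1)
    else:
        raise ValueError(f"unknown estimator: {estimator!r}")
    reported = "<" + format_pvalue(1 / runs) if count == 0 else format_pvalue(p)
    return PermutationResult(runs, count, p, reported, seed)


def baseline_curve(dataset: ExpressionDataset, n_values: Sequence[int],
                   reps: int = 300, seed: int = 0,
                   classifier: str = "centroid") -> BaselineCurve:
    """Mean LOO CR over ``reps`` random n-gene sets for each n."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n_universe = dataset.n_genes
    if max(n_values) > n_universe:
        raise ValueError("max(n_values) exceeds the gene universe")
    dataset.require_two_per_class()
    X = dataset.values()
    is_case = dataset.is_case
    means = []
    for n in n_values:
        crs = np.empty(reps)
        for rep in range(reps):
            idx = _run_rng(seed, int(n), rep).choice(n_universe, size=int(n),
                                                     replace=False)
            crs[rep] = _loo_cr_matrix(X[idx], is_case, classifier)
        means.append(float(crs.mean()))
    return BaselineCurve(tuple(int(n) for n in n_values), tuple(means), reps, seed)
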
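"""Cross-cohort comparison of classifier gene sets and per-study results.

Gene-set stability is measured with the Jaccard similarity between every
(cohort, method) pair of best-classifier gene sets, arranged in a square
matrix whose diagonal is set to zero by convention. The influence of
cohort-level factors (brain region, ethnicity, ranking method) on the
similarity values is assessed with a main-effects N-way ANOVA using
sequential (Type I) sums of squares. Per-study classification ratios are
aggregated into cross-study summary statistics (mean, sample SD, mean
permutation p with censored entries contributing their bound, and
between-method t-tests).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

logger = logging.getLogger(__name__)


def jaccard_score(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """|A intersect B| / |A union B|."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        raise ValueError("both gene sets are empty")
    return len(a & b) / len(a | b)


@dataclass
class SimilarityMatrix:
    """Jaccard similarity among classifier gene sets, diagonal zeroed."""

    labels: tuple[tuple[str, str], ...]  # (cohort_id, method)
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def to_frame(self) -> pd.DataFrame:
        names = [f"{m} {c}" for c, m in self.labels]
        return pd.DataFrame(self.values, index=names, columns=names)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def jaccard_matrix(classifier_sets: Sequence[tuple[str, str, Iterable[str]]]
                   ) -> SimilarityMatrix:
    """Square Jaccard matrix over (cohort_id, method, gene set) triples.

    Diagonal entries (a set against itself, always 1) are set to zero so
    they do not dominate a rendered heatmap.
    """
    if len(classifier_sets) < 2:
        raise ValueError("need at least 2 classifier sets")
    labels = [(c, m) for c, m, _ in classifier_sets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate (cohort, method) labels")
    sets = [set(s) for _, _, s in classifier_sets]
    n = len(sets)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = jaccard_score(sets[i], sets[j])
    return SimilarityMatrix(tuple(labels), values)


def plot_similarity(matrix: SimilarityMatrix, path) -> None:
    """Basic heatmap rendering of the similarity matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = matrix.to_frame()
    fig, ax = plt.subplots(figsize=(0.3 * len(frame) + 2,) * 2)
    im = ax.imshow(frame.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(frame)), frame.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(frame)), frame.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Jaccard similarity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# N-way main-effects ANOVA (sequential / Type I sums of squares)
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """Main-effects ANOVA table with rows per factor plus Error and Total."""

    table: pd.DataFrame  # index: factor names + Error + Total

    def row(self, source: str) -> pd.Series:
        return self.table.loc[source]

    def to_tsv(self, path) -> None:
        out = self.table.rename(columns={"sum_sq": "Sum Sq.", "df": "d.f.",
                                         "mean_sq": "Mean Sq.", "F": "F",
                                         "p": "P>F"})
        out.index.name = "Source"
        out.to_csv(path, sep="\t")


def nway_anova(response: Sequence[float], factors: Sequence[Sequence],
               factor_names: Sequence[str]) -> AnovaTable:
    """Main-effects-only ANOVA with sequential (Type I) sums of squares in
    the given factor order; F = factor mean square / error mean square."""
    y = np.asarray(response, dtype=float)
    if len(factors) != len(factor_names):
        raise ValueError("factors and factor_names lengths differ")
    data = {"y": y}
    safe_names = []
    for i, (name, fac) in enumerate(zip(factor_names, factors)):
        fac = np.asarray(fac)
        if len(fac) != len(y):
            raise ValueError(f"factor {name!r} length does not match response")
        if len(np.unique(fac)) < 2:
            raise ValueError(f"factor {name!r} has fewer than 2 observed levels")
        safe = f"f{i}"
        safe_names.append(safe)
        data[safe] = fac
    df = pd.DataFrame(data)
    formula = "y ~ " + " + ".join(f"C({s})" for s in safe_names)
    fit = ols(formula, data=df).fit()
    if fit.df_resid <= 0:
        raise ValueError("saturated model")
    anova = sm.stats.anova_lm(fit, typ=1)

    rows = []
    for safe, name in zip(safe_names, factor_names):
        r = anova.loc[f"C({safe})"]
        rows.append((name, r["sum_sq"], int(r["df"]), r["sum_sq"] / r["df"],
                     r["F"], r["PR(>F)"]))
    res = anova.loc["Residual"]
    rows.append(("Error", res["sum_sq"], int(res["df"]),
                 res["sum_sq"] / res["df"], np.nan, np.nan))
    total_ss = float(anova["sum_sq"].sum())
    total_df = int(anova["df"].sum())
    rows.append(("Total", total_ss, total_df, np.nan, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["source", "sum_sq", "df", "mean_sq",
                                        "F", "p"]).set_index("source")
    return AnovaTable(table)


def similarity_anova(matrix: SimilarityMatrix,
                     factors: Mapping[tuple[str, str], Mapping[str, str]],
                     factor_names: Sequence[str] = ("brain_region", "ethnicity",
                                                    "method"),
                     cells: str = "all") -> AnovaTable:
    """ANOVA of similarity cells on cohort-level factors.

    Every cell is labeled with its ROW study's factors. ``cells="all"``
    uses the full square matrix including the zeroed diagonal (so a
    K x K matrix contributes K^2 observations); ``cells="offdiag-upper"``
    uses only the strictly upper triangle.
    """
    n = len(matrix.labels)
    response, cols = [], {name: [] for name in factor_names}
    for i in range(n):
        row_label = matrix.labels[i]
        fac = dict(factors[row_label])
        if "method" in factor_names and "method" not in fac:
            fac["method"] = row_label[1]
        for j in range(n):
            if cells == "offdiag-upper" and j <= i:
                continue
            response.append(matrix.values[i, j])
            for name in factor_names:
                cols[name].append(fac[name])
    return nway_anova(response, [cols[name] for name in factor_names],
                      list(factor_names))


# ---------------------------------------------------------------------------
# cross-study summary
# ---------------------------------------------------------------------------

def parse_pvalue(value) -> tuple[float, bool]:
    """Parse a permutation p entry; censored entries like "<2.00e-4"
    contribute their upper bound. Returns (value, censored)."""
    if isinstance(value, str):
        s = value.strip()
        if s.startswith("<"):
            return float(s[1:]), True
        return float(s), False
    return float(value), False


@dataclass
class CrossStudySummary:
    """Per-method mean/SD of CR (percent scale), mean permutation p, and
    between-method t-test p-values on the CR vectors."""

    per_method: dict  # method -> {mean_cr, sd_cr, mean_perm_p, any_censored}
    welch_p: dict     # (method_a, method_b) -> Welch two-sample t p
    paired_p: dict    # (method_a, method_b) -> paired t p
    n_cohorts: int

    def to_dict(self) -> dict:
        return {
            "n_cohorts": self.n_cohorts,
            "per_method": self.per_method,
            "welch_p": {f"{a}_vs_{b}": p for (a, b), p in self.welch_p.items()},
            "paired_p": {f"{a}_vs_{b}": p for (a, b), p in self.paired_p.items()},
        }


def _two_sample_p(a: np.ndarray, b: np.ndarray, paired: bool) -> float:
    if np.array_equal(a, b):
        return 1.0
    if paired:
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            return 1.0 if np.allclose(d.mean(), 0.0) else 0.0
        return float(stats.ttest_rel(a, b).pvalue)
    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        return 1.0 if np.allclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def summarize_studies(results: pd.DataFrame) -> CrossStudySummary:
    """Aggregate per-cohort results across studies.

    ``results`` is tidy with columns ``cohort_id``, ``method``, ``cr`` and
    ``perm_p`` (floats, or censored strings like "<2.00e-4"). CR values on
    the [0, 1] scale are converted to percent (logged). Requires >= 2
    cohorts.
    """
    required = {"cohort_id", "method", "cr", "perm_p"}
    if not required.issubset(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    df = results.copy()
    if df["cohort_id"].nunique() < 2:
        raise ValueError("need results from at least 2 cohorts")

    df["cr"] = df["cr"].astype(float)
    frac = df.groupby("cohort_id")["cr"].transform("max") <= 1.0
    if frac.any():
        logger.info("summarize_studies: rescaled %d CR value(s) from [0,1] "
                    "to percent", int(frac.sum()))
        df.loc[frac, "cr"] = df.loc[frac, "cr"] * 100.0

    parsed = df["perm_p"].map(parse_pvalue)
    df["p_bound"] = [v for v, _ in parsed]
    df["p_censored"] = [c for _, c in parsed]

    per_method: dict[str, dict] = {}
    for method, grp in df.groupby("method", sort=False):
        per_method[method] = {
            "mean_cr": float(grp["cr"].mean()),
            "sd_cr": float(grp["cr"].std(ddof=1)),
            "mean_perm_p": float(grp["p_bound"].mean()),
            "any_censored": bool(grp["p_censored"].any()),
            "n": int(len(grp)),
        }

    methods = list(per_method)
    wide = df.pivot(index="cohort_id", columns="method", values="cr").sort_index()
    welch_p, paired_p = {}, {}
    for a, b in itertools.combinations(methods, 2):
        va, vb = wide[a].to_numpy(), wide[b].to_numpy()
        welch_p[(a, b)] = _two_sample_p(va, vb, paired=False)
        paired_p[(a, b)] = _two_sample_p(va, vb, paired=True)

    return CrossStudySummary(per_method, welch_p, paired_p,
                             n_cohorts=int(df["cohort_id"].nunique()))
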
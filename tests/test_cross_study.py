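import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coresig.cross_study import (jaccard_matrix, jaccard_score, nway_anova,
                                 parse_pvalue, similarity_anova,
                                 summarize_studies)
from coresig.data_io import CASE, CONTROL
from coresig.ranking import anova_scores

from conftest import noise_dataset


# ---------------------------------------------------------------------------
# Jaccard
# ---------------------------------------------------------------------------

def test_jaccard_basic_values():
    assert jaccard_score({"a", "b"}, {"a", "b"}) == 1.0
    assert jaccard_score({"a"}, {"b"}) == 0.0
    assert jaccard_score({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)


def test_jaccard_both_empty_errors():
    with pytest.raises(ValueError, match="empty"):
        jaccard_score(set(), set())


@settings(deadline=None, derandomize=True, max_examples=50)
@given(a=st.sets(st.sampled_from("abcdefgh"), min_size=1),
       b=st.sets(st.sampled_from("abcdefgh"), min_size=1))
def test_jaccard_symmetric_bounded_identity(a, b):
    s = jaccard_score(a, b)
    assert s == jaccard_score(b, a)
    assert 0.0 <= s <= 1.0
    assert (s == 1.0) == (a == b)


def test_jaccard_matrix_disjoint_and_diagonal():
    sets = [("c1", "SRVS", {"a", "b"}), ("c2", "SRVS", {"c", "d"}),
            ("c3", "SRVS", {"e"})]
    sim = jaccard_matrix(sets)
    assert (sim.values == 0).all()


def test_jaccard_matrix_symmetric_with_overlap():
    a = {f"g{i}" for i in range(10)}
    b = {f"g{i}" for i in range(5, 15)}
    sim = jaccard_matrix([("c1", "SRVS", a), ("c2", "SRVS", b)])
    assert sim.values[0, 1] == pytest.approx(5 / 15)
    assert (sim.values == sim.values.T).all()
    assert sim.values[0, 0] == sim.values[1, 1] == 0.0


def test_jaccard_matrix_duplicate_labels_error():
    sets = [("c1", "SRVS", {"a"}), ("c1", "SRVS", {"b"})]
    with pytest.raises(ValueError, match="duplicate"):
        jaccard_matrix(sets)


# ---------------------------------------------------------------------------
# N-way ANOVA
# ---------------------------------------------------------------------------

def test_one_factor_equal_means_f0_p1():
    y = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    fac = ["a", "a", "a", "b", "b", "b"]
    table = nway_anova(y, [fac], ["group"]).table
    assert table.loc["group", "F"] == pytest.approx(0.0, abs=1e-12)
    assert table.loc["group", "p"] == pytest.approx(1.0)


def test_single_factor_matches_oneway_oracle():
    """Single-factor N-way ANOVA must agree with the direct sum-of-squares
    F used for per-gene ranking, to 1e-10."""
    ds = noise_dataset(8, 10, 1, seed=13)
    ranked = anova_scores(ds)
    y = ds.values()[0]
    fac = [CASE if c else CONTROL for c in ds.is_case]
    table = nway_anova(y, [fac], ["class"]).table
    assert table.loc["class", "p"] == pytest.approx(ranked.pvalues["G001"],
                                                    abs=1e-10, rel=1e-10)


def sequential_ss_oracle(y, design_blocks):
    """Type-I sums of squares via explicit sequential least squares: fit an
    intercept, then add each factor's dummy block; the SS credited to a
    block is the drop in residual sum of squares."""
    n = len(y)
    X = np.ones((n, 1))
    rss_prev = float(((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2).sum())
    out = []
    for block in design_blocks:
        X = np.hstack([X, block])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(((y - X @ beta) ** 2).sum())
        out.append(rss_prev - rss)
        rss_prev = rss
    return out, rss_prev


def _dummies(levels):
    levels = np.asarray(levels)
    cats = sorted(set(levels))[1:]
    return np.column_stack([(levels == c).astype(float) for c in cats])


def test_balanced_2x2_matches_projection_oracle():
    y = np.array([3.0, 5.0, 2.0, 6.0, 7.0, 9.0, 4.0, 8.0])
    f1 = ["a", "a", "a", "a", "b", "b", "b", "b"]
    f2 = ["x", "y", "x", "y", "x", "y", "x", "y"]
    table = nway_anova(y, [f1, f2], ["first", "second"]).table
    (ss1, ss2), rss = sequential_ss_oracle(y, [_dummies(f1), _dummies(f2)])
    assert table.loc["first", "sum_sq"] == pytest.approx(ss1, abs=1e-10)
    assert table.loc["second", "sum_sq"] == pytest.approx(ss2, abs=1e-10)
    assert table.loc["Error", "sum_sq"] == pytest.approx(rss, abs=1e-10)


@pytest.mark.parametrize("order", [("f1", "f2", "f3"), ("f3", "f1", "f2")])
def test_type1_decomposition_sums_to_total(order):
    rng = np.random.default_rng(21)
    n = 40
    factors = {"f1": rng.choice(["a", "b", "c"], n),
               "f2": rng.choice(["x", "y"], n),
               "f3": rng.choice(["u", "v", "w"], n)}
    y = rng.standard_normal(n)
    table = nway_anova(y, [factors[k] for k in order], list(order)).table
    total = table.loc["Total", "sum_sq"]
    parts = table.loc[list(order) + ["Error"], "sum_sq"].sum()
    assert parts == pytest.approx(total, rel=1e-8)
    # Total SS is the centered SS of the response, independent of ordering
    assert total == pytest.approx(float(((y - y.mean()) ** 2).sum()), rel=1e-8)


def test_saturated_model_errors():
    y = [1.0, 2.0]
    with pytest.raises(ValueError, match="saturated"):
        nway_anova(y, [["a", "b"]], ["f"])


def test_similarity_anova_uses_all_cells():
    sets = [(f"c{i}", m, {f"g{i}{m}", "shared"})
            for i in range(4) for m in ("SRVS", "ANOVA")]
    sim = jaccard_matrix(sets)
    factors = {(c, m): {"brain_region": "pfc" if c in ("c0", "c1") else "ba22",
                        "ethnicity": "USA" if c in ("c0", "c2") else "Japan",
                        "method": m}
               for c in ("c0", "c1", "c2", "c3") for m in ("SRVS", "ANOVA")}
    table = similarity_anova(sim, factors).table
    n_cells = len(sim.labels) ** 2
    assert table.loc["Total", "df"] == n_cells - 1
    upper = similarity_anova(sim, factors, cells="offdiag-upper").table
    k = len(sim.labels)
    assert upper.loc["Total", "df"] == k * (k - 1) // 2 - 1


# ---------------------------------------------------------------------------
# cross-study summary
# ---------------------------------------------------------------------------

def _tidy(cohorts, methods, crs, ps):
    rows = []
    for i, c in enumerate(cohorts):
        for j, m in enumerate(methods):
            rows.append({"cohort_id": c, "method": m, "cr": crs[i][j],
                         "perm_p": ps[i][j]})
    return pd.DataFrame(rows)


def test_summary_identical_methods_give_sd0_p1():
    df = _tidy(["c1", "c2", "c3"], ["SRVS", "ANOVA"],
               [[80.0, 80.0], [90.0, 90.0], [70.0, 70.0]],
               [[0.1, 0.1]] * 3)
    summary = summarize_studies(df)
    assert summary.welch_p[("SRVS", "ANOVA")] == 1.0
    assert summary.paired_p[("SRVS", "ANOVA")] == 1.0
    df2 = _tidy(["c1", "c2"], ["SRVS"], [[80.0], [80.0]], [[0.1]] * 2)
    assert summarize_studies(df2).per_method["SRVS"]["sd_cr"] == 0.0


def test_summary_censored_entries_contribute_bound():
    assert parse_pvalue("<2.00e-4") == (2e-4, True)
    df = _tidy(["c1", "c2"], ["SRVS"], [[80.0], [90.0]],
               [["<2.00e-4"], [1e-3]])
    summary = summarize_studies(df)
    assert summary.per_method["SRVS"]["mean_perm_p"] == pytest.approx(6e-4)
    assert summary.per_method["SRVS"]["any_censored"]


def test_summary_fraction_scale_rescaled_to_percent():
    df = _tidy(["c1", "c2"], ["SRVS"], [[0.8], [0.9]], [[0.1], [0.2]])
    summary = summarize_studies(df)
    assert summary.per_method["SRVS"]["mean_cr"] == pytest.approx(85.0)


def test_summary_cohort_order_invariance():
    crs = [[80.0, 75.0], [60.0, 85.0], [90.0, 88.0]]
    ps = [[0.1, 0.2]] * 3
    a = summarize_studies(_tidy(["c1", "c2", "c3"], ["SRVS", "ANOVA"], crs, ps))
    b = summarize_studies(_tidy(["c3", "c1", "c2"], ["SRVS", "ANOVA"],
                                [crs[2], crs[0], crs[1]], ps))
    assert a.per_method == b.per_method
    assert a.welch_p == b.welch_p
    assert a.paired_p == b.paired_p


def test_summary_welch_matches_scipy():
    crs = [[80.0, 75.0], [60.0, 85.0], [90.0, 88.0], [55.0, 70.0]]
    df = _tidy(["c1", "c2", "c3", "c4"], ["SRVS", "ANOVA"], crs, [[0.1, 0.1]] * 4)
    summary = summarize_studies(df)
    expected = stats.ttest_ind([80, 60, 90, 55], [75, 85, 88, 70],
                               equal_var=False).pvalue
    assert summary.welch_p[("SRVS", "ANOVA")] == pytest.approx(expected)


def test_summary_requires_two_cohorts():
    df = _tidy(["c1"], ["SRVS"], [[80.0]], [[0.1]])
    with pytest.raises(ValueError, match="2 cohorts"):
        summarize_studies(df)
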
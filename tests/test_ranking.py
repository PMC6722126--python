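import itertools
import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coresig.data_io import CASE, CONTROL
from coresig.ranking import SRVSConfig, anova_scores, srvs_scores
from coresig.synthetic import CohortSpec, generate_dataset

from conftest import make_dataset, noise_dataset


# ---------------------------------------------------------------------------
# one-way ANOVA ranking
# ---------------------------------------------------------------------------

def test_anova_matches_sum_of_squares_oracle():
    """Direct SS oracle: cases (1,2,3), controls (4,5,6)."""
    ds = make_dataset([[1, 2, 3, 4, 5, 6]],
                      [CASE, CASE, CASE, CONTROL, CONTROL, CONTROL])
    ranked = anova_scores(ds)
    # by hand: grand mean 3.5, SSB = 3*(2-3.5)^2 + 3*(5-3.5)^2 = 13.5
    #          SSW = 2 + 2 = 4, F = 13.5 / (4/4) = 13.5
    f_expected = 13.5
    p_expected = stats.f.sf(f_expected, 1, 4)
    p = ranked.pvalues["G001"]
    assert p == pytest.approx(p_expected, abs=1e-12)
    assert ranked.scores["G001"] == pytest.approx(-np.log10(p_expected), abs=1e-10)


def test_anova_f_equals_pooled_t_squared():
    ds = noise_dataset(9, 13, 40, seed=11)
    ranked = anova_scores(ds)
    X = ds.values()
    is_case = ds.is_case
    t = stats.ttest_ind(X[:, is_case], X[:, ~is_case], axis=1, equal_var=True)
    for gene, t_stat, t_p in zip(ds.gene_symbols, t.statistic, t.pvalue):
        f_from_p = stats.f.isf(ranked.pvalues[gene], 1, ds.n_samples - 2)
        assert f_from_p == pytest.approx(t_stat ** 2, abs=1e-10, rel=1e-10)
        assert ranked.pvalues[gene] == pytest.approx(t_p, rel=1e-10)


def test_anova_equal_means_gives_f0_p1():
    ds = make_dataset([[1.0, 3.0, 1.0, 3.0]], [CASE, CASE, CONTROL, CONTROL])
    ranked = anova_scores(ds)
    assert ranked.pvalues["G001"] == 1.0


def test_anova_degenerate_zero_within_variance():
    ds = make_dataset([[2.0, 2.0, 2.0, 2.0],    # constant everywhere -> p = 1
                       [1.0, 1.0, 5.0, 5.0]],   # constant within, shifted -> tiny p
                      [CASE, CASE, CONTROL, CONTROL])
    ranked = anova_scores(ds)
    assert ranked.pvalues["G001"] == 1.0
    assert 0 < ranked.pvalues["G002"] <= np.nextafter(0.0, 1.0)
    assert ranked.order[0] == "G002"


@settings(deadline=None, derandomize=True, max_examples=25)
@given(a=st.floats(min_value=0.1, max_value=50).flatmap(
           lambda x: st.sampled_from([x, -x])),
       b=st.floats(min_value=-100, max_value=100))
def test_anova_affine_invariance(a, b):
    ds = noise_dataset(6, 6, 5, seed=5)
    before = anova_scores(ds).pvalues
    transformed = make_dataset(a * ds.values() + b, ds.labels)
    after = anova_scores(transformed).pvalues
    for gene in before:
        assert after[gene] == pytest.approx(before[gene], rel=1e-8, abs=1e-12)


# ---------------------------------------------------------------------------
# SRVS ranking
# ---------------------------------------------------------------------------

def _perfect_predictor_dataset(seed):
    rng = np.random.default_rng(seed)
    labels = [CASE] * 6 + [CONTROL] * 6
    y = np.array([1.0] * 6 + [-1.0] * 6)
    values = rng.standard_normal((10, 12))
    values[4] = y  # gene 5 equals the label vector exactly
    return make_dataset(values, labels)


@pytest.mark.parametrize("seed", [0, 1, 42])
def test_srvs_perfect_predictor_ranks_first(seed):
    ds = _perfect_predictor_dataset(seed)
    cfg = SRVSConfig(iterations=500, subset_size=3, l1_penalty=0.05, seed=seed)
    ranked = srvs_scores(ds, cfg)
    assert ranked.order[0] == "G005"
    assert ranked.scores["G005"] == max(ranked.scores.values())


def test_srvs_seeded_determinism():
    ds = _perfect_predictor_dataset(3)
    cfg = SRVSConfig(iterations=100, subset_size=3, l1_penalty=0.05, seed=9)
    first = srvs_scores(ds, cfg)
    second = srvs_scores(ds, cfg)
    assert first.scores == second.scores
    assert first.order == second.order


def lasso_oracle(Z, y, alpha):
    """Exact l1-penalized least squares for tiny designs by enumerating
    support/sign patterns: minimizes (1/2n)||y - Zw||^2 + alpha*||w||_1.

    For each sign pattern s in {-1,0,+1}^p, the stationary point on the
    implied support solves Z_S'Z_S w = Z_S'y - n*alpha*s_S; it is the
    global optimum iff signs match and off-support subgradients satisfy
    |Z_j'(y - Zw)| <= n*alpha.
    """
    n, p = Z.shape
    best_w, best_obj = np.zeros(p), np.inf

    def objective(w):
        r = y - Z @ w
        return 0.5 * (r @ r) / n + alpha * np.abs(w).sum()

    for signs in itertools.product((-1, 0, 1), repeat=p):
        s = np.array(signs, dtype=float)
        support = s != 0
        w = np.zeros(p)
        if support.any():
            Zs = Z[:, support]
            try:
                w_s = np.linalg.solve(Zs.T @ Zs,
                                      Zs.T @ y - n * alpha * s[support])
            except np.linalg.LinAlgError:
                continue
            if not np.all(np.sign(w_s) == s[support]):
                continue
            w[support] = w_s
        grad_off = Z[:, ~support].T @ (y - Z @ w)
        if np.any(np.abs(grad_off) > n * alpha * (1 + 1e-9)):
            continue
        obj = objective(w)
        if obj < best_obj:
            best_obj, best_w = obj, w.copy()
    return best_w


def test_srvs_single_subset_matches_bruteforce_l1_oracle():
    """One iteration covering all 3 genes: SRVS scores are the absolute
    coefficients of the single l1 regression, which the sign-pattern
    enumeration oracle solves in closed form."""
    values = np.array([[2.1, 1.8, 2.5, 0.4, 0.2, 0.6],
                       [1.0, 1.4, 0.9, 1.1, 1.3, 0.8],
                       [0.3, 0.9, 0.5, 1.9, 2.2, 1.7]])
    labels = [CASE, CASE, CASE, CONTROL, CONTROL, CONTROL]
    ds = make_dataset(values, labels)
    alpha = 0.07
    cfg = SRVSConfig(iterations=1, subset_size=3, l1_penalty=alpha, seed=0)
    ranked = srvs_scores(ds, cfg)

    # replicate the standardization independently
    X = values.T
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    y = np.array([1.0] * 3 + [-1.0] * 3)
    y = y - y.mean()
    w = lasso_oracle(Z, y, alpha)
    for j, gene in enumerate(ds.gene_symbols):
        assert ranked.scores[gene] == pytest.approx(abs(w[j]), abs=1e-6)


def test_srvs_sample_order_invariance():
    ds = _perfect_predictor_dataset(8)
    cfg = SRVSConfig(iterations=150, subset_size=3, l1_penalty=0.05, seed=4)
    base = srvs_scores(ds, cfg)
    perm = np.random.default_rng(0).permutation(ds.n_samples)
    shuffled = make_dataset(ds.values()[:, perm],
                            [ds.labels.iloc[i] for i in perm])
    again = srvs_scores(shuffled, cfg)
    for gene in base.scores:
        assert again.scores[gene] == pytest.approx(base.scores[gene], abs=1e-9)


def test_srvs_unsampled_genes_score_zero(caplog):
    ds = noise_dataset(3, 3, 8, seed=1)
    cfg = SRVSConfig(iterations=2, subset_size=1, l1_penalty=0.01, seed=0)
    with caplog.at_level(logging.WARNING):
        ranked = srvs_scores(ds, cfg)
    assert any("never sampled" in r.message for r in caplog.records)
    assert min(ranked.scores.values()) == 0.0


def test_srvs_subset_size_too_large_errors():
    ds = noise_dataset(3, 3, 4, seed=1)
    with pytest.raises(ValueError, match="subset_size"):
        srvs_scores(ds, SRVSConfig(iterations=5, subset_size=10, l1_penalty=0.1))


def test_srvs_penalty_grid_selection_runs():
    ds = _perfect_predictor_dataset(2)
    cfg = SRVSConfig(iterations=60, subset_size=3, l1_penalty=None, seed=0)
    ranked = srvs_scores(ds, cfg)
    assert ranked.order[0] == "G005"


# ---------------------------------------------------------------------------
# planted-signal recovery (stochastic)
# ---------------------------------------------------------------------------

def test_both_rankings_recover_planted_genes_in_top_40():
    """delta = 2 within-class SDs, 20 informative of 200 pool genes,
    40+40 samples: each method should place >= 90% of the informative
    genes within the top 40 ranks (averaged over 10 seeds)."""
    frac_srvs, frac_anova = [], []
    for seed in range(10):
        spec = CohortSpec(n_cases=40, n_controls=40, n_genome=200, n_pool=200,
                          n_informative=20, effect_size=2.0, seed=seed)
        ds, truth = generate_dataset(spec)
        informative = set(truth.informative)
        anova_top = set(anova_scores(ds).top(40))
        cfg = SRVSConfig(iterations=500, subset_size=20, l1_penalty=0.02,
                         seed=seed)
        srvs_top = set(srvs_scores(ds, cfg).top(40))
        frac_anova.append(len(anova_top & informative) / 20)
        frac_srvs.append(len(srvs_top & informative) / 20)
    assert np.mean(frac_anova) >= 0.9
    assert np.mean(frac_srvs) >= 0.9
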
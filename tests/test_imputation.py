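"""EMB machinery: time basis, EM against closed-form oracles, bootstrap
draws, conditional-normal imputation and the item/score-level MI contracts."""

import numpy as np
import pandas as pd
import pytest

from eq5dsim.amputation import ampute, build_gr_schedule, generic_schedule
from eq5dsim.datasets import ITEMS, item_mask
from eq5dsim.imputation import (
    ImputationError,
    build_time_basis,
    em_mvn,
    emb_draws,
    impute_from_draw,
    mi_items,
    mi_scores,
)
from eq5dsim.scoring import score_dataset


# ---------------------------------------------------------------------------
# time basis


def test_time_basis_caps_degree_at_t_minus_one():
    basis = build_time_basis([0, 1], degree=3)
    assert basis.shape == (2, 1)


def test_time_basis_orthogonal_over_three_point_grid():
    basis = build_time_basis([0, 1, 2], degree=2)
    assert basis.shape == (3, 2)
    gram = basis.T.to_numpy() @ basis.to_numpy()
    assert np.allclose(gram, np.eye(2), atol=1e-12)


def test_time_basis_deterministic_and_validated():
    a = build_time_basis([0, 1, 2], 2)
    b = build_time_basis([0, 1, 2], 2)
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(ImputationError):
        build_time_basis([0, 1], degree=0)


# ---------------------------------------------------------------------------
# EM


def test_em_complete_data_is_one_step_mle():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(300, 4)) @ rng.normal(size=(4, 4))
    fit = em_mvn(X)
    assert fit.n_iterations == 1
    assert np.allclose(fit.mean, X.mean(axis=0))
    assert np.allclose(fit.cov, np.cov(X, rowvar=False, ddof=0))


def _factorized_mle_bivariate(X):
    """Closed-form MLE for bivariate data with monotone missingness in col 2:
    factorize p(x1) p(x2 | x1); reconstruct joint moments."""
    x1, x2 = X[:, 0], X[:, 1]
    obs = ~np.isnan(x2)
    mu1 = x1.mean()
    s11 = x1.var()
    b = np.polyfit(x1[obs], x2[obs], 1)
    resid = x2[obs] - np.polyval(b, x1[obs])
    s_cond = resid.var()
    mu2 = b[1] + b[0] * mu1
    s12 = b[0] * s11
    s22 = s_cond + b[0] ** 2 * s11
    return np.array([mu1, mu2]), np.array([[s11, s12], [s12, s22]])


def test_em_matches_factorized_mle_under_monotone_missingness():
    rng = np.random.default_rng(3)
    n = 400
    x1 = rng.normal(1.0, 1.5, n)
    x2 = 0.8 * x1 + rng.normal(0.0, 0.7, n)
    X = np.column_stack([x1, x2])
    X[rng.random(n) < 0.4, 1] = np.nan  # MCAR monotone pattern in col 2
    fit = em_mvn(X, tol=1e-10, max_iter=2000)
    mu_o, cov_o = _factorized_mle_bivariate(X)
    assert fit.converged
    assert np.allclose(fit.mean, mu_o, atol=1e-6)
    assert np.allclose(fit.cov, cov_o, atol=1e-6)


def test_em_loglik_nondecreasing():
    rng = np.random.default_rng(5)
    X = rng.multivariate_normal([0, 1, -1], [[1, 0.5, 0.2], [0.5, 1, 0.3], [0.2, 0.3, 1]], 250)
    X[rng.random((250, 3)) < 0.25] = np.nan
    X[np.isnan(X).all(axis=1), 0] = 0.0  # keep every row partially observed
    fit = em_mvn(X)
    trace = np.asarray(fit.loglik_trace)
    assert np.all(np.diff(trace) >= -1e-8)


def test_em_rejects_all_missing_column():
    X = np.column_stack([np.arange(5.0), np.full(5, np.nan)])
    with pytest.raises(ImputationError):
        em_mvn(X)


# ---------------------------------------------------------------------------
# bootstrap draws


def test_emb_determinism_and_psd():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(120, 3))
    X[rng.random((120, 3)) < 0.2] = np.nan
    a = emb_draws(X, M=3, seed=9)
    b = emb_draws(X, M=3, seed=9)
    for fa, fb in zip(a, b):
        assert np.array_equal(fa.mean, fb.mean)
        assert np.array_equal(fa.cov, fb.cov)
        assert np.all(np.linalg.eigvalsh(fa.cov) > -1e-10)
    assert any(not np.array_equal(fa.mean, fc.mean) for fa, fc in zip(a, emb_draws(X, 3, seed=10)))


def test_bootstrap_mean_spread_shrinks_with_n():
    def spread(n, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        fits = emb_draws(X, M=20, seed=seed)
        return np.std([f.mean[0] for f in fits])

    # bootstrap SE of the mean scales like 1/sqrt(n): factor 5 in sqrt(n)
    ratio = spread(200, 4) / spread(5000, 4)
    assert 2.5 < ratio < 10.0


def test_emb_requires_at_least_two_imputations():
    with pytest.raises(ImputationError):
        emb_draws(np.zeros((10, 2)), M=1)


# ---------------------------------------------------------------------------
# conditional draws


def test_impute_preserves_observed_rows():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(50, 3))
    fit = em_mvn(X)
    out = impute_from_draw(X, fit, np.random.default_rng(0))
    assert np.array_equal(out, X)


def test_impute_conditional_mean_matches_closed_form():
    rho, s1, s2, mu = 0.7, 1.0, 2.0, np.array([1.0, -1.0])
    cov = np.array([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]])
    from eq5dsim.imputation import MultivariateNormalFit

    fit = MultivariateNormalFit(mu, cov, 1, True)
    y1 = 2.0
    X = np.tile([y1, np.nan], (20_000, 1))
    out = impute_from_draw(X, fit, np.random.default_rng(11))
    expected = mu[1] + rho * (s2 / s1) * (y1 - mu[0])
    assert out[:, 1].mean() == pytest.approx(expected, abs=0.05)
    assert out[:, 1].std() == pytest.approx(s2 * np.sqrt(1 - rho**2), rel=0.05)


def test_impute_diagonal_covariance_ignores_observed():
    from eq5dsim.imputation import MultivariateNormalFit

    fit = MultivariateNormalFit(np.array([0.0, 5.0]), np.diag([1.0, 4.0]), 1, True)
    X = np.column_stack([np.linspace(-3, 3, 10_000), np.full(10_000, np.nan)])
    out = impute_from_draw(X, fit, np.random.default_rng(7))
    # marginal draw: no dependence on the observed column
    assert abs(np.corrcoef(X[:, 0], out[:, 1])[0, 1]) < 0.03
    assert out[:, 1].mean() == pytest.approx(5.0, abs=0.07)


# ---------------------------------------------------------------------------
# item- and score-level MI contracts


def test_mi_no_missingness_returns_identical_copies(gr_cohort, default_vs):
    for fn in (mi_items, mi_scores):
        imp = fn(gr_cohort, M=3, seed=0, vs=default_vs)
        for d in imp.datasets:
            pd.testing.assert_frame_equal(d, imp.datasets[0])
        assert np.allclose(d["index"], gr_cohort["index"])


def test_mi_items_levels_and_observed_preservation(gr_cohort, default_vs):
    amp = ampute(gr_cohort, build_gr_schedule(35), seed=4)
    imp = mi_items(amp, M=4, seed=1, vs=default_vs)
    obs = item_mask(amp.data)
    for d in imp.datasets:
        items = d[list(ITEMS)]
        assert items.notna().all(axis=None)
        assert items.isin([1, 2, 3, 4, 5]).all(axis=None)
        assert d["index"].notna().all()  # all completed rows scorable
        for item in ITEMS:
            sel = obs[item]
            assert (d.loc[sel, item] == amp.data.loc[sel, item]).all()


def test_mi_scores_reproducible_and_preserves_observed(gr_cohort, default_vs):
    amp = ampute(gr_cohort, build_gr_schedule(35), seed=4)
    a = mi_scores(amp, M=3, seed=2, vs=default_vs)
    b = mi_scores(amp, M=3, seed=2, vs=default_vs)
    for da, db in zip(a.datasets, b.datasets):
        pd.testing.assert_frame_equal(da, db)
    scored = score_dataset(amp.data, default_vs)
    obs = scored["index"].notna()
    for d in a.datasets:
        assert np.allclose(d.loc[obs, "index"], scored.loc[obs, "index"])
        assert d["index"].notna().all()


def test_between_imputation_variance_positive_under_missingness(gr_cohort, default_vs):
    amp = ampute(gr_cohort, build_gr_schedule(35), seed=4)
    imp = mi_scores(amp, M=8, seed=3, vs=default_vs)
    means = [d["index"].mean() for d in imp.datasets]
    assert np.var(means) > 0


def test_mcar_self_masking_score_imputation_unbiased(gr_cohort, default_vs):
    """Blank 10% of items MCAR; Rubin-pooled mean of imputed scores should
    agree with the masked truth within Monte-Carlo error."""
    rng = np.random.default_rng(0)
    data = gr_cohort.copy()
    blank_rows = rng.random(len(data)) < 0.10
    data.loc[blank_rows, list(ITEMS)] = np.nan
    data.loc[blank_rows, "index"] = np.nan
    imp = mi_scores(data, M=20, seed=6, vs=default_vs)
    true_masked = gr_cohort.loc[blank_rows, "index"]
    imputed_means = [d.loc[blank_rows, "index"].mean() for d in imp.datasets]
    mc_se = true_masked.std() / np.sqrt(blank_rows.sum())
    assert abs(np.mean(imputed_means) - true_masked.mean()) < 2.5 * mc_se


def test_mcar_self_masking_item_differences_concentrate_at_zero(gr_cohort, default_vs):
    rng = np.random.default_rng(1)
    data = gr_cohort.copy()
    blank_rows = rng.random(len(data)) < 0.10
    data.loc[blank_rows, list(ITEMS)] = np.nan
    data.loc[blank_rows, "index"] = np.nan
    imp = mi_items(data, M=10, seed=7, vs=default_vs)
    diffs = []
    for d in imp.datasets:
        diffs.append(
            (gr_cohort.loc[blank_rows, list(ITEMS)] - d.loc[blank_rows, list(ITEMS)]).to_numpy().ravel()
        )
    diffs = np.concatenate(diffs)
    share = lambda v: np.mean(diffs == v)
    # exact recovery is the modal outcome; gross errors are rare
    assert share(0) > max(share(-1), share(1))
    assert share(-3) + share(-4) < share(-1)
    assert share(3) + share(4) < share(1)
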
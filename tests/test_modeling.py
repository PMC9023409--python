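"""Mixed model and the four approaches: closed-form oracles, an external
mixed-model cross-check, predicted-mean equivalences and approach contracts."""

import numpy as np
import pandas as pd
import pytest

from eq5dsim.amputation import AmputationSchedule, MissingnessPattern, ampute, build_gr_schedule
from eq5dsim.cohort import generate_cohort, gr_like
from eq5dsim.datasets import ITEMS, covariate_table
from eq5dsim.lmm import LMMError, fit_random_intercept, reml_objective
from eq5dsim.modeling import (
    ModelSpec,
    beta_time_of,
    fit_lmm,
    predict_means,
    run_approach_1_cc,
    run_approach_2_available,
    run_approach_3_mi_score,
    run_approach_4_mi_item,
)
from eq5dsim.scoring import score_dataset


def simulate_linear_panel(n, beta_time, sigma_b, sigma_e, seed, T=2):
    """Continuous-outcome panel with known coefficients (oracle generator)."""
    rng = np.random.default_rng(seed)
    age = rng.normal(50, 10, n)
    x = rng.normal(size=n)
    b = rng.normal(0, sigma_b, n)
    rows = []
    for i in range(n):
        for t in range(T):
            y = 0.5 + beta_time * t + 0.01 * age[i] + 0.3 * x[i] + b[i] + rng.normal(0, sigma_e)
            rows.append({"subject_id": i, "time": t, "y": y, "age": age[i], "x": x[i]})
    return pd.DataFrame(rows)


def design_of(panel):
    X = np.column_stack(
        [np.ones(len(panel)), (panel["time"] == 1).astype(float), panel["age"], panel["x"]]
    )
    return X, ["const", "time_1", "age", "x"]


def test_zero_intercept_variance_matches_ols():
    panel = simulate_linear_panel(300, 0.4, sigma_b=0.0, sigma_e=1.0, seed=1)
    X, cols = design_of(panel)
    fit = fit_random_intercept(panel["y"].to_numpy(), X, panel["subject_id"].to_numpy(), columns=cols)
    ols = np.linalg.lstsq(X, panel["y"].to_numpy(), rcond=None)[0]
    assert np.allclose(fit.beta, ols, atol=1e-4)
    assert fit.sigma_b2 < 0.05


def test_balanced_two_timepoint_slope_is_mean_paired_difference():
    panel = simulate_linear_panel(150, 0.7, sigma_b=1.0, sigma_e=0.5, seed=2)
    X = np.column_stack([np.ones(len(panel)), (panel["time"] == 1).astype(float)])
    fit = fit_random_intercept(
        panel["y"].to_numpy(), X, panel["subject_id"].to_numpy(), columns=["const", "time_1"]
    )
    wide = panel.pivot(index="subject_id", columns="time", values="y")
    paired = (wide[1] - wide[0]).mean()
    assert fit.beta[1] == pytest.approx(paired, abs=1e-6)


def test_matches_statsmodels_mixedlm():
    """Independent cross-check against a general-purpose REML implementation."""
    statsmodels = pytest.importorskip("statsmodels.api")
    panel = simulate_linear_panel(200, 0.4, sigma_b=0.8, sigma_e=0.6, seed=3)
    X, cols = design_of(panel)
    fit = fit_random_intercept(panel["y"].to_numpy(), X, panel["subject_id"].to_numpy(), columns=cols)
    sm_fit = statsmodels.MixedLM(
        panel["y"].to_numpy(), X, groups=panel["subject_id"].to_numpy()
    ).fit(reml=True)
    assert np.allclose(fit.beta, sm_fit.fe_params, atol=1e-5)
    assert fit.sigma_e2 == pytest.approx(sm_fit.scale, rel=1e-3)
    assert fit.sigma_b2 == pytest.approx(float(np.asarray(sm_fit.cov_re)[0, 0]), rel=1e-2, abs=1e-4)
    assert np.allclose(
        np.sqrt(np.diag(fit.beta_covariance)), sm_fit.bse_fe, rtol=1e-3
    )


def test_reml_optimum_is_locally_optimal():
    panel = simulate_linear_panel(200, 0.4, sigma_b=0.8, sigma_e=0.6, seed=4)
    X, cols = design_of(panel)
    y, g = panel["y"].to_numpy(), panel["subject_id"].to_numpy()
    fit = fit_random_intercept(y, X, g, columns=cols)
    theta = fit.sigma_b2 / fit.sigma_e2
    at_opt = reml_objective(fit, y, X, g, theta)
    assert at_opt <= reml_objective(fit, y, X, g, theta * 1.1) + 1e-7
    assert at_opt <= reml_objective(fit, y, X, g, theta * 0.9) + 1e-7


def test_wald_interval_coverage_for_time_slope():
    """95% intervals for the time coefficient cover the truth at nominal rate."""
    true_beta = 0.3
    hits = 0
    n_sim = 100
    for s in range(n_sim):
        panel = simulate_linear_panel(120, true_beta, sigma_b=0.7, sigma_e=0.7, seed=1000 + s)
        X, cols = design_of(panel)
        fit = fit_random_intercept(
            panel["y"].to_numpy(), X, panel["subject_id"].to_numpy(), columns=cols
        )
        se = np.sqrt(fit.beta_covariance[1, 1])
        hits += abs(fit.beta[1] - true_beta) < 1.96 * se
    assert 89 <= hits <= 99


def test_constant_column_rejected_with_name():
    panel = simulate_linear_panel(50, 0.1, 0.5, 0.5, seed=5)
    X = np.column_stack([np.ones(len(panel)), np.zeros(len(panel))])
    with pytest.raises(LMMError, match="dead_dummy"):
        fit_random_intercept(
            panel["y"].to_numpy(), X, panel["subject_id"].to_numpy(), columns=["const", "dead_dummy"]
        )


# ---------------------------------------------------------------------------
# predicted means


def test_time_dummy_model_reproduces_raw_means_on_balanced_data(gr_cohort):
    spec = ModelSpec(covariates=())
    fit = fit_lmm(gr_cohort, spec)
    pm = predict_means(fit, covariate_table(gr_cohort), spec=spec)
    raw = gr_cohort.groupby("time")["index"].mean()
    for r in pm.table.itertuples():
        assert r.mean == pytest.approx(raw.loc[r.time], abs=1e-8)


def test_predicted_mean_se_shrinks_with_sample_size(default_vs):
    ses = {}
    for n in (200, 800):
        data = score_dataset(generate_cohort(gr_like(seed=6, n_subjects=n)), default_vs)
        fit = fit_lmm(data)
        ses[n] = predict_means(fit, covariate_table(data)).table["se"].iloc[0]
    assert ses[800] < ses[200]
    assert ses[200] / ses[800] == pytest.approx(2.0, rel=0.35)


def test_fit_requires_scored_rows(gr_cohort):
    empty = gr_cohort.copy()
    empty["index"] = np.nan
    with pytest.raises(LMMError):
        fit_lmm(empty)


# ---------------------------------------------------------------------------
# approaches


def test_all_approaches_identical_at_zero_missingness(gr_cohort, default_vs):
    r1 = run_approach_1_cc(gr_cohort, default_vs)
    r2 = run_approach_2_available(gr_cohort, default_vs)
    r3 = run_approach_3_mi_score(gr_cohort, default_vs, M=3, seed=0)
    r4 = run_approach_4_mi_item(gr_cohort, default_vs, M=3, seed=0)
    for r in (r2, r3, r4):
        assert np.allclose(r.means["mean"], r1.means["mean"], atol=1e-10)
        assert r.beta_time == pytest.approx(r1.beta_time, abs=1e-10)
    assert np.allclose(r3.means["se"], r2.means["se"], atol=1e-10)  # B = 0


def test_available_data_keeps_partial_subjects(gr_cohort, default_vs):
    unr_t1 = AmputationSchedule(
        0.3, [MissingnessPattern(tuple((1, i) for i in ITEMS), 1.0)]
    )
    amp = ampute(gr_cohort, unr_t1, seed=1)
    r1 = run_approach_1_cc(amp, default_vs)
    r2 = run_approach_2_available(amp, default_vs)
    assert r2.n_rows > r1.n_rows
    assert r2.n_subjects == 450  # every subject still has a scored baseline row
    assert r1.n_subjects < 450


def test_cc_overestimates_under_health_weighted_dropout(gr_cohort, default_vs):
    """Health-selected dropout leaves healthier complete cases, so the CC
    trajectory sits above the full-cohort truth at both timepoints."""
    truth = run_approach_2_available(gr_cohort, default_vs)
    diffs = []
    for s in range(10):
        amp = ampute(gr_cohort, build_gr_schedule(65), seed=s)
        cc = run_approach_1_cc(amp, default_vs)
        diffs.append(cc.means["mean"].to_numpy() - truth.means["mean"].to_numpy())
    assert (np.mean(diffs, axis=0) > 0).all()


def test_pooled_se_dominates_mean_within_se(gr_cohort, default_vs):
    amp = ampute(gr_cohort, build_gr_schedule(35), seed=2)
    res = run_approach_3_mi_score(amp, default_vs, M=8, seed=1)
    from eq5dsim.imputation import mi_scores

    imp = mi_scores(amp, 8, 1, default_vs)
    per_imp_se = []
    for d in imp.datasets:
        fit = fit_lmm(d)
        used = d.dropna(subset=["index"])["subject_id"].unique()
        pm = predict_means(fit, covariate_table(d[d.subject_id.isin(used)]))
        per_imp_se.append(pm.table["se"].to_numpy())
    assert (res.means["se"].to_numpy() >= np.mean(per_imp_se, axis=0) - 1e-12).all()


def test_mi_item_imputations_all_scorable(gr_cohort, default_vs):
    amp = ampute(gr_cohort, build_gr_schedule(45), seed=3)
    res, imp = run_approach_4_mi_item(amp, default_vs, M=4, seed=2, return_imputations=True)
    for d in imp.datasets:
        assert d["index"].notna().all()
    assert res.m == 4
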
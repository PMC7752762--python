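"""Tests of the random-intercept REML fitter and Satterthwaite inference."""

import numpy as np
import pandas as pd
import pytest

from wasatrial.config import CohortConfig
from wasatrial.lmm import (
    ModelSpec,
    _group_structure,
    _neg2_reml_at_theta,
    _weighted_normal_eqs,
    contrast_test,
    fit_lmm,
    fit_random_intercept,
    multi_contrast_test,
    omnibus_group_test,
    pairwise_12mo_contrasts,
    satterthwaite_df,
)
from wasatrial.synthetic import generate_cohort

from conftest import small_config

# printed 6-subject fixture: 2 visits each, one covariate
FIXTURE_Y = np.array([1.3, 2.1, 0.4, 0.9, 2.2, 2.9, 1.0, 1.7, 3.1, 3.6, 0.2, 1.1])
FIXTURE_X = np.column_stack(
    [
        np.ones(12),
        np.tile([0.0, 1.0], 6),  # visit indicator
        np.array([0.5, 0.5, -1.2, -1.2, 0.8, 0.8, -0.3, -0.3, 1.5, 1.5, -1.0, -1.0]),
    ]
)
FIXTURE_G = np.repeat(np.arange(6), 2)


def _dense_gls(y, X, groups, s2_u, s2_e):
    """Direct dense-matrix GLS oracle: beta = (X'V^-1X)^-1 X'V^-1 y."""
    n = len(y)
    Z = (groups[:, None] == np.unique(groups)[None, :]).astype(float)
    V = s2_e * np.eye(n) + s2_u * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    A = X.T @ Vinv @ X
    return np.linalg.solve(A, X.T @ Vinv @ y), np.linalg.inv(A)


def test_reml_beta_matches_dense_gls_oracle():
    """Fixed effects equal the explicit GLS solution at the fitted variances."""
    fit = fit_random_intercept(FIXTURE_Y, FIXTURE_X, FIXTURE_G)
    beta_oracle, vcov_oracle = _dense_gls(
        FIXTURE_Y, FIXTURE_X, FIXTURE_G, fit.sigma2_subject, fit.sigma2_residual
    )
    np.testing.assert_allclose(fit.beta.to_numpy(), beta_oracle, atol=1e-8)
    np.testing.assert_allclose(fit.vcov_beta, vcov_oracle, atol=1e-8)


def test_reml_objective_is_locally_optimal():
    """The restricted likelihood at the estimate beats nearby perturbations."""
    fit = fit_random_intercept(FIXTURE_Y, FIXTURE_X, FIXTURE_G)
    order, starts, sizes = _group_structure(FIXTURE_G)
    Xs, ys = FIXTURE_X[order], FIXTURE_Y[order]
    at_opt = _neg2_reml_at_theta(fit.theta, Xs, ys, starts, sizes)
    for d_u in (-0.05, 0.05):
        for d_e in (-0.05, 0.05):
            theta = fit.theta * (1 + np.array([d_u, d_e]))
            assert _neg2_reml_at_theta(theta, Xs, ys, starts, sizes) >= at_opt - 1e-9


def test_reml_matches_statsmodels_mixedlm():
    """Independent cross-check of variance components and fixed effects."""
    sm = pytest.importorskip("statsmodels.api")
    fit = fit_random_intercept(FIXTURE_Y, FIXTURE_X, FIXTURE_G)
    res = sm.MixedLM(FIXTURE_Y, FIXTURE_X, groups=FIXTURE_G).fit(reml=True)
    np.testing.assert_allclose(fit.beta.to_numpy(), res.fe_params, atol=1e-5)
    np.testing.assert_allclose(fit.sigma2_residual, res.scale, rtol=1e-4)
    np.testing.assert_allclose(fit.sigma2_subject, float(np.asarray(res.cov_re)[0, 0]), rtol=1e-3)


def test_degenerate_variance_split():
    """Responses constant within subject: residual variance 0, subject
    variance the between-subject variance of the means."""
    y = np.array([3.0, 3.0, 3.0, 7.0, 7.0, 7.0])
    fit = fit_random_intercept(y, np.ones((6, 1)), np.array([1, 1, 1, 2, 2, 2]))
    assert fit.sigma2_residual == pytest.approx(0.0, abs=1e-8)
    assert fit.sigma2_subject == pytest.approx(np.var([3.0, 7.0], ddof=1), rel=1e-5)


def test_subject_variance_zero_reduces_to_ols():
    """Constrained sigma2_subject = 0: beta, vcov and Satterthwaite df all
    collapse to ordinary least squares and its residual df."""
    rng = np.random.default_rng(2)
    n = 60
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ np.array([1.0, -0.5]) + rng.normal(size=n)
    groups = np.arange(n) // 3
    fit = fit_random_intercept(y, X, groups, constrain_subject_var_zero=True)
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    s2 = resid @ resid / (n - 2)
    np.testing.assert_allclose(fit.beta.to_numpy(), beta_ols, atol=1e-10)
    np.testing.assert_allclose(fit.vcov_beta, s2 * np.linalg.inv(X.T @ X), rtol=1e-10)
    df = satterthwaite_df(fit, np.array([0.0, 1.0]))
    assert abs(df - (n - 2)) < 0.1


def test_satterthwaite_balanced_between_subject_design():
    """Two groups of subjects with replicate measurements: the df of the
    group-mean contrast is the classical two-sample df on subject means."""
    k, m = 10, 3
    rng = np.random.default_rng(7)
    subs = np.repeat(np.arange(2 * k), m)
    grp = (subs >= k).astype(float)
    y = 1.5 * grp + rng.normal(0, 1.2, 2 * k)[subs] + rng.normal(0, 0.8, 2 * k * m)
    X = np.column_stack([np.ones(2 * k * m), grp])
    fit = fit_random_intercept(y, X, subs)
    df = satterthwaite_df(fit, np.array([0.0, 1.0]))
    assert abs(df - (2 * k - 2)) < 0.5


def test_satterthwaite_df_is_stable_under_tiny_theta_perturbation():
    fit = fit_random_intercept(FIXTURE_Y, FIXTURE_X, FIXTURE_G)
    c = np.array([0.0, 1.0, 0.0])

    def df_at(theta):
        order, starts, sizes = _group_structure(FIXTURE_G)
        lam = theta[0] / theta[1]
        XtWX, _, _ = _weighted_normal_eqs(FIXTURE_X[order], FIXTURE_Y[order], starts, sizes, lam)
        import dataclasses

        f2 = dataclasses.replace(
            fit,
            sigma2_subject=theta[0],
            sigma2_residual=theta[1],
            vcov_beta=theta[1] * np.linalg.inv(XtWX),
        )
        return satterthwaite_df(f2, c)

    base = df_at(fit.theta)
    for j in (0, 1):
        theta = fit.theta.copy()
        theta[j] += 1e-6
        assert abs(df_at(theta) - base) < 0.01


def test_single_row_hypothesis_equals_squared_t():
    fit = fit_random_intercept(FIXTURE_Y, FIXTURE_X, FIXTURE_G)
    c = np.array([0.0, 1.0, 0.5])
    t_res = contrast_test(fit, c)
    f_res = multi_contrast_test(fit, c[None, :])
    assert f_res.F == pytest.approx(t_res.t**2, rel=1e-10)
    assert f_res.df2 == pytest.approx(t_res.df, rel=1e-6)


def test_estimates_invariant_to_row_order_and_relabeling(default_cohort):
    _, participants, outcomes, _ = default_cohort
    spec = ModelSpec(measure="fat_mass")
    fit1 = fit_lmm(outcomes, participants, spec)
    shuffled = outcomes.sample(frac=1.0, random_state=5).reset_index(drop=True)
    relabel = {pid: f"Q{i:04d}" for i, pid in enumerate(participants["participant_id"][::-1])}
    shuffled2 = shuffled.assign(participant_id=shuffled["participant_id"].map(relabel))
    participants2 = participants.assign(
        participant_id=participants["participant_id"].map(relabel)
    )
    fit2 = fit_lmm(shuffled2, participants2, spec)
    np.testing.assert_allclose(fit1.beta.to_numpy(), fit2.beta.to_numpy(), atol=1e-5)
    np.testing.assert_allclose(fit1.sigma2_subject, fit2.sigma2_subject, rtol=1e-5)


def test_noise_free_cohort_recovers_contrasts_exactly():
    """Without noise the men's HLC-HLF contrast equals the generating -2.98 kg."""
    cfg = CohortConfig(
        seed=5,
        retention_prob=1.0,
        dexa_missing_fraction=0.0,
        subject_sd_kg=0.0,
        residual_sd_kg=0.0,
        adherence_effect_kg=0.0,
    )
    participants, outcomes, _ = generate_cohort(cfg)
    fit = fit_lmm(outcomes, participants, ModelSpec(measure="weight"))
    results = {c.label: c.estimate for c in pairwise_12mo_contrasts(fit)}
    assert results["HLC vs HLF, men"] == pytest.approx(-2.98, abs=1e-8)
    assert results["Men vs women, HLC"] == pytest.approx(-2.32, abs=1e-8)
    assert results["HLC vs HLF, women"] == pytest.approx(0.0, abs=1e-8)


def test_relabeling_diets_flips_within_sex_contrasts(default_cohort):
    _, participants, outcomes, _ = default_cohort
    fit = fit_lmm(outcomes, participants, ModelSpec(measure="weight"))
    swapped = participants.assign(diet=participants["diet"].map({"HLC": "HLF", "HLF": "HLC"}))
    fit_sw = fit_lmm(outcomes, swapped, ModelSpec(measure="weight"))
    orig = {c.label: c for c in pairwise_12mo_contrasts(fit)}
    flip = {c.label: c for c in pairwise_12mo_contrasts(fit_sw)}
    for label in ("HLC vs HLF, women", "HLC vs HLF, men"):
        assert flip[label].estimate == pytest.approx(-orig[label].estimate, rel=1e-5)


def test_satterthwaite_df_bounded_by_residual_df(default_cohort):
    _, participants, outcomes, _ = default_cohort
    for measure in ("weight", "lean_mass"):
        fit = fit_lmm(outcomes, participants, ModelSpec(measure=measure))
        for c in pairwise_12mo_contrasts(fit):
            assert 0 < c.df <= fit.n_obs - fit.rank + 0.5
        ob = omnibus_group_test(fit)
        assert ob.df1 == 3 and ob.F >= 0 and 0 <= ob.p <= 1


def test_few_groups_is_an_error(default_cohort):
    _, participants, outcomes, _ = default_cohort
    only_one = participants[(participants["diet"] == "HLC") & (participants["sex"] == "F")]
    with pytest.raises(ValueError, match="group"):
        fit_lmm(outcomes, only_one, ModelSpec(measure="weight"))


def test_analysis_set_flag_changes_sample(default_cohort):
    """'all' keeps participants without DEXA in the weight model (mean-imputed
    body fat); 'dexa' restricts to complete cases."""
    _, participants, outcomes, _ = default_cohort
    fit_dexa = fit_lmm(outcomes, participants, ModelSpec(measure="weight", analysis_set="dexa"))
    fit_all = fit_lmm(outcomes, participants, ModelSpec(measure="weight", analysis_set="all"))
    assert fit_all.n_subjects > fit_dexa.n_subjects
    assert fit_all.n_obs > fit_dexa.n_obs
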
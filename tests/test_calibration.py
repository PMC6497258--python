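"""Calibration engine: likelihood, MLE fitting, AIC and selection logic."""

import numpy as np
import pytest
from scipy import stats

from gestphys.calibration import (
    DegenerateVarianceError,
    FitResult,
    GrowthCurveMLE,
    NoFeasibleModelError,
    PreferredModelSelector,
    SummaryDataset,
    SummaryPoint,
    aic,
    fit_mle,
    impute_summary,
    log_likelihood,
    select_model,
)
from gestphys.families import BODY_MASS, make_spec


def dataset_from(covs, means, sd=None, n=None, **kw):
    pts = tuple(
        SummaryPoint(
            float(c), float(m),
            sd=None if sd is None else float(np.broadcast_to(sd, np.shape(covs)).flat[i]),
            n=None if n is None else int(np.broadcast_to(n, np.shape(covs)).flat[i]),
        )
        for i, (c, m) in enumerate(zip(covs, means))
    )
    return SummaryDataset(pts, **kw)


# ---------------------------------------------------------------------------
# imputation

def test_impute_fills_missing_with_20pct_cv_and_n1():
    ds = impute_summary(dataset_from([1.0], [10.0]))
    p = ds.points[0]
    assert p.sd == pytest.approx(2.0) and p.n == 1
    assert p.imputed_sd and p.imputed_n


def test_impute_leaves_complete_points_untouched():
    ds = impute_summary(dataset_from([1.0], [5.0], sd=[1.0], n=[12]))
    p = ds.points[0]
    assert p.sd == 1.0 and p.n == 12
    assert not p.imputed_sd and not p.imputed_n


def test_impute_rejects_zero_mean_without_sd():
    with pytest.raises(DegenerateVarianceError):
        impute_summary(dataset_from([1.0], [0.0]))


# ---------------------------------------------------------------------------
# likelihood

def test_loglik_zero_residual_unit_variance():
    spec = make_spec("linear", (0.0, 1.0))
    ds = dataset_from([5.0], [5.0], sd=[1.0], n=[1])
    assert log_likelihood(spec, ds) == pytest.approx(-0.5 * np.log(2 * np.pi))


def test_loglik_matches_gaussian_density_product():
    # for n=1 records the likelihood is the product of normal densities
    spec = make_spec("linear", (1.0, 0.5))
    covs, means, sds = [2.0, 7.0], [2.4, 4.1], [0.3, 0.8]
    ds = dataset_from(covs, means, sd=sds, n=[1, 1])
    expected = sum(
        stats.norm.logpdf(m, loc=spec(c), scale=s)
        for c, m, s in zip(covs, means, sds)
    )
    assert log_likelihood(spec, ds) == pytest.approx(expected, rel=1e-12)


def test_loglik_decreases_with_residual():
    ds_near = dataset_from([1.0], [1.1], sd=[1.0], n=[3])
    ds_far = dataset_from([1.0], [3.0], sd=[1.0], n=[3])
    spec = make_spec("linear", (0.0, 1.0))
    assert log_likelihood(spec, ds_near) > log_likelihood(spec, ds_far)


def test_loglik_requires_imputed_positive_variance():
    spec = make_spec("linear", (0.0, 1.0))
    with pytest.raises(ValueError, match="impute"):
        log_likelihood(spec, dataset_from([1.0], [1.0]))
    with pytest.raises(DegenerateVarianceError):
        log_likelihood(spec, dataset_from([1.0], [1.0], sd=[0.0], n=[1]))


def test_loglik_translation_equivariance():
    rng = np.random.default_rng(3)
    covs = np.arange(1.0, 9.0)
    means = 2.0 + 0.5 * covs + rng.normal(0, 0.1, covs.size)
    shift = 7.3
    fit0 = fit_mle("linear", dataset_from(covs, means, sd=0.2, n=4), seed=1)
    fit1 = fit_mle("linear", dataset_from(covs + shift, means, sd=0.2, n=4), seed=1)
    assert fit1.loglik == pytest.approx(fit0.loglik, abs=1e-6)
    assert fit1.spec.theta[1] == pytest.approx(fit0.spec.theta[1], abs=1e-6)
    assert fit1.spec.theta[0] == pytest.approx(
        fit0.spec.theta[0] - shift * fit0.spec.theta[1], abs=1e-5
    )


# ---------------------------------------------------------------------------
# AIC

def test_aic_identity_printed_rows():
    assert aic(3, -739.00) == pytest.approx(1484.00)
    assert aic(3, -1059.02) == pytest.approx(2124.04)
    assert aic(2, 0.0) == 4.0


def test_fit_result_enforces_aic_identity():
    spec = make_spec("linear", (0.0, 1.0))
    with pytest.raises(ValueError, match="AIC"):
        FitResult(spec=spec, loglik=-10.0, k=2, aic=0.0, converged=True,
                  n_starts=1, seed=0)


# ---------------------------------------------------------------------------
# fitting

def test_noiseless_exact_recovery():
    covs = np.arange(1.0, 11.0)
    means = 2.0 * covs
    ds = dataset_from(covs, means, sd=0.2 * means, n=1)
    fit = fit_mle("linear_growth", ds, seed=0, n_starts=5)
    assert fit.converged
    assert fit.spec.theta[0] == pytest.approx(2.0, abs=1e-8)


def test_fit_requires_enough_points():
    ds = dataset_from([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], sd=0.1, n=1)
    with pytest.raises(ValueError, match="points"):
        fit_mle("cubic", ds, seed=0)


def test_optimizer_matches_grid_search_oracle():
    # 2-parameter family on 5 points vs an exhaustive 201x201 grid
    true = (1.0, 0.3)
    covs = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    rng = np.random.default_rng(11)
    means = true[0] * covs + true[1] * covs**2 + rng.normal(0, 0.2, covs.size)
    ds = dataset_from(covs, means, sd=0.5, n=3)
    fit = fit_mle("quadratic_growth", ds, seed=4, n_starts=10)

    t0 = np.linspace(true[0] - 1.0, true[0] + 1.0, 201)
    t1 = np.linspace(true[1] - 0.2, true[1] + 0.2, 201)
    g0, g1 = np.meshgrid(t0, t1, indexing="ij")
    pred = g0[..., None] * covs + g1[..., None] * covs**2
    # same weighted-residual objective the likelihood maximises
    ssr = np.sum(3.0 * (means - pred) ** 2 / 0.5**2, axis=-1)
    i, j = np.unravel_index(np.argmin(ssr), ssr.shape)
    cell0, cell1 = t0[1] - t0[0], t1[1] - t1[0]
    assert abs(fit.spec.theta[0] - t0[i]) <= cell0
    assert abs(fit.spec.theta[1] - t1[j]) <= cell1
    grid_best = make_spec("quadratic_growth", (t0[i], t1[j]))
    assert fit.loglik >= log_likelihood(grid_best, impute_summary(ds)) - 1e-9


def test_theta_independent_terms_do_not_move_argmax():
    # maximising the full likelihood equals minimising the weighted SSR
    rng = np.random.default_rng(5)
    covs = np.arange(2.0, 12.0)
    means = 3.0 + 0.7 * covs + rng.normal(0, 0.3, covs.size)
    sd, n = 0.5, 4
    ds = dataset_from(covs, means, sd=sd, n=n)
    fit = fit_mle("linear", ds, seed=2, n_starts=5)
    # closed-form weighted least squares (equal weights here)
    design = np.stack([np.ones_like(covs), covs], axis=1)
    wls, *_ = np.linalg.lstsq(design, means, rcond=None)
    np.testing.assert_allclose(fit.spec.theta, wls, atol=1e-6)


# ---------------------------------------------------------------------------
# selection

def _result(family_id, theta, loglik, covariate_kind="age_weeks", seed=0):
    spec = make_spec(family_id, theta, covariate_kind)
    k = spec.family.k
    return FitResult(spec=spec, loglik=loglik, k=k, aic=2 * k - 2 * loglik,
                     converged=True, n_starts=1, seed=seed)


def test_selection_negativity_screen_prefers_positive_runner_up():
    # fetal-brain-like scenario: the cubic growth wins on AIC but dips
    # negative in early gestation; the Gompertz runner-up is preferred
    cubic = _result("cubic_growth", (-2.1208, 0.15645, 0.0034746), -10927.7)
    gompertz = _result("gompertz", (0.01574, 0.70707, 0.064827), -10943.7)
    report = select_model([cubic, gompertz])
    assert report.ranked[0].family_id == "cubic_growth"
    assert report.preferred == "gompertz"
    assert report.rationale == "lowest_nonneg_aic"
    assert report.screened_out["cubic_growth"] == pytest.approx(0.1)


def test_selection_plain_argmin_when_all_feasible():
    a = _result("linear", (1.0, 0.1), -50.0)
    b = _result("quadratic", (1.0, 0.1, 0.01), -49.9)
    report = select_model([a, b])
    assert report.preferred == "linear"
    assert report.rationale == "lowest_aic"


def test_selection_tiebreak_prefers_age_covariate():
    # plasma-volume-like tie: a 0.06 AIC gap is too small to matter, and the
    # age-based covariate avoids an intermediate body-mass model
    luecke = _result(
        "modified_luecke_power_law",
        (1.1650, 0.14125, -0.083058, 2.5002),
        -(365.07 - 8) / 2,
        covariate_kind=BODY_MASS,
    )
    logistic = _result(
        "modified_logistic", (1.2406, 0.31338, 17.813, 2.4958), -(365.13 - 8) / 2
    )
    report = select_model([luecke, logistic])
    assert report.ranked[0].family_id == "modified_luecke_power_law"
    assert report.preferred == "modified_logistic"
    assert report.rationale == "tiebreak"


def test_selection_all_screened_out():
    neg = _result("linear", (-5.0, 0.0), -1.0)
    with pytest.raises(NoFeasibleModelError):
        select_model([neg])


# ---------------------------------------------------------------------------
# sklearn surface

def test_estimator_fit_predict_and_params():
    from sklearn.base import clone

    x = np.arange(1.0, 11.0)
    y = 2.0 * x
    est = GrowthCurveMLE(family="linear_growth", n_starts=5, random_state=0)
    cloned = clone(est)
    assert cloned.get_params()["family"] == "linear_growth"
    est.fit(x, y, sd=0.2 * y, n=1)
    assert est.converged_
    assert est.aic_ == pytest.approx(2 * est.k_ - 2 * est.loglik_)
    np.testing.assert_allclose(est.predict([3.0, 6.0]), [6.0, 12.0], atol=1e-6)


def test_preferred_model_selector_recovers_generating_family():
    spec = make_spec("quadratic_growth", (2.0, 0.5))
    x = np.arange(5.0, 41.0, 5.0)
    rng = np.random.default_rng(8)
    y = np.asarray(spec(x)) * (1 + rng.normal(0, 0.02, x.size))
    sel = PreferredModelSelector(
        families=["linear_growth", "quadratic_growth", "gompertz"],
        n_starts=8, random_state=1,
    )
    sel.fit(x, y, sd=0.05 * np.abs(y), n=5)
    assert sel.preferred_ == "quadratic_growth"
    assert sel.predict([20.0])[0] == pytest.approx(spec(20.0), rel=0.05)
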
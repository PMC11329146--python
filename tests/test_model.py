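"""Trend model: fit/predict behaviour, pointwise densities, invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import huntwatch as hw
from huntwatch.model import (
    ModelSpec,
    PosteriorDraws,
    log_pointwise_density,
    loglik_matrix,
    nb_logpmf,
    predict,
    predictive_draws,
)
from huntwatch.panel import PanelValidationError

from conftest import make_panel


def _point_mass_draws(alpha, theta, years, beta=0.0, S=400, spec=None):
    """Degenerate posterior with every draw at the same parameter point."""
    T = len(years)
    return PosteriorDraws(
        alpha=np.full((1, S), float(alpha)),
        beta=np.full((1, S), float(beta)),
        u=np.zeros((1, S, 1)),
        v=np.zeros((1, S, 1)),
        gamma=np.zeros((1, S, T)),
        sigma_u=np.zeros((1, S)),
        sigma_v=np.zeros((1, S)),
        sigma_gamma=np.zeros((1, S)),
        theta=np.full((1, S), float(theta)),
        provinces=("A",),
        regions=("R",),
        region_index=np.array([0]),
        training_years=tuple(years),
        model_spec=spec or ModelSpec("pm", True, 1, "nested"),
        seed=0,
    )


def test_constant_counts_recover_location():
    """Intercept-only NB fit on constant counts centres on the data level."""
    panel = make_panel({"A": [100] * 9})
    est = hw.NegativeBinomialTrendModel(
        include_linear_trend=False, rw_order=0, training_cutoff=2019, seed=1
    )
    est.fit(panel)
    mu_post = np.exp(est.draws_.flat("alpha"))
    assert 90 < mu_post.mean() < 110
    summ = predict(est.draws_, [2020], seed=2, region_of={"A": "R"})
    assert 95 <= summ["median"].iloc[0] <= 105


def test_needs_three_training_years():
    panel = make_panel({"A": [10, 11]})
    with pytest.raises(PanelValidationError, match="3 training years"):
        hw.NegativeBinomialTrendModel(training_cutoff=2012).fit(panel)


def test_point_mass_predictive_matches_nb_quantiles():
    """With a degenerate posterior and sigma_gamma = 0 the predictive
    distribution is exactly NB at the linear predictor; with huge theta it
    collapses to Poisson quantile width around round(exp(eta))."""
    years = tuple(range(2011, 2020))
    mu = 500.0
    d = _point_mass_draws(np.log(mu), 1e9, years, S=2000)
    summ = predict(d, [2020, 2021], seed=3, pred_reps=5, region_of={"A": "R"})
    med = summ["median"].to_numpy()
    assert np.all(np.abs(med - mu) <= 2)
    width = (summ["hi95"] - summ["lo95"]).to_numpy()
    pois_width = stats.poisson.ppf(0.975, mu) - stats.poisson.ppf(0.025, mu)
    assert np.all(np.abs(width - pois_width) <= 5)


def test_prediction_requires_future_years(small_fit):
    with pytest.raises(ValueError, match="after the last training year"):
        predict(small_fit.draws_, [2019], seed=0)


def test_fit_and_predict_deterministic_under_seed(small_panel):
    panel, _, _ = small_panel
    kw = dict(training_cutoff=2019, chains=2, draws=300, warmup=300, seed=77)
    a = hw.NegativeBinomialTrendModel(**kw).fit(panel)
    b = hw.NegativeBinomialTrendModel(**kw).fit(panel)
    np.testing.assert_array_equal(a.draws_.alpha, b.draws_.alpha)
    np.testing.assert_array_equal(a.draws_.theta, b.draws_.theta)
    s1 = a.predictive_summary(seed=5)
    s2 = b.predictive_summary(seed=5)
    pd.testing.assert_frame_equal(s1, s2)


def test_predictive_median_monte_carlo_stability(small_fit):
    """More predictive draws move the reported median by well under 1%."""
    lo = small_fit.predictive_summary(seed=1, pred_reps=2)
    hi = small_fit.predictive_summary(seed=2, pred_reps=20)
    rel = np.abs(hi["median"] - lo["median"]) / hi["median"]
    assert rel.max() < 0.01


def test_predictive_median_monotone_in_level(small_panel):
    """Multiplying all training counts by c scales predictive medians by ~c."""
    panel, _, _ = small_panel
    doubled = hw.LicensePanel(
        provinces=panel.provinces,
        region_of=panel.region_of,
        years=panel.years,
        counts={k: 2 * v for k, v in panel.counts.items()},
    )
    kw = dict(training_cutoff=2019, chains=2, draws=600, warmup=600, seed=13)
    m1 = hw.NegativeBinomialTrendModel(**kw).fit(panel).predictive_summary(seed=4)
    m2 = hw.NegativeBinomialTrendModel(**kw).fit(doubled).predictive_summary(seed=4)
    ratio = m2["median"].to_numpy() / m1["median"].to_numpy()
    assert abs(np.median(ratio) - 2.0) < 0.1


def test_missing_training_cell_is_tolerated():
    counts = {"A": [100, 102, 98, None, 97, 96, 95, 99, 94], "B": [200] * 9}
    panel = make_panel(counts, region_of={"A": "R", "B": "R"})
    est = hw.NegativeBinomialTrendModel(
        include_linear_trend=False, rw_order=1, training_cutoff=2019,
        chains=2, draws=300, warmup=300, seed=3,
    )
    est.fit(panel)  # must not raise
    with pytest.warns(UserWarning, match="excluded"):
        lpd = log_pointwise_density(est.draws_, panel, [("A", 2013), ("A", 2014)])
    assert list(lpd["year"]) == [2013]  # 2014 is the missing season


# ------------------------------------------------------------------
# log pointwise predictive density


def test_lpd_single_draw_equals_direct_pmf():
    years = tuple(range(2011, 2020))
    d = _point_mass_draws(np.log(120.0), 30.0, years, S=1)
    panel = make_panel({"A": [115] * 9})
    ll, cells = loglik_matrix(d, panel, [("A", 2011)])
    direct = stats.nbinom.logpmf(115, 30.0, 30.0 / (30.0 + 120.0))
    assert ll[0, 0] == pytest.approx(direct, abs=1e-10)
    lpd = log_pointwise_density(d, panel, [("A", 2011)])
    assert lpd["lpd"].iloc[0] == pytest.approx(direct, abs=1e-10)


def test_lpd_identical_draws_equal_one_draw_value():
    years = tuple(range(2011, 2020))
    one = _point_mass_draws(np.log(120.0), 30.0, years, S=1)
    many = _point_mass_draws(np.log(120.0), 30.0, years, S=64)
    panel = make_panel({"A": [115] * 9})
    a = log_pointwise_density(one, panel, [("A", 2011)])["lpd"].iloc[0]
    b = log_pointwise_density(many, panel, [("A", 2011)])["lpd"].iloc[0]
    assert a == pytest.approx(b, abs=1e-12)


def test_lpd_matches_high_precision_summation():
    """log-mean-exp over heterogeneous draws vs extended-precision average."""
    rng = np.random.default_rng(0)
    S = 40
    years = tuple(range(2011, 2020))
    alphas = np.log(100.0) + rng.normal(0, 0.2, S)
    thetas = np.exp(np.log(25.0) + rng.normal(0, 0.3, S))
    d = PosteriorDraws(
        alpha=alphas[None, :],
        beta=np.zeros((1, S)),
        u=np.zeros((1, S, 1)),
        v=np.zeros((1, S, 1)),
        gamma=np.zeros((1, S, len(years))),
        sigma_u=np.zeros((1, S)),
        sigma_v=np.zeros((1, S)),
        sigma_gamma=np.zeros((1, S)),
        theta=thetas[None, :],
        provinces=("A",),
        regions=("R",),
        region_index=np.array([0]),
        training_years=years,
        model_spec=ModelSpec("m", False, 0, "nested"),
        seed=0,
    )
    panel = make_panel({"A": [93] * 9})
    got = log_pointwise_density(d, panel, [("A", 2015)])["lpd"].iloc[0]
    pmf = np.array(
        [stats.nbinom.logpmf(93, t, t / (t + np.exp(a))) for a, t in zip(alphas, thetas)],
        dtype=np.longdouble,
    )
    expected = float(np.log(np.exp(pmf).mean()))
    assert got == pytest.approx(expected, abs=1e-10)


def test_nb_logpmf_agrees_with_scipy():
    y = np.arange(0, 50)
    got = nb_logpmf(y, 12.3, 7.5)
    ref = stats.nbinom.logpmf(y, 7.5, 7.5 / (7.5 + 12.3))
    np.testing.assert_allclose(got, ref, atol=1e-12)


def test_draws_persistence_round_trip(small_fit):
    d = small_fit.draws_
    back = PosteriorDraws.from_frame(d.to_frame(), d.meta())
    np.testing.assert_allclose(back.alpha, d.alpha)
    np.testing.assert_allclose(back.v, d.v)
    np.testing.assert_allclose(back.gamma, d.gamma)
    assert back.model_spec == d.model_spec
    assert back.provinces == d.provinces


def test_diagnostics_flag_convergence(small_fit):
    diag = small_fit.diagnostics_
    assert diag.max_rhat <= 1.05 and diag.usable
    assert diag.min_ess_bulk > 20


def test_sum_to_zero_constraints_hold(small_fit):
    d = small_fit.draws_
    np.testing.assert_allclose(d.flat("u").sum(axis=1), 0.0, atol=1e-10)
    # province effects sum to zero within every region
    for r in range(len(d.regions)):
        members = np.flatnonzero(d.region_index == r)
        np.testing.assert_allclose(d.flat("v")[:, members].sum(axis=1), 0.0, atol=1e-10)
    # random walk anchored at the first training year
    np.testing.assert_allclose(d.flat("gamma")[:, 0], 0.0, atol=1e-12)


def test_sklearn_get_set_params_clone():
    from sklearn.base import clone

    est = hw.NegativeBinomialTrendModel(rw_order=0, seed=5)
    est2 = clone(est)
    assert est2.get_params()["rw_order"] == 0
    est2.set_params(draws=123)
    assert est2.draws == 123 and est.draws != 123


def test_posterior_centre_tracks_frequentist_nb_glm():
    """On a single-unit log-linear NB trend (no random walk), the posterior
    means of intercept and slope approximate the maximum-likelihood NB
    regression fitted independently by statsmodels."""
    import statsmodels.api as sm
    from statsmodels.discrete.discrete_model import NegativeBinomial

    rng = np.random.default_rng(14)
    t = np.arange(12, dtype=float)
    mu = np.exp(np.log(2000.0) - 0.05 * t)
    theta = 80.0
    y = rng.negative_binomial(theta, theta / (theta + mu))
    panel = make_panel({"A": list(map(int, y))})

    est = hw.NegativeBinomialTrendModel(
        include_linear_trend=True, rw_order=0, training_cutoff=int(max(panel.years)),
        chains=2, draws=2000, warmup=1500, seed=6,
    ).fit(panel)
    a_post = est.draws_.flat("alpha")
    b_post = est.draws_.flat("beta")

    X = sm.add_constant(t)
    mle = NegativeBinomial(y, X).fit(disp=0)
    assert abs(b_post.mean() - mle.params[1]) < 3 * b_post.std()
    assert abs(a_post.mean() - mle.params[0]) < 3 * a_post.std()
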
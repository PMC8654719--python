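"""Cluster-robust regression, clustered bootstrap and LOESS."""

import numpy as np
import pytest

from esbench import (
    BootstrapSpec,
    ClusterOLS,
    LoessSpec,
    cluster_bootstrap_ci,
    fit_cluster_ols,
    loess_curve,
)

from conftest import brute_force_sandwich


def test_exact_line_has_zero_adjusted_se():
    x = np.array([0.0, 1, 2, 3, 4, 5])
    y = 1 + 2 * x
    g = ["a", "a", "b", "b", "c", "c"]
    fit = fit_cluster_ols(y, x, g)
    assert fit.beta == pytest.approx(2.0, abs=1e-12)
    assert fit.intercept == pytest.approx(1.0, abs=1e-12)
    assert fit.se_adj == pytest.approx(0.0, abs=1e-10)


def test_six_point_sandwich_matches_hand_oracle():
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 6.0])
    y = np.array([0.5, 1.9, 4.4, 5.6, 9.1, 12.0])
    g = np.array([0, 0, 1, 1, 2, 2])
    fit = fit_cluster_ols(y, x, g)
    (b0, b1), se = brute_force_sandwich(y, x, g)
    assert fit.beta == pytest.approx(b1, abs=1e-10)
    assert fit.intercept == pytest.approx(b0, abs=1e-10)
    assert fit.se_adj == pytest.approx(se, abs=1e-10)


def test_singleton_clusters_equal_heteroskedastic_sandwich():
    rng = np.random.default_rng(8)
    x = rng.normal(size=9)
    y = 0.5 - 0.3 * x + rng.normal(size=9)
    g = np.arange(9)
    fit = fit_cluster_ols(y, x, g)
    _, se = brute_force_sandwich(y, x, g)
    assert fit.se_adj == pytest.approx(se, abs=1e-10)


def test_single_cluster_and_constant_covariate_are_errors():
    y = np.array([1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="clusters"):
        fit_cluster_ols(y, np.array([0.0, 1.0, 2.0]), ["a", "a", "a"])
    with pytest.raises(ValueError, match="constant"):
        fit_cluster_ols(y, np.array([1.0, 1.0, 1.0]), ["a", "b", "c"])


def test_cluster_ci_covers_true_slope_at_nominal_rate():
    # clustered data with known slope -0.19; t(G-1) interval should cover
    # in about 95% of runs, and never below 93% over 500 simulations
    rng = np.random.default_rng(42)
    G, m, covered = 30, 8, 0
    for _ in range(500):
        x = rng.normal(size=G * m)
        y = (
            1.0
            - 0.19 * x
            + np.repeat(rng.normal(0, 0.5, G), m)
            + rng.normal(0, 1, G * m)
        )
        fit = fit_cluster_ols(y, x, np.repeat(np.arange(G), m))
        covered += fit.ci_lower <= -0.19 <= fit.ci_upper
    assert covered / 500 >= 0.93


def test_zero_time_trend_is_not_detected():
    # magnitudes simulated with no year effect: slope near 0, CI covers 0
    rng = np.random.default_rng(7)
    G, m = 40, 19
    years = rng.integers(1990, 2022, G * m).astype(float)
    y = np.abs(rng.lognormal(np.log(0.69), 0.83, G * m))
    fit = fit_cluster_ols(y, years, np.repeat(np.arange(G), m))
    assert abs(fit.beta) < 0.01
    assert fit.ci_lower <= 0.0 <= fit.ci_upper


def test_bootstrap_collapses_on_exact_line_and_is_deterministic():
    x = np.arange(8.0)
    y = 1 + 2 * x
    g = np.repeat([0, 1, 2, 3], 2)
    spec = BootstrapSpec(n_replicates=500, seed=4)
    ci1 = cluster_bootstrap_ci(y, x, g, spec)
    ci2 = cluster_bootstrap_ci(y, x, g, spec)
    assert ci1 == ci2
    assert ci1[0] == pytest.approx(2.0, abs=1e-10)
    assert ci1[1] == pytest.approx(2.0, abs=1e-10)


def test_bootstrap_interval_close_to_analytic_ols_width_when_independent():
    rng = np.random.default_rng(12)
    n = 400
    x = rng.normal(size=n)
    y = 1 + 0.5 * x + rng.normal(size=n)
    ci = cluster_bootstrap_ci(y, x, np.arange(n), BootstrapSpec(2000, seed=9))
    import statsmodels.api as sm

    ols = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = ols.conf_int()[1]
    assert (ci[1] - ci[0]) == pytest.approx(hi - lo, rel=0.15)


def test_bootstrap_interval_contains_point_estimate():
    rng = np.random.default_rng(3)
    misses = 0
    for rep in range(30):
        G, m = 12, 6
        x = rng.normal(size=G * m)
        y = 0.3 * x + np.repeat(rng.normal(0, 0.4, G), m) + rng.normal(size=G * m)
        g = np.repeat(np.arange(G), m)
        fit = fit_cluster_ols(y, x, g)
        lo, hi = cluster_bootstrap_ci(y, x, g, BootstrapSpec(800, seed=rep))
        misses += not (lo <= fit.beta <= hi)
    assert misses <= 1


def test_loess_reproduces_line_and_quadratic():
    x = np.linspace(0, 10, 40)
    grid = np.linspace(0.5, 9.5, 21)
    line = 2 - 0.3 * x
    assert loess_curve(x, line, LoessSpec(span=0.5, degree=1), grid) == pytest.approx(
        2 - 0.3 * grid, abs=1e-8
    )
    quad = 1 + 0.5 * x - 0.2 * x**2
    assert loess_curve(x, quad, LoessSpec(span=1.0, degree=2), grid) == pytest.approx(
        1 + 0.5 * grid - 0.2 * grid**2, abs=1e-8
    )


def test_loess_stays_within_data_range_on_noise():
    rng = np.random.default_rng(0)
    x = np.linspace(0, 1, 60)
    y = rng.normal(0.5, 0.1, 60)
    fitted = loess_curve(x, y, LoessSpec(span=0.75, degree=2))
    assert fitted.min() >= y.min() - 0.05 and fitted.max() <= y.max() + 0.05


def test_loess_refuses_extrapolation_and_tiny_samples():
    x = np.linspace(0, 1, 20)
    y = x.copy()
    with pytest.raises(ValueError, match="extrapolation"):
        loess_curve(x, y, grid=np.array([1.5]))
    with pytest.raises(ValueError, match="at least"):
        loess_curve(x[:3], y[:3], LoessSpec(span=0.75, degree=2))


def test_model_results_summary_mentions_clusters():
    rng = np.random.default_rng(1)
    x = rng.normal(size=20)
    y = 1 + 0.2 * x + rng.normal(size=20)
    res = (
        ClusterOLS(y, x, np.repeat(np.arange(5), 4))
        .fit()
        .with_bootstrap(BootstrapSpec(200, seed=1))
    )
    text = res.summary()
    assert "n_clusters = 5" in text
    assert "bootstrap" in text
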
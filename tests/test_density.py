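import numpy as np
import pytest
from scipy import stats

from tapsync import fit_kde, isj_bandwidth, negative_log_likelihood
from tapsync.density import DENSITY_FLOOR, silverman_bandwidth


def test_gaussian_density_at_mode():
    x = np.random.default_rng(0).normal(0.0, 30.0, 2000)
    kde = fit_kde(x)
    want = 1.0 / (30.0 * np.sqrt(2.0 * np.pi))  # 0.0133
    assert kde.pdf(0.0) == pytest.approx(want, rel=0.15)


def test_density_normalised_and_nonnegative():
    for seed in (1, 2, 3):
        x = np.random.default_rng(seed).normal(-30.0, 25.0, 500)
        kde = fit_kde(x)
        assert kde.integral == pytest.approx(1.0, abs=1e-3)
        assert np.all(kde.density >= 0.0)
        assert kde.grid[0] < x.min() and kde.grid[-1] > x.max()


def test_bimodal_sample_keeps_local_minimum():
    rng = np.random.default_rng(4)
    x = np.concatenate([rng.normal(0.0, 20.0, 1000), rng.normal(150.0, 20.0, 1000)])
    kde = fit_kde(x)
    mid = kde.pdf(75.0)
    assert mid < kde.pdf(0.0) and mid < kde.pdf(150.0)
    # valley is a genuine local minimum on the grid between the modes
    sel = (kde.grid > 40) & (kde.grid < 110)
    assert kde.density[sel].min() < 0.6 * kde.pdf(0.0)


def test_nll_unit_normal_mode():
    x = np.random.default_rng(5).normal(0.0, 1.0, 4000)
    kde = fit_kde(x)
    got = negative_log_likelihood([0.0], kde)
    assert got == pytest.approx(-np.log(stats.norm.pdf(0.0)), abs=0.05)


def test_nll_additivity_and_floor():
    x = np.random.default_rng(6).normal(0.0, 10.0, 500)
    kde = fit_kde(x)
    data = np.array([-5.0, 3.0, 12.0])
    single = negative_log_likelihood(data, kde)
    double = negative_log_likelihood(np.concatenate([data, data]), kde)
    assert double == pytest.approx(2.0 * single, rel=1e-12)
    far = negative_log_likelihood([1e6], kde)
    assert far == pytest.approx(-np.log(DENSITY_FLOOR))


def test_input_validation():
    with pytest.raises(ValueError):
        fit_kde(np.zeros(10))  # too few
    with pytest.raises(ValueError):
        fit_kde(np.full(100, 3.0))  # zero variance
    with pytest.raises(ValueError):
        fit_kde(np.r_[np.nan, np.zeros(99)])
    kde = fit_kde(np.random.default_rng(7).normal(size=200))
    with pytest.raises(ValueError):
        negative_log_likelihood([], kde)
    with pytest.raises(ValueError):
        fit_kde(np.random.default_rng(7).normal(size=200), bandwidth="bogus")


def test_isj_near_amise_on_gaussian():
    x = np.random.default_rng(8).normal(0.0, 1.0, 2000)
    amise = 1.06 * np.std(x) * len(x) ** (-0.2)
    assert isj_bandwidth(x) == pytest.approx(amise, rel=0.25)


def test_isj_sharper_than_silverman_on_mixture():
    rng = np.random.default_rng(9)
    x = np.concatenate([rng.normal(0, 15, 1000), rng.normal(150, 15, 1000)])
    assert isj_bandwidth(x) < silverman_bandwidth(x)


def test_bandwidth_rule_stability():
    # results must be tolerance-stable to the selector switch
    x = np.random.default_rng(10).normal(-30.0, 25.0, 2000)
    data = np.random.default_rng(11).normal(-30.0, 25.0, 140)
    nlls = [negative_log_likelihood(data, fit_kde(x, bandwidth=bw))
            for bw in ("isj", "silverman")]
    assert nlls[0] == pytest.approx(nlls[1], rel=0.02)


def test_kde_converges_in_l1():
    true = stats.norm(0.0, 20.0)
    def l1(n, seed):
        kde = fit_kde(np.random.default_rng(seed).normal(0.0, 20.0, n))
        return np.trapezoid(np.abs(kde.density - true.pdf(kde.grid)), kde.grid)
    assert l1(5000, 13) < l1(200, 12)


def test_explicit_bandwidth_and_export():
    x = np.random.default_rng(14).normal(size=300)
    kde = fit_kde(x, bandwidth=0.5)
    assert kde.bandwidth == 0.5
    df = kde.to_frame()
    assert list(df.columns) == ["grid_ms", "density"]
    assert len(df) == len(kde.grid)
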
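import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from tapsync import (
    DegenerateModelError,
    InconsistentEstimateError,
    ObserverParams,
    StimulusCondition,
    estimate_separate,
    fuse_common,
    make_trial,
    posterior_common,
    select_stream,
    simulate_asynchronies,
    simulate_trial,
    update_prior,
)


def quadrature_posterior(t_a, t_b, mu_p, sa, sb, sp, ps):
    """Independent oracle: numerical quadrature of the marginal likelihoods."""
    def common(s):
        return (stats.norm.pdf(t_a, s, sa) * stats.norm.pdf(t_b, s, sb)
                * stats.norm.pdf(s, mu_p, sp))
    # integrate around the narrow posterior peak (precision-weighted mean)
    w = np.array([sa, sb, sp], dtype=float) ** -2.0
    center = float(np.dot(w, [t_a, t_b, mu_p]) / w.sum())
    width = float(w.sum() ** -0.5)
    l1, _ = integrate.quad(common, center - 15 * width, center + 15 * width,
                           limit=400)
    l2 = (stats.norm.pdf(t_a, mu_p, np.hypot(sa, sp))
          * stats.norm.pdf(t_b, mu_p, np.hypot(sb, sp)))
    return ps * l1 / (ps * l1 + (1 - ps) * l2)


def test_posterior_matches_quadrature_spot_checks():
    p = ObserverParams(variant="CI", sigma_p=80.0, p_single=0.7,
                      sigma_a=15.0, sigma_b=25.0)
    for t_a, t_b, mu in [(-5.0, 10.0, 0.0), (30.0, -40.0, 10.0), (0.0, 150.0, -20.0)]:
        got = posterior_common(t_a, t_b, mu, p)
        want = quadrature_posterior(t_a, t_b, mu, 15.0, 25.0, 80.0, 0.7)
        assert got == pytest.approx(want, abs=1e-9)


def test_posterior_prior_extremes():
    p1 = ObserverParams(variant="MI")
    p0 = ObserverParams(variant="MS")
    assert posterior_common(0.0, 500.0, 0.0, p1) == 1.0
    assert posterior_common(0.0, 0.0, 0.0, p0) == 0.0


def test_posterior_vectorised_matches_scalar():
    p = ObserverParams(variant="CI", p_single=0.5)
    t_a = np.array([-10.0, 0.0, 40.0])
    t_b = np.array([5.0, 90.0, -20.0])
    vec = posterior_common(t_a, t_b, 0.0, p)
    scal = [posterior_common(a, b, 0.0, p) for a, b in zip(t_a, t_b)]
    assert np.allclose(vec, scal)


def test_posterior_pa_discounts_known_offset():
    base = dict(sigma_p=100.0, p_single=0.5, sigma_a=10.0, sigma_b=10.0)
    ci = ObserverParams(variant="CI", **base)
    pa = ObserverParams(variant="CI_PA", known_offset_ms=150.0, **base)
    # a 150 ms separation looks like strong evidence against a common cause
    # to CI, but is fully explained away by the phase-aware observer
    assert posterior_common(0.0, 150.0, 0.0, ci) < 0.05
    assert posterior_common(0.0, 150.0, 0.0, pa) > 0.5
    # CI_PA on discounted coordinates equals CI on aligned ones
    assert posterior_common(0.0, 150.0, 0.0, pa) == pytest.approx(
        posterior_common(0.0, 0.0, 0.0, ci), rel=1e-12)


def test_degenerate_sigmas_raise():
    p = ObserverParams(variant="CI", sigma_p=0.0, p_single=0.5,
                      sigma_a=0.0, sigma_b=0.0)
    with pytest.raises(DegenerateModelError):
        posterior_common(0.0, 1.0, 0.0, p)


def test_fusion_weights_closed_form():
    got = fuse_common(10.0, 30.0, 0.0, 10.0, 20.0, 40.0)
    w = np.array([1 / 100.0, 1 / 400.0, 1 / 1600.0])
    want = float(np.dot(w, [10.0, 30.0, 0.0]) / w.sum())
    assert got == pytest.approx(want, rel=1e-12)


def test_fusion_zero_variance_dominates():
    assert fuse_common(12.0, 99.0, -5.0, 0.0, 20.0, 50.0) == 12.0
    with pytest.raises(InconsistentEstimateError):
        fuse_common(12.0, 13.0, 0.0, 0.0, 0.0, 50.0)


def test_estimate_separate_uninformative_prior():
    assert estimate_separate(25.0, 0.0, 10.0, np.inf) == pytest.approx(25.0)


@settings(max_examples=50, deadline=None)
@given(t_a=st.floats(-200, 200), t_b=st.floats(-200, 200),
       mu=st.floats(-100, 100),
       sa=st.floats(1, 100), sb=st.floats(1, 100), sp=st.floats(1, 500))
def test_fused_estimate_within_hull(t_a, t_b, mu, sa, sb, sp):
    fused = fuse_common(t_a, t_b, mu, sa, sb, sp)
    lo, hi = min(t_a, t_b, mu), max(t_a, t_b, mu)
    assert lo - 1e-9 <= fused <= hi + 1e-9


@settings(max_examples=30, deadline=None)
@given(t_a=st.floats(-150, 150), t_b=st.floats(-150, 150),
       mu=st.floats(-80, 80), ps=st.floats(0.05, 0.95),
       sa=st.floats(2, 80), sb=st.floats(2, 80), sp=st.floats(5, 300))
def test_posterior_is_probability(t_a, t_b, mu, ps, sa, sb, sp):
    p = ObserverParams(variant="CI", sigma_p=sp, p_single=ps,
                      sigma_a=sa, sigma_b=sb)
    q = posterior_common(t_a, t_b, mu, p)
    assert 0.0 <= q <= 1.0


def test_select_stream_statistics(rng):
    s, chosen = select_stream(np.zeros(20000), np.ones(20000), 0.7, rng)
    assert abs(chosen.mean() - 0.7) < 0.02
    assert set(np.unique(s)) <= {0.0, 1.0}
    s1, c1 = select_stream(1.0, 2.0, 1.0, rng)
    assert (s1, c1) == (1.0, "A")


def test_select_stream_invalid_beta(rng):
    with pytest.raises(ValueError):
        select_stream(0.0, 1.0, 1.5, rng)


def test_update_prior_identity():
    assert update_prior(3.5) == 3.5


def test_simulate_trial_window_and_determinism(ci_params, dual_condition):
    trial = make_trial(dual_condition, seed=11)
    s1 = simulate_trial(ci_params, trial, np.random.default_rng(5))
    s2 = simulate_trial(ci_params, trial, np.random.default_rng(5))
    assert np.array_equal(s1.asynchronies, s2.asynchronies)
    assert len(s1.asynchronies) == 14
    assert s1.window == (15, 28)


def test_simulate_window_validation(ci_params, dual_condition):
    trial = make_trial(dual_condition, seed=11)
    with pytest.raises(ValueError):
        simulate_trial(ci_params, trial, np.random.default_rng(0), window=(1, 31))


def test_anticipation_shifts_mean():
    cond = StimulusCondition(phase_offset_ms=0.0, jitter_sd_ms=(0.0, 0.0))
    base = dict(variant="CI", p_single=0.9, sigma_p=100.0,
                sigma_a=10.0, sigma_b=10.0, sigma_m=10.0)
    rng1, rng2 = np.random.default_rng(21), np.random.default_rng(21)
    a = simulate_asynchronies(ObserverParams(d=-30.0, **base), cond, 80, rng1)
    b = simulate_asynchronies(ObserverParams(d=0.0, **base), cond, 80, rng2)
    assert np.mean(a) - np.mean(b) == pytest.approx(-30.0, abs=1e-9)
    assert np.mean(a) == pytest.approx(-30.0, abs=3.0)


def test_single_metronome_runs(single_condition):
    p = ObserverParams(variant="CI", p_single=0.6)
    asyn = simulate_asynchronies(p, single_condition, 5, np.random.default_rng(2))
    assert asyn.shape == (5, 14)
    assert np.all(np.isfinite(asyn))


def test_average_decision_mode_between_branches():
    cond = StimulusCondition(phase_offset_ms=150.0, jitter_sd_ms=(0.0, 0.0))
    p = ObserverParams(variant="CI", p_single=0.5, sigma_p=150.0, beta=1.0,
                      sigma_a=10.0, sigma_b=10.0, sigma_m=0.0, d=0.0)
    thr = simulate_asynchronies(p, cond, 40, np.random.default_rng(9))
    avg = simulate_asynchronies(p, cond, 40, np.random.default_rng(9),
                                decision="average")
    assert not np.array_equal(thr, avg)
    with pytest.raises(ValueError):
        simulate_asynchronies(p, cond, 2, np.random.default_rng(0),
                              decision="bogus")
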
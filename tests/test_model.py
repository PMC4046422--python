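import json

import numpy as np
import pandas as pd
import pytest

from tapsync import (
    CALIBRATION_CONDITION,
    DEFAULT_BOUNDS,
    ObserverParams,
    StimulusCondition,
    SynchronyModel,
    fit_condition,
    simulate_asynchronies,
)

QUICK = dict(n_sim=600)
QUICK_FIT = dict(maxiter=10, popsize=6, tol=0.01)


@pytest.fixture(scope="module")
def mi_data():
    truth = ObserverParams(variant="MI", sigma_p=100.0, d=-30.0)
    cond = StimulusCondition(phase_offset_ms=0.0, jitter_sd_ms=(0.0, 0.0))
    rng = np.random.default_rng(42)
    return simulate_asynchronies(truth, cond, 10, rng).ravel(), cond


def test_bounds_lookup():
    assert DEFAULT_BOUNDS.for_names(["d", "beta"]) == [(-100.0, 100.0), (0.0, 1.0)]
    assert DEFAULT_BOUNDS.sigma_p == (10.0, 500.0)


def test_free_parameter_counts(mi_data):
    data, cond = mi_data
    assert SynchronyModel(data, cond, "MI").free_names == ["sigma_p", "d"]
    assert SynchronyModel(data, cond, "MS", beta=0.5).free_names == ["sigma_p", "d"]
    assert SynchronyModel(data, cond, "CI", beta=0.5).free_names == [
        "sigma_p", "p_single", "d"]
    assert SynchronyModel(data, cond, "CI", estimate_beta=True).free_names == [
        "sigma_p", "p_single", "d", "beta"]
    # MI has no stream preference: estimate_beta is a no-op
    assert SynchronyModel(data, cond, "MI", estimate_beta=True).free_names == [
        "sigma_p", "d"]


def test_constructor_validation(mi_data):
    data, cond = mi_data
    with pytest.raises(ValueError):
        SynchronyModel(data, cond, "XX", beta=0.5)
    with pytest.raises(ValueError):
        SynchronyModel(data, cond, "CI")  # beta neither given nor estimated
    with pytest.raises(ValueError):
        SynchronyModel([], cond, "MI")
    with pytest.raises(ValueError):
        SynchronyModel([np.nan], cond, "MI")


def test_nll_is_deterministic_given_seed(mi_data):
    data, cond = mi_data
    m = SynchronyModel(data, cond, "MI", **QUICK)
    a = m.nll([100.0, -30.0], seed=5)
    b = m.nll([100.0, -30.0], seed=5)
    c = m.nll([100.0, -30.0], seed=6)
    assert a == b
    assert a != c
    assert m.loglike([100.0, -30.0], seed=5) == -a


def test_nll_prefers_truth_over_distant_theta(mi_data):
    data, cond = mi_data
    m = SynchronyModel(data, cond, "MI", **QUICK)
    assert m.nll([100.0, -30.0], seed=1) < m.nll([100.0, 60.0], seed=1)


def test_fit_reproducible_and_recovers_d(mi_data):
    data, cond = mi_data
    m = SynchronyModel(data, cond, "MI", **QUICK)
    r1 = m.fit(seed=3, **QUICK_FIT)
    r2 = m.fit(seed=3, **QUICK_FIT)
    assert r1.theta == r2.theta
    assert r1.nll == r2.nll
    assert r1.theta["d"] == pytest.approx(-30.0, abs=20.0)
    assert r1.k_free == 2
    assert r1.n_data == len(data)
    assert r1.bic == pytest.approx(2 * r1.nll + 2 * np.log(len(data)))
    assert len(r1.nll_replicates) == 3


def test_results_surface(mi_data, tmp_path):
    data, cond = mi_data
    r = SynchronyModel(data, cond, "MI", **QUICK).fit(seed=3, **QUICK_FIT)
    s = r.summary()
    assert "MI" in s and "sigma_p" in s and "free" in s and "fixed" in s
    d = r.to_dict()
    assert d["variant"] == "MI" and d["condition"] == cond.label
    p = tmp_path / "fit.json"
    r.to_json(p)
    assert json.loads(p.read_text())["bic"] == pytest.approx(r.bic)
    sim = r.simulate(100, seed=0)
    assert sim.shape == (100,)


def test_ci_pa_inherits_condition_offset(mi_data):
    data, _ = mi_data
    cond = StimulusCondition(phase_offset_ms=100.0, jitter_sd_ms=(0.0, 0.0))
    m = SynchronyModel(data, cond, "CI_PA", beta=0.5)
    p = m._params_from_theta(np.array([100.0, 0.5, -30.0]))
    assert p.known_offset_ms == 100.0
    assert p.variant == "CI_PA"


def test_from_dataframe_selects_rows(mi_data):
    data, cond = mi_data
    df = pd.DataFrame({
        "participant": ["P1"] * len(data) + ["P2"] * 3,
        "condition": [cond.label] * len(data) + ["off150_j0-0"] * 3,
        "asynchrony_ms": np.concatenate([data, [0.0, 1.0, 2.0]]),
    })
    m = SynchronyModel.from_dataframe(df, cond, "MI", participant="P1")
    assert len(m.data) == len(data)
    with pytest.raises(ValueError):
        SynchronyModel.from_dataframe(df, cond, "MI", participant="P9")


def test_fit_condition_wrapper(mi_data):
    data, cond = mi_data
    r = fit_condition(data, cond, "MI", seed=3, **QUICK, **QUICK_FIT)
    assert r.variant == "MI"
    assert np.isfinite(r.bic)


def test_calibration_condition_is_wide_offset():
    assert CALIBRATION_CONDITION.phase_offset_ms == 150.0
    assert CALIBRATION_CONDITION.jitter_a == CALIBRATION_CONDITION.jitter_b == 0.0
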
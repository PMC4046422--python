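"""Generative causal-inference observer for sensorimotor synchronization.

The observer hears one or two metronome streams and, on every beat, must
decide whether the sensed tone onsets ``t_A`` and ``t_B`` arise from a single
common beat (C = 1) or from two independent beats (C = 2). Under C = 1 the
onsets are fused with the temporal prior by precision weighting; under C = 2
each stream is estimated separately against the prior and one stream is
selected with probability ``beta`` (for A). The resulting beat-onset estimate
drives a tap, offset by an anticipation term ``d`` and corrupted by motor
noise ``sigma_m``.

All per-beat quantities live in a *relative* time frame whose origin is the
pre-jitter grid onset of metronome A for the current beat. In that frame the
prior mean for beat ``m`` is simply the previous beat's estimate, and the
simulated tap time *is* the asynchrony the experiment measures.

Four variants are supported:

``CI``
    full causal inference; ``p_single`` is the prior probability of a
    common beat.
``CI_PA``
    causal inference with phase-offset adaptation: a known, consistent
    offset of stream B is subtracted from ``t_B`` inside the common-cause
    judgement only, so the offset no longer counts as evidence for
    separate sources (fusion itself still uses the raw ``t_B``).
``MI``
    mandatory integration (``p_single`` forced to 1).
``MS``
    mandatory separation (``p_single`` forced to 0).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.special import expit

from .stimulus import StimulusCondition, StimulusTrial, sample_stimuli

__all__ = [
    "VARIANTS",
    "ObserverParams",
    "BeatPercept",
    "AsynchronySeries",
    "DegenerateModelError",
    "InconsistentEstimateError",
    "sense_onsets",
    "posterior_common",
    "fuse_common",
    "estimate_separate",
    "select_stream",
    "update_prior",
    "simulate_trial",
    "simulate_asynchronies",
    "DEFAULT_WINDOW",
]

VARIANTS = ("CI", "CI_PA", "MI", "MS")

#: analysis window in 1-based beat indices, inclusive
DEFAULT_WINDOW = (15, 28)


class DegenerateModelError(ValueError):
    """All relevant variances are zero: the inference problem is degenerate."""


class InconsistentEstimateError(ValueError):
    """Two or more zero-variance inputs disagree: no consistent estimate exists."""


@dataclass(frozen=True)
class ObserverParams:
    """Parameter vector of the generative observer.

    ``sigma_a``, ``sigma_b`` are sensory-registration noise s.d.s (ms) for
    streams A and B; ``sigma_p`` the prior s.d.; ``p_single`` the prior
    probability of a common beat; ``d`` the anticipation offset (typically
    negative, ms); ``sigma_m`` motor-noise s.d.; ``beta`` the probability of
    preferring stream A when the streams are treated as separate.
    ``known_offset_ms`` is the consistent phase offset assumed adapted-to,
    used by the CI_PA variant only.
    """

    variant: str = "CI"
    sigma_p: float = 100.0
    p_single: Optional[float] = None
    d: float = -30.0
    beta: float = 0.5
    sigma_a: float = 10.0
    sigma_b: float = 10.0
    sigma_m: float = 10.0
    known_offset_ms: float = 0.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        for name in ("sigma_a", "sigma_b", "sigma_p", "sigma_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.variant == "MI":
            if self.p_single is None:
                object.__setattr__(self, "p_single", 1.0)
            elif self.p_single != 1.0:
                raise ValueError("MI requires p_single = 1")
        elif self.variant == "MS":
            if self.p_single is None:
                object.__setattr__(self, "p_single", 0.0)
            elif self.p_single != 0.0:
                raise ValueError("MS requires p_single = 0")
        elif self.p_single is None:
            object.__setattr__(self, "p_single", 0.5)
        if not 0.0 <= self.p_single <= 1.0:
            raise ValueError("p_single must lie in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")

    def with_(self, **kwargs) -> "ObserverParams":
        return replace(self, **kwargs)


@dataclass
class BeatPercept:
    """Per-beat internal state of the observer (relative time frame)."""

    t_a: float
    t_b: Optional[float]
    mu_p: float
    p_common: Optional[float]
    s_hat: float
    s_hat_a: Optional[float] = None
    s_hat_b: Optional[float] = None
    chosen_stream: str = "fused"


@dataclass
class AsynchronySeries:
    """Windowed tap asynchronies for one trial, referenced to metronome A's grid."""

    condition: str
    trial: int
    asynchronies: np.ndarray
    window: tuple[int, int] = DEFAULT_WINDOW

    def __post_init__(self):
        self.asynchronies = np.asarray(self.asynchronies, dtype=float)
        lo, hi = self.window
        if len(self.asynchronies) != hi - lo + 1:
            raise ValueError("series length must equal window size")


# ---------------------------------------------------------------------------
# per-beat operations
# ---------------------------------------------------------------------------

def sense_onsets(onset_a, onset_b, grid_a, sigma_a, sigma_b, rng):
    """Sample sensed onsets relative to metronome A's grid for this beat.

    ``t_A = (onset_A - grid_A) + N(0, sigma_A^2)`` and likewise for B. For a
    single-metronome beat pass ``onset_b=None``; only ``t_A`` is produced.
    """
    t_a = np.asarray(onset_a - grid_a, dtype=float) + rng.normal(0.0, sigma_a, np.shape(onset_a))
    if onset_b is None:
        return t_a, None
    t_b = np.asarray(onset_b - grid_a, dtype=float) + rng.normal(0.0, sigma_b, np.shape(onset_b))
    return t_a, t_b


def _log_likelihoods(t_a, t_b, mu_p, va, vb, vp):
    """Log marginal likelihoods of the common- and separate-cause models.

    ``L1`` marginalises a single source ``s ~ N(mu_p, vp)`` observed through
    both streams; ``L2`` marginalises an independent source per stream.
    Closed forms of the Gaussian integrals.
    """
    v1 = va * vb + va * vp + vb * vp
    if v1 <= 0:
        raise DegenerateModelError(
            "common-cause likelihood is degenerate: at least two of "
            "sigma_a, sigma_b, sigma_p must be positive"
        )
    q1 = ((t_a - t_b) ** 2 * vp + (t_a - mu_p) ** 2 * vb + (t_b - mu_p) ** 2 * va) / v1
    log_l1 = -0.5 * q1 - np.log(2.0 * np.pi) - 0.5 * np.log(v1)
    sa, sb = va + vp, vb + vp
    log_l2 = (
        -0.5 * ((t_a - mu_p) ** 2 / sa + (t_b - mu_p) ** 2 / sb)
        - np.log(2.0 * np.pi)
        - 0.5 * (np.log(sa) + np.log(sb))
    )
    return log_l1, log_l2


def posterior_common(t_a, t_b, mu_p, params: ObserverParams, *,
                     sigma_a=None, sigma_b=None):
    """Posterior probability that the two sensed onsets share a common cause.

    For the CI_PA variant, ``t_B`` is replaced by ``t_B - known_offset_ms``
    inside this computation only. ``sigma_a``/``sigma_b`` override the
    likelihood widths used in the judgement (e.g. jitter-calibrated
    reliabilities); they default to the sensory noise in ``params``.
    """
    ps = params.p_single
    shape = np.broadcast(np.asarray(t_a), np.asarray(t_b), np.asarray(mu_p)).shape
    if ps >= 1.0:
        return np.float64(1.0) if shape == () else np.ones(shape)
    if ps <= 0.0:
        return np.float64(0.0) if shape == () else np.zeros(shape)
    sa = params.sigma_a if sigma_a is None else sigma_a
    sb = params.sigma_b if sigma_b is None else sigma_b
    if sa == 0.0 and sb == 0.0 and params.sigma_p == 0.0:
        raise DegenerateModelError("all of sigma_a, sigma_b, sigma_p are zero")
    t_b_eff = np.asarray(t_b, dtype=float)
    if params.variant == "CI_PA":
        t_b_eff = t_b_eff - params.known_offset_ms
    log_l1, log_l2 = _log_likelihoods(
        np.asarray(t_a, dtype=float), t_b_eff, np.asarray(mu_p, dtype=float),
        sa ** 2, sb ** 2, params.sigma_p ** 2,
    )
    return expit(np.log(ps / (1.0 - ps)) + log_l1 - log_l2)


def _precision_combine(values, sigmas):
    """Precision-weighted mean with zero-variance limit handling."""
    exact = [v for v, s in zip(values, sigmas) if s == 0.0]
    if exact:
        for other in exact[1:]:
            if not np.allclose(exact[0], other):
                raise InconsistentEstimateError(
                    "multiple zero-variance inputs disagree"
                )
        out = np.broadcast_arrays(exact[0], *values)[0]
        return out if np.ndim(out) else float(out)
    num = 0.0
    den = 0.0
    for v, s in zip(values, sigmas):
        w = 1.0 / s ** 2  # s may be inf -> weight 0
        num = num + w * np.asarray(v, dtype=float)
        den = den + w
    if np.ndim(den) == 0 and den == 0.0:
        raise DegenerateModelError("no input carries any precision")
    return num / den


def fuse_common(t_a, t_b, mu_p, sigma_a, sigma_b, sigma_p):
    """Fused beat estimate: precision-weighted average of t_A, t_B and mu_p.

    ``s_hat = (t_A/sA^2 + t_B/sB^2 + mu_p/sp^2) / (1/sA^2 + 1/sB^2 + 1/sp^2)``.
    A zero-variance input takes all the weight; two zero-variance inputs with
    unequal values raise :class:`InconsistentEstimateError`.
    """
    return _precision_combine((t_a, t_b, mu_p), (sigma_a, sigma_b, sigma_p))


def estimate_separate(t_x, mu_p, sigma_x, sigma_p):
    """Single-stream beat estimate: precision-weighted average of t_X and mu_p."""
    return _precision_combine((t_x, mu_p), (sigma_x, sigma_p))


def select_stream(s_hat_a, s_hat_b, beta, rng):
    """Pick stream A's estimate with probability ``beta``, else stream B's.

    Returns ``(s_hat, chosen)``; for scalar inputs ``chosen`` is ``"A"`` or
    ``"B"``, for arrays a boolean mask (True where A was chosen). The choice
    is drawn independently per beat.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    shape = np.broadcast(np.asarray(s_hat_a), np.asarray(s_hat_b)).shape
    choose_a = rng.uniform(size=shape) < beta
    s_hat = np.where(choose_a, s_hat_a, s_hat_b)
    if shape == ():
        return float(s_hat), ("A" if choose_a else "B")
    return s_hat, choose_a


def update_prior(s_hat_prev):
    """Prior mean for beat m is the estimate from beat m-1 (relative frame).

    On the first beat the prior mean is 0 (the observer expects the beat on
    metronome A's grid).
    """
    return s_hat_prev


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

def _effective_sigmas(params: ObserverParams, condition: StimulusCondition,
                      calibrated_reliability: bool) -> tuple[float, float]:
    """Likelihood widths used in inference and estimation.

    With ``calibrated_reliability`` the observer's assumed width for each
    stream incorporates that stream's jitter s.d. (the cue's learned
    reliability), on top of the sensory registration noise.
    """
    if not calibrated_reliability:
        return params.sigma_a, params.sigma_b
    sa = float(np.hypot(params.sigma_a, condition.jitter_a))
    sb = float(np.hypot(params.sigma_b, condition.jitter_b))
    return sa, sb


def _run_beats(params: ObserverParams, condition: StimulusCondition,
               rel_a: np.ndarray, rel_b: Optional[np.ndarray],
               rng: np.random.Generator, *, decision: str = "threshold",
               calibrated_reliability: bool = True) -> np.ndarray:
    """Run the observer over a batch of trials.

    ``rel_a``/``rel_b`` are onsets relative to metronome A's grid, shape
    (n_trials, n_beats). Returns simulated asynchronies of the same shape.
    The random stream is consumed identically for every variant (sensory
    noise, stream-selection uniform, motor noise -- in that order, per
    beat), so variants that coincide mathematically produce bit-identical
    output under a shared seed.
    """
    if decision not in ("threshold", "average"):
        raise ValueError("decision must be 'threshold' or 'average'")
    n_trials, n_beats = rel_a.shape
    dual = rel_b is not None
    sa_eff, sb_eff = _effective_sigmas(params, condition, calibrated_reliability)
    mu_p = np.zeros(n_trials)
    out = np.empty((n_trials, n_beats))
    for m in range(n_beats):
        t_a = rel_a[:, m] + rng.normal(0.0, params.sigma_a, n_trials)
        if dual:
            t_b = rel_b[:, m] + rng.normal(0.0, params.sigma_b, n_trials)
        u = rng.uniform(size=n_trials)
        motor = rng.normal(0.0, params.sigma_m, n_trials)
        if dual:
            p_common = posterior_common(t_a, t_b, mu_p, params,
                                        sigma_a=sa_eff, sigma_b=sb_eff)
            s_fused = fuse_common(t_a, t_b, mu_p, sa_eff, sb_eff, params.sigma_p)
            s_a = estimate_separate(t_a, mu_p, sa_eff, params.sigma_p)
            s_b = estimate_separate(t_b, mu_p, sb_eff, params.sigma_p)
            s_sel = np.where(u < params.beta, s_a, s_b)
            if decision == "threshold":
                s_hat = np.where(np.asarray(p_common) >= 0.5, s_fused, s_sel)
            else:
                s_hat = p_common * s_fused + (1.0 - p_common) * s_sel
        else:
            s_hat = estimate_separate(t_a, mu_p, sa_eff, params.sigma_p)
        out[:, m] = s_hat + params.d + motor
        mu_p = update_prior(np.asarray(s_hat, dtype=float))
    return out


def _window_slice(window: tuple[int, int], n_beats: int) -> slice:
    lo, hi = window
    if not (1 <= lo <= hi <= n_beats):
        raise ValueError(
            f"analysis window {window} exceeds trial length of {n_beats} beats"
        )
    return slice(lo - 1, hi)


def simulate_trial(params: ObserverParams, trial: StimulusTrial,
                   rng: np.random.Generator, *, window=DEFAULT_WINDOW,
                   decision: str = "threshold",
                   calibrated_reliability: bool = True,
                   trial_id: int = 0) -> AsynchronySeries:
    """Simulate the observer tapping through one stimulus trial.

    Per beat: sense both onsets, judge the common-cause posterior, fuse if
    ``p_common >= 0.5`` else estimate each stream and select one, then emit
    a tap at ``s_hat + d + N(0, sigma_m^2)``; the estimate becomes the next
    beat's prior mean. Returns the asynchronies inside the analysis window.
    """
    sl = _window_slice(window, trial.n_beats)
    rel_a = (trial.onsets_a - trial.grid_onsets_a)[None, :]
    rel_b = None
    if trial.onsets_b is not None:
        rel_b = (trial.onsets_b - trial.grid_onsets_a)[None, :]
    asyn = _run_beats(params, trial.condition, rel_a, rel_b, rng,
                      decision=decision,
                      calibrated_reliability=calibrated_reliability)
    return AsynchronySeries(condition=trial.condition.label, trial=trial_id,
                            asynchronies=asyn[0, sl], window=tuple(window))


def simulate_asynchronies(params: ObserverParams, condition: StimulusCondition,
                          n_trials: int, rng: np.random.Generator, *,
                          window=DEFAULT_WINDOW, decision: str = "threshold",
                          calibrated_reliability: bool = True) -> np.ndarray:
    """Simulate a batch of trials; returns windowed asynchronies (T, W).

    Draws fresh stimuli for every trial from the condition's statistics, so
    the output reflects both stimulus variability and observer noise.
    """
    sl = _window_slice(window, condition.n_beats)
    stim = sample_stimuli(condition, n_trials, rng)
    rel_a = stim["onsets_a"] - stim["grid"]
    rel_b = None
    if stim["onsets_b"] is not None:
        rel_b = stim["onsets_b"] - stim["grid"]
    asyn = _run_beats(params, condition, rel_a, rel_b, rng, decision=decision,
                      calibrated_reliability=calibrated_reliability)
    return asyn[:, sl]
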
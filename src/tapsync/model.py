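"""Fitting observer variants to asynchrony data by simulated KDE likelihood.

The model has no closed-form likelihood: for a candidate parameter vector
the observer is simulated through fresh stimuli matching the condition's
phase-offset and jitter statistics, the simulated asynchronies are turned
into a smooth density (Gaussian KDE, ISJ bandwidth), and the data's negative
log-likelihood under that density is the objective. A seeded differential-
evolution search minimises it over the bounded free parameters, with common
random numbers across parameter evaluations so the objective is a
deterministic (and reasonably smooth) function of the parameters. The final
parameter vector is re-evaluated with three fresh simulation seeds and the
median NLL is reported, guarding against a lucky draw.

Free parameters by variant (fixed ones are excluded from the BIC's k):

========  =====================================
variant   free parameters
========  =====================================
MI        sigma_p, d
MS        sigma_p, d  (+ beta when calibrating)
CI        sigma_p, p_single, d  (+ beta)
CI_PA     sigma_p, p_single, d  (+ beta)
========  =====================================

``beta`` is calibrated once, on the phase-offset 150 ms / jitter {0, 0}
condition, and then held fixed for every other condition, mirroring the
experimental fitting protocol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .comparison import bic
from .density import fit_kde, negative_log_likelihood
from .observer import DEFAULT_WINDOW, ObserverParams, simulate_asynchronies
from .stimulus import StimulusCondition

__all__ = ["FitBounds", "SynchronyModel", "SynchronyResults",
           "fit_condition", "calibrate_beta", "DEFAULT_BOUNDS",
           "CALIBRATION_CONDITION"]


@dataclass(frozen=True)
class FitBounds:
    """Box bounds of the free parameters (ms where applicable)."""

    sigma_p: tuple[float, float] = (10.0, 500.0)
    p_single: tuple[float, float] = (0.0, 1.0)
    d: tuple[float, float] = (-100.0, 100.0)
    beta: tuple[float, float] = (0.0, 1.0)

    def for_names(self, names: Sequence[str]) -> list[tuple[float, float]]:
        return [getattr(self, n) for n in names]


DEFAULT_BOUNDS = FitBounds()

#: the condition on which beta is calibrated
CALIBRATION_CONDITION = StimulusCondition(phase_offset_ms=150.0,
                                          jitter_sd_ms=(0.0, 0.0))


def _free_names(variant: str, estimate_beta: bool) -> list[str]:
    if variant in ("MI", "MS"):
        names = ["sigma_p", "d"]
    else:
        names = ["sigma_p", "p_single", "d"]
    if estimate_beta and variant != "MI":
        names.append("beta")
    return names


@dataclass
class SynchronyResults:
    """Fit of one observer variant to one condition's asynchrony data.

    Attributes mirror the usual likelihood-results surface: ``params`` is
    the full observer parameter vector at the optimum, ``nll`` the median
    re-evaluated negative log-likelihood, ``bic`` the Bayesian information
    criterion ``2*NLL + k*ln(n)`` counting only the free parameters.
    """

    model: "SynchronyModel"
    params: ObserverParams
    theta: dict[str, float]
    nll: float
    nll_optimizer: float
    bic: float
    n_data: int
    k_free: int
    converged: bool
    n_evaluations: int
    seed: int
    restarts: int = 1
    nll_replicates: tuple[float, ...] = ()

    @property
    def variant(self) -> str:
        return self.params.variant

    @property
    def condition(self) -> str:
        return self.model.condition.label

    def simulate(self, n: int, seed: Optional[int] = None) -> np.ndarray:
        """Asynchronies simulated at the fitted parameters."""
        return self.model.simulate(self.params, n, seed=seed)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "variant": self.variant,
            "theta": dict(self.theta),
            "beta": self.params.beta,
            "nll": self.nll,
            "bic": self.bic,
            "n_data": self.n_data,
            "k_free": self.k_free,
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [
            "Synchrony model fit",
            "=" * 46,
            f"variant:        {self.variant}",
            f"condition:      {self.condition}",
            f"n observations: {self.n_data}",
            f"free params k:  {self.k_free}",
            f"NLL:            {self.nll:.3f}",
            f"BIC:            {self.bic:.3f}",
            f"converged:      {self.converged}",
            "-" * 46,
            f"{'parameter':<12}{'estimate':>12}  {'status':<10}",
        ]
        fixed = {"sigma_a": self.params.sigma_a, "sigma_b": self.params.sigma_b,
                 "sigma_m": self.params.sigma_m}
        for name in ("sigma_p", "p_single", "d", "beta"):
            val = getattr(self.params, name)
            status = "free" if name in self.theta else "fixed"
            lines.append(f"{name:<12}{val:>12.4g}  {status:<10}")
        for name, val in fixed.items():
            lines.append(f"{name:<12}{val:>12.4g}  {'fixed':<10}")
        return "\n".join(lines)

    def plot_fit(self, ax=None, n_sim: Optional[int] = None, seed: int = 0):
        """Overlay the data KDE and the fitted model's simulated KDE."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data_kde = fit_kde(self.model.data, min_samples=2)
        sim = self.simulate(n_sim or self.model.n_sim, seed=seed)
        sim_kde = fit_kde(sim)
        ax.plot(data_kde.grid, data_kde.density, "k--", label="data")
        ax.plot(sim_kde.grid, sim_kde.density, label=f"{self.variant} fit")
        ax.set_xlabel("asynchrony (ms)")
        ax.set_ylabel("density (1/ms)")
        ax.legend()
        return ax


class SynchronyModel:
    """One observer variant confronted with one condition's asynchrony data.

    Parameters
    ----------
    data : array-like
        Observed (or synthetic) windowed asynchronies for the condition, ms.
    condition : StimulusCondition
        Stimulus statistics under which simulated asynchronies are drawn.
    variant : {"CI", "CI_PA", "MI", "MS"}
    beta : float, optional
        Stream-A preference, normally pre-calibrated; required for MS, CI
        and CI_PA unless ``estimate_beta`` is set. Ignored by MI.
    estimate_beta : bool
        Treat beta as a free parameter (the calibration-condition fit).
    base_params : ObserverParams, optional
        Source of the fixed configuration constants sigma_a, sigma_b,
        sigma_m (defaults 10 ms each).
    n_sim : int
        Simulated asynchronies per likelihood evaluation.
    """

    def __init__(self, data, condition: StimulusCondition, variant: str = "CI", *,
                 beta: Optional[float] = None, estimate_beta: bool = False,
                 base_params: Optional[ObserverParams] = None,
                 bounds: FitBounds = DEFAULT_BOUNDS, n_sim: int = 2000,
                 window=DEFAULT_WINDOW, calibrated_reliability: bool = True,
                 decision: str = "threshold"):
        self.data = np.asarray(data, dtype=float).ravel()
        if len(self.data) == 0:
            raise ValueError("data must be non-empty")
        if not np.all(np.isfinite(self.data)):
            self.data = self.data[np.isfinite(self.data)]
            if len(self.data) == 0:
                raise ValueError("data contains no finite values")
        self.condition = condition
        if variant not in ("CI", "CI_PA", "MI", "MS"):
            raise ValueError(f"unknown variant {variant!r}")
        self.variant = variant
        self.bounds = bounds
        self.n_sim = int(n_sim)
        self.window = tuple(window)
        self.calibrated_reliability = calibrated_reliability
        self.decision = decision
        base = base_params or ObserverParams(variant=variant)
        self._base = {"sigma_a": base.sigma_a, "sigma_b": base.sigma_b,
                      "sigma_m": base.sigma_m}
        self.estimate_beta = estimate_beta and variant != "MI"
        if variant == "MI":
            beta = 1.0  # never used: MI always fuses
        if beta is None and not self.estimate_beta:
            raise ValueError(
                f"variant {variant} needs a calibrated beta (or estimate_beta=True)"
            )
        self.beta = beta
        self.free_names = _free_names(variant, self.estimate_beta)
        self._window_len = self.window[1] - self.window[0] + 1

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, condition: StimulusCondition,
                       variant: str = "CI", *, participant: Optional[str] = None,
                       **kwargs) -> "SynchronyModel":
        """Build from a tidy dataset (columns participant, condition,
        asynchrony_ms), selecting one condition (and optionally participant)."""
        sub = df[df["condition"] == condition.label]
        if participant is not None:
            sub = sub[sub["participant"] == participant]
        if sub.empty:
            raise ValueError(
                f"no rows for condition {condition.label!r}"
                + (f" and participant {participant!r}" if participant else "")
            )
        return cls(sub["asynchrony_ms"].to_numpy(), condition, variant, **kwargs)

    # -- simulation ---------------------------------------------------------

    def _params_from_theta(self, theta: np.ndarray) -> ObserverParams:
        free = dict(zip(self.free_names, np.asarray(theta, dtype=float)))
        kwargs = dict(self._base)
        kwargs["variant"] = self.variant
        kwargs["sigma_p"] = free["sigma_p"]
        kwargs["d"] = free["d"]
        if self.variant in ("CI", "CI_PA"):
            kwargs["p_single"] = float(np.clip(free["p_single"], 0.0, 1.0))
        kwargs["beta"] = float(np.clip(free.get("beta", self.beta), 0.0, 1.0))
        if self.variant == "CI_PA":
            kwargs["known_offset_ms"] = self.condition.phase_offset_ms
        return ObserverParams(**kwargs)

    def simulate(self, params: ObserverParams, n: int,
                 seed: Optional[int] = None,
                 rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Simulate ``n`` windowed asynchronies under this condition."""
        if rng is None:
            rng = np.random.default_rng(seed)
        n_trials = math.ceil(n / self._window_len)
        asyn = simulate_asynchronies(
            params, self.condition, n_trials, rng, window=self.window,
            decision=self.decision,
            calibrated_reliability=self.calibrated_reliability,
        )
        return asyn.ravel()[:n]

    def loglike(self, theta, seed: int = 0) -> float:
        """Simulated-KDE log-likelihood of the data at ``theta``."""
        return -self.nll(theta, seed=seed)

    def nll(self, theta, seed: int = 0) -> float:
        params = self._params_from_theta(np.atleast_1d(theta))
        sim = self.simulate(params, self.n_sim, seed=seed)
        density = fit_kde(sim)
        return negative_log_likelihood(self.data, density)

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int = 0, *, maxiter: int = 40, popsize: int = 12,
            tol: float = 0.01, restarts: int = 1,
            n_reval: int = 3) -> SynchronyResults:
        """Minimise the simulated-likelihood NLL by differential evolution.

        ``seed`` drives both the optimizer and the common-random-numbers
        simulation seed; two fits with the same seed are identical. The
        best parameter vector is re-evaluated with ``n_reval`` fresh
        simulation seeds and the median NLL is reported (and used for the
        BIC).
        """
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(restarts + 1)
        bounds = self.bounds.for_names(self.free_names)
        best = None
        n_evals = 0
        converged = False
        for r in range(restarts):
            run_ss = children[r]
            sim_seed, de_seed = [int(s) for s in
                                 run_ss.generate_state(2) % (2 ** 31)]
            res = differential_evolution(
                lambda th: self.nll(th, seed=sim_seed),
                bounds=bounds, seed=de_seed, maxiter=maxiter, popsize=popsize,
                tol=tol, init="sobol", polish=False, updating="deferred",
            )
            n_evals += res.nfev
            converged = converged or bool(res.success)
            if best is None or res.fun < best[1]:
                best = (res.x, res.fun)
        theta_hat, nll_opt = best
        reval_seeds = children[restarts].generate_state(n_reval) % (2 ** 31)
        replicates = tuple(self.nll(theta_hat, seed=int(s)) for s in reval_seeds)
        nll_final = float(np.median(replicates))
        k = len(self.free_names)
        params = self._params_from_theta(theta_hat)
        return SynchronyResults(
            model=self,
            params=params,
            theta={n: float(v) for n, v in zip(self.free_names, theta_hat)},
            nll=nll_final,
            nll_optimizer=float(nll_opt),
            bic=bic(nll_final, k, len(self.data)),
            n_data=len(self.data),
            k_free=k,
            converged=converged,
            n_evaluations=n_evals,
            seed=seed,
            restarts=restarts,
            nll_replicates=replicates,
        )


def fit_condition(data, condition: StimulusCondition, variant: str, *,
                  beta: Optional[float] = None, seed: int = 0,
                  bounds: FitBounds = DEFAULT_BOUNDS,
                  **fit_kwargs) -> SynchronyResults:
    """Fit one variant to one condition's asynchronies with beta held fixed."""
    model_kwargs = {k: fit_kwargs.pop(k) for k in
                    ("n_sim", "window", "calibrated_reliability", "decision",
                     "base_params") if k in fit_kwargs}
    model = SynchronyModel(data, condition, variant, beta=beta, bounds=bounds,
                           **model_kwargs)
    return model.fit(seed=seed, **fit_kwargs)


def calibrate_beta(data, variant: str, *,
                   condition: StimulusCondition = CALIBRATION_CONDITION,
                   seed: int = 0, bounds: FitBounds = DEFAULT_BOUNDS,
                   **fit_kwargs) -> SynchronyResults:
    """Joint fit with beta free on the calibration condition.

    By protocol this is the 150 ms phase offset, jitter {0, 0} condition:
    there the two streams are maximally separated, so the asynchrony
    distribution's two lobes pin down the stream-A preference. The returned
    results carry ``params.beta``; pass that to :func:`fit_condition` for
    every other condition.
    """
    model_kwargs = {k: fit_kwargs.pop(k) for k in
                    ("n_sim", "window", "calibrated_reliability", "decision",
                     "base_params") if k in fit_kwargs}
    model = SynchronyModel(data, condition, variant, estimate_beta=True,
                           bounds=bounds, **model_kwargs)
    return model.fit(seed=seed, **fit_kwargs)
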
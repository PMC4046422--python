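"""BIC-based model comparison and the scaled goodness-of-fit index.

Model fits are compared by summing BIC across conditions within each
participant, differencing against a reference variant, and averaging the
differences across participants (positive = worse than the reference). The
overall goodness of fit rescales a fit's BIC between two anchors: the BIC
of the data under a KDE of the data itself (best achievable, r2 = 1) and
the BIC under a featureless reference density (worst case, r2 = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .density import KDEDensity, fit_kde, negative_log_likelihood

__all__ = ["bic", "delta_bic", "delta_bic_table", "goodness_r2",
           "reference_bics", "GoodnessOfFit", "DegenerateReferenceError"]


class DegenerateReferenceError(ValueError):
    """The random-reference BIC does not exceed the best-fit BIC."""


def bic(nll: float, k_free: int, n: int) -> float:
    """Bayesian information criterion ``2*NLL + k*ln(n)``; lower is better."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if k_free < 0:
        raise ValueError("k_free must be non-negative")
    return 2.0 * float(nll) + k_free * np.log(n)


@dataclass
class GoodnessOfFit:
    """A fit's BIC placed between the best- and worst-case anchors."""

    l_theta: float
    l_max: float
    l_rand: float

    @property
    def r2(self) -> float:
        return goodness_r2(self.l_theta, self.l_max, self.l_rand)


def goodness_r2(l_theta: float, l_max: float, l_rand: float) -> float:
    """Scaled goodness of fit, 1 at the best-fit anchor, 0 at the random one.

    ``r2 = 1 - (L(theta) - L(Max)) / (L(Rand) - L(Max))``, clipped to [0, 1].
    """
    if l_rand <= l_max:
        raise DegenerateReferenceError(
            "random-reference BIC must exceed the best-fit BIC"
        )
    r2 = 1.0 - (l_theta - l_max) / (l_rand - l_max)
    return float(np.clip(r2, 0.0, 1.0))


def _uniform_reference(data: np.ndarray, bw: float) -> KDEDensity:
    lo = float(np.min(data)) - bw
    hi = float(np.max(data)) + bw
    grid = np.linspace(lo, hi, 512)
    dens = np.full_like(grid, 1.0 / (hi - lo))
    return KDEDensity(grid=grid, density=dens, bandwidth=bw, n_samples=len(data))


def _spline_reference(data: np.ndarray, bw: float,
                      rng: np.random.Generator, n_knots: int = 10) -> KDEDensity:
    """Cubic spline through jittered uniform histogram counts.

    A wiggly but featureless density over the data's support: expected
    uniform bin counts are perturbed by Poisson-scale noise and smoothed by
    a cubic spline, then clipped and renormalised.
    """
    lo = float(np.min(data)) - bw
    hi = float(np.max(data)) + bw
    knots = np.linspace(lo, hi, n_knots)
    expected = len(data) / n_knots
    counts = expected + rng.normal(0.0, np.sqrt(expected), n_knots)
    counts = np.clip(counts, 0.1 * expected, None)
    spline = CubicSpline(knots, counts)
    grid = np.linspace(lo, hi, 512)
    dens = np.clip(spline(grid), 1e-12, None)
    dens /= np.trapezoid(dens, grid)
    return KDEDensity(grid=grid, density=dens, bandwidth=bw, n_samples=len(data))


def reference_bics(data, *, method: str = "uniform", seed: int = 0,
                   **kde_kwargs) -> tuple[float, float]:
    """Best- and worst-case reference BICs ``(L_max, L_rand)`` for a dataset.

    ``L_max`` scores the data against a KDE of itself; ``L_rand`` against a
    featureless density over the data's support ("uniform", the default, or
    "spline" for the cubic-spline variant). Both references carry zero free
    parameters in the BIC.
    """
    x = np.asarray(data, dtype=float).ravel()
    self_kde = fit_kde(x, **kde_kwargs)
    l_max = bic(negative_log_likelihood(x, self_kde), 0, len(x))
    if method == "uniform":
        ref = _uniform_reference(x, self_kde.bandwidth)
    elif method == "spline":
        ref = _spline_reference(x, self_kde.bandwidth, np.random.default_rng(seed))
    else:
        raise ValueError(f"unknown reference method {method!r}")
    l_rand = bic(negative_log_likelihood(x, ref), 0, len(x))
    return l_max, l_rand


def _check_grid(df: pd.DataFrame) -> None:
    required = {"participant", "condition", "variant", "bic"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fit table is missing columns: {sorted(missing)}")
    counts = df.pivot_table(index=["participant", "variant"], columns="condition",
                            values="bic", aggfunc="count")
    if counts.isna().any().any() or (counts != 1).any().any():
        holes = counts.stack(future_stack=True)
        holes = holes[holes.isna() | (holes != 1)]
        raise ValueError(
            "incomplete fit grid; missing or duplicated cells:\n"
            + holes.to_string()
        )


def delta_bic(fits: pd.DataFrame, reference: str = "CI_PA") -> pd.Series:
    """Mean summed-BIC difference of each variant against a reference.

    ``fits`` is a tidy table with one row per (participant, condition,
    variant) carrying a ``bic`` column. BICs are summed across conditions
    within participant, differenced against the reference variant, and the
    differences averaged across participants. Positive values mean the
    variant fits worse than the reference.
    """
    _check_grid(fits)
    if reference not in set(fits["variant"]):
        raise ValueError(f"reference variant {reference!r} absent from fits")
    summed = fits.groupby(["participant", "variant"])["bic"].sum().unstack()
    delta = summed.sub(summed[reference], axis=0)
    return delta.mean(axis=0).rename("delta_bic")


def delta_bic_table(fits: pd.DataFrame, variant: str,
                    reference: str = "CI_PA") -> pd.DataFrame:
    """Per-condition mean BIC difference (variant minus reference).

    Returns a condition-indexed table; positive values mean the reference
    fits better in that condition. With conditions labelled
    ``offNNN_jA-B`` the index is split into an offset-by-jitter grid.
    """
    _check_grid(fits)
    wide = fits.pivot_table(index=["participant", "condition"], columns="variant",
                            values="bic")
    diff = (wide[variant] - wide[reference]).groupby("condition").mean()
    parts = diff.index.str.extract(r"off(?P<offset>\d+)_j(?P<jitter>.+)")
    if not parts["offset"].isna().any():
        table = pd.DataFrame({
            "offset_ms": parts["offset"].astype(int).values,
            "jitter": parts["jitter"].values,
            "delta_bic": diff.values,
        })
        return table.pivot(index="offset_ms", columns="jitter", values="delta_bic")
    return diff.to_frame("delta_bic")
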
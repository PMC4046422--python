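"""Empirical-side analyses of tap asynchronies.

Covers asynchrony extraction from raw tap times, per-trial variability
summaries, and the unimodal-versus-bimodal classification of asynchrony
distributions by comparing one- and two-component Gaussian mixtures with
the BIC. All asynchronies are referenced to the pre-jitter grid of
metronome A; negative values mean the tap preceded the beat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .observer import AsynchronySeries, DEFAULT_WINDOW
from .stimulus import StimulusTrial

__all__ = ["GMMComparison", "compute_asynchronies", "asynchrony_sd",
           "gmm_compare", "mean_asynchrony", "modality_table"]

log = logging.getLogger(__name__)


@dataclass
class GMMComparison:
    """One- versus two-centre Gaussian mixture comparison for one dataset.

    ``delta_bic = BIC_1 - BIC_2``; the distribution is called bimodal
    exactly when the two-centre model wins (``delta_bic > 0``). The stored
    means/weights/variances belong to the winning model, means sorted
    ascending.
    """

    n: int
    bic_1: float
    bic_2: float
    means: np.ndarray
    weights: np.ndarray
    variances: np.ndarray

    @property
    def delta_bic(self) -> float:
        return self.bic_1 - self.bic_2

    @property
    def modality(self) -> str:
        return "bimodal" if self.delta_bic > 0 else "unimodal"


def compute_asynchronies(taps, trial: StimulusTrial, *,
                         window=DEFAULT_WINDOW,
                         trial_id: int = 0) -> AsynchronySeries:
    """Pair taps with windowed grid beats and return signed asynchronies.

    Each pre-jitter grid beat of metronome A inside the analysis window is
    matched to its nearest tap within half a period; the asynchrony is
    ``tap - grid_onset``. Beats with no tap in range yield NaN; when two
    taps fall in one beat's half-period window the nearer one wins.
    """
    taps = np.sort(np.asarray(taps, dtype=float))
    lo, hi = window
    if not (1 <= lo <= hi <= trial.n_beats):
        raise ValueError(f"window {window} exceeds trial length {trial.n_beats}")
    grid = trial.grid_onsets_a[lo - 1:hi]
    half = trial.period_ms / 2.0
    out = np.full(len(grid), np.nan)
    for i, g in enumerate(grid):
        d = taps - g
        in_range = np.abs(d) <= half
        if not in_range.any():
            continue
        candidates = d[in_range]
        if len(candidates) > 1:
            log.info("beat %d: %d taps in range, keeping the nearest",
                     lo + i, len(candidates))
        out[i] = candidates[np.argmin(np.abs(candidates))]
    return AsynchronySeries(condition=trial.condition.label, trial=trial_id,
                            asynchronies=out, window=tuple(window))


def asynchrony_sd(data: pd.DataFrame,
                  grouping: tuple[str, ...] = ("condition",)
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial asynchrony s.d. and group-level mean +/- s.e.m.

    ``data`` is tidy with at least columns ``condition``, ``trial`` and
    ``asynchrony_ms`` (plus ``participant`` if present). Trials with fewer
    than two finite asynchronies are dropped with a warning. Returns
    ``(per_trial, summary)``: the per-trial sample s.d. table and, per
    ``grouping``, its mean, s.e.m. and trial count.
    """
    keys = [c for c in ("participant", "condition", "trial") if c in data.columns]
    if "condition" not in keys or "trial" not in keys:
        raise ValueError("data needs 'condition' and 'trial' columns")
    per_trial = (
        data.dropna(subset=["asynchrony_ms"])
        .groupby(keys)["asynchrony_ms"]
        .agg(sd=lambda x: x.std(ddof=1), n="count")
        .reset_index()
    )
    short = per_trial["n"] < 2
    if short.any():
        log.warning("dropping %d trial(s) with fewer than 2 asynchronies",
                    int(short.sum()))
        per_trial = per_trial[~short]
    group_keys = [g for g in grouping if g in per_trial.columns]
    summary = (
        per_trial.groupby(group_keys)["sd"]
        .agg(mean_sd="mean", sem_sd="sem", n_trials="count")
        .reset_index()
    )
    return per_trial, summary


def gmm_compare(asynchronies, *, seed: int = 0, n_init: int = 5,
                variance_floor: float = 1.0, min_points: int = 20) -> GMMComparison:
    """Classify an asynchrony distribution as unimodal or bimodal.

    Fits Gaussian mixtures with one and two centres (unequal variances, EM
    with ``n_init`` restarts, variance floored at ``variance_floor`` ms^2)
    and compares their BICs; free-parameter counts are 2 and 5.
    """
    x = np.asarray(asynchronies, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if len(x) < min_points:
        raise ValueError(f"need at least {min_points} finite points, got {len(x)}")
    X = x[:, None]
    fits = {}
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=n_init, reg_covar=variance_floor,
                             random_state=seed)
        gm.fit(X)
        fits[k] = gm
    bic_1 = float(fits[1].bic(X))
    bic_2 = float(fits[2].bic(X))
    best = fits[2] if bic_1 - bic_2 > 0 else fits[1]
    means = best.means_.ravel()
    order = np.argsort(means)
    return GMMComparison(
        n=len(x),
        bic_1=bic_1,
        bic_2=bic_2,
        means=means[order],
        weights=best.weights_.ravel()[order],
        variances=best.covariances_.reshape(-1)[order],
    )


def mean_asynchrony(gmm: GMMComparison):
    """Best-fitting GMM centres: one mean if unimodal, an ordered pair if bimodal."""
    if gmm.modality == "unimodal":
        return float(gmm.means[0])
    return float(gmm.means[0]), float(gmm.means[1])


def modality_table(data: pd.DataFrame, *, seed: int = 0,
                   by: tuple[str, ...] = ("participant", "condition"),
                   min_points: int = 20) -> pd.DataFrame:
    """GMM modality call per group (default: participant x condition).

    Pools each group's finite asynchronies, runs :func:`gmm_compare` and
    tabulates the BICs, modality and mixture centres.
    """
    keys = [c for c in by if c in data.columns]
    rows = []
    for key, sub in data.groupby(keys):
        x = sub["asynchrony_ms"].dropna().to_numpy()
        if len(x) < min_points:
            continue
        cmp = gmm_compare(x, seed=seed)
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(
            n=cmp.n, bic_1=cmp.bic_1, bic_2=cmp.bic_2,
            delta_bic=cmp.delta_bic, modality=cmp.modality,
            mean_low=cmp.means[0],
            mean_high=cmp.means[-1] if len(cmp.means) > 1 else np.nan,
        )
        rows.append(row)
    return pd.DataFrame(rows)
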
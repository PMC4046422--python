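"""Dual- and single-metronome stimulus generation.

A stimulus trial consists of one or two auditory metronome streams with a
common underlying period. Stream B lags stream A by a fixed phase offset
``phi``, and each stream's beat onsets are independently perturbed around the
isochronous grid by zero-mean Gaussian "jitter". All times are real-valued
milliseconds from trial start; beat indices are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "StimulusCondition",
    "StimulusTrial",
    "make_trial",
    "sample_stimuli",
    "condition_label",
]


@dataclass(frozen=True)
class StimulusCondition:
    """One cell of the metronome design.

    Parameters
    ----------
    phase_offset_ms : float
        Delay ``phi`` of metronome B relative to metronome A (>= 0).
    jitter_sd_ms : tuple of float, or float
        Per-beat jitter standard deviations ``(sigma_jA, sigma_jB)`` for a
        dual-stream condition, or a single s.d. when ``n_streams == 1``.
    n_beats : int
        Number of beats per trial.
    period_range_ms : tuple of float
        Interval from which the per-trial period is drawn uniformly.
    n_streams : int
        1 (single metronome) or 2 (dual metronome).
    clip_jitter : bool
        If True, clip jitter at +/- period/2 to prevent beat-order
        inversions in extreme synthetic settings. Off by default: the jitter
        is plain unbounded Gaussian.
    """

    phase_offset_ms: float = 0.0
    jitter_sd_ms: tuple[float, float] | float = (0.0, 0.0)
    n_beats: int = 30
    period_range_ms: tuple[float, float] = (470.0, 530.0)
    n_streams: int = 2
    clip_jitter: bool = False

    def __post_init__(self):
        if self.n_streams not in (1, 2):
            raise ValueError("n_streams must be 1 or 2")
        if self.phase_offset_ms < 0:
            raise ValueError("phase offset must be non-negative")
        if self.n_beats < 2:
            raise ValueError("need at least 2 beats")
        lo, hi = self.period_range_ms
        if not (0 < lo <= hi):
            raise ValueError("period range must be positive and non-empty")
        ja, jb = self.jitter_a, self.jitter_b
        if ja < 0 or jb < 0:
            raise ValueError("jitter s.d. must be non-negative")

    @property
    def jitter_a(self) -> float:
        if np.isscalar(self.jitter_sd_ms):
            return float(self.jitter_sd_ms)
        return float(self.jitter_sd_ms[0])

    @property
    def jitter_b(self) -> float:
        if np.isscalar(self.jitter_sd_ms):
            return 0.0
        return float(self.jitter_sd_ms[1])

    @property
    def label(self) -> str:
        return condition_label(self)


def condition_label(condition: StimulusCondition) -> str:
    """Short identifier for a condition, e.g. ``off050_j10-50`` or ``single_j50``."""
    if condition.n_streams == 1:
        return f"single_j{condition.jitter_a:g}"
    return (
        f"off{condition.phase_offset_ms:03.0f}"
        f"_j{condition.jitter_a:g}-{condition.jitter_b:g}"
    )


@dataclass(frozen=True)
class StimulusTrial:
    """One realised trial: the isochronous grid plus jittered onsets."""

    condition: StimulusCondition
    period_ms: float
    grid_onsets_a: np.ndarray
    onsets_a: np.ndarray
    onsets_b: Optional[np.ndarray]
    rng_seed: Optional[int] = None

    @property
    def n_beats(self) -> int:
        return len(self.grid_onsets_a)

    def to_frame(self, trial: int = 0) -> pd.DataFrame:
        """Tabular view (columns: trial, beat, grid_a, onset_a, onset_b)."""
        beats = np.arange(1, self.n_beats + 1)
        return pd.DataFrame(
            {
                "trial": trial,
                "beat": beats,
                "grid_a": self.grid_onsets_a,
                "onset_a": self.onsets_a,
                "onset_b": self.onsets_b if self.onsets_b is not None else np.nan,
            }
        )


def sample_stimuli(
    condition: StimulusCondition, n_trials: int, rng: np.random.Generator
) -> dict:
    """Draw a batch of trials for one condition.

    Returns a dict of arrays: ``period`` (T,), ``grid`` (T, B),
    ``onsets_a`` (T, B) and ``onsets_b`` (T, B) or None. Jitter is applied
    per beat independently; the underlying grid stays isochronous.
    """
    lo, hi = condition.period_range_ms
    b = condition.n_beats
    period = rng.uniform(lo, hi, size=n_trials)
    grid = period[:, None] * np.arange(b)[None, :]
    jit_a = rng.normal(0.0, condition.jitter_a, size=(n_trials, b))
    jit_b = rng.normal(0.0, condition.jitter_b, size=(n_trials, b))
    if condition.clip_jitter:
        half = (period / 2.0)[:, None]
        jit_a = np.clip(jit_a, -half, half)
        jit_b = np.clip(jit_b, -half, half)
    onsets_a = grid + jit_a
    onsets_b = None
    if condition.n_streams == 2:
        onsets_b = grid + condition.phase_offset_ms + jit_b
    return {"period": period, "grid": grid, "onsets_a": onsets_a, "onsets_b": onsets_b}


def make_trial(condition: StimulusCondition, seed: Optional[int] = None,
               rng: Optional[np.random.Generator] = None) -> StimulusTrial:
    """Generate a single reproducible trial for ``condition``.

    The per-trial period is drawn uniformly from the condition's period
    range and shared by both streams; each stream receives independent
    Gaussian per-beat jitter.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    batch = sample_stimuli(condition, 1, rng)
    return StimulusTrial(
        condition=condition,
        period_ms=float(batch["period"][0]),
        grid_onsets_a=batch["grid"][0],
        onsets_a=batch["onsets_a"][0],
        onsets_b=None if batch["onsets_b"] is None else batch["onsets_b"][0],
        rng_seed=seed,
    )
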
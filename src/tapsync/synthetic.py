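"""Synthetic participant cohorts with the dual-metronome experiment's design.

No tapping dataset accompanies the study design this package models, so the
whole analysis chain is exercised on simulated participants: each carries a
ground-truth observer parameter vector drawn from configurable ranges and
taps through the full design (12 dual-metronome conditions of 10 trials x
30 beats, plus 30 single-metronome trials). Ground truth is stored next to
the data so parameter- and model-recovery can be tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import DEFAULT_BOUNDS
from .observer import DEFAULT_WINDOW, ObserverParams, simulate_asynchronies
from .stimulus import StimulusCondition

__all__ = ["ExperimentDesign", "SyntheticParticipant", "SchemaError",
           "DEFAULT_PARAM_RANGES", "sample_params", "generate_cohort",
           "cohort_frame", "write_dataset", "read_dataset"]


class SchemaError(ValueError):
    """A dataset file does not match the expected schema."""


@dataclass(frozen=True)
class ExperimentDesign:
    """The factorial metronome design: offsets x jitter pairs, plus baselines."""

    phase_offsets_ms: tuple[float, ...] = (0.0, 50.0, 100.0, 150.0)
    jitter_pairs_ms: tuple[tuple[float, float], ...] = ((0.0, 0.0), (10.0, 50.0), (50.0, 10.0))
    trials_per_condition: int = 10
    beats_per_trial: int = 30
    analysis_window: tuple[int, int] = DEFAULT_WINDOW
    single_jitters_ms: tuple[float, ...] = (0.0, 10.0, 50.0)
    single_trials_per_jitter: int = 10
    period_range_ms: tuple[float, float] = (470.0, 530.0)

    def __post_init__(self):
        lo, hi = self.analysis_window
        if not (1 <= lo <= hi <= self.beats_per_trial):
            raise ValueError("analysis window must lie within the beat range")

    def dual_conditions(self) -> list[StimulusCondition]:
        return [
            StimulusCondition(phase_offset_ms=off, jitter_sd_ms=jit,
                              n_beats=self.beats_per_trial,
                              period_range_ms=self.period_range_ms)
            for off in self.phase_offsets_ms
            for jit in self.jitter_pairs_ms
        ]

    def single_conditions(self) -> list[StimulusCondition]:
        return [
            StimulusCondition(jitter_sd_ms=j, n_streams=1,
                              n_beats=self.beats_per_trial,
                              period_range_ms=self.period_range_ms)
            for j in self.single_jitters_ms
        ]

    def all_conditions(self) -> list[StimulusCondition]:
        return self.dual_conditions() + self.single_conditions()

    def to_dict(self) -> dict:
        return asdict(self)


#: uniform sampling ranges for ground-truth observer parameters.
#:
#: sigma_p mid-range of the fit bounds; p_single and beta spread to give
#: participant-level heterogeneity in integration thresholds and stream
#: preference; d the usual negative anticipation; sigma_a/sigma_b 20 ms
#: auditory beat-onset registration noise (an observer with this width
#: fuses 50 ms-offset streams for any common-beat prior above one half,
#: but separates them at 100 ms and beyond); sigma_m spans the
#: inter-individual range of tapping motor/timekeeper variability.
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "sigma_p": (60.0, 200.0),
    "p_single": (0.5, 0.9),
    "d": (-60.0, -15.0),
    "beta": (0.25, 0.75),
    "sigma_a": (20.0, 20.0),
    "sigma_b": (20.0, 20.0),
    "sigma_m": (12.0, 28.0),
}

_FIT_BOUNDED = {"sigma_p": DEFAULT_BOUNDS.sigma_p,
                "p_single": DEFAULT_BOUNDS.p_single,
                "d": DEFAULT_BOUNDS.d,
                "beta": DEFAULT_BOUNDS.beta}


def sample_params(rng: np.random.Generator, variant: str = "CI",
                  param_ranges: Optional[dict] = None) -> ObserverParams:
    """Draw one participant's ground-truth parameters from uniform ranges."""
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    for name, (lo, hi) in ranges.items():
        if name in _FIT_BOUNDED:
            blo, bhi = _FIT_BOUNDED[name]
            if lo < blo or hi > bhi:
                raise ValueError(
                    f"range for {name} ({lo}, {hi}) exceeds the fit bounds "
                    f"({blo}, {bhi})"
                )
    draws = {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()}
    if variant == "MI":
        draws["p_single"] = 1.0
    elif variant == "MS":
        draws["p_single"] = 0.0
    return ObserverParams(variant=variant, **draws)


@dataclass
class SyntheticParticipant:
    """One simulated participant: ground truth plus their full dataset."""

    participant: str
    params: ObserverParams
    seed: int
    data: pd.DataFrame = field(repr=False)


def _participant_rng(master_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    )


def simulate_participant(pid: str, params: ObserverParams,
                         rng: np.random.Generator,
                         design: ExperimentDesign, *,
                         calibrated_reliability: bool = True) -> pd.DataFrame:
    """Tap one observer through every condition of the design (tidy output)."""
    lo, hi = design.analysis_window
    beats = np.arange(lo, hi + 1)
    frames = []
    for cond in design.all_conditions():
        n_trials = (design.trials_per_condition if cond.n_streams == 2
                    else design.single_trials_per_jitter)
        p = params
        if params.variant == "CI_PA" and cond.n_streams == 2:
            p = params.with_(known_offset_ms=cond.phase_offset_ms)
        asyn = simulate_asynchronies(
            p, cond, n_trials, rng, window=design.analysis_window,
            calibrated_reliability=calibrated_reliability,
        )
        n_t, n_w = asyn.shape
        frames.append(pd.DataFrame({
            "participant": pid,
            "condition": cond.label,
            "trial": np.repeat(np.arange(1, n_t + 1), n_w),
            "beat": np.tile(beats, n_t),
            "asynchrony_ms": asyn.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def generate_cohort(n_participants: int = 9, *, seed: int = 0,
                    variant: str = "CI",
                    param_ranges: Optional[dict] = None,
                    design: Optional[ExperimentDesign] = None,
                    params: Optional[list[ObserverParams]] = None,
                    calibrated_reliability: bool = True
                    ) -> list[SyntheticParticipant]:
    """Generate a cohort of synthetic participants.

    Each participant's ground-truth parameters are drawn from
    ``param_ranges`` (or given explicitly via ``params``) and their data
    simulated over the full design. The whole cohort is reproducible from
    ``seed`` alone; each participant is additionally regenerable from
    (seed, index, params).
    """
    design = design or ExperimentDesign()
    cohort = []
    for i in range(n_participants):
        rng = _participant_rng(seed, i)
        p = params[i] if params is not None else sample_params(rng, variant, param_ranges)
        pid = f"P{i + 1:02d}"
        data = simulate_participant(pid, p, rng, design,
                                    calibrated_reliability=calibrated_reliability)
        cohort.append(SyntheticParticipant(participant=pid, params=p,
                                           seed=seed, data=data))
    return cohort


def cohort_frame(cohort: list[SyntheticParticipant]) -> pd.DataFrame:
    """Concatenate a cohort into one tidy DataFrame."""
    return pd.concat([p.data for p in cohort], ignore_index=True)


REQUIRED_COLUMNS = ("participant", "condition", "trial", "beat", "asynchrony_ms")


def write_dataset(cohort: list[SyntheticParticipant], path) -> Path:
    """Write a cohort to ``path/data.csv`` plus ``path/ground_truth.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort_frame(cohort).to_csv(path / "data.csv", index=False)
    truth = {
        p.participant: {
            "seed": p.seed,
            "params": {k: v for k, v in asdict(p.params).items()},
        }
        for p in cohort
    }
    with open(path / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return path


def read_dataset(path) -> tuple[pd.DataFrame, dict]:
    """Read a dataset directory back; validates the CSV schema.

    Returns ``(data, ground_truth)``; ground truth is ``{}`` when no
    sidecar file exists (e.g. a genuinely empirical dataset).
    """
    path = Path(path)
    csv = path / "data.csv" if path.is_dir() else path
    if not csv.exists():
        raise FileNotFoundError(csv)
    df = pd.read_csv(csv)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"data file is missing column(s): {missing}")
    for col in ("trial", "beat", "asynchrony_ms"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:10]  # 1-based incl. header
            raise SchemaError(f"non-numeric values in {col!r} at file row(s) {rows}")
    truth_file = (path / "ground_truth.json") if path.is_dir() else None
    truth = {}
    if truth_file is not None and truth_file.exists():
        with open(truth_file) as fh:
            truth = json.load(fh)
    return df, truth
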
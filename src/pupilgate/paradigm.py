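"""RSVP stimulus scheduling for the familiar-face oddball authentication task.

The task presents rapid serial visual presentation (RSVP) streams of face
photographs: within each trial one *target* (a familiar face) is hidden among
*nontarget* (stranger) faces.  Stimuli are flashed for ``stimulus_duration``
ms followed by a ``blank_duration`` ms blank, so consecutive onsets within a
trial are ``stimulus_duration + blank_duration`` ms apart.  Trials group into
blocks separated by longer rest intervals, and the whole task is preceded and
followed by preparation/relaxation periods.

With the default configuration (10 blocks x 5 trials x 10 stimuli, 100 ms
stimulus + 100 ms blank, 2 s inter-trial and 5 s inter-block intervals) a
trial lasts 2 s, a block 20 s, and the core task 245 s.

Event onsets are expressed on the recording clock: the first stimulus occurs
at ``preparation_period`` ms, so schedules align directly with recordings
that span the total duration.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, SizingError

__all__ = [
    "ParadigmConfig",
    "StimulusEvent",
    "Schedule",
    "build_schedule",
    "assign_stimuli",
    "events_to_table",
    "schedule_from_table",
]

TARGET = "target"
NONTARGET = "nontarget"


@dataclass(frozen=True)
class ParadigmConfig:
    """Timing and count parameters of the RSVP task.

    All durations are in milliseconds.  Defaults reproduce the reference
    protocol: 50 trials in 10 blocks, 500 stimuli of which 50 are targets,
    and a 245 s core task flanked by 30 s preparation/relaxation periods.
    """

    n_blocks: int = 10
    trials_per_block: int = 5
    stimuli_per_trial: int = 10
    stimulus_duration: float = 100.0
    blank_duration: float = 100.0
    inter_trial_interval: float = 2000.0
    inter_block_interval: float = 5000.0
    targets_per_trial: int = 1
    preparation_period: float = 30_000.0
    relaxation_period: float = 30_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_blocks", "trials_per_block", "stimuli_per_trial", "targets_per_trial"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        for name in ("stimulus_duration", "blank_duration"):
            v = getattr(self, name)
            if not v > 0:
                raise ConfigError(f"{name} must be > 0 ms, got {v!r}")
        for name in (
            "inter_trial_interval",
            "inter_block_interval",
            "preparation_period",
            "relaxation_period",
        ):
            v = getattr(self, name)
            if v < 0:
                raise ConfigError(f"{name} must be >= 0 ms, got {v!r}")
        # <= rather than <: a degenerate all-target trial (1 stimulus) is a
        # legal, if useless, schedule and useful for testing timing arithmetic
        if self.targets_per_trial > self.stimuli_per_trial:
            raise ConfigError(
                "targets_per_trial must be <= stimuli_per_trial "
                f"({self.targets_per_trial} > {self.stimuli_per_trial})"
            )

    @property
    def stimulus_onset_asynchrony(self) -> float:
        """Spacing between consecutive stimulus onsets within a trial (ms)."""
        return self.stimulus_duration + self.blank_duration

    @property
    def trial_duration(self) -> float:
        return self.stimuli_per_trial * self.stimulus_onset_asynchrony

    @property
    def block_duration(self) -> float:
        """Block span including the inter-trial interval after every trial.

        An interval follows each trial of a block (including the last), so a
        block of five 2-s trials with 2-s intervals spans 20 s.
        """
        return self.trials_per_block * (self.trial_duration + self.inter_trial_interval)

    @property
    def core_duration(self) -> float:
        """Task duration excluding preparation/relaxation (ms)."""
        return self.n_blocks * self.block_duration + (self.n_blocks - 1) * self.inter_block_interval

    @property
    def total_duration(self) -> float:
        return self.core_duration + self.preparation_period + self.relaxation_period

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def n_events(self) -> int:
        return self.n_trials * self.stimuli_per_trial

    @property
    def n_target_slots(self) -> int:
        return self.n_trials * self.targets_per_trial

    @property
    def n_nontarget_slots(self) -> int:
        return self.n_events - self.n_target_slots


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus presentation.

    ``onset`` is in ms on the recording clock (preparation period included);
    ``trial`` is the global 0-based trial index across the whole task.
    """

    onset: float
    block: int
    trial: int
    position: int
    label: str
    stimulus_id: str


@dataclass(frozen=True)
class Schedule:
    """A fully timed stimulus schedule."""

    config: ParadigmConfig
    events: tuple[StimulusEvent, ...]
    core_duration: float = field(init=False)
    total_duration: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "core_duration", self.config.core_duration)
        object.__setattr__(self, "total_duration", self.config.total_duration)

    @property
    def n_targets(self) -> int:
        return sum(e.label == TARGET for e in self.events)

    @property
    def n_nontargets(self) -> int:
        return len(self.events) - self.n_targets


def build_schedule(config: ParadigmConfig, seed: int | None = None) -> Schedule:
    """Construct the event schedule for ``config``.

    Timing is deterministic given the configuration; the position of the
    target(s) within each trial is drawn uniformly from the seeded generator
    (``config.seed`` unless ``seed`` overrides it).  Placeholder stimulus ids
    (``t####``/``n####`` serials) are attached so the schedule is usable
    before :func:`assign_stimuli`.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    soa = config.stimulus_onset_asynchrony
    events: list[StimulusEvent] = []
    n_t = n_n = 0
    trial_global = 0
    for b in range(config.n_blocks):
        block_start = config.preparation_period + b * (
            config.block_duration + config.inter_block_interval
        )
        for t in range(config.trials_per_block):
            trial_start = block_start + t * (config.trial_duration + config.inter_trial_interval)
            target_positions = set(
                rng.choice(config.stimuli_per_trial, size=config.targets_per_trial, replace=False)
            )
            for p in range(config.stimuli_per_trial):
                if p in target_positions:
                    label, sid = TARGET, f"t{n_t:04d}"
                    n_t += 1
                else:
                    label, sid = NONTARGET, f"n{n_n:04d}"
                    n_n += 1
                events.append(
                    StimulusEvent(
                        onset=trial_start + p * soa,
                        block=b,
                        trial=trial_global,
                        position=p,
                        label=label,
                        stimulus_id=sid,
                    )
                )
            trial_global += 1
    return Schedule(config=config, events=tuple(events))


def assign_stimuli(
    schedule: Schedule,
    target_pool: list[str],
    nontarget_pool: list[str],
    seed: int = 0,
) -> Schedule:
    """Fill stimulus slots from photograph pools.

    Nontarget slots are filled by seeded sampling *without* replacement (each
    stranger face appears at most once over the whole task, so repeated
    exposure cannot familiarize it); target slots are filled *with*
    replacement from the (small) familiar-face pool.  The assignment order is
    a seeded shuffle, counterbalancing which pool items land early vs late.
    """
    if not target_pool:
        raise SizingError("target_pool is empty")
    n_nt = schedule.n_nontargets
    if len(nontarget_pool) < n_nt:
        raise SizingError(
            f"nontarget_pool too small: need {n_nt} unique ids, have {len(nontarget_pool)}"
        )
    rng = np.random.default_rng(seed)
    nt_ids = list(rng.permutation(np.asarray(nontarget_pool, dtype=object))[:n_nt])
    t_ids = list(rng.choice(np.asarray(target_pool, dtype=object), size=schedule.n_targets))
    events = []
    for e in schedule.events:
        sid = t_ids.pop(0) if e.label == TARGET else nt_ids.pop(0)
        events.append(dataclasses.replace(e, stimulus_id=str(sid)))
    return Schedule(config=schedule.config, events=tuple(events))


def events_to_table(schedule: Schedule) -> pd.DataFrame:
    """One row per event: (onset_ms, block, trial, position, label, stimulus_id)."""
    return pd.DataFrame(
        {
            "onset_ms": [e.onset for e in schedule.events],
            "block": [e.block for e in schedule.events],
            "trial": [e.trial for e in schedule.events],
            "position": [e.position for e in schedule.events],
            "label": [e.label for e in schedule.events],
            "stimulus_id": [e.stimulus_id for e in schedule.events],
        }
    )


def schedule_from_table(table: pd.DataFrame, config: ParadigmConfig) -> Schedule:
    """Rebuild a :class:`Schedule` from an event table (inverse of :func:`events_to_table`)."""
    events = tuple(
        StimulusEvent(
            onset=float(r.onset_ms),
            block=int(r.block),
            trial=int(r.trial),
            position=int(r.position),
            label=str(r.label),
            stimulus_id=str(r.stimulus_id),
        )
        for r in table.itertuples(index=False)
    )
    return Schedule(config=config, events=events)
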
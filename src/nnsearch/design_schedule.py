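"""Trial timing and run structure of an adaptive scanning session.

A session has six runs.  Run 1 presents every stimulus once in random
order; each later run re-presents the subset selected by the closed
loop, the run sizes following the shrinking schedule
200, 31, 25, 20, 16, 13.  Stimuli appear for 2 s separated by 2 s
blanks; every 4th stimulus is followed by an extra 4 s event that
alternates between a blank probe and the referent (the referent event
is the image itself in the perception condition and an imagery cue in
the imagery condition), again followed by a 2 s gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REFERENT_ID",
    "DEFAULT_SCHEDULE",
    "TimingConfig",
    "Event",
    "RunDesign",
    "SessionDesign",
    "build_run",
    "build_session",
    "events_to_onset_table",
    "onset_table_to_events",
]

#: Reserved stimulus id for referent / referent-cue events.
REFERENT_ID = "REF"

#: Non-referent stimuli per run, as optimised for the six-run session.
DEFAULT_SCHEDULE = (200, 31, 25, 20, 16, 13)


@dataclass(frozen=True)
class TimingConfig:
    """Event timing in seconds and scan parameters."""

    stimulus_duration: float = 2.0
    gap: float = 2.0
    referent_duration: float = 4.0
    blank_probe_duration: float = 4.0
    probe_every: int = 4
    first_probe_is_blank: bool = True
    inter_run_gap: float = 24.0
    washout: float = 8.0
    TR: float = 1.0

    def __post_init__(self) -> None:
        for name in ("stimulus_duration", "gap", "referent_duration",
                     "blank_probe_duration", "TR"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.probe_every < 1:
            raise ValueError("probe_every must be >= 1")


@dataclass(frozen=True)
class Event:
    kind: str  # "stimulus" | "referent" | "blank_probe"
    onset: float
    duration: float
    stimulus_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("stimulus", "referent", "blank_probe"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("event duration must be positive")
        if self.kind == "stimulus" and self.stimulus_id is None:
            raise ValueError("stimulus events need a stimulus id")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class RunDesign:
    run_index: int  # 1-based
    events: list
    n_scans: int
    TR: float

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        for a, b in zip(self.events, self.events[1:]):
            if b.onset < a.end:
                raise ValueError("events overlap")
        if self.events and self.events[-1].end > self.n_scans * self.TR:
            raise ValueError("last event ends after the final scan")

    @property
    def stimulus_ids(self) -> list:
        return [e.stimulus_id for e in self.events if e.kind == "stimulus"]

    def events_of_kind(self, kind: str) -> list:
        return [e for e in self.events if e.kind == kind]


def build_run(
    stimulus_ids,
    run_index: int,
    timing_cfg: TimingConfig | None = None,
    rng: np.random.Generator | None = None,
) -> RunDesign:
    """Lay out one run: shuffled stimuli with interleaved probe events.

    After every ``probe_every``-th stimulus an extra event is inserted,
    strictly alternating blank probe and referent (phase set by
    ``first_probe_is_blank``, resetting each run).
    """
    cfg = timing_cfg or TimingConfig()
    ids = list(stimulus_ids)
    if not ids:
        raise ValueError("stimulus_ids must be non-empty")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate stimulus ids in run")
    rng = rng or np.random.default_rng()
    order = [ids[i] for i in rng.permutation(len(ids))]

    events: list = []
    t = 0.0
    next_is_blank = cfg.first_probe_is_blank
    for i, sid in enumerate(order, start=1):
        events.append(Event("stimulus", t, cfg.stimulus_duration, sid))
        t += cfg.stimulus_duration + cfg.gap
        if i % cfg.probe_every == 0:
            if next_is_blank:
                events.append(Event("blank_probe", t, cfg.blank_probe_duration))
                t += cfg.blank_probe_duration + cfg.gap
            else:
                events.append(Event("referent", t, cfg.referent_duration, REFERENT_ID))
                t += cfg.referent_duration + cfg.gap
            next_is_blank = not next_is_blank

    last_end = events[-1].end
    n_scans = math.ceil((last_end + cfg.washout) / cfg.TR)
    return RunDesign(run_index=run_index, events=events, n_scans=n_scans, TR=cfg.TR)


@dataclass
class SessionDesign:
    """A (lazily completed) six-run session for one condition.

    Run 1 is built eagerly from the full stimulus set; later runs are
    appended by :meth:`add_run` once the adaptive loop has chosen their
    subsets.  Determinism: the per-run shuffles derive from ``seed`` and
    the run index only, not from when runs are added.
    """

    condition: str  # "perception" | "imagery"
    schedule: tuple
    timing: TimingConfig
    seed: int
    runs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.condition not in ("perception", "imagery"):
            raise ValueError(f"unknown condition {self.condition!r}")
        sizes = list(self.schedule)
        if any(b >= a for a, b in zip(sizes[1:], sizes[2:])):
            raise ValueError("schedule must be strictly decreasing after run 1")

    def _rng_for_run(self, run_index: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, run_index])

    @property
    def n_runs_planned(self) -> int:
        return len(self.schedule)

    @property
    def complete(self) -> bool:
        return len(self.runs) == len(self.schedule)

    def add_run(self, stimulus_ids) -> RunDesign:
        k = len(self.runs)  # 0-based index of the run being added
        if k >= len(self.schedule):
            raise ValueError("session already has all scheduled runs")
        expected = self.schedule[k]
        if len(list(stimulus_ids)) != expected:
            raise ValueError(
                f"run {k + 1} expects {expected} stimuli, got {len(list(stimulus_ids))}"
            )
        run = build_run(stimulus_ids, k + 1, self.timing, self._rng_for_run(k + 1))
        self.runs.append(run)
        return run


def build_session(
    schedule,
    condition: str,
    timing_cfg: TimingConfig | None = None,
    seed: int = 0,
    stimulus_ids=None,
) -> SessionDesign:
    """Create a session and build its first run from the full stimulus set."""
    cfg = timing_cfg or TimingConfig()
    schedule = tuple(schedule)
    ids = list(stimulus_ids) if stimulus_ids is not None else [
        f"stim{i:03d}" for i in range(schedule[0])
    ]
    if len(ids) != schedule[0]:
        raise ValueError(
            f"schedule[0]={schedule[0]} must equal the stimulus-set size {len(ids)}"
        )
    session = SessionDesign(condition=condition, schedule=schedule, timing=cfg, seed=seed)
    session.add_run(ids)
    return session


def events_to_onset_table(run: RunDesign) -> pd.DataFrame:
    """BIDS-style events table (onset, duration, trial_type, stimulus_id)."""
    if not run.events:
        raise ValueError("run has no events")
    rows = [
        {
            "onset": e.onset,
            "duration": e.duration,
            "trial_type": e.kind,
            "stimulus_id": e.stimulus_id if e.stimulus_id is not None else "n/a",
        }
        for e in run.events
    ]
    return pd.DataFrame(rows)


def onset_table_to_events(
    table: pd.DataFrame | str | Path, run_index: int, n_scans: int, TR: float
) -> RunDesign:
    """Inverse of :func:`events_to_onset_table` (lossless round-trip)."""
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table, sep="\t", keep_default_na=False)

    def _sid(value):
        if not isinstance(value, str):
            return None if pd.isna(value) else str(value)
        return None if value in ("n/a", "") else value

    events = [
        Event(
            kind=row.trial_type,
            onset=float(row.onset),
            duration=float(row.duration),
            stimulus_id=_sid(row.stimulus_id),
        )
        for row in table.itertuples()
    ]
    return RunDesign(run_index=run_index, events=events, n_scans=n_scans, TR=TR)
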
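"""Conditioning-protocol schedules.

A protocol is defined by its intertrial-interval (ITI) distribution, the
number of trials per session, the reward probability, and optional
distractor cues or uncued "background" rewards delivered between trials.
Every trial consists of a brief cue (0.25 s tone by default), a trace
period (1 s), outcome delivery, and a fixed consumption period (3 s), so
the trial block occupies ``cue_duration + trace_duration +
consumption_period`` seconds (4.25 s for the cue-reward groups).

An ITI draw precedes every trial, including the first of each session, so
a schedule of L trials contains L ITIs before trial L's cue.  Session
boundaries carry no modeled time gap: absolute event times double as
cumulative conditioning time, which is the clock used for total
time-to-learn analyses.

The nominal inter-reward interval (IRI) of a protocol is
``(mean_iti + trial_block) / reward_prob``: partial reinforcement
lengthens the IRI without changing the ITI or the inter-cue interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "DistractorSpec",
    "BackgroundRewardSpec",
    "ProtocolSpec",
    "Event",
    "EventSchedule",
    "ScheduleInfeasibleError",
    "build_schedule",
    "nominal_iri",
    "elapsed_time_before_trial",
    "PROTOCOLS",
]

EventType = Literal[
    "session_start", "session_end", "cs_plus", "cs_minus", "reward", "background_reward"
]


class ScheduleInfeasibleError(RuntimeError):
    """Raised when distractor/background events cannot be packed into a gap."""


class DistractorSpec(BaseModel):
    """Unrewarded distractor cue (CS-) delivered between trials.

    Onsets follow an exponential renewal process with the given mean,
    restarted at the beginning of each inter-trial gap.
    """

    mean_s: float = Field(gt=0)
    label: str = "cs_minus"


class BackgroundRewardSpec(BaseModel):
    """Uncued rewards of a distinct identity delivered between trials.

    ``events_per_interval`` deliveries are placed sequentially in each
    inter-trial gap; each spacing is drawn uniform on mean +/- jitter and
    measured from the previous reward delivery of any identity (the
    trial's own reward, or the preceding background delivery).
    """

    identity: str = "background"
    events_per_interval: int = Field(ge=1)
    mean_spacing_s: float = Field(gt=0)
    jitter: float = Field(default=0.2, ge=0, lt=1)


class ProtocolSpec(BaseModel):
    """Complete specification of one conditioning protocol group."""

    name: str
    mean_iti: float = Field(gt=0, description="mean intertrial interval, seconds")
    iti_jitter: float = Field(default=0.2, ge=0, lt=1, description="uniform +/- fraction of mean")
    trials_per_session: int = Field(gt=0)
    n_sessions: int = Field(default=1, gt=0)
    reward_prob: float = Field(default=1.0, ge=0, le=1)
    cue_duration: float = Field(default=0.25, gt=0)
    trace_duration: float = Field(default=1.0, ge=0)
    consumption_period: float = Field(default=3.0, ge=0)
    pre_session_delay: float = Field(default=0.0, ge=0)
    reward_identity: str = "sucrose"
    distractor: Optional[DistractorSpec] = None
    background_reward: Optional[BackgroundRewardSpec] = None

    @model_validator(mode="after")
    def _check(self) -> "ProtocolSpec":
        if self.mean_iti * (1 - self.iti_jitter) <= 0:
            raise ValueError("ITI jitter would allow nonpositive intervals")
        return self

    @property
    def cue_to_reward(self) -> float:
        """Delay from cue onset to outcome delivery (the trial period)."""
        return self.cue_duration + self.trace_duration

    @property
    def trial_block(self) -> float:
        """Duration of the full trial block: cue + trace + consumption."""
        return self.cue_to_reward + self.consumption_period

    @property
    def n_trials(self) -> int:
        return self.trials_per_session * self.n_sessions


@dataclass(frozen=True)
class Event:
    time: float
    session_index: int
    event_type: str
    identity: str = ""
    trial_index: Optional[int] = None


@dataclass
class EventSchedule:
    """Ordered timeline of conditioning events.

    Times are seconds from the start of the first session; trial indices
    are 1-based and continue across sessions.  Because sessions are
    concatenated without a modeled gap, event times equal cumulative
    conditioning time.
    """

    events: list[Event]
    spec: Optional[ProtocolSpec] = None
    _trials: Optional[pd.DataFrame] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(b < a - 1e-9 for a, b in zip(times, times[1:])):
            raise ValueError("event times must be nondecreasing")

    @property
    def n_trials(self) -> int:
        return sum(1 for e in self.events if e.event_type == "cs_plus")

    def trial_table(self) -> pd.DataFrame:
        """Per-trial summary: cue time, reward flag/time, session index."""
        if self._trials is not None:
            return self._trials
        cues = {e.trial_index: e for e in self.events if e.event_type == "cs_plus"}
        rewards = {e.trial_index: e for e in self.events if e.event_type == "reward"}
        rows = []
        for idx in sorted(cues):
            cue = cues[idx]
            rew = rewards.get(idx)
            rows.append(
                {
                    "trial_index": idx,
                    "session_index": cue.session_index,
                    "cue_time": cue.time,
                    "rewarded": rew is not None,
                    "reward_time": rew.time if rew is not None else np.nan,
                }
            )
        self._trials = pd.DataFrame(rows)
        return self._trials

    def cue_times(self) -> np.ndarray:
        return np.array([e.time for e in self.events if e.event_type == "cs_plus"])

    def reward_times(self, identity: Optional[str] = None) -> np.ndarray:
        out = [
            e.time
            for e in self.events
            if e.event_type in ("reward", "background_reward")
            and (identity is None or e.identity == identity)
        ]
        return np.array(out)

    def session_bounds(self) -> list[tuple[float, float]]:
        starts = [e.time for e in self.events if e.event_type == "session_start"]
        ends = [e.time for e in self.events if e.event_type == "session_end"]
        return list(zip(starts, ends))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "session_index": [e.session_index for e in self.events],
                "trial_index": [e.trial_index for e in self.events],
                "time_s": [e.time for e in self.events],
                "event_type": [e.event_type for e in self.events],
                "identity": [e.identity for e in self.events],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventSchedule":
        events = []
        for row in frame.itertuples(index=False):
            tidx = row.trial_index
            if pd.isna(tidx):
                tidx = None
            else:
                tidx = int(tidx)
            events.append(
                Event(
                    time=float(row.time_s),
                    session_index=int(row.session_index),
                    event_type=str(row.event_type),
                    identity="" if pd.isna(row.identity) else str(row.identity),
                    trial_index=tidx,
                )
            )
        return cls(events=events)


def nominal_iri(
    mean_iti: float,
    reward_prob: float = 1.0,
    trial_block: float = 4.25,
) -> float:
    """Nominal inter-reward interval: ``(mean_iti + trial_block) / reward_prob``.

    At 100% reinforcement this equals the inter-cue interval; partial
    reinforcement divides by the reward probability (e.g. a 60-s ITI at
    50% reward gives an IRI of 128.5 s).
    """
    if mean_iti <= 0:
        raise ValueError("mean_iti must be positive")
    if not 0 < reward_prob <= 1:
        raise ValueError("IRI undefined for reward_prob outside (0, 1]")
    return (mean_iti + trial_block) / reward_prob


def build_schedule(spec: ProtocolSpec, seed: int) -> EventSchedule:
    """Draw one realization of a protocol's event timeline.

    ITIs are i.i.d. uniform on ``mean * (1 +/- jitter)``; one ITI precedes
    every trial including the first of each session.  Rewards are
    delivered per ``Bernoulli(reward_prob)`` at cue onset + trial period.
    Distractor cues follow an exponential renewal process within each
    inter-trial gap; background rewards are placed by sequential uniform
    spacing from the previous delivery.  All between-trial events fall
    strictly outside trial blocks.

    Reproducible: the same spec and seed give a byte-identical schedule.
    """
    rng = np.random.default_rng(seed)
    events: list[Event] = []
    t = 0.0
    trial_index = 0
    lo = spec.mean_iti * (1 - spec.iti_jitter)
    hi = spec.mean_iti * (1 + spec.iti_jitter)

    for sess in range(1, spec.n_sessions + 1):
        events.append(Event(t, sess, "session_start"))
        t += spec.pre_session_delay
        prev_block_end = t
        prev_reward_time = None  # last delivery of any reward identity
        for _ in range(spec.trials_per_session):
            trial_index += 1
            iti = rng.uniform(lo, hi) if hi > lo else spec.mean_iti
            cue_time = t + iti
            # between-trial events live in [prev_block_end, cue_time)
            _place_gap_events(
                events, spec, rng, sess, prev_block_end, cue_time, prev_reward_time
            )
            events.append(Event(cue_time, sess, "cs_plus", "cs_plus", trial_index))
            rewarded = rng.random() < spec.reward_prob
            reward_time = cue_time + spec.cue_to_reward
            if rewarded:
                events.append(
                    Event(reward_time, sess, "reward", spec.reward_identity, trial_index)
                )
                prev_reward_time = reward_time
            # consumption period is scheduled on every trial (rewarded or
            # omitted) so the ITI and inter-cue interval are unchanged
            # under partial reinforcement
            t = cue_time + spec.trial_block
            prev_block_end = t
        events.append(Event(t, sess, "session_end"))

    events.sort(key=lambda e: (e.time, _EVENT_ORDER.get(e.event_type, 5)))
    return EventSchedule(events=events, spec=spec)


_EVENT_ORDER = {
    "session_start": 0,
    "cs_minus": 1,
    "background_reward": 2,
    "cs_plus": 3,
    "reward": 4,
    "session_end": 6,
}


def _place_gap_events(
    events: list[Event],
    spec: ProtocolSpec,
    rng: np.random.Generator,
    sess: int,
    gap_start: float,
    gap_end: float,
    prev_reward_time: Optional[float],
) -> None:
    if spec.distractor is not None:
        s = gap_start
        while True:
            s += rng.exponential(spec.distractor.mean_s)
            if s >= gap_end:
                break
            events.append(Event(s, sess, "cs_minus", spec.distractor.label))
    bg = spec.background_reward
    if bg is not None:
        anchor = prev_reward_time if prev_reward_time is not None else gap_start
        lo = bg.mean_spacing_s * (1 - bg.jitter)
        hi = bg.mean_spacing_s * (1 + bg.jitter)
        for _ in range(bg.events_per_interval):
            placed = False
            for _attempt in range(100):
                s = anchor + rng.uniform(lo, hi)
                if gap_start <= s < gap_end:
                    events.append(Event(s, sess, "background_reward", bg.identity))
                    anchor = s
                    placed = True
                    break
            if not placed:
                raise ScheduleInfeasibleError(
                    f"cannot place background reward in gap "
                    f"[{gap_start:.1f}, {gap_end:.1f}) s (spacing {bg.mean_spacing_s} s)"
                )


def elapsed_time_before_trial(schedule: EventSchedule, trial_index: int) -> float:
    """Cumulative conditioning time up to the cue onset of the given trial.

    Between-session time is excluded (sessions are concatenated), so this
    is simply the cue onset time on the schedule clock.  For a
    ``trial_index`` one past the final trial, returns the end of the last
    trial block (the final ITI is never drawn).
    """
    if trial_index < 1:
        raise IndexError("trial indices are 1-based")
    table = schedule.trial_table()
    n = len(table)
    if trial_index <= n:
        return float(table.loc[table.trial_index == trial_index, "cue_time"].iloc[0])
    if trial_index == n + 1:
        ends = [e.time for e in schedule.events if e.event_type == "session_end"]
        return float(ends[-1])
    raise IndexError(f"trial {trial_index} out of range (schedule has {n} trials)")


def _p(name: str, **kw) -> ProtocolSpec:
    base = dict(iti_jitter=0.2, n_sessions=8)
    base.update(kw)
    return ProtocolSpec(name=name, **base)


#: The thirteen experimental protocol groups.  Cue-reward groups share a
#: 0.25-s cue, 1-s trace, and 3-s consumption period; the two cue-shock
#: groups use a 15-s cue, 2-s trace, 1-s shock, and a 300-s pre-session
#: baseline, with ISI = mean ITI + 18 s.
PROTOCOLS: dict[str, ProtocolSpec] = {
    "iti30": _p("iti30", mean_iti=30, trials_per_session=100),
    "iti60": _p("iti60", mean_iti=60, trials_per_session=50),
    "iti300": _p("iti300", mean_iti=300, trials_per_session=11),
    "iti600": _p("iti600", mean_iti=600, trials_per_session=6),
    "iti3600": _p("iti3600", mean_iti=3600, iti_jitter=0.0, trials_per_session=2),
    "iti60_few": _p("iti60_few", mean_iti=60, trials_per_session=6),
    "iti60_few_context": _p("iti60_few_context", mean_iti=60, trials_per_session=6),
    "iti60_csminus": _p(
        "iti60_csminus",
        mean_iti=600,
        trials_per_session=6,
        distractor=DistractorSpec(mean_s=60.0),
    ),
    "iti600_milk": _p(
        "iti600_milk",
        mean_iti=600,
        trials_per_session=6,
        background_reward=BackgroundRewardSpec(
            identity="chocolate_milk", events_per_interval=2, mean_spacing_s=180.0
        ),
    ),
    "iti60_p50": _p("iti60_p50", mean_iti=60, trials_per_session=50, n_sessions=12, reward_prob=0.5),
    "iti60_p10": _p("iti60_p10", mean_iti=60, trials_per_session=50, n_sessions=32, reward_prob=0.1),
    "isi45": _p(
        "isi45",
        mean_iti=27.33,
        trials_per_session=13,
        n_sessions=3,
        cue_duration=15.0,
        trace_duration=2.0,
        consumption_period=1.0,
        pre_session_delay=300.0,
        reward_identity="shock",
    ),
    "isi135": _p(
        "isi135",
        mean_iti=118.0,
        trials_per_session=5,
        n_sessions=3,
        cue_duration=15.0,
        trace_duration=2.0,
        consumption_period=1.0,
        pre_session_delay=300.0,
        reward_identity="shock",
    ),
}
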
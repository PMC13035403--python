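"""Behavioral learning analysis: cue-evoked licking and learned-trial detection.

The behavioral measure of learning is anticipatory licking: the number of
lick onsets in the 1.25-s window from cue onset to reward delivery minus
the count in the 1.25-s baseline window before cue onset ("cue-evoked
licks", or "delta lick rate" when divided by the window length).

The learned trial is detected from the cumulative sum of the per-trial
cue-evoked licks.  A diagonal is drawn from the origin to the end of the
cumsum curve and the learned trial is the first trial whose vertical
distance to the diagonal reaches 75% of the maximum distance.  If the
diagonal lies below the curve at that trial -- licking was decreasing
there rather than increasing -- the diagonal's endpoint is re-anchored to
the cumsum value at that trial and the procedure repeats until it lands
on an increasing segment.  The distance at the learned trial, normalized
so the top of the diagonal equals 1, measures the abruptness of learning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from irilearn.schedule import EventSchedule, elapsed_time_before_trial

__all__ = [
    "LickTrain",
    "TrialLickMetrics",
    "LearnedTrialResult",
    "cue_evoked_licks",
    "cumsum_change_point",
    "abruptness",
    "classify_learner",
    "align_trial_one",
    "rewards_before_trial",
    "total_time_to_learn",
    "iti_lick_rate",
    "sigmoid_fit",
    "SigmoidFit",
]


@dataclass
class LickTrain:
    """Lick-contact onset/offset times (seconds, session clock)."""

    onsets: np.ndarray
    offsets: np.ndarray
    session_index: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.onsets.shape != self.offsets.shape:
            raise ValueError("onsets and offsets must have equal length")

    def to_frame(self) -> pd.DataFrame:
        sess = (
            self.session_index
            if self.session_index is not None
            else np.ones(len(self.onsets), dtype=int)
        )
        return pd.DataFrame(
            {"session_index": sess, "onset_s": self.onsets, "offset_s": self.offsets}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LickTrain":
        return cls(
            onsets=frame["onset_s"].to_numpy(float),
            offsets=frame["offset_s"].to_numpy(float),
            session_index=frame["session_index"].to_numpy(int),
        )


def cue_evoked_licks(
    licks: LickTrain, schedule: EventSchedule, window: float = 1.25
) -> pd.DataFrame:
    """Per-trial lick counts in the pre-cue and cue windows.

    Counts lick onsets in ``[t - window, t)`` and ``[t, t + window)`` for
    each cue onset ``t``.  Returns a frame with columns ``trial_index``,
    ``licks_pre``, ``licks_cue``, ``delta_licks`` and ``delta_rate`` (Hz).
    Trials whose baseline window would precede the session start are
    flagged with ``baseline_truncated``.
    """
    table = schedule.trial_table()
    onsets = np.sort(licks.onsets)
    starts = {e.session_index: e.time for e in schedule.events if e.event_type == "session_start"}
    rows = []
    for row in table.itertuples(index=False):
        t = row.cue_time
        pre = int(np.searchsorted(onsets, t) - np.searchsorted(onsets, t - window))
        cue = int(np.searchsorted(onsets, t + window) - np.searchsorted(onsets, t))
        truncated = t - window < starts.get(row.session_index, 0.0)
        rows.append(
            {
                "trial_index": row.trial_index,
                "session_index": row.session_index,
                "licks_pre": pre,
                "licks_cue": cue,
                "delta_licks": cue - pre,
                "delta_rate": (cue - pre) / window,
                "baseline_truncated": truncated,
            }
        )
    return pd.DataFrame(rows)


# alias kept for symmetry with the domain-type name in docs
TrialLickMetrics = pd.DataFrame


@dataclass
class LearnedTrialResult:
    """Outcome of the cumsum change-point detection.

    ``learned_trial`` is 1-based, or None when the series is degenerate
    (no inflection: constant, linear, or the re-anchoring loop failed to
    converge).  ``max_distance`` and ``threshold_distance`` refer to the
    final diagonal; ``anchor`` is the (index, cumsum value) endpoint of
    that diagonal.
    """

    learned_trial: Optional[int]
    max_distance: float = np.nan
    threshold_distance: float = np.nan
    n_reanchor_iterations: int = 0
    direction: str = "positive"
    anchor: tuple[int, float] = (0, np.nan)
    degenerate: bool = False
    abruptness: Optional[float] = None


def cumsum_change_point(
    series: Sequence[float],
    direction: Literal["positive", "negative"] = "positive",
    end_anchor: Optional[int] = None,
    threshold_frac: float = 0.75,
) -> LearnedTrialResult:
    """Detect the learned trial from a per-trial response series.

    Parameters
    ----------
    series
        Per-trial responses (cue-evoked licks, normalized dopamine, ...).
        Length >= 3.
    direction
        ``"negative"`` negates the series first, to detect a
        negative-going inflection (omission dips, cue-shock dopamine).
    end_anchor
        Optional index (1-based trial) at which to anchor the end of the
        initial diagonal instead of the final trial; used for the
        dopamine learned trial, whose diagonal ends at 1.5x the
        behavioral learned trial.
    threshold_frac
        Fraction of the maximum curve-to-diagonal distance defining the
        learned trial (0.75 by default).

    Notes
    -----
    The cumsum starts at S_0 = 0 so the trial-1 distance is well defined.
    The distance is vertical (same-abscissa difference), as the two axes
    carry different units.  If the signed distance at the detected trial
    is negative (diagonal below the curve: responding decreasing), the
    diagonal endpoint is re-anchored to the cumsum value at that trial
    and the rule re-applied, at most ``len(series)`` times.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("series must be 1-D with length >= 3")
    if direction == "negative":
        x = -x
    elif direction != "positive":
        raise ValueError("direction must be 'positive' or 'negative'")
    n = len(x)
    S = np.concatenate([[0.0], np.cumsum(x)])

    anchor = n if end_anchor is None else int(min(max(end_anchor, 1), n))
    n_iter = 0
    while True:
        first, d_first, dmax = _detect_once_frac(S, anchor, threshold_frac)
        if first is None:
            return LearnedTrialResult(
                None, direction=direction, degenerate=True,
                n_reanchor_iterations=n_iter, anchor=(anchor, float(S[anchor])),
            )
        if d_first >= 0:
            res = LearnedTrialResult(
                learned_trial=first,
                max_distance=dmax,
                threshold_distance=threshold_frac * dmax,
                n_reanchor_iterations=n_iter,
                direction=direction,
                anchor=(anchor, float(S[anchor])),
            )
            res.abruptness = abruptness_from(S, res)
            return res
        n_iter += 1
        if n_iter > n or first == anchor:
            return LearnedTrialResult(
                None, direction=direction, degenerate=True,
                n_reanchor_iterations=n_iter, anchor=(anchor, float(S[anchor])),
            )
        anchor = first


def _detect_once_frac(
    S: np.ndarray, n_anchor: int, frac: float
) -> tuple[Optional[int], float, float]:
    if n_anchor < 1:
        return None, 0.0, 0.0
    idx = np.arange(n_anchor + 1)
    line = S[n_anchor] * idx / n_anchor
    d = line - S[: n_anchor + 1]
    absd = np.abs(d)
    dmax = float(absd.max())
    if dmax <= 1e-12:
        return None, 0.0, 0.0
    hits = np.nonzero(absd >= frac * dmax - 1e-12)[0]
    first = int(hits[0])
    return first, float(d[first]), dmax


def abruptness_from(S: np.ndarray, result: LearnedTrialResult) -> Optional[float]:
    """Distance at the learned trial in diagonal-top units (top = 1)."""
    if result.learned_trial is None:
        return None
    n_anchor, s_anchor = result.anchor
    if abs(s_anchor) <= 1e-12:
        return None
    line = s_anchor * result.learned_trial / n_anchor
    return float((line - S[result.learned_trial]) / s_anchor)


def abruptness(series: Sequence[float], result: LearnedTrialResult) -> Optional[float]:
    """Recompute abruptness for a detection result on its source series."""
    if result.learned_trial is None:
        return None
    x = np.asarray(series, dtype=float)
    if result.direction == "negative":
        x = -x
    S = np.concatenate([[0.0], np.cumsum(x)])
    return abruptness_from(S, result)


def classify_learner(per_session_delta_rates: Sequence[float], min_rate: float = 0.5) -> bool:
    """Learner iff >= 2 sessions show a session-mean delta lick rate above 0.5 Hz."""
    rates = np.asarray(per_session_delta_rates, dtype=float)
    if len(rates) < 2:
        raise ValueError("need at least two sessions to classify")
    return int((rates > min_rate).sum()) >= 2


def align_trial_one(
    licks: LickTrain,
    schedule: EventSchedule,
    mode: Literal["first_consumption", "raw"] = "first_consumption",
    consumption_window: float = 5.0,
) -> int:
    """Index of the trial to treat as "trial 1".

    ``first_consumption`` returns the first rewarded trial with a lick
    onset within 5 s of reward delivery (mice must actually consume the
    reward for conditioning to begin); ``raw`` always returns 1, the
    convention for partial-reinforcement protocols where omission trials
    must be counted from the first presentation.
    """
    if mode == "raw":
        return 1
    table = schedule.trial_table()
    onsets = np.sort(licks.onsets)
    for row in table.itertuples(index=False):
        if not row.rewarded:
            continue
        k = np.searchsorted(onsets, row.reward_time)
        if k < len(onsets) and onsets[k] <= row.reward_time + consumption_window:
            return int(row.trial_index)
    raise ValueError("alignment failure: no reward was ever consumed within 5 s")


def rewards_before_trial(schedule: EventSchedule, trial_index: int) -> int:
    """Number of trial rewards delivered on trials before ``trial_index``."""
    table = schedule.trial_table()
    return int(table.loc[table.trial_index < trial_index, "rewarded"].sum())


def total_time_to_learn(schedule: EventSchedule, learned_trial: int) -> float:
    """Cumulative conditioning time through the learned trial's block.

    Sums all ITI and trial periods from conditioning start up to, but not
    including, the trial period following the learned trial: with the
    leading-ITI convention this is L trial blocks plus L + 1 ITIs, i.e.
    the elapsed time before trial L + 1.
    """
    if learned_trial < 1:
        raise ValueError("learned trial must be >= 1")
    return elapsed_time_before_trial(schedule, learned_trial + 1)


def _consumption_bout_end(
    onsets: np.ndarray, offsets: np.ndarray, reward_time: float, max_gap: float = 0.5
) -> Optional[float]:
    """End time of the consumption bout starting at the first lick after reward.

    The bout runs from the first lick onset following reward delivery
    through all licks whose off-to-on gap from the previous lick is
    <= ``max_gap`` (500 ms).  Returns the offset of the last bout lick,
    or None if no lick follows the reward.
    """
    k = int(np.searchsorted(onsets, reward_time))
    if k >= len(onsets):
        return None
    end = offsets[k]
    for j in range(k + 1, len(onsets)):
        if onsets[j] - end <= max_gap:
            end = offsets[j]
        else:
            break
    return float(end)


def iti_lick_rate(licks: LickTrain, schedule: EventSchedule) -> pd.DataFrame:
    """Lick rate in each inter-trial window, excluding consumption bouts.

    Each window begins at the session start (for the first trial of a
    session) or at the end of the previous trial's consumption bout, and
    ends at the next cue onset.  Returns per-window rates plus the
    ``median`` convenience attribute in ``frame.attrs``.
    """
    table = schedule.trial_table()
    order = np.argsort(licks.onsets)
    onsets = licks.onsets[order]
    offsets = licks.offsets[order]
    starts = {e.session_index: e.time for e in schedule.events if e.event_type == "session_start"}
    rows = []
    prev = {"session": None, "bout_end": None}
    for row in table.itertuples(index=False):
        if prev["session"] != row.session_index:
            win_start = starts[row.session_index]
        else:
            win_start = prev["bout_end"]
        win_end = row.cue_time
        if win_end > win_start:
            n = int(np.searchsorted(onsets, win_end) - np.searchsorted(onsets, win_start))
            rows.append(
                {
                    "trial_index": row.trial_index,
                    "window_start": win_start,
                    "window_end": win_end,
                    "n_licks": n,
                    "rate_hz": n / (win_end - win_start),
                }
            )
        if row.rewarded:
            bout_end = _consumption_bout_end(onsets, offsets, row.reward_time)
            if bout_end is None:
                bout_end = row.cue_time + 4.25
        else:
            bout_end = row.cue_time + (
                schedule.spec.trial_block if schedule.spec else 4.25
            )
        prev = {"session": row.session_index, "bout_end": bout_end}
    frame = pd.DataFrame(rows)
    frame.attrs["median_rate_hz"] = float(frame["rate_hz"].median()) if len(frame) else np.nan
    return frame


@dataclass
class SigmoidFit:
    """4-parameter logistic fit y = L / (1 + exp(-k (x - x0))) + b."""

    L: float
    k: float
    x0: float
    b: float
    converged: bool

    @property
    def half_rise(self) -> float:
        return self.x0

    @property
    def rise95(self) -> float:
        """Trial at which the sigmoid reaches 95% of its asymptote."""
        return self.x0 + np.log(19.0) / self.k


def sigmoid_fit(series: Sequence[float]) -> SigmoidFit:
    """Least-squares 4-parameter logistic fit to a per-trial response series."""
    y = np.asarray(series, dtype=float)
    if len(y) < 5:
        raise ValueError("need at least 5 points for a sigmoid fit")
    x = np.arange(1, len(y) + 1, dtype=float)
    span = float(y.max() - y.min())
    if span <= 1e-12:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, converged=False)

    def f(x, L, k, x0, b):
        return L / (1.0 + np.exp(-k * (x - x0))) + b

    p0 = [span, 0.5, float(x[np.argmin(np.abs(y - (y.min() + span / 2)))]), float(y.min())]
    try:
        popt, _ = curve_fit(f, x, y, p0=p0, maxfev=20000)
    except RuntimeError:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    return SigmoidFit(*[float(v) for v in popt], converged=True)
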
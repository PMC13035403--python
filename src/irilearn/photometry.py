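"""Two-channel photometry analysis: dF/F and dopamine response quantification.

dF/F is computed session-wide from the isosbestic control: the 405-nm
signal is scaled and aligned to the 470-nm signal by ordinary least
squares, and dF/F = 100 * (f470 - fitted405) / fitted405.  Cue responses
are baseline-subtracted AUCs over 0.5-s windows; reward responses anchor
to the first lick after delivery (or delivery itself when a contact
spans it); omission responses use 2-s windows to capture the slower,
broader dopamine dip.  Responses are normalized per animal to the mean
of the three largest reward responses, with a separate 2-s-window
normalizer for omissions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from irilearn.behavior import LickTrain, LearnedTrialResult, cumsum_change_point
from irilearn.schedule import EventSchedule
from irilearn.synthetic import PhotometryTrace

__all__ = [
    "DffTrace",
    "fit_dff",
    "cue_response",
    "reward_response",
    "omission_response",
    "peak_response",
    "trial_responses",
    "normalize_responses",
    "dopamine_learned_trial",
    "omission_dip_trial",
]


@dataclass
class DffTrace:
    """dF/F (percent) with the 405->470 least-squares map that produced it."""

    time_s: np.ndarray
    dff_percent: np.ndarray
    fit_slope: float
    fit_intercept: float
    sampling_rate: float
    session_index: Optional[np.ndarray] = None


def fit_dff(trace: PhotometryTrace) -> DffTrace:
    """Session-wide dF/F from the isosbestic fit.

    Ordinary least squares of f470 on f405 gives the fitted 405 signal;
    dF/F = 100 * (f470 - fitted) / fitted.  When the trace carries
    multiple sessions the fit is computed per session and the segments
    concatenated.
    """
    if trace.session_index is not None and len(np.unique(trace.session_index)) > 1:
        parts = []
        slopes, intercepts = [], []
        for sess in np.unique(trace.session_index):
            m = trace.session_index == sess
            sub = PhotometryTrace(
                trace.time_s[m], trace.f470[m], trace.f405[m], trace.sampling_rate
            )
            d = fit_dff(sub)
            parts.append(d.dff_percent)
            slopes.append(d.fit_slope)
            intercepts.append(d.fit_intercept)
        return DffTrace(
            time_s=trace.time_s,
            dff_percent=np.concatenate(parts),
            fit_slope=float(np.mean(slopes)),
            fit_intercept=float(np.mean(intercepts)),
            sampling_rate=trace.sampling_rate,
            session_index=trace.session_index,
        )

    x = np.asarray(trace.f405, dtype=float)
    y = np.asarray(trace.f470, dtype=float)
    if x.shape != y.shape:
        raise ValueError("channel lengths differ")
    if np.ptp(x) <= 1e-12:
        if np.ptp(y) <= 1e-12:
            # both channels constant (noiseless null signal): the
            # intercept-only limit of the fit, dF/F identically zero
            slope, intercept = 0.0, float(y.mean())
        else:
            raise ValueError("constant 405-nm channel: isosbestic fit is singular")
    else:
        slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    dff = 100.0 * (y - fitted) / fitted
    return DffTrace(
        time_s=np.asarray(trace.time_s, dtype=float),
        dff_percent=dff,
        fit_slope=float(slope),
        fit_intercept=float(intercept),
        sampling_rate=trace.sampling_rate,
        session_index=trace.session_index,
    )


def _window_auc(dff: DffTrace, start: float, width: float) -> float:
    """Trapezoidal AUC of dF/F over the half-open window [start, start+width)."""
    t = dff.time_s
    i0 = int(np.searchsorted(t, start - 1e-9))
    i1 = int(np.searchsorted(t, start + width - 1e-9))
    if i1 - i0 < 2:
        raise ValueError("window contains fewer than 2 samples")
    return float(np.trapezoid(dff.dff_percent[i0:i1], dx=1.0 / dff.sampling_rate))


def cue_response(dff: DffTrace, cue_onset: float, window: float = 0.5) -> float:
    """Cue-evoked AUC: 0.5 s after cue onset minus the 0.5 s before it."""
    return _window_auc(dff, cue_onset, window) - _window_auc(
        dff, cue_onset - window, window
    )


def _reward_anchor(
    licks: Optional[LickTrain], reward_time: float, horizon: float = 5.0
) -> tuple[float, bool]:
    """First lick onset after delivery; delivery time if a contact spans it.

    Falls back to the delivery time (flagged) when no lick occurs within
    the consumption horizon.
    """
    if licks is None or len(licks.onsets) == 0:
        return reward_time, True
    spanning = (licks.onsets <= reward_time) & (licks.offsets >= reward_time)
    if spanning.any():
        return reward_time, False
    after = licks.onsets[licks.onsets > reward_time]
    if len(after) == 0 or after[0] > reward_time + horizon:
        return reward_time, True
    return float(after[0]), False


def reward_response(
    dff: DffTrace,
    reward_time: float,
    licks: Optional[LickTrain],
    cue_onset: Optional[float] = None,
    window: float = 0.5,
) -> float:
    """Reward-evoked AUC anchored to the first post-delivery lick.

    The 0.5-s response window starts at the first detected lick onset
    after reward delivery, or at delivery itself when a lick contact
    spans the delivery time.  Baseline is the trial's 0.5-s pre-cue
    window (delivery - 1.25 s when no cue onset is given).
    """
    anchor, _flagged = _reward_anchor(licks, reward_time)
    if cue_onset is None:
        cue_onset = reward_time - 1.25
    return _window_auc(dff, anchor, window) - _window_auc(dff, cue_onset - window, window)


def omission_response(dff: DffTrace, cue_onset: float, window: float = 2.0) -> float:
    """Omission AUC: 2-s window starting at the (withheld) reward time,
    1.25 s after cue onset, minus the 2-s pre-cue baseline window."""
    return _window_auc(dff, cue_onset + 1.25, window) - _window_auc(
        dff, cue_onset - window, window
    )


def peak_response(
    dff: DffTrace, start: float, window: float, baseline_start: float, baseline_width: float
) -> float:
    """Peak response: max dF/F in the window minus the baseline-window mean."""
    t = dff.time_s
    i0, i1 = np.searchsorted(t, [start - 1e-9, start + window - 1e-9])
    b0, b1 = np.searchsorted(
        t, [baseline_start - 1e-9, baseline_start + baseline_width - 1e-9]
    )
    if i1 - i0 < 1 or b1 - b0 < 1:
        raise ValueError("empty response or baseline window")
    return float(dff.dff_percent[i0:i1].max() - dff.dff_percent[b0:b1].mean())


def trial_responses(
    dff: DffTrace, schedule: EventSchedule, licks: Optional[LickTrain] = None
) -> pd.DataFrame:
    """Per-trial cue/reward/omission responses (AUC and peak variants)."""
    rows = []
    for row in schedule.trial_table().itertuples(index=False):
        cue = cue_response(dff, row.cue_time)
        cue_pk = peak_response(
            dff, row.cue_time, 0.5, row.cue_time - 0.5, 0.5
        )
        rew = om = rew_pk = rew_2s = np.nan
        if row.rewarded:
            rew = reward_response(dff, row.reward_time, licks, cue_onset=row.cue_time)
            anchor, _ = _reward_anchor(licks, row.reward_time)
            rew_pk = peak_response(dff, anchor, 0.5, row.cue_time - 0.5, 0.5)
            # 2-s-window reward response used as the omission normalizer
            rew_2s = _window_auc(dff, anchor, 2.0) - _window_auc(
                dff, row.cue_time - 2.0, 2.0
            )
        else:
            om = omission_response(dff, row.cue_time)
        rows.append(
            {
                "trial_index": row.trial_index,
                "rewarded": row.rewarded,
                "cue_auc": cue,
                "cue_peak": cue_pk,
                "reward_auc": rew,
                "reward_peak": rew_pk,
                "reward_auc_2s": rew_2s,
                "omission_auc": om,
            }
        )
    return pd.DataFrame(rows)


def normalize_responses(responses: pd.DataFrame) -> pd.DataFrame:
    """Normalize responses to the mean of the animal's three largest
    reward responses.

    Cue and reward AUCs (and peaks) are divided by the top-3 mean of the
    0.5-s-window reward responses; omission AUCs by the top-3 mean of the
    2-s-window reward responses, matching the dip measurement window.
    Requires at least 3 rewarded trials.  Adds ``*_norm`` columns and
    records the normalizers in ``frame.attrs``.
    """
    out = responses.copy()
    rew = out["reward_auc"].dropna().to_numpy()
    if len(rew) < 3:
        raise ValueError("need at least 3 rewarded trials to normalize")
    norm_05 = float(np.sort(rew)[-3:].mean())
    rew2 = out["reward_auc_2s"].dropna().to_numpy()
    norm_2s = float(np.sort(rew2)[-3:].mean()) if len(rew2) >= 3 else np.nan
    if norm_05 <= 0:
        out.attrs["normalizer_flagged"] = True
    out["cue_auc_norm"] = out["cue_auc"] / norm_05
    out["reward_auc_norm"] = out["reward_auc"] / norm_05
    pk = out["reward_peak"].dropna().to_numpy()
    norm_pk = float(np.sort(pk)[-3:].mean()) if len(pk) >= 3 else np.nan
    out["cue_peak_norm"] = out["cue_peak"] / norm_pk
    out["reward_peak_norm"] = out["reward_peak"] / norm_pk
    out["omission_auc_norm"] = out["omission_auc"] / norm_2s
    out.attrs["normalizer_05s"] = norm_05
    out.attrs["normalizer_2s"] = norm_2s
    out.attrs["normalizer_peak"] = norm_pk
    return out


def dopamine_learned_trial(
    norm_cue: Sequence[float], behavior_learned_trial: int
) -> LearnedTrialResult:
    """Learned trial of the normalized cue dopamine response.

    Runs the cumsum change-point detector with the initial diagonal
    anchored at 1.5x the behavioral learned trial (clamped to the series
    length), compensating for cue responses that decrease with extended
    training.
    """
    n = len(norm_cue)
    anchor = int(np.ceil(1.5 * behavior_learned_trial))
    anchor = min(anchor, n)
    return cumsum_change_point(norm_cue, end_anchor=anchor)


def omission_dip_trial(omission_responses: Sequence[float]) -> LearnedTrialResult:
    """Omission trial at which the dopamine dip emerges.

    The change-point detector is run with negative direction on the
    omission-trial-indexed response series to find the negative-going
    inflection.
    """
    return cumsum_change_point(omission_responses, direction="negative")
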
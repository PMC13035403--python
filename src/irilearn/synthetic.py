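"""Synthetic lick trains and two-channel photometry with known ground truth.

These generators emulate the structure of the head-fixed conditioning
recordings well enough to exercise every analysis stage: Poisson baseline
licking, post-reward consumption bouts, anticipatory licking emerging at
a planted change-point trial, and photometry built from kernel-convolved
cue/reward transients on a 470-nm channel with a linearly related 405-nm
isosbestic channel.  Every generator returns its ground truth (planted
change points, per-trial expected responses) so detector accuracy can be
scored without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from irilearn.behavior import LickTrain
from irilearn.schedule import EventSchedule

__all__ = [
    "BehaviorGenParams",
    "PhotometryGenParams",
    "PhotometryTrace",
    "gen_licks",
    "gen_photometry",
    "double_exp_kernel",
]


@dataclass
class BehaviorGenParams:
    """Parameters of the synthetic licking model.

    Baseline licking is homogeneous Poisson at ``baseline_lick_rate``.
    Inside each trial's cue-to-reward window the rate steps from baseline
    to ``anticipatory_rate`` at ``change_point_trial``, with an optional
    linear ramp over ``ramp_trials`` trials.  Rewarded deliveries are
    followed by a consumption bout of regularly spaced contacts whose
    off-to-on gaps are under 500 ms by construction, so the bout is
    excluded from ITI lick-rate windows.

    The default change point (trial 8) emulates the rapid-learning,
    long-ITI cohorts, whose learned trial is ~9.  The cumsum detector's
    75% rule fires systematically before a planted sharp step, with a
    lead of about a quarter of the change-point trial, so planted-recovery
    accuracy should only be expected in this early-learning regime (see
    the methods note).
    """

    baseline_lick_rate: float = 0.3
    anticipatory_rate: float = 4.0
    change_point_trial: int = 8
    ramp_trials: int = 0
    consumption_latency: float = 0.15
    consumption_duration: float = 2.0
    consumption_rate: float = 8.0
    contact_duration: float = 0.05
    seed: int = 0


@dataclass
class PhotometryGenParams:
    """Parameters of the synthetic two-channel photometry model.

    The 470-nm channel is ``baseline + transients + shared artifact +
    noise`` where each cue/reward event contributes an
    amplitude-weighted double-exponential transient.  The 405-nm channel
    is ``gain * (baseline + shared artifact) + offset + noise`` and
    carries no event transients, mimicking an isosbestic control.
    """

    sampling_rate: float = 120.0
    kernel_rise: float = 0.05
    kernel_decay: float = 0.5
    cue_amp_trajectory: Optional[np.ndarray] = None
    reward_amp_trajectory: Optional[np.ndarray] = None
    noise_sd: float = 0.1
    baseline_f: float = 100.0
    iso_gain: float = 1.0
    iso_offset: float = 0.0
    shared_artifact_sd: float = 0.0
    artifact_timescale: float = 2.0
    seed: int = 0


@dataclass
class PhotometryTrace:
    """Paired 470/405-nm fluorescence series on a uniform time base."""

    time_s: np.ndarray
    f470: np.ndarray
    f405: np.ndarray
    sampling_rate: float
    session_index: Optional[np.ndarray] = None


def gen_licks(
    schedule: EventSchedule, params: BehaviorGenParams
) -> tuple[LickTrain, dict]:
    """Generate a lick train over a schedule.

    Returns the train and a ground-truth dict with the planted change
    point and the per-trial expected cue-evoked lick count
    (``(rate_trial - baseline) * 1.25``).
    """
    rng = np.random.default_rng(params.seed)
    spec = schedule.spec
    window = spec.cue_to_reward if spec is not None else 1.25
    bounds = schedule.session_bounds()
    table = schedule.trial_table()

    onsets = []
    # homogeneous Poisson baseline over each session
    for t0, t1 in bounds:
        n = rng.poisson(params.baseline_lick_rate * (t1 - t0))
        onsets.append(np.sort(rng.uniform(t0, t1, size=n)))

    # anticipatory licking inside the cue->reward window, rate stepping
    # (with linear ramp) at the planted change point; trial k's rate adds
    # (anticipatory - baseline) * ramp_frac(k) of extra Poisson licks
    expected_delta = np.zeros(len(table))
    extra = params.anticipatory_rate - params.baseline_lick_rate
    for i, row in enumerate(table.itertuples(index=False)):
        k = row.trial_index
        if k < params.change_point_trial:
            frac = 0.0
        elif params.ramp_trials <= 0:
            frac = 1.0
        else:
            frac = min(1.0, (k - params.change_point_trial + 1) / params.ramp_trials)
        rate = extra * frac
        expected_delta[i] = rate * window
        if rate > 0:
            n = rng.poisson(rate * window)
            onsets.append(rng.uniform(row.cue_time, row.cue_time + window, size=n))

    # consumption bouts: regular contacts with sub-500-ms gaps
    bout_period = 1.0 / params.consumption_rate
    for row in table.itertuples(index=False):
        if not row.rewarded:
            continue
        start = row.reward_time + params.consumption_latency
        times = np.arange(start, start + params.consumption_duration, bout_period)
        onsets.append(times)
    for e in schedule.events:
        if e.event_type == "background_reward":
            start = e.time + params.consumption_latency
            times = np.arange(start, start + params.consumption_duration, bout_period)
            onsets.append(times)

    all_onsets = np.sort(np.concatenate(onsets)) if onsets else np.empty(0)
    train = LickTrain(
        onsets=all_onsets, offsets=all_onsets + params.contact_duration
    )
    truth = {
        "change_point_trial": params.change_point_trial,
        "expected_delta_licks": expected_delta,
    }
    return train, truth


def double_exp_kernel(
    rise: float, decay: float, sampling_rate: float, duration: float = 3.0
) -> np.ndarray:
    """Difference-of-exponentials transient kernel, normalized to unit peak."""
    t = np.arange(0.0, duration, 1.0 / sampling_rate)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    peak = k.max()
    if peak > 0:
        k = k / peak
    return k


def _smooth_noise(
    rng: np.random.Generator, n: int, sd: float, timescale: float, fs: float
) -> np.ndarray:
    """Low-frequency Gaussian noise with the requested pointwise sd."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    width = max(1, int(round(timescale * fs)))
    kern = np.exp(-0.5 * (np.arange(-3 * width, 3 * width + 1) / width) ** 2)
    kern /= kern.sum()
    smooth = np.convolve(white, kern, mode="same")
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def gen_photometry(
    schedule: EventSchedule, params: PhotometryGenParams
) -> tuple[PhotometryTrace, dict]:
    """Generate a two-channel photometry trace over a schedule.

    Sessions are sampled independently at ``sampling_rate`` and
    concatenated.  Amplitude trajectories index trials 1-based; missing
    trajectories default to zero amplitude.  Returns the trace and a
    ground-truth dict with the per-trial cue/reward amplitudes.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    kernel = double_exp_kernel(params.kernel_rise, params.kernel_decay, fs)
    table = schedule.trial_table()
    n_trials = len(table)

    cue_amp = np.zeros(n_trials + 1)
    rew_amp = np.zeros(n_trials + 1)
    if params.cue_amp_trajectory is not None:
        traj = np.asarray(params.cue_amp_trajectory, dtype=float)
        cue_amp[1 : 1 + min(n_trials, len(traj))] = traj[:n_trials]
    if params.reward_amp_trajectory is not None:
        traj = np.asarray(params.reward_amp_trajectory, dtype=float)
        rew_amp[1 : 1 + min(n_trials, len(traj))] = traj[:n_trials]

    seg_t, seg_470, seg_405, seg_sess = [], [], [], []
    for sess_idx, (t0, t1) in enumerate(schedule.session_bounds(), start=1):
        n = int(np.ceil((t1 - t0 + 2.0) * fs))  # 2-s tail past session end
        t = t0 + np.arange(n) / fs
        signal = np.zeros(n)
        for row in table.itertuples(index=False):
            if row.session_index != sess_idx:
                continue
            a = cue_amp[row.trial_index]
            if a != 0.0:
                _add_transient(signal, t0, fs, row.cue_time, a, kernel)
            if row.rewarded:
                a = rew_amp[row.trial_index]
                if a != 0.0:
                    _add_transient(signal, t0, fs, row.reward_time, a, kernel)
        artifact = _smooth_noise(
            rng, n, params.shared_artifact_sd, params.artifact_timescale, fs
        )
        f470 = (
            params.baseline_f
            + signal
            + artifact
            + params.noise_sd * rng.standard_normal(n)
        )
        f405 = (
            params.iso_gain * (params.baseline_f + artifact)
            + params.iso_offset
            + params.noise_sd * rng.standard_normal(n)
        )
        seg_t.append(t)
        seg_470.append(f470)
        seg_405.append(f405)
        seg_sess.append(np.full(n, sess_idx, dtype=int))

    trace = PhotometryTrace(
        time_s=np.concatenate(seg_t),
        f470=np.concatenate(seg_470),
        f405=np.concatenate(seg_405),
        sampling_rate=fs,
        session_index=np.concatenate(seg_sess),
    )
    truth = {
        "cue_amplitudes": cue_amp[1:],
        "reward_amplitudes": rew_amp[1:],
    }
    return trace, truth


def _add_transient(
    signal: np.ndarray, t0: float, fs: float, when: float, amp: float, kernel: np.ndarray
) -> None:
    i = int(round((when - t0) * fs))
    if i < 0 or i >= len(signal):
        return
    j = min(len(signal), i + len(kernel))
    signal[i:j] += amp * kernel[: j - i]
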
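"""Microstimulus temporal-difference reinforcement learning.

Each event (cue or reward) launches a memory trace whose height decays by
a factor ``d`` per time step.  The trace height is read out by ``m``
Gaussian basis functions ("microstimuli") with centers equally spaced on
(0, 1], each weighted by the current trace height, so stimulus identity
is carried forward in a temporally smeared code.  The full inter-trial
interval is simulated at ``dt`` resolution, so ITI states can themselves
acquire value -- the mechanism by which this model could, in principle,
express trial-spacing effects.

Learning is TD(lambda) with accumulating eligibility traces:

    delta_t = r_t + gamma * V(x_t) - V(x_{t-1})
    e_t     = gamma * lambda * e_{t-1} + x_{t-1}
    w      += alpha * delta_t * e_t

The per-trial association quantity is the maximum value between cue
onset and reward delivery; behavior emerges when it crosses the
threshold.  The per-trial dopamine proxy is the prediction error at the
cue and the reward steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from irilearn.models.base import SimResult, first_crossing
from irilearn.schedule import EventSchedule, nominal_iri

__all__ = ["TdrlMsParams", "simulate_tdrl_microstimulus", "simulate_tdrl_scaled"]


@dataclass
class TdrlMsParams:
    """Microstimulus TDRL parameters (defaults: the best-fit combination)."""

    dt: float = 0.25           # s, set to cue duration
    lam: float = 0.99          # eligibility-trace decay
    sigma: float = 0.08        # microstimulus width
    d: float = 0.9             # per-step memory-trace decay
    gamma: float = 0.99        # temporal discount
    m: int = 3                 # microstimuli per event
    alpha: float = 0.1         # learning rate
    threshold: float = 0.3     # behavior-generation threshold on value


def _feature_table(d: float, sigma: float, m: int, max_age: int) -> np.ndarray:
    """Microstimulus features for every trace age 0..max_age.

    Row ``a`` holds the m basis responses for trace height ``d**a``:
    ``y * exp(-(y - mu_j)^2 / (2 sigma^2))`` with centers mu_j = j/m.
    """
    ages = np.arange(max_age + 1)
    y = d ** ages
    centers = (np.arange(1, m + 1) / m)[None, :]
    return y[:, None] * np.exp(-((y[:, None] - centers) ** 2) / (2 * sigma**2))


def simulate_tdrl_microstimulus(
    schedule: EventSchedule, params: TdrlMsParams
) -> SimResult:
    """Run microstimulus TDRL over a conditioning schedule.

    The schedule is discretized at ``params.dt``; cue and reward times
    are rounded to the nearest step.  Reward magnitude is 1.
    """
    p = params
    table = schedule.trial_table()
    t_end = max(e.time for e in schedule.events) + p.dt
    n_steps = int(math.ceil(t_end / p.dt)) + 1

    cue_steps = np.round(table["cue_time"].to_numpy() / p.dt).astype(int)
    rew_rows = table[table["rewarded"]]
    rew_steps = np.round(rew_rows["reward_time"].to_numpy() / p.dt).astype(int)
    reward_at = np.zeros(n_steps)
    reward_at[rew_steps] = 1.0
    cue_at_step = {int(s): i for i, s in enumerate(cue_steps)}
    rew_at_step = set(int(s) for s in rew_steps)

    feat = _feature_table(p.d, p.sigma, p.m, n_steps)
    zero = np.zeros(p.m)

    w_c = np.zeros(p.m)
    w_r = np.zeros(p.m)
    e_c = np.zeros(p.m)
    e_r = np.zeros(p.m)
    age_c = -1  # -1: no event yet
    age_r = -1
    v_prev = 0.0
    f_c_prev = zero
    f_r_prev = zero
    gl = p.gamma * p.lam
    a = p.alpha

    n_trials = len(table)
    quantity = np.full(n_trials, -np.inf)
    da_cue = np.zeros(n_trials)
    da_rew = np.zeros(n_trials)
    spec = schedule.spec
    delay = spec.cue_to_reward if spec is not None else 1.25
    end_times = np.where(
        table["rewarded"].to_numpy(),
        table["reward_time"].to_numpy(),
        table["cue_time"].to_numpy() + delay,
    )
    end_steps = np.round(end_times / p.dt).astype(int)
    trial_of_step = _trial_windows(cue_steps, end_steps, n_steps)

    for t in range(n_steps):
        if t in cue_at_step:
            age_c = 0
        elif age_c >= 0:
            age_c += 1
        if t in rew_at_step:
            age_r = 0
        elif age_r >= 0:
            age_r += 1
        f_c = feat[age_c] if age_c >= 0 else zero
        f_r = feat[age_r] if age_r >= 0 else zero
        v = float(w_c @ f_c + w_r @ f_r)
        delta = reward_at[t] + p.gamma * v - v_prev
        e_c = gl * e_c + f_c_prev
        e_r = gl * e_r + f_r_prev
        ad = a * delta
        w_c = w_c + ad * e_c
        w_r = w_r + ad * e_r
        k = trial_of_step[t]
        if k >= 0 and v > quantity[k]:
            quantity[k] = v
        if t in cue_at_step:
            da_cue[cue_at_step[t]] = delta
        if k >= 0 and t in rew_at_step:
            da_rew[k] = delta
        v_prev = v
        f_c_prev = f_c
        f_r_prev = f_r

    quantity[np.isneginf(quantity)] = 0.0
    return SimResult(
        per_trial_quantity=quantity,
        learned_trial=first_crossing(quantity, p.threshold),
        threshold=p.threshold,
        params=asdict(p),
        da_cue=da_cue,
        da_reward=da_rew,
    )


def _trial_windows(cue_steps, end_steps, n_steps) -> np.ndarray:
    """Map step -> 0-based trial index inside [cue, reward] windows, else -1."""
    out = np.full(n_steps, -1, dtype=int)
    for i, (cs, re) in enumerate(zip(cue_steps, end_steps)):
        out[cs : min(re + 1, n_steps)] = i
    return out


def simulate_tdrl_scaled(
    schedule: EventSchedule, params: TdrlMsParams, k_scale: float = 0.0003
) -> SimResult:
    """Microstimulus TDRL with the learning rate scaled by the IRI.

    Replaces ``alpha`` with ``1 - exp(-k_scale * IRI)`` where IRI is the
    schedule's nominal inter-reward interval, then runs the standard
    simulator.  With the best-fit ``k_scale = 3e-4`` the 60-s ITI
    condition (IRI 64.25 s) uses alpha ~ 0.0191.
    """
    spec = schedule.spec
    if spec is None:
        raise ValueError("schedule must carry its protocol spec to derive the IRI")
    iri = nominal_iri(spec.mean_iti, spec.reward_prob, spec.trial_block)
    alpha = 1.0 - math.exp(-k_scale * iri)
    scaled = TdrlMsParams(**{**asdict(params), "alpha": alpha})
    res = simulate_tdrl_microstimulus(schedule, scaled)
    res.params["k_scale"] = k_scale
    return res
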
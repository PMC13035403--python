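"""ANCCR: adjusted net contingency of causal relations.

ANCCR learns retrospectively, at reward times, whether the cue
consistently precedes reward.  The retrospective (predecessor)
association is cached as ``M_cr`` and converted to a prospective
(successor) association with a Bayes'-rule-like normalization by the
baseline event rates:

    M_cr  <- (1 - alpha)   * M_cr  + alpha   * E_cue   (at each reward)
    M_x   <- (1 - alpha_0) * M_x   + alpha_0 * E_x     (every dt, any x)
    M->cr  = M_cr * M_reward / M_cue

where ``E_x`` is an exponentially decaying eligibility trace with time
constant ``T = k * IRI``.  For the Bayes normalization to be coherent,
the retrospective association and the baseline rates must integrate the
same span of past experience; because ``M_cr`` updates once per reward
while the baselines update every ``dt``, this forces the associative
learning rate to

    alpha = 1 - (1 - alpha_0) ** (IRI / dt)      (~ alpha_0 * IRI / dt)

i.e. learning per reward scales proportionally with the inter-reward
interval -- the model's signature prediction.

The per-trial association quantity is the net contingency, a
``w``-weighted blend of the prospective and retrospective contingencies:

    NC = w * (M->cr - M_reward) + (1 - w) * (M_cr - M_cue)

and behavior emerges at the threshold crossing.  The dopamine proxy is
NC at cue times and NC plus an innate meaningfulness of 1 at rewards.

The simulation is event-driven: eligibility decay and the geometric
baseline relaxation between events are applied in closed form on the
``dt`` grid, which is exact and keeps long-ITI schedules cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from irilearn.models.base import SimResult, first_crossing
from irilearn.schedule import EventSchedule, nominal_iri

__all__ = ["AnccrParams", "alpha_from_iri", "simulate_anccr"]

_BASELINE_FLOOR = 1e-9


@dataclass
class AnccrParams:
    """ANCCR parameters (defaults: the best-fit combination)."""

    alpha0: float = 4e-5       # baseline learning rate (per dt)
    k: float = 0.5             # eligibility time constant scale, T = k * IRI
    w: float = 0.5             # prospective/retrospective blend
    dt: float = 0.2            # s
    threshold: float = 0.4     # behavior-generation threshold on NC
    innate_meaningfulness: float = 1.0  # added to the reward dopamine proxy
    iri: Optional[float] = None  # override; else derived from the schedule


def alpha_from_iri(
    alpha0: float, iri_s: float, dt_s: float
) -> tuple[float, float]:
    """Associative learning rate implied by equal timescales of history.

    Returns ``(exact, small_rate_approximation)`` where the exact form is
    ``1 - (1 - alpha0) ** (IRI / dt)`` and the approximation is
    ``alpha0 * IRI / dt`` (valid for small rates).  At IRI = dt the exact
    form reduces to alpha0; doubling the IRI doubles alpha in the
    small-rate limit.
    """
    if not 0 < alpha0 < 1:
        raise ValueError("alpha0 must lie in (0, 1)")
    if iri_s <= 0 or dt_s <= 0:
        raise ValueError("IRI and dt must be positive")
    exact = 1.0 - math.exp((iri_s / dt_s) * math.log1p(-alpha0))
    approx = alpha0 * iri_s / dt_s
    return exact, approx


def _relax(
    M: float, E0: float, n: int, a: float, beta: float, alpha0: float
) -> tuple[float, float]:
    """Advance a baseline M and its eligibility trace by n quiet dt steps.

    Per step the trace decays by ``beta`` and the baseline relaxes as
    ``M <- a * M + alpha0 * E``; the geometric sum is applied in closed
    form: ``M_n = a^n M_0 + alpha0 E_0 beta (a^n - beta^n) / (a - beta)``.
    """
    if n <= 0:
        return M, E0
    an = a**n
    bn = beta**n
    if abs(a - beta) > 1e-12:
        M = an * M + alpha0 * E0 * beta * (an - bn) / (a - beta)
    else:
        M = an * M + alpha0 * E0 * n * an
    return M, E0 * bn


def simulate_anccr(schedule: EventSchedule, params: AnccrParams) -> SimResult:
    """Run ANCCR over a conditioning schedule.

    Event times are rounded to the ``dt`` grid.  Eligibility traces and
    baselines are maintained for the cue, the trial-reward identity, and
    any background-reward identity; cross-identity associations are not
    learned (learning is identity specific), so background rewards only
    contribute to their own baseline.
    """
    p = params
    spec = schedule.spec
    if p.iri is not None:
        iri = p.iri
    elif spec is not None:
        iri = nominal_iri(spec.mean_iti, spec.reward_prob, spec.trial_block)
    else:
        rts = schedule.reward_times()
        if len(rts) < 2:
            raise ValueError("cannot derive the IRI from this schedule")
        iri = float(np.mean(np.diff(rts)))
    alpha, _ = alpha_from_iri(p.alpha0, iri, p.dt)
    T = p.k * iri
    beta = math.exp(-p.dt / T)
    a0 = 1.0 - p.alpha0

    # ordered (step, kind, trial_index) event stream on the dt grid
    stream: list[tuple[int, str, int]] = []
    reward_identity = spec.reward_identity if spec is not None else "reward"
    for e in schedule.events:
        if e.event_type == "cs_plus":
            stream.append((int(round(e.time / p.dt)), "cue", e.trial_index))
        elif e.event_type == "reward":
            stream.append((int(round(e.time / p.dt)), "rew", e.trial_index))
        elif e.event_type == "background_reward":
            stream.append((int(round(e.time / p.dt)), "bg", -1))
    stream.sort(key=lambda s: s[0])

    E = {"cue": 0.0, "rew": 0.0, "bg": 0.0}
    M_base = {"cue": 0.0, "rew": 0.0, "bg": 0.0}
    M_cr = 0.0

    table = schedule.trial_table()
    n_trials = len(table)
    quantity = np.zeros(n_trials)
    da_cue = np.zeros(n_trials)
    da_rew = np.full(n_trials, np.nan)

    def net_contingency() -> float:
        m_c = max(M_base["cue"], _BASELINE_FLOOR)
        m_r = M_base["rew"]
        prospective = M_cr * m_r / m_c
        pc = prospective - m_r
        rc = M_cr - M_base["cue"]
        return p.w * pc + (1.0 - p.w) * rc

    step = 0
    for ev_step, kind, trial in stream:
        gap = ev_step - step
        if gap > 0:
            # quiet steps: closed-form decay + baseline relaxation
            for key in E:
                M_base[key], E[key] = _relax(
                    M_base[key], E[key], gap - 1, a0, beta, p.alpha0
                )
                E[key] *= beta
        # event step: bump the trace, then apply this step's baseline update
        E[kind] += 1.0
        for key in E:
            M_base[key] = a0 * M_base[key] + p.alpha0 * E[key]
        if kind == "rew":
            M_cr = (1.0 - alpha) * M_cr + alpha * E["cue"]
            nc = net_contingency()
            if trial > 0:
                quantity[trial - 1] = nc
                da_rew[trial - 1] = nc + p.innate_meaningfulness
        elif kind == "cue":
            nc = net_contingency()
            da_cue[trial - 1] = nc
            # omission trials keep the cue-time contingency as their readout
            quantity[trial - 1] = nc
        step = ev_step

    res_params = asdict(p)
    res_params.update({"alpha": alpha, "T": T, "iri": iri})
    return SimResult(
        per_trial_quantity=quantity,
        learned_trial=first_crossing(quantity, p.threshold),
        threshold=p.threshold,
        params=res_params,
        da_cue=da_cue,
        da_reward=da_rew,
    )
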
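"""Wagner's standard operating procedure (SOP) associative model.

Each stimulus (cue, reward) is represented by a node of elements
distributed across an inactive state (I), a primary active state (A1)
and a secondary, refractory active state (A2).  Presenting a stimulus
moves a fraction ``p1`` of inactive elements into A1; on every step a
fraction ``pd1`` of A1 decays into A2 and a fraction ``pd2`` of A2
returns to I.  The cue-reward association V is strengthened by A1-A1
co-activity and weakened by A1(cue)-A2(reward) co-activity:

    dV = pA1_cs * (L_plus * pA1_us * r1  -  L_minus * pA2_us * r2)

After learning, cue presentations additionally drive reward elements
from I directly into A2 in proportion to V (the conditioned response),
which depresses subsequent learning.  Longer ITIs let more elements
drain back to I, so more can enter A1 on the next trial -- the
mechanism by which SOP expresses a (qualitative) trial-spacing effect.

The per-trial association quantity is the maximum V between cue onset
and reward delivery; behavior emerges at the threshold crossing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from irilearn.models.base import SimResult, first_crossing
from irilearn.schedule import EventSchedule

__all__ = ["SopParams", "simulate_sop"]


@dataclass
class SopParams:
    """SOP parameters (defaults: the best-fit combination)."""

    dt: float = 0.25       # s, set to cue duration
    r1: float = 1.0        # reward magnitude for A1 coincidence
    r2: float = 0.5        # reward magnitude for A2 coincidence
    L_plus: float = 0.2    # excitatory learning scale (A1cs x A1us)
    L_minus: float = 0.1   # inhibitory learning scale (A1cs x A2us)
    p1_cs: float = 0.1     # I->A1 on cue presentation
    p1_us: float = 0.6     # I->A1 on reward presentation
    pd1_cs: float = 0.1    # A1->A2 decay, cue node
    pd2_cs: float = 0.0001  # A2->I decay, cue node
    pd1_us: float = 0.25   # A1->A2 decay, reward node
    pd2_us: float = 0.1    # A2->I decay, reward node
    threshold: float = 0.1
    enforce_decay_order: bool = True

    def validate(self) -> None:
        for name in ("p1_cs", "p1_us", "pd1_cs", "pd2_cs", "pd1_us", "pd2_us"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.enforce_decay_order and (
            self.pd1_cs <= self.pd2_cs or self.pd1_us <= self.pd2_us
        ):
            raise ValueError("SOP requires pd1 > pd2 for each node")


def simulate_sop(schedule: EventSchedule, params: SopParams) -> SimResult:
    """Run SOP over a conditioning schedule discretized at ``params.dt``.

    Cue and reward presentations occupy the single step containing their
    onset.  State fractions are conserved (pI + pA1 + pA2 = 1 per node).
    """
    p = params
    p.validate()
    table = schedule.trial_table()
    t_end = max(e.time for e in schedule.events) + p.dt
    n_steps = int(math.ceil(t_end / p.dt)) + 1

    cue_steps = np.round(table["cue_time"].to_numpy() / p.dt).astype(int)
    spec = schedule.spec
    delay = spec.cue_to_reward if spec is not None else 1.25
    rewarded = table["rewarded"].to_numpy()
    rew_times = np.where(
        rewarded, table["reward_time"].to_numpy(), table["cue_time"].to_numpy() + delay
    )
    end_steps = np.round(rew_times / p.dt).astype(int)
    cue_at = {int(s): i for i, s in enumerate(cue_steps)}
    rew_at = {int(e): i for i, e in enumerate(end_steps) if rewarded[i]}

    # per-node state fractions
    i_cs, a1_cs, a2_cs = 1.0, 0.0, 0.0
    i_us, a1_us, a2_us = 1.0, 0.0, 0.0
    V = 0.0

    n_trials = len(table)
    quantity = np.full(n_trials, -np.inf)
    trial_of_step = np.full(n_steps, -1, dtype=int)
    for i, (cs, re) in enumerate(zip(cue_steps, end_steps)):
        trial_of_step[cs : min(re + 1, n_steps)] = i

    for t in range(n_steps):
        if t in cue_at:
            moved = p.p1_cs * i_cs
            i_cs -= moved
            a1_cs += moved
            # conditioned response: the learned cue drives reward elements
            # from I directly into their refractory A2 state
            cr = min(1.0, max(0.0, V)) * i_us
            i_us -= cr
            a2_us += cr
        if t in rew_at:
            moved = p.p1_us * i_us
            i_us -= moved
            a1_us += moved
        # distributed decay runs every step
        d1 = p.pd1_cs * a1_cs
        d2 = p.pd2_cs * a2_cs
        a1_cs -= d1
        a2_cs += d1 - d2
        i_cs += d2
        d1 = p.pd1_us * a1_us
        d2 = p.pd2_us * a2_us
        a1_us -= d1
        a2_us += d1 - d2
        i_us += d2
        V += a1_cs * (p.L_plus * a1_us * p.r1 - p.L_minus * a2_us * p.r2)
        k = trial_of_step[t]
        if k >= 0 and V > quantity[k]:
            quantity[k] = V

    quantity[np.isneginf(quantity)] = 0.0
    return SimResult(
        per_trial_quantity=quantity,
        learned_trial=first_crossing(quantity, p.threshold),
        threshold=p.threshold,
        params=asdict(p),
    )
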
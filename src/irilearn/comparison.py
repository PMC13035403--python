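"""Model comparison across ITI conditions: sweeps, log-RSS, AIC, weights.

Each candidate model is simulated on every ITI condition for the number
of trials the corresponding experimental group experienced, with 20
iterations per condition.  Goodness of fit is the residual sum of
squares of log10 trials-to-learn against the experimental group means
(log-transformed to even out the wide range across conditions); models
are then ranked by AIC = 2k + n * ln(meanRSS) -- reported with k = 0 by
convention -- and compared through relative weights
``exp(-0.5 * (AIC - AIC_min))``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from irilearn.models.base import SimResult
from irilearn.schedule import ProtocolSpec, build_schedule

__all__ = [
    "ConditionSpec",
    "DEFAULT_CONDITIONS",
    "EXPERIMENTAL_TRIALS_TO_LEARN",
    "SweepResult",
    "run_condition",
    "rss_log",
    "mean_rss",
    "aic",
    "model_weights",
    "sim_time_to_learn",
    "sweep",
]


@dataclass(frozen=True)
class ConditionSpec:
    """One simulated ITI condition.

    ``n_trials`` is the number of trials the matching experimental group
    experienced over 8 days of conditioning; simulations run as a single
    uninterrupted session of that length.
    """

    label: str
    mean_iti: float
    n_trials: int
    n_iterations: int = 20
    iti_jitter: float = 0.2
    reward_prob: float = 1.0

    @property
    def trial_block(self) -> float:
        return 4.25

    @property
    def nominal_iri(self) -> float:
        return (self.mean_iti + self.trial_block) / self.reward_prob

    def to_protocol(self) -> ProtocolSpec:
        return ProtocolSpec(
            name=self.label,
            mean_iti=self.mean_iti,
            iti_jitter=self.iti_jitter,
            trials_per_session=self.n_trials,
            n_sessions=1,
            reward_prob=self.reward_prob,
        )


#: Trial counts per condition over 8 days of conditioning.
DEFAULT_CONDITIONS: dict[str, ConditionSpec] = {
    "30": ConditionSpec("30", 30.0, 800),
    "60": ConditionSpec("60", 60.0, 400),
    "300": ConditionSpec("300", 300.0, 88),
    "600": ConditionSpec("600", 600.0, 48),
    "3600": ConditionSpec("3600", 3600.0, 16, iti_jitter=0.0),
}

#: Experimental group-mean trials-to-learn used as the sweep reference.
EXPERIMENTAL_TRIALS_TO_LEARN: dict[str, float] = {
    "30": 176.0,
    "60": 94.0,
    "300": 16.7,
    "600": 8.8,
    "3600": 3.6,
}


def run_condition(
    model: Callable[..., SimResult],
    params,
    condition: ConditionSpec,
    seeds: Sequence[int],
) -> list[Optional[int]]:
    """Simulate one condition once per seed; None marks a censored run
    (threshold never crossed)."""
    out = []
    proto = condition.to_protocol()
    for seed in seeds:
        schedule = build_schedule(proto, seed=int(seed))
        res = model(schedule, params)
        out.append(res.learned_trial)
    return out


def rss_log(
    sim_trials: Mapping[str, float], exp_trials: Mapping[str, float]
) -> float:
    """Sum over conditions of (log10 simulated - log10 experimental)^2."""
    if set(sim_trials) != set(exp_trials):
        raise ValueError("condition labels do not match")
    total = 0.0
    for label, sim in sim_trials.items():
        exp = exp_trials[label]
        if sim <= 0 or exp <= 0:
            raise ValueError("trials-to-learn must be positive for log RSS")
        total += (math.log10(sim) - math.log10(exp)) ** 2
    return total


def _censor(value: Optional[int], n_trials: int) -> int:
    # censored runs contribute the maximum simulated trial count + 1 so
    # non-learning parameter combinations still rank below learning ones
    return value if value is not None else n_trials + 1


def mean_rss(
    per_condition: Mapping[str, Sequence[Optional[int]]],
    exp_trials: Mapping[str, float],
    conditions: Mapping[str, ConditionSpec],
    strategy: str = "per_iteration",
) -> float:
    """Mean RSS of simulated vs experimental trials-to-learn.

    ``per_iteration`` (default) computes the RSS of each iteration's
    learned trials against the experimental means and averages across
    iterations; ``mean_of_sim`` first averages learned trials per
    condition and computes a single RSS.
    """
    labels = list(per_condition)
    filled = {
        lab: [
            _censor(v, conditions[lab].n_trials) for v in per_condition[lab]
        ]
        for lab in labels
    }
    if strategy == "mean_of_sim":
        sim_means = {lab: float(np.mean(filled[lab])) for lab in labels}
        return rss_log(sim_means, {lab: exp_trials[lab] for lab in labels})
    if strategy != "per_iteration":
        raise ValueError("strategy must be 'per_iteration' or 'mean_of_sim'")
    n_iter = min(len(v) for v in filled.values())
    rss_values = [
        rss_log(
            {lab: filled[lab][i] for lab in labels},
            {lab: exp_trials[lab] for lab in labels},
        )
        for i in range(n_iter)
    ]
    return float(np.mean(rss_values))


def aic(mean_rss_value: float, n: int, k: int = 0) -> float:
    """AIC = 2k + n * ln(meanRSS); reported with k = 0 by default."""
    if mean_rss_value <= 0:
        raise ValueError("meanRSS must be positive")
    return 2 * k + n * math.log(mean_rss_value)


def model_weights(aics: Mapping[str, float]) -> dict[str, float]:
    """Relative weight of each model: exp(-0.5 * (AIC - AIC_min)).

    The best (minimum-AIC) model has weight 1; weights are invariant to
    adding a constant to every AIC.
    """
    if not aics:
        raise ValueError("need at least one model")
    amin = min(aics.values())
    return {m: math.exp(-0.5 * (a - amin)) for m, a in aics.items()}


def sim_time_to_learn(condition: ConditionSpec, learned_trial: Optional[int]) -> Optional[float]:
    """Conditioning time to learn: L trial blocks plus L + 1 mean ITIs.

    Follows the leading-ITI convention (one ITI precedes every trial, so
    learning after trial L spans L + 1 ITIs).  None for censored runs.
    """
    if learned_trial is None:
        return None
    L = learned_trial
    return L * condition.trial_block + (L + 1) * condition.mean_iti


@dataclass
class SweepResult:
    """One parameter combination's score across all conditions."""

    params: dict
    per_condition: dict[str, list[Optional[int]]]
    mean_rss: float
    aic_k0: Optional[float] = None
    weight: Optional[float] = None
    n_censored: int = 0


def sweep(
    model: Callable[..., SimResult],
    make_params: Callable[..., object],
    grid: Mapping[str, Sequence],
    conditions: Mapping[str, ConditionSpec],
    exp_trials: Mapping[str, float],
    seeds: Sequence[int],
    constraint: Optional[Callable[[dict], bool]] = None,
    n_aic: int = 52,
    strategy: str = "per_iteration",
) -> list[SweepResult]:
    """Evaluate every grid combination and rank by mean RSS.

    ``make_params`` turns a keyword dict into the model's parameter
    object.  ``constraint`` filters combinations (e.g. SOP's pd1 > pd2).
    ``n_aic`` is the sample size entering the AIC, defaulting to the 52
    learner animals across the five ITI groups.  Returns results sorted
    best first, with AIC and relative weights filled in.
    """
    names = list(grid)
    results: list[SweepResult] = []
    for combo in itertools.product(*(grid[n] for n in names)):
        kw = dict(zip(names, combo))
        if constraint is not None and not constraint(kw):
            continue
        params = make_params(**kw)
        per_condition = {}
        n_cens = 0
        for lab, cond in conditions.items():
            trials = run_condition(model, params, cond, seeds[: cond.n_iterations])
            n_cens += sum(v is None for v in trials)
            per_condition[lab] = trials
        m = mean_rss(per_condition, exp_trials, conditions, strategy=strategy)
        results.append(
            SweepResult(params=kw, per_condition=per_condition, mean_rss=m, n_censored=n_cens)
        )
    if not results:
        raise ValueError("empty grid (or constraint removed every combination)")
    results.sort(key=lambda r: r.mean_rss)
    aics = {i: aic(r.mean_rss, n_aic) for i, r in enumerate(results)}
    weights = model_weights(aics)
    for i, r in enumerate(results):
        r.aic_k0 = aics[i]
        r.weight = weights[i]
    return results
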
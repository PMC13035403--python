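"""Log-log scaling of trials-to-learn against the inter-reward interval.

The central empirical relationship: across ITI conditions the number of
trials needed to learn falls as a power law of the IRI with exponent
close to -1,

    log10(trials_to_learn) = slope * log10(IRI) + intercept,

so learning rate (1/trials) is proportional to IRI and total
conditioning time is constant.  The fitted line also yields point
predictions for extreme spacing, partial reinforcement (where the IRI
doubles at 50% reward while the inter-cue interval is unchanged), and
identity-specific reward rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ScalingFit",
    "fit_loglog",
    "predict_trials",
    "BEHAVIOR_REFERENCE_FIT",
    "DOPAMINE_REFERENCE_FIT",
    "GROUP_MEAN_POINTS",
]


@dataclass(frozen=True)
class ScalingFit:
    """Least-squares line on (log10 IRI, log10 trials)."""

    slope: float
    intercept: float
    r_squared: float = np.nan
    iris: tuple = field(default_factory=tuple)
    trials: tuple = field(default_factory=tuple)

    log_base: int = 10


#: Group-mean trials-to-learn vs nominal IRI for the four conditions with
#: proportional scaling (mean ITI 30/60/300/600 s at 100% reward).
GROUP_MEAN_POINTS: tuple[tuple[float, float], ...] = (
    (34.25, 176.0),
    (64.25, 94.0),
    (304.25, 16.7),
    (604.25, 8.8),
)

#: Reference behavioral coefficients (fit to the group means above).
BEHAVIOR_REFERENCE_FIT = ScalingFit(slope=-1.0593, intercept=3.8753)

#: Reference dopaminergic coefficients (line through the 60-s and 600-s
#: group means of the dopamine learned trial).
DOPAMINE_REFERENCE_FIT = ScalingFit(slope=-1.0359, intercept=3.4338)


def fit_loglog(iris: Sequence[float], trials: Sequence[float]) -> ScalingFit:
    """Ordinary least squares of log10 trials-to-learn on log10 IRI.

    With exactly two points this is the exact line through them (the
    two-group dopamine case); R^2 is then 1 by construction.
    """
    x = np.asarray(iris, dtype=float)
    y = np.asarray(trials, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need at least two (IRI, trials) pairs")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("IRIs and trials-to-learn must be positive")
    lx, ly = np.log10(x), np.log10(y)
    res = stats.linregress(lx, ly)
    return ScalingFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        iris=tuple(x),
        trials=tuple(y),
    )


def predict_trials(fit: ScalingFit, iri_s: float) -> float:
    """Predicted trials-to-learn at a given IRI: 10^(intercept + slope * log10 IRI)."""
    if iri_s <= 0:
        raise ValueError("IRI must be positive")
    return float(10.0 ** (fit.intercept + fit.slope * np.log10(iri_s)))
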
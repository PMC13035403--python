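"""Common result container for model simulations."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np


@dataclass
class SimResult:
    """Per-trial association quantity and threshold-crossing learned trial.

    ``per_trial_quantity`` holds the model's association readout on each
    trial (maximum value between cue and reward for TDRL and SOP; net
    cue-reward contingency for ANCCR).  ``learned_trial`` is the first
    1-based trial whose quantity exceeds the threshold, or None when the
    threshold is never crossed (censored).  ``da_cue``/``da_reward``
    carry the model's per-trial dopamine proxy (prediction error for
    TDRL, contingency-derived signal for ANCCR).
    """

    per_trial_quantity: np.ndarray
    learned_trial: Optional[int]
    threshold: float
    params: dict[str, Any] = field(default_factory=dict)
    da_cue: Optional[np.ndarray] = None
    da_reward: Optional[np.ndarray] = None


def first_crossing(quantity: np.ndarray, threshold: float) -> Optional[int]:
    """First 1-based index exceeding the threshold, or None."""
    above = np.nonzero(np.asarray(quantity) > threshold)[0]
    return int(above[0]) + 1 if len(above) else None
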
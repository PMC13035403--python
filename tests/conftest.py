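import numpy as np
import pytest

from irilearn.schedule import ProtocolSpec, build_schedule


@pytest.fixture
def spec60():
    """Single-session 60-s ITI protocol (50 trials, 100% reward)."""
    return ProtocolSpec(
        name="iti60", mean_iti=60, iti_jitter=0.2, trials_per_session=50, n_sessions=1
    )


@pytest.fixture
def spec60_fixed():
    """Degenerate (jitter 0) 60-s ITI protocol: fully deterministic timing."""
    return ProtocolSpec(
        name="iti60_fixed", mean_iti=60, iti_jitter=0.0, trials_per_session=50,
        n_sessions=1,
    )


@pytest.fixture
def sched60(spec60):
    return build_schedule(spec60, seed=11)


@pytest.fixture
def sched60_fixed(spec60_fixed):
    return build_schedule(spec60_fixed, seed=0)


def oracle_learned_trial(series, direction="positive", frac=0.75, end_anchor=None):
    """Brute-force cumsum change-point oracle: explicit loops over every
    candidate trial, with the re-anchoring rule spelled out step by step.

    Independent of the vectorized implementation; used to pin detector
    behavior on arbitrary series.
    """
    x = [float(v) for v in series]
    if direction == "negative":
        x = [-v for v in x]
    S = [0.0]
    for v in x:
        S.append(S[-1] + v)
    n = len(x)
    anchor = n if end_anchor is None else min(max(int(end_anchor), 1), n)
    for _ in range(n + 1):
        d = []
        for i in range(anchor + 1):
            line = S[anchor] * i / anchor
            d.append(line - S[i])
        dmax = max(abs(v) for v in d)
        if dmax <= 1e-12:
            return None
        first = None
        for i in range(anchor + 1):
            if abs(d[i]) >= frac * dmax - 1e-12:
                first = i
                break
        if d[first] >= 0:
            return first
        if first == anchor:
            return None
        anchor = first
    return None
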
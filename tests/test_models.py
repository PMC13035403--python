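import math

import numpy as np
import pytest

from irilearn.models import (
    AnccrParams,
    SopParams,
    TdrlMsParams,
    alpha_from_iri,
    simulate_anccr,
    simulate_sop,
    simulate_tdrl_microstimulus,
    simulate_tdrl_scaled,
)
from irilearn.schedule import ProtocolSpec, build_schedule


@pytest.fixture(scope="module")
def sched60_small():
    spec = ProtocolSpec(
        name="s", mean_iti=60, iti_jitter=0.2, trials_per_session=30, n_sessions=1
    )
    return build_schedule(spec, seed=2)


class TestAlphaFromIri:
    def test_single_step_identity(self):
        exact, _ = alpha_from_iri(0.05, iri_s=0.2, dt_s=0.2)
        assert exact == pytest.approx(0.05)

    def test_direct_evaluation(self):
        """alpha0 4e-5, dt 0.2, IRI 64.25 -> 1 - (1 - 4e-5)^321.25."""
        exact, approx = alpha_from_iri(4e-5, 64.25, 0.2)
        expected = 1.0 - math.exp(321.25 * math.log(1 - 4e-5))
        assert exact == pytest.approx(expected, rel=1e-12)
        assert exact == pytest.approx(0.012766, abs=1e-5)
        assert approx == pytest.approx(4e-5 * 321.25)

    def test_small_rate_doubling_limit(self):
        """alpha(2 IRI) / alpha(IRI) -> 2 as alpha0 -> 0."""
        for alpha0 in (1e-4, 1e-6, 1e-8):
            a1, _ = alpha_from_iri(alpha0, 60.0, 0.2)
            a2, _ = alpha_from_iri(alpha0, 120.0, 0.2)
            assert a2 / a1 == pytest.approx(2.0, rel=50 * alpha0 * 300)
        a1, _ = alpha_from_iri(1e-9, 60.0, 0.2)
        a2, _ = alpha_from_iri(1e-9, 120.0, 0.2)
        assert a2 / a1 == pytest.approx(2.0, rel=1e-4)

    def test_monotone_and_saturating(self):
        iris = [1, 10, 100, 1000, 1e5, 1e7]
        alphas = [alpha_from_iri(4e-5, i, 0.2)[0] for i in iris]
        assert all(b > a for a, b in zip(alphas, alphas[1:]))
        assert alphas[-1] == pytest.approx(1.0, abs=1e-6)

    def test_approximation_accurate_at_small_alpha(self):
        # relative error of the linear form is ~alpha/2, so within 1% for
        # alpha below 0.02
        exact, approx = alpha_from_iri(4e-5, 80.0, 0.2)
        assert exact < 0.02 and approx == pytest.approx(exact, rel=0.01)


class TestTdrlMicrostimulus:
    def test_zero_learning_rate_no_learning(self, sched60_small):
        res = simulate_tdrl_microstimulus(sched60_small, TdrlMsParams(alpha=0.0))
        assert np.allclose(res.per_trial_quantity, 0.0)
        assert res.learned_trial is None

    def test_tabular_td0_reduction(self):
        """m=1, lambda=0, sigma large, d=1: the cue step is a single state
        and its value after n pairings follows the 1 - (1 - a)^n recursion
        with a the effective per-pairing update (oracle recursion)."""
        spec = ProtocolSpec(
            name="tiny", mean_iti=10, iti_jitter=0.0, trials_per_session=12,
            n_sessions=1, cue_duration=0.25, trace_duration=0.0,
            consumption_period=0.25,
        )
        sched = build_schedule(spec, seed=0)
        p = TdrlMsParams(alpha=0.3, lam=0.0, m=1, sigma=1e3, d=1.0, gamma=1.0,
                         threshold=1e9)
        res = simulate_tdrl_microstimulus(sched, p)
        # oracle: iterate the TD(0) recursion independently over the same
        # discretized event steps
        oracle = _tabular_oracle(sched, p)
        assert np.allclose(res.per_trial_quantity, oracle, atol=1e-9)

    def test_value_bounded_by_discounted_reward(self, sched60_small):
        res = simulate_tdrl_microstimulus(sched60_small, TdrlMsParams())
        assert res.per_trial_quantity.max() <= 1.0 / (1 - 0.99) + 1

    def test_scaled_variant_alpha(self, sched60_small):
        res = simulate_tdrl_scaled(sched60_small, TdrlMsParams(), k_scale=0.0003)
        assert res.params["alpha"] == pytest.approx(1 - math.exp(-0.0003 * 64.25))
        zero = simulate_tdrl_scaled(sched60_small, TdrlMsParams(), k_scale=0.0)
        assert zero.learned_trial is None


def _tabular_oracle(sched, p):
    """Step-by-step TD(0) value iteration with a single constant feature
    per event, written independently of the simulator."""
    table = sched.trial_table()
    t_end = max(e.time for e in sched.events) + p.dt
    n_steps = int(math.ceil(t_end / p.dt)) + 1
    cue_steps = np.round(table["cue_time"].to_numpy() / p.dt).astype(int)
    rew_steps = np.round(table["reward_time"].to_numpy() / p.dt).astype(int)
    # with d=1 the trace height is 1 forever after the first event; the
    # single microstimulus (center 1, huge sigma) is then the constant
    # feature f = 1 * exp(-(1-1)^2/...) = 1
    w = {"c": 0.0, "r": 0.0}
    v_prev = 0.0
    f_prev = {"c": 0.0, "r": 0.0}
    reward = np.zeros(n_steps)
    reward[rew_steps] = 1.0
    seen = {"c": False, "r": False}
    out = np.zeros(len(table))
    cue_set = {int(s): i for i, s in enumerate(cue_steps)}
    rew_set = {int(s): i for i, s in enumerate(rew_steps)}
    for t in range(n_steps):
        if t in cue_set:
            seen["c"] = True
        if t in rew_set:
            seen["r"] = True
        f = {k: 1.0 if seen[k] else 0.0 for k in ("c", "r")}
        v = w["c"] * f["c"] + w["r"] * f["r"]
        delta = reward[t] + p.gamma * v - v_prev
        for k in ("c", "r"):
            w[k] += p.alpha * delta * f_prev[k]
        if t in cue_set:
            i = cue_set[t]
            out[i] = max(out[i], v)
        if t in rew_set:
            i = rew_set[t]
            out[i] = max(out[i], v)
        v_prev = v
        f_prev = f
    return out


class TestSop:
    def test_no_stimuli_flat(self):
        spec = ProtocolSpec(
            name="empty", mean_iti=60, iti_jitter=0.0, trials_per_session=1,
            n_sessions=1, reward_prob=1.0,
        )
        sched = build_schedule(spec, seed=0)
        res = simulate_sop(sched, SopParams(threshold=1e9))
        assert res.learned_trial is None

    def test_fraction_conservation(self, sched60_small):
        """pI + pA1 + pA2 = 1 to 1e-12 at every step: the transfer rules
        subtract exactly what they add (mirrored here step by step)."""
        i1, a1, a2 = 1.0, 0.0, 0.0
        for step in range(10_000):
            if step % 100 == 0:
                m = 0.1 * i1
                i1 -= m
                a1 += m
            d1 = 0.25 * a1
            d2 = 0.1 * a2
            a1 -= d1
            a2 += d1 - d2
            i1 += d2
            assert abs(i1 + a1 + a2 - 1.0) < 1e-12
        # and the simulator itself stays bounded as a consequence
        res = simulate_sop(sched60_small, SopParams())
        assert res.per_trial_quantity.shape == (30,)
        assert np.isfinite(res.per_trial_quantity).all()

    def test_paired_beats_unpaired(self):
        """Paired cue->reward develops more association than explicitly
        unpaired presentations (maximal separation) after equal numbers
        of presentations."""
        paired_spec = ProtocolSpec(
            name="p", mean_iti=60, iti_jitter=0.0, trials_per_session=40, n_sessions=1
        )
        paired = simulate_sop(build_schedule(paired_spec, seed=0), SopParams(threshold=1e9))
        # unpaired: reward arrives half an ITI after the cue
        unpaired_spec = ProtocolSpec(
            name="u", mean_iti=60, iti_jitter=0.0, trials_per_session=40, n_sessions=1,
            trace_duration=30.0,
        )
        unpaired = simulate_sop(build_schedule(unpaired_spec, seed=0), SopParams(threshold=1e9))
        assert paired.per_trial_quantity[-1] > unpaired.per_trial_quantity[-1]

    def test_probability_constraint(self):
        with pytest.raises(ValueError):
            SopParams(pd1_cs=0.1, pd2_cs=0.2).validate()
        with pytest.raises(ValueError):
            SopParams(p1_cs=1.5).validate()


class TestAnccr:
    def test_unpaired_streams_stay_subthreshold(self):
        """Cue never paired with reward: net contingency hovers near zero
        and never crosses 0.4."""
        hits = 0
        for seed in range(10):
            spec = ProtocolSpec(
                name="null", mean_iti=60, iti_jitter=0.2, trials_per_session=400,
                n_sessions=1, reward_prob=1.0, trace_duration=30.0 + seed,
            )
            sched = build_schedule(spec, seed=seed)
            # shuffle reward times within the session to break pairing
            rng = np.random.default_rng(seed)
            frame = sched.to_frame()
            rew = frame.event_type == "reward"
            lo, hi = frame.time_s.min(), frame.time_s.max()
            frame.loc[rew, "time_s"] = np.sort(rng.uniform(lo, hi, rew.sum()))
            frame = frame.sort_values("time_s", kind="stable")
            from irilearn.schedule import EventSchedule

            shuffled = EventSchedule.from_frame(frame)
            shuffled.spec = spec
            res = simulate_anccr(shuffled, AnccrParams())
            if res.learned_trial is not None:
                hits += 1
        assert hits <= 1

    def test_infinite_threshold_never_learns(self, sched60_small):
        res = simulate_anccr(sched60_small, AnccrParams(threshold=np.inf))
        assert res.learned_trial is None

    def test_proportional_scaling_60_vs_600(self):
        """Best-fit parameters: mean trials-to-learn ratio between the 60-s
        and 600-s conditions lies in [5, 20] (proportional scaling, 10x)."""
        def mean_trials(mean_iti, n_trials):
            out = []
            for seed in range(20):
                spec = ProtocolSpec(
                    name="c", mean_iti=mean_iti, iti_jitter=0.2,
                    trials_per_session=n_trials, n_sessions=1,
                )
                res = simulate_anccr(build_schedule(spec, seed=seed), AnccrParams())
                assert res.learned_trial is not None
                out.append(res.learned_trial)
            return np.mean(out)

        ratio = mean_trials(60, 400) / mean_trials(600, 48)
        assert 5 <= ratio <= 20

    def test_reproducible_given_seed(self, sched60_small):
        a = simulate_anccr(sched60_small, AnccrParams())
        b = simulate_anccr(sched60_small, AnccrParams())
        assert np.array_equal(a.per_trial_quantity, b.per_trial_quantity)

    def test_reward_dopamine_carries_innate_meaningfulness(self, sched60_small):
        res = simulate_anccr(sched60_small, AnccrParams())
        # reward dopamine = NC + 1 >= cue dopamine = NC on every trial
        mask = ~np.isnan(res.da_reward)
        assert np.all(res.da_reward[mask] >= res.da_cue[mask])
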
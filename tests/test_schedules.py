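"""Schedule state machines and stratified samplers."""

import numpy as np
import pytest
from scipy import stats

from habitnet.schedules import (
    InsufficientDataError,
    ScheduleError,
    concurrent,
    fr,
    init_state,
    sample_vi_intervals,
    sample_vr_requirements,
    step,
    tandem,
    vi,
    vr,
    vt,
    yoke_vi_to_vr,
)


def run_session(spec, responses, rng, n_rewards=100):
    """Step a schedule through a response sequence; return delivery steps."""
    state = init_state(spec, n_rewards, rng)
    delivered = []
    for t, resp in enumerate(responses):
        if step(spec, state, resp).delivered:
            delivered.append(t)
    return delivered


class TestSamplers:
    def test_ratio_one_is_degenerate(self, rng):
        assert list(sample_vr_requirements(1, 10, rng)) == [1] * 10

    def test_vr_mean_matches_ratio(self, rng):
        req = sample_vr_requirements(15, 10_000, rng)
        assert (req >= 1).all()
        assert abs(req.mean() - 15) / 15 < 0.10

    def test_vr_matches_geometric_cdf(self, rng):
        # empirical CDF against the closed-form geometric CDF (p = 1/5)
        req = sample_vr_requirements(5, 1000, rng)
        ks = max(
            abs(np.mean(req <= k) - stats.geom.cdf(k, 0.2))
            for k in range(1, int(req.max()) + 1)
        )
        assert ks < 0.05

    def test_vi_mean_matches_interval(self, rng):
        iv = sample_vi_intervals(60, 10_000, rng)
        assert (iv > 0).all()
        assert abs(iv.mean() - 60) / 60 < 0.10

    def test_vi_matches_exponential_cdf(self, rng):
        iv = sample_vi_intervals(10, 1000, rng)
        ks = stats.kstest(iv, stats.expon(scale=10).cdf).statistic
        assert ks < 0.05

    @pytest.mark.parametrize(
        "fn,bad",
        [
            (sample_vr_requirements, dict(ratio=0.5, n_rewards=10)),
            (sample_vr_requirements, dict(ratio=5, n_rewards=0)),
            (sample_vi_intervals, dict(mean_interval=0, n_rewards=10)),
            (sample_vi_intervals, dict(mean_interval=5, n_rewards=0)),
        ],
    )
    def test_parameter_errors(self, fn, bad, rng):
        with pytest.raises(ScheduleError):
            fn(**bad, rng=rng)

    def test_permutation_preserves_marginal(self, rng):
        # stratified draw is exact up to permutation: sorted values are fixed
        a = np.sort(sample_vi_intervals(30, 500, rng))
        b = np.sort(sample_vi_intervals(30, 500, rng))
        assert np.allclose(a, b)


class TestRatioSchedules:
    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_fr_delivers_every_kth(self, k, rng):
        n = 50
        delivered = run_session(fr(k), [0] * n, rng)
        assert len(delivered) == n // k

    def test_fr1_every_operant_response(self, rng):
        responses = [0, 1, 0, 2, 0]
        delivered = run_session(fr(1), responses, rng)
        assert delivered == [0, 2, 4]

    def test_vr_counts_only_target_responses(self, rng):
        spec = vr(5)
        state = init_state(spec, 10, rng)
        state.pregenerated_sequence = np.array([2, 1])
        out = [step(spec, state, r).delivered for r in [1, 0, 1, 0, 9, 0]]
        # requirement 2 met on the 2nd operant response, then requirement 1
        assert out == [False, False, False, True, False, True]

    def test_vr_delivery_bound(self, rng):
        # deliveries after n operant responses never exceed n / min requirement
        spec = vr(4)
        state = init_state(spec, 200, rng)
        min_req = state.pregenerated_sequence.min()
        n_op = 300
        delivered = sum(step(spec, state, 0).delivered for _ in range(n_op))
        assert delivered <= n_op // min_req


class TestIntervalSchedules:
    def test_vi_holds_reward_until_collected(self, rng):
        spec = vi(5)
        state = init_state(spec, 10, rng)
        state.pregenerated_sequence = np.full(10, 3.0)
        # arm it: 3 non-operant steps
        for _ in range(3):
            assert not step(spec, state, 9).delivered
        assert state.armed
        # 100 further non-operant responses: reward held throughout
        for _ in range(100):
            assert not step(spec, state, 9).delivered
            assert state.armed
        assert step(spec, state, 0).delivered
        assert not state.armed

    def test_vi_never_outpaces_elapsed_intervals(self, rng):
        spec = vi(2)
        state = init_state(spec, 500, rng)
        responses = rng.integers(0, 3, size=400)  # operant-heavy stream
        delivered = 0
        for t, r in enumerate(responses):
            delivered += step(spec, state, int(r)).delivered
            cum = np.cumsum(state.pregenerated_sequence)
            assert delivered <= np.searchsorted(cum, t + 1) + 1

    def test_vt_independent_of_responses(self, rng):
        spec = vt(4)
        seed = 99
        seqs = []
        for responses in ([0] * 200, list(np.random.default_rng(5).integers(0, 50, 200))):
            r = np.random.default_rng(seed)
            seqs.append(run_session(spec, responses, r))
        assert seqs[0] == seqs[1] and len(seqs[0]) > 0

    def test_vi_arming_probability_increases_with_wait(self, rng):
        # hazard of becoming armed is non-decreasing in time since the last
        # operant response (exponential clock keeps running between responses)
        spec = vi(20)
        armed_after = {2: 0, 20: 0}
        for gap in armed_after:
            hits = 0
            for s in range(300):
                r = np.random.default_rng(s)
                state = init_state(spec, 5, r)
                step(spec, state, 0)  # operant response clears/collects
                for _ in range(gap):
                    step(spec, state, 9)
                hits += state.armed
            armed_after[gap] = hits
        assert armed_after[20] > armed_after[2]


class TestCompoundSchedules:
    def test_tandem_vr_then_vi0_delivers_on_third_response(self, rng):
        spec = tandem(vr(2), vi(0))
        state = init_state(spec, 5, rng)
        state.component_states[0].pregenerated_sequence = np.array([2, 2, 2])
        out = [step(spec, state, 0).delivered for _ in range(6)]
        # VR 2 consumed by responses 1-2; VI 0 arms and pays on response 3
        assert out == [False, False, True, False, False, True]

    def test_tandem_with_zero_length_component_equals_simple(self):
        plain = vi(7)
        padded = tandem(vi(7), vr(0))
        responses = list(np.random.default_rng(3).integers(0, 4, 400))
        a = run_session(plain, responses, np.random.default_rng(42))
        b = run_session(padded, responses, np.random.default_rng(42))
        assert a == b and len(a) > 5

    def test_tandem_needs_two_components(self):
        with pytest.raises(ScheduleError):
            tandem(vi(5))

    def test_all_degenerate_tandem_rejected_at_step(self, rng):
        spec = tandem(vr(0), vr(0))
        state = init_state(spec, 5, rng)
        with pytest.raises(ScheduleError):
            step(spec, state, 0)

    def test_concurrent_arms_deliver_for_own_response_only(self, rng):
        spec = concurrent(fr(1, response=0), fr(2, response=1))
        state = init_state(spec, 10, rng)
        assert step(spec, state, 0).delivered      # arm 0: FR 1
        assert not step(spec, state, 1).delivered  # arm 1 needs 2 responses
        assert step(spec, state, 1).delivered
        assert not step(spec, state, 7).delivered  # unscheduled response

    def test_concurrent_requires_distinct_responses(self):
        with pytest.raises(ScheduleError):
            concurrent(vi(5, response=0), vi(5, response=0))

    def test_concurrent_vi_vt_sums_magnitudes(self, rng):
        spec = concurrent(vi(1, response=0), vt(1))
        state = init_state(spec, 50, rng)
        total = sum(step(spec, state, 0).count for _ in range(40))
        assert total > 0


class TestYoking:
    def test_mean_of_inter_reward_intervals(self):
        assert yoke_vi_to_vr([10, 20, 40]) == 15.0

    def test_single_interval(self):
        assert yoke_vi_to_vr([5, 5 + 7]) == 7.0

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            yoke_vi_to_vr([12])
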
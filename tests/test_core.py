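"""Unit and property tests for the odds-form bias-weighted updater."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from beliefbias.core import (
    PROB_FLOOR,
    BiasPolicy,
    Evidence,
    apply_update,
    classify_evidence,
    clamp_probability,
    odds_to_probability,
    probability_to_odds,
    run_sequence,
)

probs = st.floats(min_value=1e-6, max_value=1.0 - 1e-6)
lrs = st.floats(min_value=0.05, max_value=20.0)


class TestOddsConversion:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.5, 1.0), (0.90, 9.0), (0.10, 1.0 / 9.0)],
    )
    def test_probability_to_odds_examples(self, p, expected):
        assert probability_to_odds(p) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "o, expected",
        [(1.0, 0.5), (9.0, 0.9), (0.336953, 0.2520306), (0.33695156183620373, 0.2520297)],
    )
    def test_odds_to_probability_examples(self, o, expected):
        assert odds_to_probability(o) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("bad", [-0.1, 1.2, float("nan"), float("inf")])
    def test_probability_domain_errors(self, bad):
        with pytest.raises(ValueError, match="probability"):
            probability_to_odds(bad)

    @pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
    def test_odds_domain_errors(self, bad):
        with pytest.raises(ValueError, match="odds"):
            odds_to_probability(bad)

    def test_extreme_inputs_are_clamped_not_rejected(self):
        assert probability_to_odds(0.0) == pytest.approx(PROB_FLOOR, rel=1e-6)
        assert odds_to_probability(probability_to_odds(1.0)) == 1.0 - PROB_FLOOR

    @settings(derandomize=True, max_examples=200)
    @given(p=probs)
    def test_round_trip(self, p):
        p = clamp_probability(p)
        assert odds_to_probability(probability_to_odds(p)) == pytest.approx(p, rel=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "belief, lr, expected",
        [
            (0.90, 0.72, "disconfirming"),
            (0.10, 0.72, "confirming"),
            (0.50, 0.72, "disconfirming"),  # tie at threshold counts as favouring A
            (0.50, 1.3, "confirming"),
            (0.30, 1.3, "disconfirming"),
            (0.30, 1.0, "neutral"),
            (0.90, 1.0, "neutral"),
        ],
    )
    def test_examples(self, belief, lr, expected):
        assert classify_evidence(belief, Evidence(lr)) == expected

    def test_classification_uses_pre_update_belief(self):
        # a Neutral start crosses the threshold on trial 1; every later
        # trial is judged against the already-crossed belief
        traj = run_sequence(0.5, [Evidence(0.678)] * 10, BiasPolicy.confirmation_bias(0.5))
        assert traj.classifications() == ["disconfirming"] + ["confirming"] * 9


class TestApplyUpdate:
    def test_unbiased_update_matches_direct_arithmetic(self):
        # odds 9 * 0.72 = 6.48; 6.48 / 7.48
        assert apply_update(0.9, Evidence(0.72), 1.0) == pytest.approx(0.866310, abs=1e-6)

    def test_half_weight_update(self):
        # odds 9 * sqrt(0.72) = 7.6367532; 7.6367532 / 8.6367532
        assert apply_update(0.9, Evidence(0.72), 0.5) == pytest.approx(0.8842157, abs=1e-6)

    @settings(derandomize=True, max_examples=100)
    @given(p=probs, w=st.floats(min_value=0.0, max_value=1.0))
    def test_neutral_evidence_is_identity(self, p, w):
        p = clamp_probability(p)
        assert apply_update(p, Evidence(1.0), w) == pytest.approx(p, rel=1e-12)

    @pytest.mark.parametrize("bad_w", [-0.1, 1.1, float("nan")])
    def test_invalid_weight_rejected(self, bad_w):
        with pytest.raises(ValueError, match="weight"):
            apply_update(0.5, Evidence(0.72), bad_w)

    @pytest.mark.parametrize("bad_lr", [0.0, -2.0, float("inf"), float("nan")])
    def test_invalid_likelihood_ratio_rejected(self, bad_lr):
        with pytest.raises(ValueError, match="likelihood_ratio"):
            Evidence(bad_lr)


class TestRunSequence:
    def test_loyalist_unbiased_endpoint(self):
        traj = run_sequence(0.90, [Evidence(0.72)] * 10, BiasPolicy.unbiased())
        assert traj.final_belief == pytest.approx(0.252029, abs=1e-6)

    def test_loyalist_biased_endpoint(self):
        traj = run_sequence(0.90, [Evidence(0.72)] * 10, BiasPolicy.confirmation_bias(0.5))
        assert traj.final_belief == pytest.approx(0.635230, abs=1e-5)

    def test_neutral_stream_leaves_belief_unchanged(self):
        for prior in (0.2, 0.5, 0.9):
            traj = run_sequence(prior, [Evidence(1.0)] * 10, BiasPolicy.confirmation_bias(0.3))
            assert traj.final_belief == pytest.approx(prior, rel=1e-12)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            run_sequence(0.5, [], BiasPolicy.unbiased())

    def test_trajectory_is_chained(self):
        traj = run_sequence(0.7, [Evidence(0.8), Evidence(1.4), Evidence(0.6)])
        assert traj.records[0].pre_belief == traj.initial_belief
        for prev, cur in zip(traj.records, traj.records[1:]):
            assert cur.pre_belief == prev.post_belief

    @settings(derandomize=True, max_examples=100)
    @given(p=probs, lr_list=st.lists(lrs, min_size=1, max_size=8))
    def test_unbiased_identical_to_product_formula(self, p, lr_list):
        """w = 1 everywhere must agree bit-for-bit with summing log-LRs."""
        stream = [Evidence(lr) for lr in lr_list]
        traj = run_sequence(p, stream, BiasPolicy(1.0, 1.0))
        lo = math.log(clamp_probability(p)) - math.log1p(-clamp_probability(p))
        for lr in lr_list:
            lo += 1.0 * math.log(lr)
        expected = (
            1.0 / (1.0 + math.exp(-lo)) if lo >= 0 else math.exp(lo) / (1.0 + math.exp(lo))
        )
        expected = clamp_probability(expected)
        assert traj.final_belief == expected  # bit-identical

    @settings(derandomize=True, max_examples=100)
    @given(p=probs, lr_list=st.lists(lrs, min_size=2, max_size=8), data=st.data())
    def test_unbiased_order_invariance(self, p, lr_list, data):
        stream = [Evidence(lr) for lr in lr_list]
        perm = data.draw(st.permutations(stream))
        a = run_sequence(p, stream).final_belief
        b = run_sequence(p, list(perm)).final_belief
        assert a == pytest.approx(b, abs=1e-9)

    def test_biased_order_dependence(self):
        """A mixed stream under bias: two orderings, two different finals."""
        up, down = Evidence(2.0), Evidence(0.5)
        policy = BiasPolicy.confirmation_bias(0.5)
        first = run_sequence(0.5, [up] * 5 + [down] * 5, policy).final_belief
        second = run_sequence(0.5, [down] * 5 + [up] * 5, policy).final_belief
        assert abs(first - second) > 1e-6

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_time_dilation(self, k):
        """w = 0.5 on all-disconfirming evidence: 2k biased trials == k unbiased."""
        lr = 0.9  # weak enough that belief stays above threshold throughout
        biased = run_sequence(0.95, [Evidence(lr)] * (2 * k), BiasPolicy.confirmation_bias(0.5))
        unbiased = run_sequence(0.95, [Evidence(lr)] * k, BiasPolicy.unbiased())
        assert all(c == "disconfirming" for c in biased.classifications())
        assert biased.final_belief == pytest.approx(unbiased.final_belief, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(
        p=st.floats(min_value=0.2, max_value=0.95),
        lr=st.floats(min_value=0.3, max_value=0.999),
        n=st.integers(1, 10),
    )
    def test_monotone_decline_under_contrary_evidence(self, p, lr, n):
        traj = run_sequence(p, [Evidence(lr)] * n, BiasPolicy(1.0, 0.4))
        beliefs = traj.beliefs
        assert all(b2 < b1 for b1, b2 in zip(beliefs, beliefs[1:]))

    @settings(derandomize=True, max_examples=60)
    @given(
        w=st.floats(min_value=0.01, max_value=0.99),
        lr=st.floats(min_value=0.1, max_value=0.95),
        n=st.integers(1, 12),
    )
    def test_bias_dominance_on_disconfirming_stream(self, w, lr, n):
        """Down-weighting contrary evidence keeps belief pointwise higher."""
        stream = [Evidence(lr)] * n
        biased = run_sequence(0.97, stream, BiasPolicy.confirmation_bias(w)).beliefs
        unbiased = run_sequence(0.97, stream, BiasPolicy.unbiased()).beliefs
        assert all(b >= u for b, u in zip(biased, unbiased))

    @settings(derandomize=True, max_examples=60)
    @given(p=st.floats(min_value=0.51, max_value=0.99), lr=st.floats(min_value=0.2, max_value=0.9))
    def test_zero_weight_ignores_disconfirmation(self, p, lr):
        traj = run_sequence(p, [Evidence(lr)] * 6, BiasPolicy.confirmation_bias(0.0))
        assert traj.final_belief == clamp_probability(p)

    @settings(derandomize=True, max_examples=100)
    @given(p=probs, c=st.floats(min_value=0.1, max_value=10.0))
    def test_unbiased_reversibility(self, p, c):
        traj = run_sequence(p, [Evidence(c), Evidence(1.0 / c)], BiasPolicy.unbiased())
        assert traj.final_belief == pytest.approx(clamp_probability(p), abs=1e-12)


class TestBiasPolicy:
    def test_unbiased_flag(self):
        assert BiasPolicy.unbiased().is_unbiased
        assert not BiasPolicy.confirmation_bias(0.5).is_unbiased

    @pytest.mark.parametrize("kwargs", [
        {"w_confirming": 1.2},
        {"w_disconfirming": -0.1},
        {"threshold": 0.0},
        {"threshold": 1.0},
    ])
    def test_invalid_policies_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BiasPolicy(**kwargs)
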
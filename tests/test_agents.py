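"""Proposer strategies, the noisy-maximizer responder, and the game engine."""

import math

import numpy as np
import pytest

from triadic_ug.agents import (
    ProposerState,
    ResponderConfig,
    build_strategy,
    propose_minimal,
    propose_outbidder,
    propose_reluctant_increase,
    respond_maximizer,
    simulate_experiment,
)
from triadic_ug.data_model import AcceptedSide, Condition, consecutive_views, proposer_views
from triadic_ug.design import generate_design

RNG = np.random.default_rng(0)


class TestProposerStrategies:
    @pytest.mark.parametrize(
        "state",
        [
            ProposerState(),
            ProposerState(last_own_offer=5, last_own_accepted=False),
            ProposerState(current_first_offer_seen=5),
        ],
    )
    def test_minimal_always_offers_one(self, state):
        assert propose_minimal(state) == 1

    def test_reluctant_steps_up_after_rejection(self):
        s = ProposerState(last_own_offer=3, last_own_accepted=False)
        assert propose_reluctant_increase(s, RNG) == 4

    def test_reluctant_caps_at_eight(self):
        s = ProposerState(last_own_offer=8, last_own_accepted=False)
        assert propose_reluctant_increase(s, RNG) == 8

    def test_reluctant_first_offer_is_start(self):
        assert propose_reluctant_increase(ProposerState(), RNG, start=2) == 2

    def test_reluctant_decrease_frequency_after_acceptance(self):
        rng = np.random.default_rng(1)
        s = ProposerState(last_own_offer=4, last_own_accepted=True)
        offers = [
            propose_reluctant_increase(s, rng, p_decrease_after_accept=0.5)
            for _ in range(1000)
        ]
        frac_decreased = np.mean([o == 3 for o in offers])
        assert abs(frac_decreased - 0.5) < 0.05

    def test_outbidder_enumeration_at_threshold_4(self):
        # outbids exactly first offers 0..3: keeping 8-(f+1) >= 4 grapes
        for f in range(9):
            s = ProposerState(current_first_offer_seen=f)
            offer = propose_outbidder(s, RNG, share_threshold=4)
            if f <= 3:
                assert offer == f + 1
            else:
                assert offer == 1  # minimal fallback

    def test_outbidder_delegates_without_visible_offer(self):
        assert propose_outbidder(ProposerState(), RNG) == 1

    def test_strategy_zoo_builds_nested_fallback(self):
        strat = build_strategy(
            "outbidder", share_threshold=4, fallback={"name": "constant", "offer": 3}
        )
        assert strat(ProposerState(current_first_offer_seen=7), RNG) == 3
        with pytest.raises(KeyError):
            build_strategy("nope")


class TestResponder:
    def test_exact_maximizer_limit(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            assert respond_maximizer((5, 1), rng, weber_w=0.0) is AcceptedSide.LEFT
            assert respond_maximizer((1, 5), rng, weber_w=0.0) is AcceptedSide.RIGHT

    def test_lone_valid_offer_always_accepted(self):
        rng = np.random.default_rng(3)
        assert respond_maximizer((None, 4), rng) is AcceptedSide.RIGHT
        assert respond_maximizer((4, 0), rng) is AcceptedSide.LEFT
        assert respond_maximizer((0, None), rng) is AcceptedSide.NONE

    def test_tie_broken_by_side_bias(self):
        rng = np.random.default_rng(4)
        lefts = np.mean(
            [respond_maximizer((4, 4), rng, side_bias=0.5) is AcceptedSide.LEFT
             for _ in range(1000)]
        )
        assert abs(lefts - 0.5) < 0.03

    def test_error_rate_matches_closed_form(self):
        # offers 7 vs 8: ratio 7/8, expected error 0.5 * exp(-0.125 / 0.3)
        rng = np.random.default_rng(5)
        expected = 0.5 * math.exp(-0.125 / 0.3)
        errors = np.mean(
            [respond_maximizer((7, 8), rng, weber_w=0.3) is AcceptedSide.LEFT
             for _ in range(10_000)]
        )
        assert abs(errors - expected) < 3 * math.sqrt(expected * (1 - expected) / 10_000)

    def test_argmax_property_without_ties(self):
        rng = np.random.default_rng(6)
        offers = rng.integers(1, 9, size=(10_000, 2))
        offers = offers[offers[:, 0] != offers[:, 1]]
        for left, right in offers:
            got = respond_maximizer((int(left), int(right)), rng, weber_w=0.0)
            want = AcceptedSide.LEFT if left > right else AcceptedSide.RIGHT
            assert got is want


class TestGameEngine:
    def test_identical_seeds_identical_datasets(self, schedule):
        strats = {"P1": build_strategy("reluctant_increase"), "P2": build_strategy("minimal")}
        a = simulate_experiment(schedule, strats, seed=11)
        b = simulate_experiment(schedule, strats, seed=11)
        assert a == b

    def test_minimal_agents_all_offers_one(self, schedule):
        strats = {"P1": build_strategy("minimal"), "P2": build_strategy("minimal")}
        ds = simulate_experiment(
            schedule, strats, responder=ResponderConfig(weber_w=0.0), seed=1
        )
        for t in ds:
            for offer in (t.offer_left, t.offer_right):
                assert offer in (None, 1)
            assert t.accepted_side is not AcceptedSide.NONE

    def test_outbidder_vs_minimal_wins_every_consecutive_trial(self, schedule):
        strats = {
            "P1": build_strategy("minimal"),
            "P2": build_strategy("outbidder", share_threshold=4),
        }
        ds = simulate_experiment(
            schedule, strats, responder=ResponderConfig(weber_w=0.0), seed=2
        )
        views = consecutive_views(ds)
        assert views
        for v in views:
            if v.second_proposer.endswith("P2") or v.second_proposer == "P2":
                assert v.second_offer == v.first_offer + 1  # outbids offer 1
                assert v.outbid

    def test_output_passes_dataset_validation_and_design_shape(self, study_dataset):
        # constructing ExperimentDataset already validates; check shape
        assert len(study_dataset) == 7 * 128
        for triad, sessions in (
            study_dataset.to_dataframe().groupby("triad_id")["session_index"].nunique().items()
        ):
            assert sessions == 16

    def test_reluctant_agent_always_increases_after_rejection(self):
        sch = generate_design("triadic", "P1")
        strats = {
            "P1": build_strategy("reluctant_increase", p_decrease_after_accept=0.25),
            "P2": build_strategy("reluctant_increase", p_decrease_after_accept=0.25),
        }
        ds = simulate_experiment(sch, strats, seed=3)
        increases_after_reject = [
            v.own_offer > v.previous_own_offer
            for v in proposer_views(ds)
            if v.has_predecessor and v.previous_own_accepted is False
            and v.previous_own_offer < 8
        ]
        assert increases_after_reject and all(increases_after_reject)

    def test_state_resets_between_sessions(self):
        # first offer of every session is the start value under reluctance
        sch = generate_design("triadic", "P1")
        strats = {
            "P1": build_strategy("reluctant_increase"),
            "P2": build_strategy("reluctant_increase"),
        }
        ds = simulate_experiment(sch, strats, seed=4)
        for v in proposer_views(ds):
            if not v.has_predecessor and v.condition.is_triadic and v.trial_index == 1:
                assert v.own_offer == 1

    def test_study_counts_conditions(self, study_dataset):
        counts = {c: 0 for c in Condition}
        for t in study_dataset:
            counts[t.condition] += 1
        assert counts[Condition.DYADIC] == 7 * 64
        assert counts[Condition.TRIADIC_SIMULTANEOUS] == 7 * 32
        assert counts[Condition.TRIADIC_CONSECUTIVE] == 7 * 32

    def test_timeouts_recorded_as_zero_offers(self, schedule):
        strats = {"P1": build_strategy("minimal"), "P2": build_strategy("minimal")}
        ds = simulate_experiment(schedule, strats, seed=5, timeout_prob=1.0)
        for t in ds:
            assert t.accepted_side is AcceptedSide.NONE
            for offer in (t.offer_left, t.offer_right):
                assert offer in (None, 0)
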
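"""Agent strategies and the game engine that plays a schedule into data.

This is the synthetic-data generator: proposer strategies (minimal,
reluctantly-increasing, threshold outbidder, ...) and a reward-maximizing
responder with ratio-dependent discrimination error play a
:class:`~triadic_ug.design.DesignSchedule`, producing a validated
:class:`~triadic_ug.data_model.ExperimentDataset`.

The responder error model: when two offers differ, the larger one is chosen
with probability ``1 - eps(r)`` where ``r = min/max`` and
``eps(r) = 0.5 * exp(-(1 - r) / w)``.  As the Weber-like width ``w`` goes to 0
the responder becomes an exact maximizer; errors concentrate where the two
quantities are hard to tell apart (ratio near 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .data_model import (
    MAX_GRAPES,
    AcceptedSide,
    Condition,
    ExperimentDataset,
    Side,
    Trial,
)
from .design import DesignSchedule


@dataclass
class ProposerState:
    """What a proposer carries between trials (reset at session boundaries by
    default): their own previous offer, whether it was accepted, and — in the
    consecutive-second position only — the first offer currently on the table."""

    last_own_offer: int | None = None
    last_own_accepted: bool | None = None
    current_first_offer_seen: int | None = None


def propose_minimal(state: ProposerState, rng: np.random.Generator | None = None) -> int:
    """Always offer the minimum sendable amount (1 grape)."""
    return 1


def propose_reluctant_increase(
    state: ProposerState,
    rng: np.random.Generator,
    start: int = 1,
    step_up: int = 1,
    p_decrease_after_accept: float = 0.25,
    floor: int = 1,
    cap: int = MAX_GRAPES,
) -> int:
    """Reluctantly increasing proposer: step the offer up after a rejection,
    otherwise repeat it (occasionally creeping back down after acceptance)."""
    if state.last_own_offer is None:
        return start
    if not state.last_own_accepted:
        return min(state.last_own_offer + step_up, cap)
    if rng.random() < p_decrease_after_accept:
        return max(state.last_own_offer - 1, floor)
    return state.last_own_offer


def propose_outbidder(
    state: ProposerState,
    rng: np.random.Generator,
    share_threshold: int = 4,
    fallback: Callable[[ProposerState, np.random.Generator], int] = propose_minimal,
) -> int:
    """Outbid a visible first offer ``f`` with ``f + 1`` whenever the share
    kept, ``8 - (f + 1)``, is at least ``share_threshold``; otherwise (or
    when no first offer is visible) fall back to the fallback strategy."""
    f = state.current_first_offer_seen
    if f is not None and MAX_GRAPES - (f + 1) >= share_threshold:
        return min(f + 1, MAX_GRAPES)
    return fallback(state, rng)


def propose_constant(state: ProposerState, rng: np.random.Generator, offer: int = MAX_GRAPES) -> int:
    return offer


def propose_uniform_random(
    state: ProposerState, rng: np.random.Generator, low: int = 1, high: int = MAX_GRAPES
) -> int:
    return int(rng.integers(low, high + 1))


_STRATEGIES: dict[str, Callable] = {
    "minimal": propose_minimal,
    "reluctant_increase": propose_reluctant_increase,
    "outbidder": propose_outbidder,
    "constant": propose_constant,
    "uniform_random": propose_uniform_random,
}


def build_strategy(name: str, **params) -> Callable[[ProposerState, np.random.Generator], int]:
    """Look a proposer strategy up by name and bind its parameters.

    The ``outbidder`` strategy accepts ``fallback`` either as a callable or as
    a nested ``{"name": ..., **params}`` mapping."""
    if name not in _STRATEGIES:
        raise KeyError(f"unknown strategy {name!r}; known: {sorted(_STRATEGIES)}")
    base = _STRATEGIES[name]
    if name == "outbidder" and isinstance(params.get("fallback"), Mapping):
        fb = dict(params["fallback"])
        params = {**params, "fallback": build_strategy(fb.pop("name"), **fb)}

    def strategy(state: ProposerState, rng: np.random.Generator) -> int:
        return base(state, rng, **params)

    strategy.name = name  # type: ignore[attr-defined]
    strategy.params = dict(params)  # type: ignore[attr-defined]
    return strategy


def discrimination_error(ratio: float, weber_w: float) -> float:
    """Probability of picking the smaller of two unequal offers, as a function
    of their ratio r = min/max.  Zero in the limit w -> 0."""
    if weber_w <= 0:
        return 0.0
    return 0.5 * math.exp(-(1.0 - ratio) / weber_w)


def respond_maximizer(
    offers: tuple[int | None, int | None],
    rng: np.random.Generator,
    weber_w: float = 0.0,
    side_bias: float = 0.5,
) -> AcceptedSide:
    """Reward-maximizing responder over a (left, right) pair of offers.

    A lone valid offer (>= 1 grape) is always accepted.  With two valid
    offers, the larger one is chosen with probability ``1 - eps(min/max)``;
    equal offers are broken toward LEFT with probability ``side_bias``.
    Returns NONE when no valid offer is on the table.
    """
    left, right = offers
    lv = left is not None and left >= 1
    rv = right is not None and right >= 1
    if not lv and not rv:
        return AcceptedSide.NONE
    if lv and not rv:
        return AcceptedSide.LEFT
    if rv and not lv:
        return AcceptedSide.RIGHT
    if left == right:
        return AcceptedSide.LEFT if rng.random() < side_bias else AcceptedSide.RIGHT
    larger = AcceptedSide.LEFT if left > right else AcceptedSide.RIGHT
    smaller = AcceptedSide.RIGHT if larger is AcceptedSide.LEFT else AcceptedSide.LEFT
    eps = discrimination_error(min(left, right) / max(left, right), weber_w)
    return smaller if rng.random() < eps else larger


@dataclass
class ResponderConfig:
    weber_w: float = 0.15
    side_bias: float = 0.5


def simulate_experiment(
    schedule: DesignSchedule,
    proposer_strategies: Mapping[str, Callable],
    responder: ResponderConfig | None = None,
    seed: int | None = None,
    triad_id: str = "triad1",
    proposer_ids: Mapping[str, str] | None = None,
    responder_id: str = "R",
    carry_over: bool = False,
    timeout_prob: float = 0.0,
) -> ExperimentDataset:
    """Play a schedule with the given strategies into a validated dataset.

    ``proposer_strategies`` maps proposer slots ("P1", "P2") to strategy
    callables.  Simultaneous trials draw both offers without mutual
    visibility; consecutive trials reveal the first offer to the second
    proposer before it offers.  Proposer state resets between sessions unless
    ``carry_over`` is set.  ``timeout_prob`` is the per-opportunity chance a
    proposer sends nothing (offer recorded as 0).
    """
    responder = responder or ResponderConfig()
    proposer_ids = dict(proposer_ids or {"P1": "P1", "P2": "P2"})
    rng = np.random.default_rng(seed)
    states = {slot: ProposerState() for slot in proposer_strategies}
    trials: list[Trial] = []

    def draw_offer(slot: str) -> int:
        if timeout_prob > 0 and rng.random() < timeout_prob:
            return 0
        offer = int(proposer_strategies[slot](states[slot], rng))
        return min(max(offer, 0), MAX_GRAPES)

    def update(slot: str, offer: int, accepted: bool) -> None:
        if offer >= 1:
            states[slot].last_own_offer = offer
            states[slot].last_own_accepted = accepted
        states[slot].current_first_offer_seen = None

    for sess in schedule:
        if not carry_over:
            states = {slot: ProposerState() for slot in proposer_strategies}
        left_slot, right_slot = sess.left_slot, sess.right_slot
        for t in sess.trials:
            first_side = None
            if t.condition is Condition.DYADIC:
                active = t.active_slot
                offer = draw_offer(active)
                side = sess.side_of(active)
                offers = (
                    (offer, None) if side is Side.LEFT else (None, offer)
                )
                accepted = respond_maximizer(
                    offers, rng, responder.weber_w, responder.side_bias
                )
                update(active, offer, accepted is not AcceptedSide.NONE)
            else:
                if t.condition is Condition.TRIADIC_CONSECUTIVE:
                    first = t.first_slot
                    second = _other_slot(first)
                    first_offer = draw_offer(first)
                    if first_offer >= 1:
                        states[second].current_first_offer_seen = first_offer
                    second_offer = draw_offer(second)
                    by_slot = {first: first_offer, second: second_offer}
                    first_side = sess.side_of(first)
                else:
                    by_slot = {left_slot: draw_offer(left_slot), right_slot: draw_offer(right_slot)}
                offers = (by_slot[left_slot], by_slot[right_slot])
                accepted = respond_maximizer(
                    offers, rng, responder.weber_w, responder.side_bias
                )
                update(left_slot, by_slot[left_slot], accepted is AcceptedSide.LEFT)
                update(right_slot, by_slot[right_slot], accepted is AcceptedSide.RIGHT)
            trials.append(
                Trial(
                    triad_id=triad_id,
                    session_index=sess.session_index,
                    trial_index=t.trial_index,
                    condition=t.condition,
                    left_proposer=proposer_ids[left_slot],
                    right_proposer=proposer_ids[right_slot],
                    responder=responder_id,
                    first_side=first_side,
                    offer_left=offers[0],
                    offer_right=offers[1],
                    accepted_side=accepted,
                )
            )
    return ExperimentDataset(trials)


def _other_slot(slot: str) -> str:
    return "P2" if slot == "P1" else "P1"


def simulate_study(
    n_triads: int = 7,
    proposer_strategies: Mapping[str, Callable] | None = None,
    responder: ResponderConfig | None = None,
    seed: int | None = None,
    n_triadic_start: int = 4,
) -> ExperimentDataset:
    """Simulate a whole multi-triad study under one strategy configuration.

    The first ``n_triadic_start`` triads start in the triadic block and the
    rest in the dyadic block (the study design: four of seven triads started
    triadic), with the leading proposer slot alternating across triads.
    """
    from .design import generate_design

    if proposer_strategies is None:
        proposer_strategies = {
            "P1": build_strategy("reluctant_increase"),
            "P2": build_strategy("outbidder", fallback={"name": "reluctant_increase"}),
        }
    rng = np.random.default_rng(seed)
    all_trials: list[Trial] = []
    for k in range(n_triads):
        start = "triadic" if k < n_triadic_start else "dyadic"
        leader = "P1" if k % 2 == 0 else "P2"
        schedule = generate_design(start_condition=start, first_leader=leader)
        ds = simulate_experiment(
            schedule,
            proposer_strategies,
            responder=responder,
            seed=int(rng.integers(0, 2**31 - 1)),
            triad_id=f"triad{k + 1}",
            proposer_ids={"P1": f"t{k + 1}_A", "P2": f"t{k + 1}_B"},
            responder_id=f"t{k + 1}_R",
        )
        all_trials.extend(ds.trials)
    return ExperimentDataset(all_trials)
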
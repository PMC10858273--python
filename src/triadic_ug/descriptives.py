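"""Descriptive statistics for trial-level ultimatum-game data.

Aggregate summaries reported alongside the model-based analyses: mean first
offers per condition, how often the responder took the larger of two offers,
the offer ratio on discrimination errors, responder side-choice rates in
consecutive trials, and the per-proposer total proportional offer that the
Beta models take as their response.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import pandas as pd

from .data_model import (
    MAX_GRAPES,
    AcceptedSide,
    Condition,
    ExperimentDataset,
    Side,
)

#: flag for statistics whose denominator is empty
UNDEFINED = float("nan")


def _is_sent(offer: int | None) -> bool:
    return offer is not None and offer >= 1


def mean_first_offers(dataset: ExperimentDataset) -> tuple[float, float]:
    """Mean first offer per session, split by session condition.

    The "first offer" of a session is every sent offer on its first trial:
    one per dyadic session, up to two per triadic session (both proposers
    offer on trial 1).  Returns (dyadic mean, triadic mean); NaN when a
    condition has no qualifying trials.
    """
    dyadic: list[int] = []
    triadic: list[int] = []
    for t in dataset:
        if t.trial_index != 1:
            continue
        bucket = dyadic if t.condition is Condition.DYADIC else triadic
        for offer in (t.offer_left, t.offer_right):
            if _is_sent(offer):
                bucket.append(offer)
    mean = lambda xs: sum(xs) / len(xs) if xs else UNDEFINED
    return mean(dyadic), mean(triadic)


def highest_offer_acceptance_rate(dataset: ExperimentDataset) -> float:
    """Share of unequal-offer triadic trials where the responder accepted the
    larger offer.  Equal-offer trials are excluded (no "highest" exists)."""
    hits = n = 0
    for t in dataset:
        if not t.condition.is_triadic:
            continue
        if not (_is_sent(t.offer_left) and _is_sent(t.offer_right)):
            continue
        if t.offer_left == t.offer_right or t.accepted_side is AcceptedSide.NONE:
            continue
        n += 1
        larger = AcceptedSide.LEFT if t.offer_left > t.offer_right else AcceptedSide.RIGHT
        hits += t.accepted_side is larger
    return hits / n if n else UNDEFINED


def mean_error_ratio(dataset: ExperimentDataset) -> float:
    """Mean min/max offer ratio over triadic trials where the responder took
    the smaller of two unequal offers."""
    ratios: list[float] = []
    for t in dataset:
        if not t.condition.is_triadic:
            continue
        if not (_is_sent(t.offer_left) and _is_sent(t.offer_right)):
            continue
        if t.offer_left == t.offer_right or t.accepted_side is AcceptedSide.NONE:
            continue
        smaller = AcceptedSide.LEFT if t.offer_left < t.offer_right else AcceptedSide.RIGHT
        if t.accepted_side is smaller:
            ratios.append(min(t.offer_left, t.offer_right) / max(t.offer_left, t.offer_right))
    return sum(ratios) / len(ratios) if ratios else UNDEFINED


def side_choice_rates(dataset: ExperimentDataset) -> tuple[float, float]:
    """(P(choose RIGHT | first offer from RIGHT), P(choose LEFT | first offer
    from LEFT)) over consecutive triadic trials with an acceptance."""
    counts = {Side.LEFT: [0, 0], Side.RIGHT: [0, 0]}  # side -> [same-side choices, n]
    for t in dataset:
        if t.condition is not Condition.TRIADIC_CONSECUTIVE or t.first_side is None:
            continue
        if t.accepted_side is AcceptedSide.NONE:
            continue
        c = counts[t.first_side]
        c[1] += 1
        c[0] += t.accepted_side.value == t.first_side.value
    right = counts[Side.RIGHT]
    left = counts[Side.LEFT]
    p_right = right[0] / right[1] if right[1] else UNDEFINED
    p_left = left[0] / left[1] if left[1] else UNDEFINED
    return p_right, p_left


def total_proportional_offer(
    dataset: ExperimentDataset,
    proposer: str,
    session_index: int,
    subset: str = "all",
    denominator: str = "proposer",
) -> float:
    """Grapes a proposer offered over (part of) a session, as a proportion of
    the maximum they could have offered.

    With the default per-proposer denominator, a full triadic session gives
    8 trials x 8 grapes = 64 opportunities while a full dyadic session gives
    4 x 8 = 32 (the proposer only acts on half the trials); ``subset``
    ``"first_half"`` restricts to trials 1-4 (denominators 32 / 16).  The
    alternative ``denominator="session"`` uses 64 for every full session.
    NaN when the proposer had no opportunity trials.
    """
    if subset not in ("all", "first_half"):
        raise ValueError(f"subset must be 'all' or 'first_half', got {subset!r}")
    if denominator not in ("proposer", "session"):
        raise ValueError("denominator must be 'proposer' or 'session'")
    total = 0
    opportunities = 0
    n_trials_in_subset = 0
    for t in dataset:
        if t.session_index != session_index:
            continue
        if proposer not in (t.left_proposer, t.right_proposer):
            continue
        if subset == "first_half" and t.trial_index > 4:
            continue
        n_trials_in_subset += 1
        offer = t.offer_of(proposer)
        if offer is None:
            continue  # no opportunity (inactive dyadic side)
        opportunities += 1
        total += offer
    if opportunities == 0:
        return UNDEFINED
    denom = (
        MAX_GRAPES * opportunities
        if denominator == "proposer"
        else MAX_GRAPES * n_trials_in_subset
    )
    return total / denom


def proportional_offer_table(
    dataset: ExperimentDataset, subset: str = "all", denominator: str = "proposer"
) -> pd.DataFrame:
    """Per (triad, proposer, session) total proportional offer with the
    session's block condition — the response table of the Beta models."""
    rows = []
    seen: set[tuple[str, str, int]] = set()
    sess_cond: dict[tuple[str, int], dict] = {}
    for t in dataset:
        info = sess_cond.setdefault(
            (t.triad_id, t.session_index),
            {"is_triadic": t.condition.is_triadic, "conditions": set()},
        )
        info["conditions"].add(t.condition)
        for proposer in (t.left_proposer, t.right_proposer):
            if t.offer_of(proposer) is None:
                continue
            key = (t.triad_id, proposer, t.session_index)
            if key in seen:
                continue
            seen.add(key)
    for triad_id, proposer, session in sorted(seen):
        y = total_proportional_offer(dataset, proposer, session, subset, denominator)
        if math.isnan(y):
            continue
        info = sess_cond[(triad_id, session)]
        is_triadic = info["is_triadic"]
        # first-half triadic sessions are entirely simultaneous or consecutive
        sub_condition = "dyadic"
        if is_triadic:
            first_half_conds = {
                t.condition
                for t in dataset
                if t.triad_id == triad_id and t.session_index == session and t.trial_index <= 4
            }
            sub_condition = (
                "consecutive"
                if Condition.TRIADIC_CONSECUTIVE in first_half_conds
                else "simultaneous"
            )
        rows.append(
            {
                "triad_id": triad_id,
                "proposer_id": proposer,
                "session_index": session,
                "condition": "triadic" if is_triadic else "dyadic",
                "first_half_condition": sub_condition,
                "y": y,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "triad_id",
            "proposer_id",
            "session_index",
            "condition",
            "first_half_condition",
            "y",
        ],
    )


@dataclass
class DescriptiveReport:
    mean_first_offer_dyadic: float
    mean_first_offer_triadic: float
    highest_offer_acceptance_rate: float
    mean_error_ratio: float
    side_choice_given_first_right: float
    side_choice_given_first_left: float
    n_trials: int
    n_trials_dyadic: int
    n_trials_triadic_simultaneous: int
    n_trials_triadic_consecutive: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, allow_nan=True)

    def to_text(self) -> str:
        return (
            f"mean first offer (dyadic / triadic): "
            f"{self.mean_first_offer_dyadic:.2f} / {self.mean_first_offer_triadic:.2f}\n"
            f"highest-offer acceptance rate (triadic): "
            f"{self.highest_offer_acceptance_rate:.3f}\n"
            f"mean offer ratio on errors: {self.mean_error_ratio:.3f}\n"
            f"P(choose right | first right): {self.side_choice_given_first_right:.3f}\n"
            f"P(choose left | first left): {self.side_choice_given_first_left:.3f}\n"
            f"trials: {self.n_trials} total, {self.n_trials_dyadic} dyadic, "
            f"{self.n_trials_triadic_simultaneous} simultaneous, "
            f"{self.n_trials_triadic_consecutive} consecutive\n"
        )


def describe(dataset: ExperimentDataset) -> DescriptiveReport:
    d, t = mean_first_offers(dataset)
    p_right, p_left = side_choice_rates(dataset)
    counts = {c: 0 for c in Condition}
    for trial in dataset:
        counts[trial.condition] += 1
    return DescriptiveReport(
        mean_first_offer_dyadic=d,
        mean_first_offer_triadic=t,
        highest_offer_acceptance_rate=highest_offer_acceptance_rate(dataset),
        mean_error_ratio=mean_error_ratio(dataset),
        side_choice_given_first_right=p_right,
        side_choice_given_first_left=p_left,
        n_trials=len(dataset),
        n_trials_dyadic=counts[Condition.DYADIC],
        n_trials_triadic_simultaneous=counts[Condition.TRIADIC_SIMULTANEOUS],
        n_trials_triadic_consecutive=counts[Condition.TRIADIC_CONSECUTIVE],
    )
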
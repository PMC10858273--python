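"""Counterbalanced 16-session schedule generation for one triad.

A triad runs 16 sessions of 8 trials: 8 dyadic sessions (one proposer active
per trial, alternating every two trials) and 8 triadic sessions (4 simultaneous
+ 4 consecutive trials in two contiguous blocks).  The generator produces a
schedule satisfying every aggregate counterbalance count: simultaneous-first in
half the triadic sessions, each proposer leading the consecutive block first in
half of them and going first on half the consecutive trials within each block,
each proposer opening half the dyadic sessions and offering on half the dyadic
trials, and sides swapping every two sessions so each proposer sits left for 8
sessions, 4 of each block type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .data_model import COLUMNS, Condition, Side

SLOTS = ("P1", "P2")
N_SESSIONS = 16
N_TRIALS = 8


@dataclass(frozen=True)
class TrialSlot:
    trial_index: int
    condition: Condition
    active_slot: str | None = None  # dyadic only: which proposer offers
    first_slot: str | None = None  # consecutive only: which proposer offers first


@dataclass(frozen=True)
class SessionPlan:
    session_index: int
    block: str  # "dyadic" | "triadic"
    left_slot: str  # which proposer slot sits on the left
    trials: tuple[TrialSlot, ...]

    @property
    def right_slot(self) -> str:
        return "P2" if self.left_slot == "P1" else "P1"

    def side_of(self, slot: str) -> Side:
        return Side.LEFT if slot == self.left_slot else Side.RIGHT


@dataclass
class DesignSchedule:
    sessions: list[SessionPlan] = field(default_factory=list)

    def __iter__(self):
        return iter(self.sessions)

    def __len__(self):
        return len(self.sessions)


def _other(slot: str) -> str:
    return "P2" if slot == "P1" else "P1"


def generate_design(
    start_condition: str = "dyadic",
    first_leader: str = "P1",
    seed: int | None = None,
) -> DesignSchedule:
    """Build the deterministic counterbalanced schedule.

    Parameters
    ----------
    start_condition
        Block type of session 1 (``"dyadic"`` or ``"triadic"``); blocks
        alternate session to session.
    first_leader
        Proposer slot that leads the first triadic session's consecutive block
        and opens the first dyadic session.
    seed
        Accepted for interface symmetry; the schedule is fully deterministic
        given the other arguments.
    """
    if start_condition not in ("dyadic", "triadic"):
        raise ValueError(f"start_condition must be dyadic or triadic, got {start_condition!r}")
    if first_leader not in SLOTS:
        raise ValueError(f"first_leader must be one of {SLOTS}")

    sessions: list[SessionPlan] = []
    triadic_count = 0
    dyadic_count = 0
    for s in range(1, N_SESSIONS + 1):
        parity = (s - 1) % 2
        block = start_condition if parity == 0 else ("triadic" if start_condition == "dyadic" else "dyadic")
        # sides swap every two sessions
        left_slot = "P1" if ((s - 1) // 2) % 2 == 0 else "P2"
        trials: list[TrialSlot] = []
        if block == "dyadic":
            opener = first_leader if dyadic_count % 2 == 0 else _other(first_leader)
            dyadic_count += 1
            # alternate participation every two trials: O O X X O O X X
            for i in range(N_TRIALS):
                active = opener if (i // 2) % 2 == 0 else _other(opener)
                trials.append(TrialSlot(i + 1, Condition.DYADIC, active_slot=active))
        else:
            sim_first = triadic_count % 2 == 0
            leader = first_leader if (triadic_count // 2) % 2 == 0 else _other(first_leader)
            # within the consecutive block each proposer goes first on 2 of 4
            # trials; the block leader takes trials 1 and 4 (X Y Y X)
            cons_first = [leader, _other(leader), _other(leader), leader]
            triadic_count += 1
            order = (
                [Condition.TRIADIC_SIMULTANEOUS] * 4 + [Condition.TRIADIC_CONSECUTIVE] * 4
                if sim_first
                else [Condition.TRIADIC_CONSECUTIVE] * 4 + [Condition.TRIADIC_SIMULTANEOUS] * 4
            )
            k = 0
            for i, cond in enumerate(order):
                if cond is Condition.TRIADIC_CONSECUTIVE:
                    trials.append(TrialSlot(i + 1, cond, first_slot=cons_first[k]))
                    k += 1
                else:
                    trials.append(TrialSlot(i + 1, cond))
        sessions.append(SessionPlan(s, block, left_slot, tuple(trials)))
    return DesignSchedule(sessions)


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    detail: str


def verify_design(schedule: DesignSchedule) -> list[CheckResult]:
    """Machine-check every counterbalance invariant; returns one pass/fail
    record per constraint with the observed counts."""
    checks: list[CheckResult] = []

    def add(name: str, passed: bool, detail: str) -> None:
        checks.append(CheckResult(name, bool(passed), detail))

    n_sessions = len(schedule.sessions)
    n_trials = sum(len(s.trials) for s in schedule)
    add("16 sessions x 8 trials", n_sessions == 16 and n_trials == 128,
        f"{n_sessions} sessions, {n_trials} trial slots")

    n_dyadic = sum(s.block == "dyadic" for s in schedule)
    n_triadic = sum(s.block == "triadic" for s in schedule)
    add("8 dyadic + 8 triadic sessions", n_dyadic == 8 and n_triadic == 8,
        f"{n_dyadic} dyadic, {n_triadic} triadic")

    # triadic block structure: 4+4 contiguous, sim-first in 4 of 8
    contiguous_ok = True
    sim_first_count = 0
    per_session_first_ok = True
    block_leader_counts = {s: 0 for s in SLOTS}
    for sess in schedule:
        if sess.block != "triadic":
            continue
        conds = [t.condition for t in sess.trials]
        n_sim = conds.count(Condition.TRIADIC_SIMULTANEOUS)
        n_con = conds.count(Condition.TRIADIC_CONSECUTIVE)
        halves_ok = n_sim == 4 and n_con == 4 and (
            all(c == conds[0] for c in conds[:4]) and all(c == conds[4] for c in conds[4:])
        )
        contiguous_ok &= halves_ok
        if conds and conds[0] is Condition.TRIADIC_SIMULTANEOUS:
            sim_first_count += 1
        cons = [t for t in sess.trials if t.condition is Condition.TRIADIC_CONSECUTIVE]
        firsts = [t.first_slot for t in cons]
        if firsts:
            per_session_first_ok &= all(firsts.count(s) == 2 for s in SLOTS)
            block_leader_counts[firsts[0]] = block_leader_counts.get(firsts[0], 0) + 1
    add("triadic sessions: 4 simultaneous + 4 consecutive, contiguous blocks",
        contiguous_ok and n_triadic == 8, f"contiguous={contiguous_ok}")
    add("simultaneous-first in 4 of 8 triadic sessions", sim_first_count == 4,
        f"{sim_first_count} simultaneous-first")
    add("each proposer first on 2 of 4 consecutive trials per session",
        per_session_first_ok and n_triadic == 8, f"ok={per_session_first_ok}")
    add("each proposer leads the consecutive block first in 4 triadic sessions",
        all(block_leader_counts.get(s, 0) == 4 for s in SLOTS),
        f"leader counts {block_leader_counts}")

    # dyadic structure
    dyadic_ok = True
    opener_counts = {s: 0 for s in SLOTS}
    for sess in schedule:
        if sess.block != "dyadic":
            continue
        actives = [t.active_slot for t in sess.trials]
        dyadic_ok &= all(a is not None for a in actives)
        dyadic_ok &= all(actives.count(s) == 4 for s in SLOTS)
        # alternation every two trials
        dyadic_ok &= all(
            actives[i] == actives[i + 1] for i in range(0, len(actives) - 1, 2)
        ) and all(actives[i] != actives[i + 2] for i in range(len(actives) - 2))
        if actives:
            opener_counts[actives[0]] = opener_counts.get(actives[0], 0) + 1
    add("dyadic sessions: 4 offers each, alternating every two trials",
        dyadic_ok and n_dyadic == 8, f"ok={dyadic_ok}")
    add("each proposer opens 4 of 8 dyadic sessions",
        all(opener_counts.get(s, 0) == 4 for s in SLOTS), f"opener counts {opener_counts}")

    # side assignment
    left_counts = {s: 0 for s in SLOTS}
    swap_ok = True
    side_block: dict[tuple[str, str], int] = {}
    ordered = sorted(schedule.sessions, key=lambda s: s.session_index)
    for i, sess in enumerate(ordered):
        left_counts[sess.left_slot] = left_counts.get(sess.left_slot, 0) + 1
        if i % 2 == 1:
            swap_ok &= sess.left_slot == ordered[i - 1].left_slot
        if i >= 2:
            swap_ok &= sess.left_slot != ordered[i - 2].left_slot
        for slot in SLOTS:
            side = "left" if sess.left_slot == slot else "right"
            side_block[(slot, f"{side}:{sess.block}")] = (
                side_block.get((slot, f"{side}:{sess.block}"), 0) + 1
            )
    add("each proposer sits left in 8 of 16 sessions",
        all(left_counts.get(s, 0) == 8 for s in SLOTS), f"left counts {left_counts}")
    add("sides swap every two sessions", swap_ok and n_sessions == 16, f"ok={swap_ok}")
    add("from each side: 4 triadic and 4 dyadic sessions",
        n_sessions == 16 and all(v == 4 for v in side_block.values()),
        f"{dict(side_block)}")
    return checks


def all_passed(checks: list[CheckResult]) -> bool:
    return all(c.passed for c in checks)


def schedule_frame(
    schedule: DesignSchedule,
    triad_id: str = "triad1",
    proposers: dict[str, str] | None = None,
    responder: str = "R",
) -> pd.DataFrame:
    """Export the schedule as a canonical trial table with offers and
    acceptance left blank (the plan before any behavior)."""
    proposers = proposers or {"P1": "P1", "P2": "P2"}
    rows = []
    for sess in schedule:
        left = proposers[sess.left_slot]
        right = proposers[sess.right_slot]
        for t in sess.trials:
            first_side = ""
            if t.condition is Condition.TRIADIC_CONSECUTIVE:
                first_side = sess.side_of(t.first_slot).value
            rows.append(
                {
                    "triad_id": triad_id,
                    "session_index": sess.session_index,
                    "trial_index": t.trial_index,
                    "condition": t.condition.value,
                    "left_proposer": left,
                    "right_proposer": right,
                    "responder": responder,
                    "first_side": first_side,
                    "offer_left": "",
                    "offer_right": "",
                    "accepted_side": "",
                }
            )
    return pd.DataFrame(rows, columns=COLUMNS)
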
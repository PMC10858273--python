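"""Domain types, validation and CSV serialization for trial-level ultimatum-game data.

The unit of observation is one game round (:class:`Trial`) in a repeated
dyadic/triadic ultimatum game: two proposers and one responder form a triad;
each proposer can send 1..8 grapes out of 8, keeping the remainder if the
responder accepts their offer.  Offers of 0 encode "no offer made within the
time window" and are excluded from model responses but retained in the table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

MAX_GRAPES = 8


class Condition(enum.Enum):
    """Trial condition: one proposer (dyadic) or two (triadic, offers placed
    at the same time or one after the other)."""

    DYADIC = "dyadic"
    TRIADIC_SIMULTANEOUS = "triadic_simultaneous"
    TRIADIC_CONSECUTIVE = "triadic_consecutive"

    @property
    def is_triadic(self) -> bool:
        return self is not Condition.DYADIC


class Side(enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class AcceptedSide(enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"


class ValidationError(ValueError):
    """A trial table violated the schema or a trial-level invariant."""


class SchemaError(ValidationError):
    """A mandatory column is missing or unmappable."""


@dataclass(frozen=True)
class Trial:
    """One game round.

    ``offer_left``/``offer_right`` are ``None`` when that proposer had no
    opportunity to offer (dyadic inactive side) and ``0`` when they had the
    opportunity but made no offer within the time window.
    """

    triad_id: str
    session_index: int
    trial_index: int
    condition: Condition
    left_proposer: str
    right_proposer: str
    responder: str
    first_side: Side | None = None
    offer_left: int | None = None
    offer_right: int | None = None
    accepted_side: AcceptedSide = AcceptedSide.NONE

    def __post_init__(self) -> None:
        if not 1 <= self.session_index:
            raise ValidationError(f"session_index must be >= 1, got {self.session_index}")
        if not 1 <= self.trial_index <= 8:
            raise ValidationError(f"trial_index must be in 1..8, got {self.trial_index}")
        for name, offer in (("offer_left", self.offer_left), ("offer_right", self.offer_right)):
            if offer is not None and not 0 <= offer <= MAX_GRAPES:
                raise ValidationError(f"{name} must be in 0..{MAX_GRAPES}, got {offer}")
        n_present = sum(o is not None for o in (self.offer_left, self.offer_right))
        if self.condition is Condition.DYADIC:
            if n_present != 1:
                raise ValidationError(
                    "dyadic trials must have exactly one non-missing offer, got "
                    f"{n_present}"
                )
        if self.accepted_side is AcceptedSide.LEFT and not (self.offer_left or 0) >= 1:
            raise ValidationError("accepted_side=left requires offer_left >= 1")
        if self.accepted_side is AcceptedSide.RIGHT and not (self.offer_right or 0) >= 1:
            raise ValidationError("accepted_side=right requires offer_right >= 1")
        if self.first_side is not None and self.condition is not Condition.TRIADIC_CONSECUTIVE:
            raise ValidationError("first_side is only defined for consecutive triadic trials")

    @property
    def accepted_offer(self) -> int | None:
        """The grapes the responder took, or None if nothing was accepted."""
        if self.accepted_side is AcceptedSide.LEFT:
            return self.offer_left
        if self.accepted_side is AcceptedSide.RIGHT:
            return self.offer_right
        return None

    def offer_of(self, proposer: str) -> int | None:
        if proposer == self.left_proposer:
            return self.offer_left
        if proposer == self.right_proposer:
            return self.offer_right
        return None

    def side_of(self, proposer: str) -> Side | None:
        if proposer == self.left_proposer:
            return Side.LEFT
        if proposer == self.right_proposer:
            return Side.RIGHT
        return None

    def accepted_for(self, proposer: str) -> bool:
        side = self.side_of(proposer)
        return (
            side is Side.LEFT
            and self.accepted_side is AcceptedSide.LEFT
            or side is Side.RIGHT
            and self.accepted_side is AcceptedSide.RIGHT
        )


# canonical CSV column order; this artifact defines the canonical schema and a
# dialect mapping adapts external files onto it
COLUMNS = [
    "triad_id",
    "session_index",
    "trial_index",
    "condition",
    "left_proposer",
    "right_proposer",
    "responder",
    "first_side",
    "offer_left",
    "offer_right",
    "accepted_side",
]


@dataclass
class ExperimentDataset:
    """Validated, chronologically ordered collection of trials for >= 1 triad."""

    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(t.triad_id, t.session_index, t.trial_index) for t in self.trials]
        if len(set(keys)) != len(keys):
            seen: set = set()
            dups = []
            for k in keys:
                if k in seen:
                    dups.append(k)
                seen.add(k)
            raise ValidationError(f"duplicate (triad, session, trial) keys: {dups[:5]}")
        self.trials = sorted(
            self.trials, key=lambda t: (t.triad_id, t.session_index, t.trial_index)
        )

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __eq__(self, other) -> bool:
        return isinstance(other, ExperimentDataset) and self.trials == other.trials

    @property
    def triad_ids(self) -> list[str]:
        return sorted({t.triad_id for t in self.trials})

    @property
    def roster(self) -> dict[str, dict[str, object]]:
        """Per-triad identities and roles."""
        out: dict[str, dict[str, object]] = {}
        for t in self.trials:
            r = out.setdefault(
                t.triad_id, {"proposers": set(), "responder": t.responder}
            )
            r["proposers"].update({t.left_proposer, t.right_proposer})
        return out

    def subset(self, predicate) -> "ExperimentDataset":
        return ExperimentDataset([t for t in self.trials if predicate(t)])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "triad_id": t.triad_id,
                    "session_index": t.session_index,
                    "trial_index": t.trial_index,
                    "condition": t.condition.value,
                    "left_proposer": t.left_proposer,
                    "right_proposer": t.right_proposer,
                    "responder": t.responder,
                    "first_side": t.first_side.value if t.first_side else None,
                    "offer_left": t.offer_left,
                    "offer_right": t.offer_right,
                    "accepted_side": t.accepted_side.value,
                }
            )
        return pd.DataFrame(rows, columns=COLUMNS)


@dataclass(frozen=True)
class ProposerTrialView:
    """A proposer's view of one trial in which they offered, with same-session
    lagged context: their own previous offer and its fate, and the offer the
    responder accepted on the previous trial (the "winning" offer)."""

    triad_id: str
    proposer_id: str
    session_index: int
    trial_index: int
    condition: Condition
    own_offer: int
    own_accepted: bool
    responder_id: str
    previous_own_offer: int | None = None
    previous_own_accepted: bool | None = None
    previous_winning_offer: int | None = None
    previous_winner_was_own: bool | None = None

    @property
    def has_predecessor(self) -> bool:
        return self.previous_own_offer is not None


def _parse_int(value, *, row: int, col: str) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        f = float(value)
        i = int(f)
        if i != f:
            raise ValueError
        return i
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: column {col!r} has non-integer value {value!r}")


_CONDITION_ALIASES = {c.value: c for c in Condition}
_SIDE_ALIASES = {s.value: s for s in Side}
_ACCEPTED_ALIASES = {a.value: a for a in AcceptedSide}


def load_trials(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    value_maps: Mapping[str, Mapping[str, str]] | None = None,
) -> ExperimentDataset:
    """Load a trial CSV into a validated :class:`ExperimentDataset`.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Optional mapping from canonical column names to the file's column
        names, adapting external deposits whose schema differs from the
        canonical one.  Canonical names are used as-is when absent.
    value_maps
        Optional per-column mapping of external category labels onto the
        canonical ones (e.g. ``{"condition": {"dyad": "dyadic"}}``).

    Raises
    ------
    SchemaError
        when a mandatory column is missing.
    ValidationError
        with row-numbered diagnostics when a row violates a trial invariant.
    """
    dialect = dict(dialect or {})
    value_maps = {k: dict(v) for k, v in (value_maps or {}).items()}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {canon: dialect.get(canon, canon) for canon in COLUMNS}
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}; present: {list(df.columns)}")

    trials: list[Trial] = []
    errors: list[str] = []
    for i, raw in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, raw))
        get = lambda canon: _remap(row[colmap[canon]], canon, value_maps)
        try:
            cond_raw = str(get("condition")).strip().lower()
            if cond_raw not in _CONDITION_ALIASES:
                raise ValidationError(f"unknown condition {cond_raw!r}")
            first_raw = str(get("first_side")).strip().lower()
            acc_raw = str(get("accepted_side")).strip().lower() or "none"
            if acc_raw not in _ACCEPTED_ALIASES:
                raise ValidationError(f"unknown accepted_side {acc_raw!r}")
            trials.append(
                Trial(
                    triad_id=str(get("triad_id")),
                    session_index=_parse_int(get("session_index"), row=i, col="session_index"),
                    trial_index=_parse_int(get("trial_index"), row=i, col="trial_index"),
                    condition=_CONDITION_ALIASES[cond_raw],
                    left_proposer=str(get("left_proposer")),
                    right_proposer=str(get("right_proposer")),
                    responder=str(get("responder")),
                    first_side=_SIDE_ALIASES.get(first_raw),
                    offer_left=_parse_int(get("offer_left"), row=i, col="offer_left"),
                    offer_right=_parse_int(get("offer_right"), row=i, col="offer_right"),
                    accepted_side=_ACCEPTED_ALIASES[acc_raw],
                )
            )
        except ValidationError as e:
            errors.append(f"row {i}: {e}")
    if errors:
        raise ValidationError("invalid rows:\n" + "\n".join(errors))
    return ExperimentDataset(trials)


def _remap(value, canon: str, value_maps: Mapping[str, Mapping[str, str]]):
    m = value_maps.get(canon)
    if m and str(value) in m:
        return m[str(value)]
    return value


def write_trials(dataset: ExperimentDataset, path: str | Path) -> None:
    """Write the canonical CSV (stable column order, lossless round trip;
    missing values serialized as empty fields)."""
    df = dataset.to_dataframe()
    for col in ("offer_left", "offer_right"):
        df[col] = df[col].astype("Int64")
    df.to_csv(path, index=False)


def proposer_views(dataset: ExperimentDataset) -> list[ProposerTrialView]:
    """One view per (proposer, trial in which that proposer sent an offer).

    ``previous_*`` context is computed strictly within session: the proposer's
    most recent earlier trial of the same session in which they sent an offer.
    ``previous_winning_offer`` is the offer the responder accepted on that
    previous trial (None if nothing was accepted).  Views for a proposer's
    first offered trial of a session carry no predecessor.
    """
    views: list[ProposerTrialView] = []
    by_session: dict[tuple[str, int], list[Trial]] = {}
    for t in dataset:
        by_session.setdefault((t.triad_id, t.session_index), []).append(t)
    for (triad, session), trials in sorted(by_session.items()):
        trials = sorted(trials, key=lambda t: t.trial_index)
        last: dict[str, Trial] = {}
        for t in trials:
            for proposer in (t.left_proposer, t.right_proposer):
                offer = t.offer_of(proposer)
                if offer is None or offer == 0:
                    continue  # no offer sent: no view, and does not update the lag
                prev = last.get(proposer)
                if prev is None:
                    views.append(
                        ProposerTrialView(
                            triad_id=triad,
                            proposer_id=proposer,
                            session_index=session,
                            trial_index=t.trial_index,
                            condition=t.condition,
                            own_offer=offer,
                            own_accepted=t.accepted_for(proposer),
                            responder_id=t.responder,
                        )
                    )
                else:
                    winning = prev.accepted_offer
                    views.append(
                        ProposerTrialView(
                            triad_id=triad,
                            proposer_id=proposer,
                            session_index=session,
                            trial_index=t.trial_index,
                            condition=t.condition,
                            own_offer=offer,
                            own_accepted=t.accepted_for(proposer),
                            responder_id=t.responder,
                            previous_own_offer=prev.offer_of(proposer),
                            previous_own_accepted=prev.accepted_for(proposer),
                            previous_winning_offer=winning,
                            previous_winner_was_own=(
                                prev.accepted_for(proposer) if winning is not None else None
                            ),
                        )
                    )
                last[proposer] = t
    return views


@dataclass(frozen=True)
class ConsecutiveTrialView:
    """A consecutive triadic trial seen from the second proposer's seat:
    the visible first offer, the second offer, and the second proposer's
    previous-trial outcome (same session)."""

    triad_id: str
    session_index: int
    trial_index: int
    first_proposer: str
    second_proposer: str
    responder_id: str
    first_offer: int
    second_offer: int
    outbid: bool
    second_prev_offer: int | None = None
    second_prev_accepted: bool | None = None


def consecutive_views(dataset: ExperimentDataset) -> list[ConsecutiveTrialView]:
    """Views of consecutive triadic trials where both offers were sent.

    The second proposer's previous outcome is taken from their most recent
    earlier offered trial of the same session (any condition)."""
    prev_by = {
        (v.triad_id, v.proposer_id, v.session_index, v.trial_index): v
        for v in proposer_views(dataset)
    }
    out: list[ConsecutiveTrialView] = []
    for t in dataset:
        if t.condition is not Condition.TRIADIC_CONSECUTIVE or t.first_side is None:
            continue
        if not (t.offer_left and t.offer_right):
            continue
        if t.first_side is Side.LEFT:
            first_p, second_p = t.left_proposer, t.right_proposer
            first_o, second_o = t.offer_left, t.offer_right
        else:
            first_p, second_p = t.right_proposer, t.left_proposer
            first_o, second_o = t.offer_right, t.offer_left
        v = prev_by.get((t.triad_id, second_p, t.session_index, t.trial_index))
        out.append(
            ConsecutiveTrialView(
                triad_id=t.triad_id,
                session_index=t.session_index,
                trial_index=t.trial_index,
                first_proposer=first_p,
                second_proposer=second_p,
                responder_id=t.responder,
                first_offer=first_o,
                second_offer=second_o,
                outbid=second_o > first_o,
                second_prev_offer=v.previous_own_offer if v else None,
                second_prev_accepted=v.previous_own_accepted if v else None,
            )
        )
    return out
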
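"""Trial/dataset validation, CSV round-tripping, and lagged proposer views."""

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from triadic_ug.data_model import (
    AcceptedSide,
    Condition,
    ExperimentDataset,
    SchemaError,
    Side,
    Trial,
    ValidationError,
    consecutive_views,
    load_trials,
    proposer_views,
    write_trials,
)

HEADER = (
    "triad_id,session_index,trial_index,condition,left_proposer,right_proposer,"
    "responder,first_side,offer_left,offer_right,accepted_side"
)


def make_trial(**kw):
    base = dict(
        triad_id="t1",
        session_index=1,
        trial_index=1,
        condition=Condition.TRIADIC_SIMULTANEOUS,
        left_proposer="A",
        right_proposer="B",
        responder="R",
        offer_left=5,
        offer_right=1,
        accepted_side=AcceptedSide.LEFT,
    )
    base.update(kw)
    return Trial(**base)


class TestTrialInvariants:
    def test_valid_triadic_trial(self):
        t = make_trial()
        assert t.accepted_offer == 5
        assert t.accepted_for("A") and not t.accepted_for("B")

    @pytest.mark.parametrize(
        "kw",
        [
            dict(offer_left=9),
            dict(offer_left=-1),
            dict(trial_index=9),
            dict(trial_index=0),
            dict(session_index=0),
            dict(condition=Condition.DYADIC),  # two offers on a dyadic trial
            dict(offer_left=0, accepted_side=AcceptedSide.LEFT),
            dict(first_side=Side.LEFT),  # first_side on a simultaneous trial
        ],
    )
    def test_invalid_trials_rejected(self, kw):
        with pytest.raises(ValidationError):
            make_trial(**kw)

    def test_dyadic_trial_needs_exactly_one_offer(self):
        t = make_trial(
            condition=Condition.DYADIC, offer_right=None, accepted_side=AcceptedSide.LEFT
        )
        assert t.offer_of("A") == 5 and t.offer_of("B") is None

    def test_duplicate_keys_rejected(self):
        t = make_trial()
        with pytest.raises(ValidationError, match="duplicate"):
            ExperimentDataset([t, make_trial()])


class TestCSV:
    def test_canonical_single_row(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text(HEADER + "\nt1,1,1,triadic_simultaneous,A,B,R,,5,1,left\n")
        ds = load_trials(p)
        assert len(ds) == 1
        assert ds.trials[0].accepted_side is AcceptedSide.LEFT
        assert ds.trials[0].offer_right == 1

    def test_out_of_range_offer_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(HEADER + "\nt1,1,1,triadic_simultaneous,A,B,R,,9,1,right\n")
        with pytest.raises(ValidationError, match="row 1"):
            load_trials(p)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "cols.csv"
        p.write_text("triad_id,session_index\n t1,1\n")
        with pytest.raises(SchemaError, match="missing mandatory"):
            load_trials(p)

    def test_dialect_adapts_external_names(self, tmp_path):
        p = tmp_path / "ext.csv"
        p.write_text(
            "grp,sess,trl,cond,left_proposer,right_proposer,responder,"
            "first_side,offer_left,offer_right,accepted_side\n"
            "t1,1,1,sim,A,B,R,,5,1,left\n"
        )
        ds = load_trials(
            p,
            dialect={"triad_id": "grp", "session_index": "sess", "trial_index": "trl",
                     "condition": "cond"},
            value_maps={"condition": {"sim": "triadic_simultaneous"}},
        )
        assert ds.trials[0].condition is Condition.TRIADIC_SIMULTANEOUS

    def test_empty_dataset_round_trips_as_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        write_trials(ExperimentDataset([]), p)
        assert p.read_text().strip() == HEADER
        assert len(load_trials(p)) == 0

    def test_missing_offer_round_trips_as_empty_field(self, tmp_path):
        t = make_trial(
            condition=Condition.DYADIC, offer_right=None, accepted_side=AcceptedSide.LEFT
        )
        p = tmp_path / "na.csv"
        write_trials(ExperimentDataset([t]), p)
        ds = load_trials(p)
        assert ds.trials[0].offer_right is None

    def test_round_trip_simulated_dataset_lossless(self, tmp_path, study_dataset):
        p = tmp_path / "sim.csv"
        write_trials(study_dataset, p)
        assert load_trials(p) == study_dataset


@st.composite
def datasets(draw):
    """Arbitrary small valid datasets (one triad, mixed conditions)."""
    trials = []
    n_sessions = draw(st.integers(1, 3))
    for s in range(1, n_sessions + 1):
        cond = draw(st.sampled_from(list(Condition)))
        n_trials = draw(st.integers(1, 4))
        for i in range(1, n_trials + 1):
            if cond is Condition.DYADIC:
                offer = draw(st.integers(0, 8))
                left = draw(st.booleans())
                acc = AcceptedSide.NONE
                if offer >= 1 and draw(st.booleans()):
                    acc = AcceptedSide.LEFT if left else AcceptedSide.RIGHT
                trials.append(
                    make_trial(
                        session_index=s, trial_index=i, condition=cond,
                        offer_left=offer if left else None,
                        offer_right=None if left else offer,
                        accepted_side=acc,
                    )
                )
            else:
                ol = draw(st.integers(0, 8))
                orr = draw(st.integers(0, 8))
                choices = [AcceptedSide.NONE]
                if ol >= 1:
                    choices.append(AcceptedSide.LEFT)
                if orr >= 1:
                    choices.append(AcceptedSide.RIGHT)
                first = None
                if cond is Condition.TRIADIC_CONSECUTIVE:
                    first = draw(st.sampled_from(list(Side)))
                trials.append(
                    make_trial(
                        session_index=s, trial_index=i, condition=cond,
                        offer_left=ol, offer_right=orr,
                        accepted_side=draw(st.sampled_from(choices)),
                        first_side=first,
                    )
                )
    return ExperimentDataset(trials)


@given(datasets())
@settings(max_examples=40, deadline=None, suppress_health_check=[HealthCheck.function_scoped_fixture])
def test_round_trip_lossless_property(tmp_path_factory, ds):
    p = tmp_path_factory.mktemp("rt") / "ds.csv"
    write_trials(ds, p)
    assert load_trials(p) == ds


@given(datasets())
@settings(max_examples=40, deadline=None)
def test_proposer_views_stay_within_session(ds):
    views = proposer_views(ds)
    by_key = {}
    for v in views:
        by_key.setdefault((v.proposer_id, v.session_index), []).append(v)
    for (_, session), vs in by_key.items():
        assert all(v.session_index == session for v in vs)
        assert not vs[0].has_predecessor  # first offered trial has no lag
        # count of views with predecessor = offers - 1 per proposer-session
        assert sum(v.has_predecessor for v in vs) == len(vs) - 1


class TestProposerViews:
    def test_lagged_own_offers(self):
        trials = [
            make_trial(trial_index=i, offer_left=i, offer_right=1,
                       accepted_side=AcceptedSide.LEFT)
            for i in range(1, 5)
        ]
        views = [v for v in proposer_views(ExperimentDataset(trials)) if v.proposer_id == "A"]
        assert [v.previous_own_offer for v in views] == [None, 1, 2, 3]

    def test_previous_winning_offer_from_other_proposer(self):
        t1 = make_trial(trial_index=1, offer_left=2, offer_right=6,
                        accepted_side=AcceptedSide.RIGHT)
        t2 = make_trial(trial_index=2, offer_left=3, offer_right=4,
                        accepted_side=AcceptedSide.RIGHT)
        views = proposer_views(ExperimentDataset([t1, t2]))
        v = next(v for v in views if v.proposer_id == "A" and v.trial_index == 2)
        assert v.previous_winning_offer == 6
        assert v.previous_winner_was_own is False

    def test_zero_offer_trials_excluded_and_skip_lag(self):
        t1 = make_trial(trial_index=1, offer_left=3, offer_right=1,
                        accepted_side=AcceptedSide.LEFT)
        t2 = make_trial(trial_index=2, offer_left=0, offer_right=1,
                        accepted_side=AcceptedSide.RIGHT)
        t3 = make_trial(trial_index=3, offer_left=5, offer_right=1,
                        accepted_side=AcceptedSide.LEFT)
        views = [v for v in proposer_views(ExperimentDataset([t1, t2, t3]))
                 if v.proposer_id == "A"]
        assert [v.trial_index for v in views] == [1, 3]
        assert views[1].previous_own_offer == 3  # lag skips the no-offer trial

    def test_consecutive_views_identify_roles(self):
        t = make_trial(condition=Condition.TRIADIC_CONSECUTIVE, first_side=Side.RIGHT,
                       offer_left=4, offer_right=2, accepted_side=AcceptedSide.LEFT)
        (v,) = consecutive_views(ExperimentDataset([t]))
        assert v.first_proposer == "B" and v.second_proposer == "A"
        assert v.first_offer == 2 and v.second_offer == 4 and v.outbid
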
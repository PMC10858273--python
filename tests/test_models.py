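"""Structural and contract tests of the model suite on simulated data.

Full parameter-recovery coverage lives in the acceptance suite; here each
model is checked on qualitative simulator contracts (known agent behavior
must show up in the posterior) and on invariances.
"""

import numpy as np
import pandas as pd
import pytest

from triadic_ug.agents import ResponderConfig, build_strategy, simulate_experiment
from triadic_ug.baseline_outbid import baseline_closed_form, preference_from_dataset
from triadic_ug.design import generate_design
from triadic_ug.models import (
    fit_increase_after_outcome_model,
    fit_last_vs_first_model,
    fit_match_winner_model,
    fit_outbid_simple,
    fit_outbid_stratified,
    fit_total_offer_model,
    prepare_last_vs_first,
    prepare_outbid,
    simulate_outbid_table,
    simulate_outcome_table,
    simulate_total_offer_table,
)

from conftest import fast_config


@pytest.fixture(scope="module")
def reluctant_dataset():
    """3 triads of reluctant-increase agents (always step up after rejection)."""
    from triadic_ug.agents import simulate_study

    strats = {
        "P1": build_strategy("reluctant_increase", p_decrease_after_accept=0.3),
        "P2": build_strategy("reluctant_increase", p_decrease_after_accept=0.3),
    }
    return simulate_study(n_triads=3, proposer_strategies=strats, seed=11)


class TestTotalOffer:
    def test_no_signal_difference_straddles_zero(self):
        rng = np.random.default_rng(1)
        params = dict(b0_d=-0.5, b0_t=-0.5, b1_d=0.0, b1_t=0.0, g0_d=2.5, g0_t=2.5,
                      sigma_mu=0.2, sigma_phi=0.2)
        table = simulate_total_offer_table(params, rng)
        fit = fit_total_offer_model(table, config=fast_config(1))
        assert fit.derived["diff_hpd"].contains(0.0)
        assert 0.1 < fit.derived["p_dyadic_gt_triadic"] < 0.9

    def test_out_of_range_response_rejected(self):
        table = pd.DataFrame(
            {
                "triad_id": ["t1"] * 3,
                "proposer_id": ["p"] * 3,
                "session_index": [1, 2, 3],
                "condition": ["dyadic"] * 3,
                "first_half_condition": ["dyadic"] * 3,
                "y": [0.2, 0.4, 1.4],
            }
        )
        with pytest.raises(ValueError, match="lie in"):
            fit_total_offer_model(table, config=fast_config(1))

    def test_first_half_model_estimates_contrast(self):
        rng = np.random.default_rng(2)
        params = dict(b0_d=-0.5, b0_t=-0.5, b1_d=0.0, b1_t=0.0, g0_d=2.5, g0_t=2.5,
                      bx=1.0, sigma_mu=0.2, sigma_phi=0.2)
        table = simulate_total_offer_table(params, rng, subset="first_half")
        fit = fit_total_offer_model(table, subset="first_half", config=fast_config(2))
        assert fit.derived["pp_mean_consecutive"] > fit.derived["pp_mean_simultaneous"]
        assert fit.derived["p_consecutive_gt_simultaneous"] > 0.8

    def test_single_triad_warns(self):
        rng = np.random.default_rng(3)
        params = dict(b0_d=-0.5, b0_t=-0.5, b1_d=0.0, b1_t=0.0, g0_d=2.5, g0_t=2.5,
                      sigma_mu=0.2, sigma_phi=0.2)
        table = simulate_total_offer_table(params, rng, n_triads=1)
        fit = fit_total_offer_model(table, config=fast_config(3))
        assert any("fewer than 2 triads" in w for w in fit.warnings)


class TestLastVsFirst:
    def test_session_shift_invariance(self):
        rng = np.random.default_rng(4)
        params = dict(a0=-0.6, a_cond=0.9, a_s=0.2, a_cs=0.1, sigma_p=0.4)
        from triadic_ug.models import simulate_last_vs_first_table

        table = simulate_last_vs_first_table(params, rng)
        fit_a = fit_last_vs_first_model(table, config=fast_config(4))
        shifted = table.copy()
        shifted["session_index"] = shifted["session_index"] + 100
        fit_b = fit_last_vs_first_model(shifted, config=fast_config(4))
        assert fit_a.derived["p_triadic_marginal"] == pytest.approx(
            fit_b.derived["p_triadic_marginal"], abs=1e-12
        )

    def test_prepare_drops_single_offer_sessions(self, study_dataset):
        table = prepare_last_vs_first(study_dataset)
        assert (table["n_offers"] >= 2).all()
        # every proposer-session of the simulated study has >= 2 offers
        assert len(table) == 7 * 16 * 2


class TestIncreaseAfterOutcome:
    def test_reluctant_agents_increase_after_rejection(self, reluctant_dataset):
        fit = fit_increase_after_outcome_model(reluctant_dataset, config=fast_config(5))
        assert fit.derived["p_increase_after_reject"] > 0.9
        assert (
            fit.derived["p_increase_after_reject_gt_increase_after_accept"] > 0.95
        )

    def test_outcome_blind_agents_give_null(self):
        rng = np.random.default_rng(6)
        params = dict(a0=0.0, a_prev=0.0, a_s=0.0, a_ps=0.0, sigma_p=0.3)
        table = simulate_outcome_table(params, rng)
        fit = fit_increase_after_outcome_model(table, config=fast_config(6))
        p = fit.derived["p_increase_after_reject_gt_increase_after_accept"]
        assert 0.05 < p < 0.95


class TestMatchWinner:
    def test_copycats_always_match(self, study_dataset):
        # response recomputed from data: force y = 1 to emulate copycat agents
        from triadic_ug.models import prepare_match_winner

        table = prepare_match_winner(study_dataset)
        table["y"] = 1
        fit = fit_match_winner_model(table, config=fast_config(7))
        assert fit.derived["p_match_given_own_win"] > 0.9
        assert fit.derived["p_match_given_other_win"] > 0.9

    def test_minimal_proposers_never_match_high_winners(self):
        sch = generate_design("triadic", "P1")
        strats = {
            "P1": build_strategy("constant", offer=5),
            "P2": build_strategy("minimal"),
        }
        ds = simulate_experiment(sch, strats, responder=ResponderConfig(weber_w=0.0), seed=8)
        from triadic_ug.models import prepare_match_winner

        table = prepare_match_winner(ds)
        minimal = table[table["proposer_id"] == "P2"]
        assert minimal["y"].sum() == 0  # offer 1 never matches winner 5


class TestOutbidSimple:
    def test_outbidder_agents_dominate(self):
        sch = generate_design("triadic", "P1")
        strats = {
            "P1": build_strategy("minimal"),
            "P2": build_strategy("outbidder", share_threshold=4),
        }
        ds = simulate_experiment(sch, strats, responder=ResponderConfig(weber_w=0.0), seed=9)
        table = prepare_outbid(ds)
        # P2 outbids every trial it acts second; P1 (minimal) never does
        p2 = table[table["second_proposer"] == "P2"]
        assert p2["y"].mean() == 1.0

    def test_iid_offers_give_below_half(self):
        # strict inequality: ties count against outbidding
        rng = np.random.default_rng(10)
        params = dict(a0=0.0, a_s=0.0, sigma_p=0.0)
        table = simulate_outbid_table(params, rng)
        pref = np.array([0.0, 0.3, 0.22, 0.16, 0.12, 0.08, 0.06, 0.04, 0.02])
        pref /= pref.sum()
        first = rng.choice(9, 20_000, p=pref)
        second = rng.choice(9, 20_000, p=pref)
        assert (second > first).mean() < 0.5  # enumeration oracle of the tie rule

    def test_fixed_seed_refit_identical(self, study_dataset):
        a = fit_outbid_simple(study_dataset, config=fast_config(11))
        b = fit_outbid_simple(study_dataset, config=fast_config(11))
        assert a.derived["p_positive_session_slope"] == b.derived["p_positive_session_slope"]
        pd.testing.assert_frame_equal(a.tables["per_session"], b.tables["per_session"])


class TestOutbidStratified:
    @pytest.fixture(scope="class")
    def monotone_fit(self):
        rng = np.random.default_rng(12)
        # true outbid probabilities fall ~0.9 -> 0.05 across first offers
        cum_drop = np.linspace(0, 5.0, 9)
        params = dict(a0=2.2, a_prev=0.0, a_s=0.0, a_ps=0.0, sigma_p=0.3, cum_drop=cum_drop)
        table = simulate_outbid_table(params, rng, stratified=True, n_triads=14)
        return fit_outbid_stratified(table, config=fast_config(12), pair_effects=False)

    def test_posterior_means_monotone_and_rank_correlated(self, monotone_fit):
        final = monotone_fit.tables["final_session"]
        probs = final[final["prev_accepted"] == 0].sort_values("first_offer")["p_outbid"]
        assert (np.diff(probs) <= 1e-9).all()
        # perfect rank agreement with the strictly decreasing truth
        assert probs.is_monotonic_decreasing

    def test_monotonicity_holds_for_every_posterior_draw(self, monotone_fit):
        from triadic_ug.models import _BernoulliMixedModel

        draws = monotone_fit.draws
        b = np.exp(draws.get("log_b"))
        assert (b > 0).all()
        w = draws.vector("w")
        helper = _BernoulliMixedModel(
            np.zeros(1), np.zeros((1, 1)), ["a0"], np.zeros(1, dtype=int), 1,
            mono_cat=np.zeros(1, dtype=int),
        )
        zeta, _ = helper._simplex(w)
        assert (zeta >= 0).all()
        np.testing.assert_allclose(zeta.sum(axis=1), 1.0, atol=1e-10)
        # linear predictor - b * cumsum(zeta) is non-increasing per draw
        eta_path = -b[:, None] * np.cumsum(zeta, axis=1)
        assert (np.diff(eta_path, axis=1) <= 1e-12).all()

    def test_unobserved_categories_flagged_extrapolated(self, study_dataset):
        fit = fit_outbid_stratified(study_dataset, config=fast_config(13))
        final = fit.tables["final_session"]
        observed = prepare_outbid(study_dataset, require_prev=True)
        seen = set(zip(observed["prev_accepted"], observed["first_offer"]))
        for _, row in final.iterrows():
            assert row["extrapolated"] == ((row["prev_accepted"], row["first_offer"]) not in seen)

    def test_baseline_comparison_columns(self, study_dataset):
        pref = preference_from_dataset(study_dataset)
        baseline = baseline_closed_form(pref)
        fit = fit_outbid_stratified(study_dataset, config=fast_config(14), baseline=baseline)
        final = fit.tables["final_session"]
        assert {"baseline", "p_gt_baseline"} <= set(final.columns)
        np.testing.assert_allclose(
            final[final["prev_accepted"] == 0].sort_values("first_offer")["baseline"],
            baseline.prob,
        )
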
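"""The Bayesian model suite.

Six hierarchical models of proposer behavior in the repeated ultimatum game:

* two Beta regressions of the *total proportional offer* per proposer-session
  (full data: dyadic vs triadic; first-half data: adds a simultaneous vs
  consecutive contrast), with condition-specific means, precisions and session
  slopes and triad-level random deviations on both the mean and the precision;
* a Bernoulli model of *last offer > first offer* within a session, with
  interacting condition and session effects;
* two Bernoulli models of trial-to-trial escalation in triadic sessions
  (*offer > own previous offer*, and *offer >= previously accepted offer*),
  with previous-outcome x session effects;
* two Bernoulli models of *outbidding* in consecutive trials: a simple
  session-effect model, and a stratified model where the first offer enters as
  a monotonic ordinal effect — a non-negative magnitude times the cumulative
  sum of a simplex over first-offer increments, so predicted outbid
  probability can only fall as the first offer grows, at an estimated,
  non-constant rate.

Every model gets proposer (or triad) random intercepts, non-centered, and is
sampled with the ensemble backend in :mod:`triadic_ug.bayes`.  Each ``fit_*``
function accepts either a raw :class:`~triadic_ug.data_model.ExperimentDataset`
or an already-prepared response table (as produced by the ``prepare_*``
helpers), which is what the parameter-recovery simulations feed in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln

from .baseline_outbid import BaselineTable, N_CATEGORIES
from .bayes import (
    HPDInterval,
    PosteriorDraws,
    SamplerConfig,
    hpd_interval,
    invlogit,
    marginal_invlogit,
    prob_direction,
    sample_posterior,
)
from .data_model import ExperimentDataset, consecutive_views, proposer_views
from .descriptives import proportional_offer_table

N_SESSIONS = 16

# weakly-informative defaults on the logit / log scales; recorded in every
# FitResult for auditability
PRIORS = {
    "fixed_effect_sd": 2.5,
    "random_scale": "half-Normal(1)",
    "monotonic_magnitude": "half-Normal(2)",
    "simplex": "Dirichlet(1,...,1)",
}


@dataclass
class FitResult:
    """A fitted model: posterior draws, derived summaries, and provenance."""

    model: str
    draws: PosteriorDraws
    derived: dict = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    priors: dict = field(default_factory=lambda: dict(PRIORS))
    n_obs: int = 0
    warnings: list[str] = field(default_factory=list)

    def summary_dict(self) -> dict:
        out = {"model": self.model, "n_obs": self.n_obs}
        for k, v in self.derived.items():
            if isinstance(v, HPDInterval):
                out[k] = [v.lower, v.upper]
            elif isinstance(v, (int, float, np.floating)):
                out[k] = float(v)
        return out


def _standardize_sessions(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    sd = s.std()
    return (s - s.mean()) / sd if sd > 0 else s - s.mean()


def _session_grid(obs_sessions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Observed session labels and their standardized values under the fitted
    data's scaling.  Using observed labels (not a fixed 1..16) makes derived
    summaries invariant to shifting all session labels by a constant."""
    s = np.asarray(obs_sessions, dtype=float)
    mu, sd = s.mean(), s.std()
    grid = np.unique(s)
    return grid, (grid - mu) / sd if sd > 0 else grid - mu


def _normal_lp(x: np.ndarray, sd: float) -> np.ndarray:
    return -0.5 * np.sum((x / sd) ** 2, axis=-1)


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # sum_i [ y eta - log(1 + e^eta) ], stable
    return np.sum(y * eta - np.logaddexp(0.0, eta), axis=-1)


def _compress_unit(y: np.ndarray) -> np.ndarray:
    """Shrink proportions from [0,1] into (0,1): (y (N-1) + 0.5) / N."""
    n = y.size
    return (y * (n - 1) + 0.5) / n


def _exp_clip(x):
    return np.exp(np.clip(x, -30.0, 30.0))


def _codes(values: Sequence) -> tuple[np.ndarray, list]:
    cat = pd.Categorical(values)
    return cat.codes.astype(int), list(cat.categories)


# --------------------------------------------------------------------------
# total proportional offer (Beta, modeled precision)
# --------------------------------------------------------------------------


class _TotalOfferModel:
    """y ~ Beta(mu * phi, (1 - mu) * phi) with
    logit(mu) = b0_c + b1_c * s + bx * x + sigma_mu * z_mu[triad] and
    log(phi) = g0_c + sigma_phi * z_phi[triad]."""

    def __init__(self, y, triadic, s, x, triad_idx, n_triads, include_x):
        self.y = y
        self.logit_names = None
        self.triadic = triadic
        self.s = s
        self.x = x
        self.triad_idx = triad_idx
        self.T = n_triads
        self.include_x = include_x
        names = ["b0_d", "b0_t", "b1_d", "b1_t", "g0_d", "g0_t"]
        if include_x:
            names.append("bx")
        names += ["log_sigma_mu", "log_sigma_phi"]
        names += [f"z_mu[{i}]" for i in range(n_triads)]
        names += [f"z_phi[{i}]" for i in range(n_triads)]
        self.param_names = names
        self.ndim = len(names)
        self._nfix = 7 if include_x else 6

    def unpack(self, theta):
        nf = self._nfix
        fixed = theta[:, :nf]
        ls_mu = theta[:, nf]
        ls_phi = theta[:, nf + 1]
        z_mu = theta[:, nf + 2 : nf + 2 + self.T]
        z_phi = theta[:, nf + 2 + self.T :]
        return fixed, ls_mu, ls_phi, z_mu, z_phi

    def log_prob(self, theta):
        theta = np.atleast_2d(theta)
        fixed, ls_mu, ls_phi, z_mu, z_phi = self.unpack(theta)
        sigma_mu = np.exp(np.clip(ls_mu, -30.0, 30.0))
        sigma_phi = np.exp(np.clip(ls_phi, -30.0, 30.0))
        b0 = np.where(self.triadic, fixed[:, 1:2], fixed[:, 0:1])
        b1 = np.where(self.triadic, fixed[:, 3:4], fixed[:, 2:3])
        g0 = np.where(self.triadic, fixed[:, 5:6], fixed[:, 4:5])
        eta = b0 + b1 * self.s + sigma_mu[:, None] * z_mu[:, self.triad_idx]
        if self.include_x:
            eta = eta + fixed[:, 6:7] * self.x
        mu = np.clip(invlogit(eta), 1e-12, 1 - 1e-12)
        log_phi = np.clip(g0 + sigma_phi[:, None] * z_phi[:, self.triad_idx], -30.0, 30.0)
        phi = np.exp(log_phi)
        a = mu * phi
        b = (1.0 - mu) * phi
        ll = np.sum(
            (a - 1) * np.log(self.y) + (b - 1) * np.log1p(-self.y) - betaln(a, b),
            axis=-1,
        )
        lp = _normal_lp(fixed, 2.5)
        lp += -0.5 * sigma_mu**2 + ls_mu - 0.5 * sigma_phi**2 + ls_phi
        lp += _normal_lp(z_mu, 1.0) + _normal_lp(z_phi, 1.0)
        out = ll + lp
        return np.where(np.isfinite(out), out, -np.inf)

    def initial(self, rng, nwalkers):
        p0 = 0.2 * rng.standard_normal((nwalkers, self.ndim))
        nf = self._nfix
        p0[:, 4:6] += 1.0  # log-precision start above 1
        p0[:, nf] -= 1.0  # small random-effect scales
        p0[:, nf + 1] -= 1.0
        return p0


def prepare_total_offer(
    dataset: ExperimentDataset, subset: str = "full", denominator: str = "proposer"
) -> pd.DataFrame:
    sub = "all" if subset == "full" else "first_half"
    return proportional_offer_table(dataset, subset=sub, denominator=denominator)


def fit_total_offer_model(
    data: ExperimentDataset | pd.DataFrame,
    subset: str = "full",
    config: SamplerConfig | None = None,
    denominator: str = "proposer",
) -> FitResult:
    """Fit the Beta total-proportional-offer model.

    ``subset="full"`` contrasts the dyadic and triadic conditions;
    ``subset="first_half"`` restricts to trials 1-4 and adds the
    consecutive (+0.5) vs simultaneous (-0.5) contrast (0 for dyadic rows).
    Derived quantities are mid-study posterior predictive distributions of the
    response per condition and their difference.
    """
    if subset not in ("full", "first_half"):
        raise ValueError("subset must be 'full' or 'first_half'")
    table = (
        prepare_total_offer(data, subset, denominator)
        if isinstance(data, ExperimentDataset)
        else data.copy()
    )
    warnings_list: list[str] = []
    if table["triad_id"].nunique() < 2:
        warnings_list.append("fewer than 2 triads: random-effect scales weakly identified")
    y_raw = table["y"].to_numpy(dtype=float)
    if np.any((y_raw < 0) | (y_raw > 1)):
        raise ValueError("responses must lie in [0, 1] before boundary compression")
    y = _compress_unit(y_raw)
    triadic = (table["condition"] == "triadic").to_numpy()
    s = _standardize_sessions(table["session_index"].to_numpy())
    include_x = subset == "first_half"
    x = np.zeros_like(s)
    if include_x:
        x = np.where(
            triadic,
            np.where(table["first_half_condition"] == "consecutive", 0.5, -0.5),
            0.0,
        )
    triad_idx, triads = _codes(table["triad_id"])
    model = _TotalOfferModel(y, triadic, s, x, triad_idx, len(triads), include_x)
    draws = sample_posterior(model, config)

    rng = np.random.default_rng((config.seed if config else None) or 0)
    fixed = {n: draws.get(n) for n in ("b0_d", "b0_t", "b1_d", "b1_t", "g0_d", "g0_t")}
    sigma_mu = np.exp(draws.get("log_sigma_mu"))
    sigma_phi = np.exp(draws.get("log_sigma_phi"))
    nd = draws.n_draws
    z1 = rng.standard_normal(nd)
    z2 = rng.standard_normal(nd)

    def predictive(b0, g0, shift=0.0):
        mu = invlogit(b0 + shift + sigma_mu * z1)
        phi = np.exp(g0 + sigma_phi * z2)
        return rng.beta(mu * phi, (1 - mu) * phi)

    derived: dict = {}
    if not include_x:
        y_d = predictive(fixed["b0_d"], fixed["g0_d"])
        y_t = predictive(fixed["b0_t"], fixed["g0_t"])
        derived["pp_mean_dyadic"] = float(y_d.mean())
        derived["pp_hpd_dyadic"] = hpd_interval(y_d)
        derived["pp_mean_triadic"] = float(y_t.mean())
        derived["pp_hpd_triadic"] = hpd_interval(y_t)
        diff = y_d - y_t
        derived["diff_mean"] = float(diff.mean())
        derived["diff_hpd"] = hpd_interval(diff)
        derived["p_dyadic_gt_triadic"] = prob_direction(diff)
    else:
        bx = draws.get("bx")
        y_con = predictive(fixed["b0_t"], fixed["g0_t"], shift=0.5 * bx)
        y_sim = predictive(fixed["b0_t"], fixed["g0_t"], shift=-0.5 * bx)
        derived["pp_mean_consecutive"] = float(y_con.mean())
        derived["pp_hpd_consecutive"] = hpd_interval(y_con)
        derived["pp_mean_simultaneous"] = float(y_sim.mean())
        derived["pp_hpd_simultaneous"] = hpd_interval(y_sim)
        diff = y_con - y_sim
        derived["diff_mean"] = float(diff.mean())
        derived["diff_hpd"] = hpd_interval(diff)
        derived["p_consecutive_gt_simultaneous"] = prob_direction(diff)
    return FitResult(
        model=f"total_offer[{subset}]",
        draws=draws,
        derived=derived,
        n_obs=len(table),
        warnings=warnings_list,
    )


# --------------------------------------------------------------------------
# shared Bernoulli machinery: eta = base + group effect, proposer intercepts
# --------------------------------------------------------------------------


class _BernoulliMixedModel:
    """logit(p) = X @ beta + sigma_p * z_p[group] (+ sigma_q * z_q[pair]),
    optional non-negative monotonic ordinal term - b * cumsum(simplex)[K]."""

    def __init__(
        self,
        y,
        X,
        fixed_names,
        group_idx,
        n_groups,
        pair_idx=None,
        n_pairs=0,
        mono_cat=None,
        n_cat=N_CATEGORIES,
    ):
        self.y = y
        self.X = X
        self.group_idx = group_idx
        self.G = n_groups
        self.pair_idx = pair_idx
        self.Q = n_pairs if pair_idx is not None else 0
        self.mono_cat = mono_cat
        self.n_cat = n_cat
        self.K_sticks = n_cat - 2  # simplex dim = n_cat - 1, sticks = dim - 1
        self.nfix = X.shape[1]
        names = list(fixed_names)
        if mono_cat is not None:
            names += ["log_b"] + [f"w[{i}]" for i in range(self.K_sticks)]
        names += ["log_sigma_p"] + [f"z_p[{i}]" for i in range(self.G)]
        if self.Q:
            names += ["log_sigma_q"] + [f"z_q[{i}]" for i in range(self.Q)]
        self.param_names = names
        self.ndim = len(names)

    def _simplex(self, w):
        """Stick-breaking map R^(K-1) -> simplex^K with its log-Jacobian;
        a flat Dirichlet prior then contributes exactly the Jacobian."""
        nw = w.shape[0]
        K = self.n_cat - 1  # simplex components
        zeta = np.empty((nw, K))
        remaining = np.ones(nw)
        log_jac = np.zeros(nw)
        for k in range(K - 1):
            adj = w[:, k] - math.log(K - k - 1)
            z = np.clip(invlogit(adj), 1e-15, 1.0 - 1e-15)
            zeta[:, k] = remaining * z
            log_jac += np.log(remaining) + np.log(z) + np.log1p(-z)
            remaining = remaining * (1.0 - z)
        zeta[:, K - 1] = remaining
        return zeta, log_jac

    def split(self, theta):
        i = self.nfix
        out = {"beta": theta[:, :i]}
        if self.mono_cat is not None:
            out["log_b"] = theta[:, i]
            out["w"] = theta[:, i + 1 : i + 1 + self.K_sticks]
            i += 1 + self.K_sticks
        out["log_sigma_p"] = theta[:, i]
        out["z_p"] = theta[:, i + 1 : i + 1 + self.G]
        i += 1 + self.G
        if self.Q:
            out["log_sigma_q"] = theta[:, i]
            out["z_q"] = theta[:, i + 1 : i + 1 + self.Q]
        return out

    def linpred(self, parts):
        eta = parts["beta"] @ self.X.T
        eta = eta + _exp_clip(parts["log_sigma_p"])[:, None] * parts["z_p"][:, self.group_idx]
        if self.Q:
            eta = eta + _exp_clip(parts["log_sigma_q"])[:, None] * parts["z_q"][:, self.pair_idx]
        if self.mono_cat is not None:
            zeta, _ = self._simplex(parts["w"])
            cum = np.concatenate([np.zeros((zeta.shape[0], 1)), np.cumsum(zeta, axis=1)], axis=1)
            eta = eta - _exp_clip(parts["log_b"])[:, None] * cum[:, self.mono_cat]
        return eta

    def log_prob(self, theta):
        theta = np.atleast_2d(theta)
        parts = self.split(theta)
        ll = _bernoulli_ll(self.y, self.linpred(parts))
        lp = _normal_lp(parts["beta"], 2.5)
        sp = _exp_clip(parts["log_sigma_p"])
        lp += -0.5 * sp**2 + parts["log_sigma_p"]
        lp += _normal_lp(parts["z_p"], 1.0)
        if self.Q:
            sq = _exp_clip(parts["log_sigma_q"])
            lp += -0.5 * sq**2 + parts["log_sigma_q"]
            lp += _normal_lp(parts["z_q"], 1.0)
        if self.mono_cat is not None:
            b = _exp_clip(parts["log_b"])
            lp += -0.5 * (b / 2.0) ** 2 + parts["log_b"]  # half-Normal(2), log transform
            _, log_jac = self._simplex(parts["w"])
            lp += log_jac  # Dirichlet(1,..,1) prior
        out = ll + lp
        return np.where(np.isfinite(out), out, -np.inf)

    def initial(self, rng, nwalkers):
        p0 = 0.2 * rng.standard_normal((nwalkers, self.ndim))
        for i, name in enumerate(self.param_names):
            if name.startswith("log_sigma"):
                p0[:, i] -= 1.0
        return p0

    def random_effect_sd(self, parts):
        var = _exp_clip(parts["log_sigma_p"]) ** 2
        if self.Q:
            var = var + _exp_clip(parts["log_sigma_q"]) ** 2
        return np.sqrt(var)


def _fit_bernoulli(model: _BernoulliMixedModel, config: SamplerConfig | None) -> PosteriorDraws:
    return sample_posterior(model, config)


# --------------------------------------------------------------------------
# last offer vs first offer of a session
# --------------------------------------------------------------------------


def prepare_last_vs_first(dataset: ExperimentDataset) -> pd.DataFrame:
    """One row per proposer-session with >= 2 sent offers:
    did the last offer exceed the first?"""
    rows: dict[tuple, dict] = {}
    for v in proposer_views(dataset):
        key = (v.triad_id, v.proposer_id, v.session_index)
        r = rows.setdefault(
            key,
            {
                "triad_id": v.triad_id,
                "proposer_id": v.proposer_id,
                "session_index": v.session_index,
                "condition": "triadic" if v.condition.is_triadic else "dyadic",
                "first": v.own_offer,
                "last": v.own_offer,
                "n_offers": 0,
            },
        )
        r["last"] = v.own_offer
        r["n_offers"] += 1
    out = [dict(r, y=int(r["last"] > r["first"])) for r in rows.values() if r["n_offers"] >= 2]
    return pd.DataFrame(
        out,
        columns=["triad_id", "proposer_id", "session_index", "condition", "first", "last", "n_offers", "y"],
    )


def fit_last_vs_first_model(
    data: ExperimentDataset | pd.DataFrame, config: SamplerConfig | None = None
) -> FitResult:
    """Bernoulli model of P(last offer of a session > first offer), with
    interacting condition (dyadic vs triadic) and session effects and
    proposer random intercepts.

    Derived: per-session triadic - dyadic difference in probability (with
    HPD), and session-marginalized probabilities per condition.
    """
    table = (
        prepare_last_vs_first(data) if isinstance(data, ExperimentDataset) else data.copy()
    )
    y = table["y"].to_numpy(dtype=float)
    c = (table["condition"] == "triadic").to_numpy(dtype=float)
    s_obs = table["session_index"].to_numpy()
    s = _standardize_sessions(s_obs)
    group_idx, groups = _codes(table["proposer_id"])
    X = np.column_stack([np.ones_like(s), c, s, c * s])
    model = _BernoulliMixedModel(
        y, X, ["a0", "a_cond", "a_s", "a_cs"], group_idx, len(groups)
    )
    draws = _fit_bernoulli(model, config)

    a0, ac, as_, acs = (draws.get(n) for n in ("a0", "a_cond", "a_s", "a_cs"))
    sigma = np.exp(draws.get("log_sigma_p"))
    grid, grid_std = _session_grid(s_obs)
    rows = []
    p_d_all, p_t_all = [], []
    for g, gs in zip(grid, grid_std):
        p_d = marginal_invlogit(a0 + as_ * gs, sigma)
        p_t = marginal_invlogit(a0 + ac + (as_ + acs) * gs, sigma)
        p_d_all.append(p_d)
        p_t_all.append(p_t)
        diff = p_t - p_d
        iv = hpd_interval(diff)
        rows.append(
            {
                "session": int(g),
                "p_dyadic": float(p_d.mean()),
                "p_triadic": float(p_t.mean()),
                "diff_mean": float(diff.mean()),
                "diff_hpd_lower": iv.lower,
                "diff_hpd_upper": iv.upper,
                "diff_excludes_zero": iv.excludes_zero(),
            }
        )
    per_session = pd.DataFrame(rows)
    marg_d = np.mean(p_d_all, axis=0)
    marg_t = np.mean(p_t_all, axis=0)
    derived = {
        "p_dyadic_marginal": float(marg_d.mean()),
        "p_dyadic_hpd": hpd_interval(marg_d),
        "p_triadic_marginal": float(marg_t.mean()),
        "p_triadic_hpd": hpd_interval(marg_t),
        "p_triadic_gt_dyadic": prob_direction(marg_t - marg_d),
        "p_dyadic_first_session": per_session["p_dyadic"].iloc[0],
        "p_dyadic_last_session": per_session["p_dyadic"].iloc[-1],
        "p_triadic_first_session": per_session["p_triadic"].iloc[0],
        "p_triadic_last_session": per_session["p_triadic"].iloc[-1],
        "n_sessions_diff_excludes_zero": int(per_session["diff_excludes_zero"].sum()),
    }
    return FitResult(
        model="last_vs_first",
        draws=draws,
        derived=derived,
        tables={"per_session": per_session},
        n_obs=len(table),
    )


# --------------------------------------------------------------------------
# increase after own previous outcome / match the previous winner
# --------------------------------------------------------------------------


def prepare_increase_after_outcome(dataset: ExperimentDataset) -> pd.DataFrame:
    """Triadic trials with a same-session predecessor: did the proposer offer
    more than their own previous offer, and was that previous offer accepted?"""
    rows = []
    for v in proposer_views(dataset):
        if not v.condition.is_triadic or not v.has_predecessor:
            continue
        rows.append(
            {
                "triad_id": v.triad_id,
                "proposer_id": v.proposer_id,
                "responder_id": v.responder_id,
                "session_index": v.session_index,
                "trial_index": v.trial_index,
                "prev_accepted": int(bool(v.previous_own_accepted)),
                "y": int(v.own_offer > v.previous_own_offer),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "triad_id", "proposer_id", "responder_id", "session_index",
            "trial_index", "prev_accepted", "y",
        ],
    )


def prepare_match_winner(dataset: ExperimentDataset) -> pd.DataFrame:
    """Triadic trials whose predecessor had an accepted offer: did the
    proposer match or exceed that winning offer, and was it their own?"""
    rows = []
    for v in proposer_views(dataset):
        if not v.condition.is_triadic or v.previous_winning_offer is None:
            continue
        rows.append(
            {
                "triad_id": v.triad_id,
                "proposer_id": v.proposer_id,
                "responder_id": v.responder_id,
                "session_index": v.session_index,
                "trial_index": v.trial_index,
                "prev_accepted": int(bool(v.previous_winner_was_own)),
                "y": int(v.own_offer >= v.previous_winning_offer),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "triad_id", "proposer_id", "responder_id", "session_index",
            "trial_index", "prev_accepted", "y",
        ],
    )


def _fit_outcome_model(
    table: pd.DataFrame,
    model_name: str,
    label_true: str,
    label_false: str,
    config: SamplerConfig | None,
) -> FitResult:
    y = table["y"].to_numpy(dtype=float)
    a = table["prev_accepted"].to_numpy(dtype=float)
    s_obs = table["session_index"].to_numpy()
    s = _standardize_sessions(s_obs)
    group_idx, groups = _codes(table["proposer_id"])
    X = np.column_stack([np.ones_like(s), a, s, a * s])
    model = _BernoulliMixedModel(
        y, X, ["a0", "a_prev", "a_s", "a_ps"], group_idx, len(groups)
    )
    draws = _fit_bernoulli(model, config)
    a0, ap, as_, aps = (draws.get(n) for n in ("a0", "a_prev", "a_s", "a_ps"))
    sigma = np.exp(draws.get("log_sigma_p"))
    grid, grid_std = _session_grid(s_obs)
    p_true = np.mean([marginal_invlogit(a0 + ap + (as_ + aps) * g, sigma) for g in grid_std], axis=0)
    p_false = np.mean([marginal_invlogit(a0 + as_ * g, sigma) for g in grid_std], axis=0)
    derived = {
        f"p_{label_true}": float(p_true.mean()),
        f"p_{label_true}_hpd": hpd_interval(p_true),
        f"p_{label_false}": float(p_false.mean()),
        f"p_{label_false}_hpd": hpd_interval(p_false),
        f"p_{label_false}_gt_{label_true}": prob_direction(p_false - p_true),
        f"p_{label_true}_gt_{label_false}": prob_direction(p_true - p_false),
    }
    return FitResult(model=model_name, draws=draws, derived=derived, n_obs=len(table))


def fit_increase_after_outcome_model(
    data: ExperimentDataset | pd.DataFrame, config: SamplerConfig | None = None
) -> FitResult:
    """P(offer > own previous offer) in triadic trials as a function of
    whether the previous offer was accepted or rejected, crossed with session.

    Derived: session-marginal P(increase | accepted), P(increase | rejected)
    with HPDs, and the posterior probability that increases are more common
    after rejections.
    """
    table = (
        prepare_increase_after_outcome(data)
        if isinstance(data, ExperimentDataset)
        else data.copy()
    )
    return _fit_outcome_model(
        table, "increase_after_outcome", "increase_after_accept", "increase_after_reject", config
    )


def fit_match_winner_model(
    data: ExperimentDataset | pd.DataFrame, config: SamplerConfig | None = None
) -> FitResult:
    """P(offer >= previously accepted offer) in triadic trials, split by
    whether the previous winner was the proposer's own offer."""
    table = (
        prepare_match_winner(data) if isinstance(data, ExperimentDataset) else data.copy()
    )
    return _fit_outcome_model(
        table, "match_winner", "match_given_own_win", "match_given_other_win", config
    )


# --------------------------------------------------------------------------
# outbidding in consecutive trials
# --------------------------------------------------------------------------


def prepare_outbid(dataset: ExperimentDataset, require_prev: bool = False) -> pd.DataFrame:
    """Consecutive triadic trials with both offers sent: did the second
    proposer outbid (strictly exceed) the first offer?  With ``require_prev``
    only trials where the second proposer has a same-session previous outcome
    are kept (the stratified model's dataset)."""
    rows = []
    for v in consecutive_views(dataset):
        if require_prev and v.second_prev_accepted is None:
            continue
        rows.append(
            {
                "triad_id": v.triad_id,
                "second_proposer": v.second_proposer,
                "responder_id": v.responder_id,
                "session_index": v.session_index,
                "trial_index": v.trial_index,
                "first_offer": v.first_offer,
                "prev_accepted": (
                    int(bool(v.second_prev_accepted)) if v.second_prev_accepted is not None else -1
                ),
                "y": int(v.outbid),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "triad_id", "second_proposer", "responder_id", "session_index",
            "trial_index", "first_offer", "prev_accepted", "y",
        ],
    )


def fit_outbid_simple(
    data: ExperimentDataset | pd.DataFrame, config: SamplerConfig | None = None
) -> FitResult:
    """P(second offer > first offer) over consecutive trials with a session
    fixed effect and second-proposer random intercepts."""
    table = (
        prepare_outbid(data, require_prev=False)
        if isinstance(data, ExperimentDataset)
        else data.copy()
    )
    y = table["y"].to_numpy(dtype=float)
    s_obs = table["session_index"].to_numpy()
    s = _standardize_sessions(s_obs)
    group_idx, groups = _codes(table["second_proposer"])
    X = np.column_stack([np.ones_like(s), s])
    model = _BernoulliMixedModel(y, X, ["a0", "a_s"], group_idx, len(groups))
    draws = _fit_bernoulli(model, config)
    a0, as_ = draws.get("a0"), draws.get("a_s")
    sigma = np.exp(draws.get("log_sigma_p"))
    grid, grid_std = _session_grid(s_obs)
    rows = []
    for g, gs in zip(grid, grid_std):
        p = marginal_invlogit(a0 + as_ * gs, sigma)
        iv = hpd_interval(p)
        rows.append(
            {
                "session": int(g),
                "p_outbid": float(p.mean()),
                "hpd_lower": iv.lower,
                "hpd_upper": iv.upper,
                "excludes_chance": not iv.contains(0.5),
            }
        )
    per_session = pd.DataFrame(rows)
    p_final = marginal_invlogit(a0 + as_ * grid_std[-1], sigma)
    derived = {
        "p_positive_session_slope": prob_direction(as_),
        "p_outbid_final_session": float(p_final.mean()),
        "p_outbid_final_session_hpd": hpd_interval(p_final),
        "n_sessions_excluding_chance": int(per_session["excludes_chance"].sum()),
    }
    return FitResult(
        model="outbid_simple",
        draws=draws,
        derived=derived,
        tables={"per_session": per_session},
        n_obs=len(table),
    )


def fit_outbid_stratified(
    data: ExperimentDataset | pd.DataFrame,
    config: SamplerConfig | None = None,
    baseline: BaselineTable | None = None,
    pair_effects: bool = True,
) -> FitResult:
    """Outbidding stratified by the first offer (monotonic ordinal effect)
    and the second proposer's previous outcome, crossed with session.

    The first offer enters as ``- b * C(K)`` where ``b >= 0`` and ``C`` is the
    cumulative sum of a simplex over increments between adjacent categories
    0..8 — predicted probabilities are non-increasing in the first offer for
    every posterior draw, but the per-step drops are free.  Random intercepts:
    second proposer, plus (second proposer, responder) pairs by default.
    Derived per (previous outcome, first offer): final-session outbid
    probability with HPD and exceedance probabilities versus chance (0.5) and
    versus a supplied baseline table.  Categories absent from the data are
    still predicted via the monotonic chain but flagged as extrapolation.
    """
    table = (
        prepare_outbid(data, require_prev=True)
        if isinstance(data, ExperimentDataset)
        else data.copy()
    )
    if (table["prev_accepted"] < 0).any():
        raise ValueError("stratified outbid model requires previous-outcome information")
    y = table["y"].to_numpy(dtype=float)
    a = table["prev_accepted"].to_numpy(dtype=float)
    s_obs = table["session_index"].to_numpy()
    s = _standardize_sessions(s_obs)
    cat = table["first_offer"].to_numpy(dtype=int)
    group_idx, groups = _codes(table["second_proposer"])
    pair_idx = None
    n_pairs = 0
    if pair_effects:
        pair_idx, pairs = _codes(
            table["second_proposer"].astype(str) + "|" + table["responder_id"].astype(str)
        )
        n_pairs = len(pairs)
    X = np.column_stack([np.ones_like(s), a, s, a * s])
    model = _BernoulliMixedModel(
        y,
        X,
        ["a0", "a_prev", "a_s", "a_ps"],
        group_idx,
        len(groups),
        pair_idx=pair_idx,
        n_pairs=n_pairs,
        mono_cat=cat,
    )
    draws = _fit_bernoulli(model, config)

    a0, ap, as_, aps = (draws.get(n) for n in ("a0", "a_prev", "a_s", "a_ps"))
    b = np.exp(draws.get("log_b"))
    w = draws.vector("w")
    zeta, _ = model._simplex(w)
    cum = np.concatenate([np.zeros((zeta.shape[0], 1)), np.cumsum(zeta, axis=1)], axis=1)
    var = np.exp(draws.get("log_sigma_p")) ** 2
    if pair_effects:
        var = var + np.exp(draws.get("log_sigma_q")) ** 2
    sigma_tot = np.sqrt(var)
    grid, grid_std = _session_grid(s_obs)
    observed = set(zip(table["prev_accepted"], table["first_offer"]))
    rows = []
    for prev in (0, 1):
        base_eta = a0 + ap * prev
        slope = as_ + aps * prev
        for k in range(N_CATEGORIES):
            eta_k = base_eta - b * cum[:, k]
            for g, gs in zip(grid, grid_std):
                p = marginal_invlogit(eta_k + slope * gs, sigma_tot)
                iv = hpd_interval(p)
                row = {
                    "prev_accepted": prev,
                    "first_offer": k,
                    "session": int(g),
                    "p_outbid": float(p.mean()),
                    "hpd_lower": iv.lower,
                    "hpd_upper": iv.upper,
                    "p_gt_chance": prob_direction(p, 0.5),
                    "extrapolated": (prev, k) not in observed,
                }
                if baseline is not None:
                    row["baseline"] = float(baseline.prob[k])
                    row["p_gt_baseline"] = prob_direction(p, float(baseline.prob[k]))
                rows.append(row)
    full = pd.DataFrame(rows)
    final = full[full["session"] == int(grid[-1])].reset_index(drop=True)
    derived = {
        "p_positive_slope_rejected": prob_direction(as_),
        "p_positive_slope_accepted": prob_direction(as_ + aps),
        "monotonic_magnitude_mean": float(b.mean()),
    }
    for prev, label in ((0, "rejected"), (1, "accepted")):
        sub = final[final["prev_accepted"] == prev]
        for k in range(N_CATEGORIES):
            derived[f"p_outbid_{label}_first{k}_final"] = float(
                sub.loc[sub["first_offer"] == k, "p_outbid"].iloc[0]
            )
    return FitResult(
        model="outbid_stratified",
        draws=draws,
        derived=derived,
        tables={"per_cell": full, "final_session": final},
        n_obs=len(table),
    )


# --------------------------------------------------------------------------
# generative simulators for parameter recovery
# --------------------------------------------------------------------------


def simulate_total_offer_table(
    params: dict,
    rng: np.random.Generator,
    n_triads: int = 7,
    n_sessions: int = N_SESSIONS,
    subset: str = "full",
) -> pd.DataFrame:
    """Draw a response table from the Beta model's own generative process at
    study scale: 2 proposers per triad, half the sessions dyadic."""
    rows = []
    s_all = np.arange(1, n_sessions + 1, dtype=float)
    s_std = (s_all - s_all.mean()) / s_all.std()
    for t in range(n_triads):
        u_mu = params.get("sigma_mu", 0.3) * rng.standard_normal()
        u_phi = params.get("sigma_phi", 0.3) * rng.standard_normal()
        for p in range(2):
            for i, sess in enumerate(range(1, n_sessions + 1)):
                triadic = (sess + t) % 2 == 0
                cond = "triadic" if triadic else "dyadic"
                fh = "dyadic"
                x = 0.0
                if triadic:
                    fh = "consecutive" if (sess // 2 + t) % 2 == 0 else "simultaneous"
                    x = 0.5 if fh == "consecutive" else -0.5
                eta = (
                    params["b0_t" if triadic else "b0_d"]
                    + params["b1_t" if triadic else "b1_d"] * s_std[i]
                    + params.get("bx", 0.0) * (x if subset == "first_half" else 0.0)
                    + u_mu
                )
                mu = float(invlogit(eta))
                phi = float(np.exp(params["g0_t" if triadic else "g0_d"] + u_phi))
                y = rng.beta(mu * phi, (1 - mu) * phi)
                rows.append(
                    {
                        "triad_id": f"triad{t + 1}",
                        "proposer_id": f"t{t + 1}_p{p + 1}",
                        "session_index": sess,
                        "condition": cond,
                        "first_half_condition": fh,
                        "y": y,
                    }
                )
    return pd.DataFrame(rows)


def _simulate_bernoulli_rows(
    params: dict,
    rng: np.random.Generator,
    layout: pd.DataFrame,
    eta_fn,
    group_col: str,
) -> pd.DataFrame:
    groups = layout[group_col].unique()
    u = {g: params.get("sigma_p", 0.5) * rng.standard_normal() for g in groups}
    s_all = layout["session_index"].to_numpy(dtype=float)
    s_std = _standardize_sessions(s_all)
    etas = eta_fn(layout, s_std) + np.array([u[g] for g in layout[group_col]])
    p = invlogit(etas)
    out = layout.copy()
    out["y"] = (rng.random(len(layout)) < p).astype(int)
    return out


def simulate_outcome_table(
    params: dict,
    rng: np.random.Generator,
    n_triads: int = 7,
    n_sessions: int = N_SESSIONS,
    trials_per_session: int = 7,
) -> pd.DataFrame:
    """Generative draw for the previous-outcome Bernoulli models: triadic
    proposer-trials with a random previous-outcome indicator."""
    rows = []
    for t in range(n_triads):
        for p in range(2):
            for sess in range(1, n_sessions + 1):
                if (sess + t) % 2 != 0:  # triadic sessions only
                    continue
                for trial in range(2, 2 + trials_per_session):
                    rows.append(
                        {
                            "triad_id": f"triad{t + 1}",
                            "proposer_id": f"t{t + 1}_p{p + 1}",
                            "responder_id": f"t{t + 1}_r",
                            "session_index": sess,
                            "trial_index": trial,
                            "prev_accepted": int(rng.random() < 0.5),
                        }
                    )
    layout = pd.DataFrame(rows)

    def eta_fn(df, s_std):
        a = df["prev_accepted"].to_numpy(dtype=float)
        return (
            params["a0"] + params["a_prev"] * a
            + (params["a_s"] + params["a_ps"] * a) * s_std
        )

    return _simulate_bernoulli_rows(params, rng, layout, eta_fn, "proposer_id")


def simulate_last_vs_first_table(
    params: dict,
    rng: np.random.Generator,
    n_triads: int = 7,
    n_sessions: int = N_SESSIONS,
) -> pd.DataFrame:
    rows = []
    for t in range(n_triads):
        for p in range(2):
            for sess in range(1, n_sessions + 1):
                rows.append(
                    {
                        "triad_id": f"triad{t + 1}",
                        "proposer_id": f"t{t + 1}_p{p + 1}",
                        "session_index": sess,
                        "condition": "triadic" if (sess + t) % 2 == 0 else "dyadic",
                    }
                )
    layout = pd.DataFrame(rows)

    def eta_fn(df, s_std):
        c = (df["condition"] == "triadic").to_numpy(dtype=float)
        return (
            params["a0"] + params["a_cond"] * c
            + (params["a_s"] + params["a_cs"] * c) * s_std
        )

    out = _simulate_bernoulli_rows(params, rng, layout, eta_fn, "proposer_id")
    out["first"] = 0
    out["last"] = out["y"]
    out["n_offers"] = 2
    return out


def simulate_outbid_table(
    params: dict,
    rng: np.random.Generator,
    n_triads: int = 7,
    n_sessions: int = N_SESSIONS,
    stratified: bool = False,
) -> pd.DataFrame:
    """Generative draw for the outbid models: consecutive trials with first
    offers drawn from a low-offer-leaning preference distribution."""
    pref = params.get(
        "first_offer_dist",
        np.array([0.0, 0.30, 0.22, 0.16, 0.12, 0.08, 0.06, 0.04, 0.02]),
    )
    pref = np.asarray(pref, dtype=float)
    pref = pref / pref.sum()
    rows = []
    for t in range(n_triads):
        for sess in range(1, n_sessions + 1):
            if (sess + t) % 2 != 0:
                continue
            for trial in range(1, 5):
                second = f"t{t + 1}_p{1 + (trial % 2)}"
                rows.append(
                    {
                        "triad_id": f"triad{t + 1}",
                        "second_proposer": second,
                        "responder_id": f"t{t + 1}_r",
                        "session_index": sess,
                        "trial_index": trial,
                        "first_offer": int(rng.choice(N_CATEGORIES, p=pref)),
                        "prev_accepted": int(rng.random() < 0.5) if stratified else -1,
                    }
                )
    layout = pd.DataFrame(rows)

    if stratified:
        cum_drop = np.asarray(params["cum_drop"], dtype=float)  # (9,), non-decreasing

        def eta_fn(df, s_std):
            a = df["prev_accepted"].to_numpy(dtype=float)
            k = df["first_offer"].to_numpy(dtype=int)
            return (
                params["a0"] + params["a_prev"] * a
                + (params["a_s"] + params["a_ps"] * a) * s_std
                - cum_drop[k]
            )
    else:

        def eta_fn(df, s_std):
            return params["a0"] + params["a_s"] * s_std

    return _simulate_bernoulli_rows(params, rng, layout, eta_fn, "second_proposer")
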
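"""Baseline outbidding probabilities under an independence null.

If both the first and the second offer of a consecutive trial were drawn
independently from one fixed "offer preference" distribution, how often would
the second exceed a first offer of k grapes?  The preference distribution is
estimated from observed first offers, down-weighting trials late in a session
and sessions late in the study (first offers early on are the cleanest read of
preference, before competitive escalation contaminates them).  The closed form
``B_k = sum_{j>k} p_j`` is the production path; Monte-Carlo simulation of
consecutive sessions is retained for fidelity checks and MC-error reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import ExperimentDataset, consecutive_views

N_CATEGORIES = 9  # offer categories 0..8


@dataclass
class PreferenceDistribution:
    """Weighted empirical distribution of preferred offers over 0..8."""

    p: np.ndarray  # (9,), sums to 1
    lambda_trial: float = 0.2
    lambda_session: float = 0.2
    effective_n: float = 0.0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (N_CATEGORIES,):
            raise ValueError(f"p must have {N_CATEGORIES} components, got {self.p.shape}")
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("p must be a probability vector summing to 1 within 1e-12")


@dataclass
class BaselineTable:
    """Per-first-offer baseline outbid probability with MC standard errors."""

    prob: np.ndarray  # (9,) B_k for k = 0..8
    mc_se: np.ndarray = field(default_factory=lambda: np.zeros(N_CATEGORIES))
    n_pairs: int = 0
    unobserved: np.ndarray = field(default_factory=lambda: np.zeros(N_CATEGORIES, dtype=bool))

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        self.mc_se = np.asarray(self.mc_se, dtype=float)
        self.unobserved = np.asarray(self.unobserved, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "first_offer": np.arange(N_CATEGORIES),
                "baseline_prob": self.prob,
                "mc_se": self.mc_se,
                "unobserved": self.unobserved,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "baseline_prob": self.prob.tolist(),
                "mc_se": self.mc_se.tolist(),
                "n_pairs": int(self.n_pairs),
            },
            indent=2,
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def estimate_preference_distribution(
    first_offers,
    lambda_trial: float = 0.2,
    lambda_session: float = 0.2,
) -> PreferenceDistribution:
    """Weighted empirical offer-preference distribution.

    ``first_offers`` is an iterable of ``(offer, trial_index, session_index)``
    records (offers 0..8, indices 1-based).  Each record gets weight
    ``exp(-lambda_trial * (trial - 1)) * exp(-lambda_session * (session - 1))``
    so early trials of early sessions dominate; both decays at 0 recover plain
    empirical frequencies.
    """
    records = list(first_offers)
    if not records:
        raise ValueError("need at least one first offer to estimate preferences")
    if lambda_trial < 0 or lambda_session < 0:
        raise ValueError("decay rates must be >= 0")
    counts = np.zeros(N_CATEGORIES)
    wsum = 0.0
    w2sum = 0.0
    for offer, trial, session in records:
        offer = int(offer)
        if not 0 <= offer < N_CATEGORIES:
            raise ValueError(f"offer {offer} outside 0..8")
        w = np.exp(-lambda_trial * (trial - 1)) * np.exp(-lambda_session * (session - 1))
        counts[offer] += w
        wsum += w
        w2sum += w * w
    p = counts / wsum
    return PreferenceDistribution(
        p=p,
        lambda_trial=lambda_trial,
        lambda_session=lambda_session,
        effective_n=wsum**2 / w2sum,
    )


def preference_from_dataset(
    dataset: ExperimentDataset,
    lambda_trial: float = 0.2,
    lambda_session: float = 0.2,
) -> PreferenceDistribution:
    """Estimate preferences from the first offers of consecutive triadic
    trials in a dataset (second offers are excluded: they may be strategic)."""
    records = [
        (v.first_offer, v.trial_index, v.session_index)
        for v in consecutive_views(dataset)
    ]
    return estimate_preference_distribution(records, lambda_trial, lambda_session)


def baseline_closed_form(pref: PreferenceDistribution) -> BaselineTable:
    """Exact baseline: B_k = P(independent draw > k) = sum_{j > k} p_j.
    Non-increasing in k by construction, with B_8 = 0."""
    tail = np.concatenate([np.cumsum(pref.p[::-1])[::-1][1:], [0.0]])
    return BaselineTable(prob=tail, mc_se=np.zeros(N_CATEGORIES), n_pairs=0)


def simulate_baseline(
    pref: PreferenceDistribution,
    n_sessions: int,
    seed: int | None = None,
    trials_per_session: int = 4,
) -> BaselineTable:
    """Monte-Carlo baseline: simulate consecutive sessions with both offers
    drawn iid from the preference distribution and tabulate, per first-offer
    category, the share of pairs where the second offer was higher.

    Categories never drawn as a first offer are flagged ``unobserved``.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    rng = np.random.default_rng(seed)
    n_pairs = n_sessions * trials_per_session
    first = rng.choice(N_CATEGORIES, size=n_pairs, p=pref.p)
    second = rng.choice(N_CATEGORIES, size=n_pairs, p=pref.p)
    outbid = second > first
    prob = np.zeros(N_CATEGORIES)
    se = np.zeros(N_CATEGORIES)
    unobserved = np.zeros(N_CATEGORIES, dtype=bool)
    for k in range(N_CATEGORIES):
        mask = first == k
        n_k = int(mask.sum())
        if n_k == 0:
            unobserved[k] = True
            continue
        b = float(outbid[mask].mean())
        prob[k] = b
        se[k] = np.sqrt(b * (1 - b) / n_k)
    return BaselineTable(prob=prob, mc_se=se, n_pairs=n_pairs, unobserved=unobserved)
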
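"""Simulation-based power analysis.

Can the study design — n triads, 16 counterbalanced sessions of 8 trials —
detect a condition difference in total proposer generosity, given a strategy
configuration for how agents behave in dyadic vs triadic sessions?  Each
replicate simulates the whole experiment agent-by-agent, fits the target
model, and applies the detection rule (by default: the 95% HPD
interval of the dyadic - triadic difference in posterior-predictive total
proportional offer excludes zero).  Power is the detected fraction with a
binomial confidence interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .agents import ResponderConfig, build_strategy, simulate_experiment
from .design import DesignSchedule
from .bayes import SamplerConfig
from .data_model import ExperimentDataset, Trial
from .design import generate_design
from .models import FitResult, fit_total_offer_model


@dataclass
class PowerScenario:
    """One power-analysis condition: design size, per-condition strategies,
    replicate count, and the detection rule."""

    n_triads: int = 7
    n_replicates: int = 20
    # strategy specs: {"name": ..., **params}; triadic falls back to dyadic
    dyadic_strategies: dict = field(
        default_factory=lambda: {
            "P1": {"name": "reluctant_increase"},
            "P2": {"name": "reluctant_increase"},
        }
    )
    triadic_strategies: dict = field(
        default_factory=lambda: {
            "P1": {"name": "reluctant_increase"},
            "P2": {"name": "outbidder", "fallback": {"name": "reluctant_increase"}},
        }
    )
    responder: ResponderConfig = field(default_factory=ResponderConfig)
    detection_model: str = "total_offer"
    detection_quantity: str = "diff_hpd"
    mass: float = 0.95
    n_triadic_start: int = 4
    # reduced sampler settings inside the replicate loop
    sampler: SamplerConfig = field(
        default_factory=lambda: SamplerConfig(
            draws=500, chains=2, warmup=500, check_diagnostics=False
        )
    )

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.detection_model != "total_offer":
            raise ValueError("detection rule is defined on the total-offer model")


@dataclass
class PowerResult:
    power: float
    ci_lower: float
    ci_upper: float
    n_detected: int
    n_completed: int
    n_failed: int
    replicates: pd.DataFrame

    def to_json(self) -> str:
        return json.dumps(
            {
                "power": self.power,
                "ci": [self.ci_lower, self.ci_upper],
                "n_detected": self.n_detected,
                "n_completed": self.n_completed,
                "n_failed": self.n_failed,
            },
            indent=2,
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "power.json").write_text(self.to_json())
        self.replicates.to_csv(directory / "replicates.csv", index=False)


class _ConditionSwitchingStrategy:
    """Routes each offer to the dyadic or triadic strategy for that trial,
    holding one shared state (what the agent remembers doesn't depend on
    which behavioral rule is active)."""

    def __init__(self, dyadic, triadic):
        self.dyadic = dyadic
        self.triadic = triadic
        self.current = "dyadic"

    def __call__(self, state, rng):
        return (self.dyadic if self.current == "dyadic" else self.triadic)(state, rng)


def _simulate_scenario_study(
    scenario: PowerScenario, seed: int
) -> ExperimentDataset:
    rng = np.random.default_rng(seed)
    all_trials: list[Trial] = []
    for k in range(scenario.n_triads):
        start = "triadic" if k < scenario.n_triadic_start else "dyadic"
        leader = "P1" if k % 2 == 0 else "P2"
        schedule = generate_design(start_condition=start, first_leader=leader)
        switchers = {}
        for slot in ("P1", "P2"):
            dy = dict(scenario.dyadic_strategies[slot])
            tr = dict(scenario.triadic_strategies[slot])
            switchers[slot] = _ConditionSwitchingStrategy(
                build_strategy(dy.pop("name"), **dy), build_strategy(tr.pop("name"), **tr)
            )
        # play session blocks with the right behavioral rule active
        triad_trials: list[Trial] = []
        for sess in schedule:
            mode = "dyadic" if sess.block == "dyadic" else "triadic"
            for sw in switchers.values():
                sw.current = mode
            ds = simulate_experiment(
                DesignSchedule([sess]),
                switchers,
                responder=scenario.responder,
                seed=int(rng.integers(0, 2**31 - 1)),
                triad_id=f"triad{k + 1}",
                proposer_ids={"P1": f"t{k + 1}_A", "P2": f"t{k + 1}_B"},
                responder_id=f"t{k + 1}_R",
            )
            triad_trials.extend(ds.trials)
        all_trials.extend(triad_trials)
    return ExperimentDataset(all_trials)


def run_power_analysis(scenario: PowerScenario, seed: int | None = None) -> PowerResult:
    """Simulate-fit-detect over all replicates; replicate-level fit failures
    are recorded, not fatal, and power is reported over completed replicates."""
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(scenario.n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        row = {"replicate": rep, "seed": rep_seed, "completed": False, "detected": False}
        try:
            ds = _simulate_scenario_study(scenario, rep_seed)
            cfg = SamplerConfig(
                draws=scenario.sampler.draws,
                chains=scenario.sampler.chains,
                warmup=scenario.sampler.warmup,
                check_diagnostics=scenario.sampler.check_diagnostics,
                seed=rep_seed,
            )
            fit: FitResult = fit_total_offer_model(ds, config=cfg)
            iv = fit.derived[scenario.detection_quantity]
            row.update(
                completed=True,
                detected=bool(iv.excludes_zero()),
                diff_mean=fit.derived.get("diff_mean"),
                hpd_lower=iv.lower,
                hpd_upper=iv.upper,
            )
        except Exception as e:  # fit failure: log and continue
            row["error"] = f"{type(e).__name__}: {e}"
        rows.append(row)
    replicates = pd.DataFrame(rows)
    completed = replicates["completed"].sum()
    detected = replicates["detected"].sum()
    if completed:
        lo, hi = stats.binomtest(int(detected), int(completed)).proportion_ci(0.95)
        power = detected / completed
    else:
        power, lo, hi = float("nan"), float("nan"), float("nan")
    return PowerResult(
        power=float(power),
        ci_lower=float(lo),
        ci_upper=float(hi),
        n_detected=int(detected),
        n_completed=int(completed),
        n_failed=int(len(replicates) - completed),
        replicates=replicates,
    )
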
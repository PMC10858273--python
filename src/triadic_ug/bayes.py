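"""Posterior machinery shared by all models.

The sampling backend is an affine-invariant ensemble MCMC (emcee).  A model is
any object exposing ``ndim``, flat ``param_names``, a vectorized
``log_prob(theta)`` over walker positions, and an ``initial(rng, nwalkers)``
method.  Post-warmup ensemble states are grouped into pseudo-chains for
split-R-hat / effective-sample-size diagnostics (arviz); sampling emits a
``ConvergenceWarning`` — never silently — when R-hat exceeds 1.01 or the bulk
ESS of any parameter falls below 400.

Also here: shortest-window highest-posterior-density intervals, directional
posterior probabilities, and Gauss-Hermite marginalization of inverse-logit
predictions over a Gaussian random effect.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import arviz as az
import emcee
import numpy as np
import pandas as pd


class ConvergenceWarning(UserWarning):
    """MCMC diagnostics crossed the configured thresholds."""


@dataclass(frozen=True)
class HPDInterval:
    """Shortest interval holding a given posterior mass."""

    lower: float
    upper: float
    mass: float

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def excludes_zero(self) -> bool:
        return not self.contains(0.0)


def hpd_interval(draws, mass: float = 0.95) -> HPDInterval:
    """Highest-posterior-density interval: the shortest contiguous window over
    the sorted draws containing ``ceil(mass * n)`` of them."""
    x = np.asarray(draws, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError(f"hpd_interval needs >= 2 finite draws, got {n}")
    if not 0 < mass <= 1:
        raise ValueError(f"mass must be in (0, 1], got {mass}")
    x.sort()
    k = int(math.ceil(mass * n))
    k = max(k, 1)
    if k >= n:
        return HPDInterval(float(x[0]), float(x[-1]), mass)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return HPDInterval(float(x[i]), float(x[i + k - 1]), mass)


def prob_direction(draws, threshold: float = 0.0) -> float:
    """Fraction of draws strictly above a threshold (posterior probability of
    a positive / above-threshold effect)."""
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("prob_direction needs at least one draw")
    return float(np.mean(x > threshold))


class ModelSpec(Protocol):
    ndim: int
    param_names: list[str]

    def log_prob(self, theta: np.ndarray) -> np.ndarray: ...

    def initial(self, rng: np.random.Generator, nwalkers: int) -> np.ndarray: ...


@dataclass
class SamplerConfig:
    """Ensemble-sampler settings: total retained draws ~= chains * draws."""

    draws: int = 1000
    chains: int = 4
    warmup: int = 1000
    thin: int = 1
    min_kept_steps: int = 250
    nwalkers: int | None = None
    seed: int | None = None
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0
    check_diagnostics: bool = True


@dataclass
class PosteriorDraws:
    """Named posterior draws with metadata and convergence diagnostics."""

    params: dict[str, np.ndarray]  # name -> (n_draws,)
    chain_shape: tuple[int, int]  # (pseudo-chains, draws per chain)
    diagnostics: pd.DataFrame  # columns: param, rhat, ess_bulk
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).size

    @property
    def names(self) -> list[str]:
        return list(self.params)

    def get(self, name: str) -> np.ndarray:
        return self.params[name]

    def vector(self, prefix: str) -> np.ndarray:
        """Stack ``prefix[0]``, ``prefix[1]``, ... into a (n_draws, k) array."""
        cols = sorted(
            (n for n in self.params if n.startswith(prefix + "[")),
            key=lambda n: int(n[len(prefix) + 1 : -1]),
        )
        if not cols:
            raise KeyError(f"no parameters with prefix {prefix!r}")
        return np.column_stack([self.params[c] for c in cols])

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        rows = []
        for name, x in self.params.items():
            iv = hpd_interval(x, mass)
            rows.append(
                {
                    "param": name,
                    "mean": float(np.mean(x)),
                    "sd": float(np.std(x)),
                    "hpd_lower": iv.lower,
                    "hpd_upper": iv.upper,
                }
            )
        return pd.DataFrame(rows).merge(self.diagnostics, on="param", how="left")

    def save(self, directory: str | Path) -> None:
        """Serialize draws as CSV plus a JSON metadata/diagnostics sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.params).to_csv(directory / "draws.csv", index=False)
        sidecar = {
            "chain_shape": list(self.chain_shape),
            "meta": _jsonable(self.meta),
            "diagnostics": self.diagnostics.to_dict(orient="records"),
        }
        (directory / "meta.json").write_text(json.dumps(sidecar, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def sample_posterior(model: ModelSpec, config: SamplerConfig | None = None) -> PosteriorDraws:
    """Draw from a model's posterior with an affine-invariant ensemble sampler.

    Walkers are initialized from the model's ``initial`` method; the run
    fails immediately with an informative error if any starting point has a
    non-finite log-density.  Post-warmup walker states form the pseudo-chains
    on which split-R-hat and bulk ESS are computed for every parameter.
    """
    config = config or SamplerConfig()
    rng = np.random.default_rng(config.seed)
    ndim = model.ndim
    nwalkers = config.nwalkers or max(2 * ndim + 2, 32)
    nwalkers += nwalkers % 2

    p0 = np.asarray(model.initial(rng, nwalkers), dtype=float)
    lp0 = np.asarray(model.log_prob(p0), dtype=float)
    if not np.all(np.isfinite(lp0)):
        bad = int(np.sum(~np.isfinite(lp0)))
        raise ValueError(
            f"non-finite log-density at initialization for {bad}/{nwalkers} walkers; "
            "check data preprocessing and parameter transforms"
        )

    total_target = config.draws * config.chains
    kept_steps = max(int(math.ceil(total_target / nwalkers)), config.min_kept_steps, 4)
    nsteps = config.warmup + kept_steps * config.thin

    # differential-evolution move mixture: mixes far better than the default
    # stretch move on these correlated hierarchical posteriors
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    # emcee snapshots numpy's legacy global RandomState at sampler
    # construction, so the sampler must be built inside the seeded region or
    # the run depends on unrelated process history
    state = np.random.get_state()
    np.random.seed(rng.integers(0, 2**31 - 1))
    try:
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, model.log_prob, vectorize=True, moves=moves
        )
        sampler.run_mcmc(p0, nsteps, progress=False, skip_initial_state_check=True)
    finally:
        np.random.set_state(state)

    chain = sampler.get_chain(discard=config.warmup, thin=config.thin)  # (steps, walkers, ndim)
    chain = np.moveaxis(chain, 0, 1)  # (walkers, steps, ndim)

    names = list(model.param_names)
    ds = az.convert_to_dataset(chain)  # dims: chain, draw, ndim
    rhat = np.asarray(az.rhat(ds)["x"].values, dtype=float).ravel()
    ess = np.asarray(az.ess(ds)["x"].values, dtype=float).ravel()
    diagnostics = pd.DataFrame({"param": names, "rhat": rhat, "ess_bulk": ess})

    if config.check_diagnostics:
        worst_rhat = diagnostics["rhat"].max()
        worst_ess = diagnostics["ess_bulk"].min()
        if worst_rhat > config.rhat_threshold or worst_ess < config.ess_threshold:
            warnings.warn(
                f"convergence diagnostics: max R-hat {worst_rhat:.3f} "
                f"(threshold {config.rhat_threshold}), min bulk ESS {worst_ess:.0f} "
                f"(threshold {config.ess_threshold:.0f})",
                ConvergenceWarning,
                stacklevel=2,
            )

    flat = chain.reshape(-1, ndim)
    params = {name: flat[:, j].copy() for j, name in enumerate(names)}
    meta = {
        "seed": config.seed,
        "nwalkers": nwalkers,
        "warmup": config.warmup,
        "kept_steps": kept_steps,
        "thin": config.thin,
        "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
    }
    return PosteriorDraws(params, (nwalkers, kept_steps), diagnostics, meta)


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(31)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def invlogit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def marginal_invlogit(eta: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """E[invlogit(eta + u)] with u ~ Normal(0, sigma^2), by 31-point
    Gauss-Hermite quadrature; broadcasts over draw arrays."""
    eta = np.asarray(eta, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    grid = eta[..., None] + sigma[..., None] * _GH_NODES
    return invlogit(grid) @ _GH_WEIGHTS
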
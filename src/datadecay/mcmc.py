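"""General-purpose MCMC for the audit models.

The sampler is an adaptive random-walk Metropolis-within-Gibbs over an
unconstrained parameter vector: each sweep proposes a Gaussian perturbation
to every coordinate in turn, and per-coordinate proposal scales are tuned
during warmup toward the classical 0.44 acceptance rate for scalar updates.
Chains are independent and fully determined by the configuration seed.

Models hand the sampler a log-posterior over the unconstrained vector
(constrained parameters enter through log/logit transforms with their
Jacobians) and unpack draws onto the natural scale afterwards, so reported
draws always satisfy the parameter constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["MCMCConfig", "PosteriorDraws", "run_mwg"]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration.

    ``draws`` is the number of retained post-warmup draws per chain; the
    default 4 chains x 2500 draws summarizes 10,000 draws in total.
    """

    chains: int = 4
    draws: int = 2500
    warmup: int = 1000
    seed: int = 0
    adapt_target: float = 0.44

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if self.chains < 2:
            # R-hat needs >= 2 chains; allow 1 only for throwaway fits.
            import warnings

            warnings.warn("single-chain runs cannot be checked with R-hat")
        if self.draws < 1 or self.warmup < 0:
            raise ValueError("draws must be >= 1 and warmup >= 0")
        if not 0.0 < self.adapt_target < 1.0:
            raise ValueError("adapt_target must lie in (0, 1)")

    def scaled(self, factor: float) -> "MCMCConfig":
        """A cheaper copy with draws/warmup scaled down (floor 50)."""
        return replace(
            self,
            draws=max(50, int(self.draws * factor)),
            warmup=max(50, int(self.warmup * factor)),
        )


@dataclass
class PosteriorDraws:
    """MCMC draws keyed by parameter name, each an array (chains, draws).

    ``meta`` carries the model label, seed/config and any data summaries the
    reporting layer needs (type mix, ages, stage denominators, ...).
    """

    draws: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.draws.values()}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent draw shapes: {shapes}")

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    def flat(self, name: str) -> np.ndarray:
        """All draws of one parameter, chains concatenated."""
        return self.draws[name].reshape(-1)

    def stack(self, names: Sequence[str]) -> np.ndarray:
        """(total draws, len(names)) matrix of flattened draws."""
        return np.column_stack([self.flat(n) for n in names])

    def subset(self, names: Sequence[str]) -> "PosteriorDraws":
        return PosteriorDraws({n: self.draws[n] for n in names}, dict(self.meta))

    # -- serialization: flat (chain, iteration, parameter, value) table ----

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            nc, nd = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(nc), nd),
                        "iteration": np.tile(np.arange(nd), nc),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta: dict | None = None) -> "PosteriorDraws":
        draws = {}
        for name, grp in frame.groupby("parameter", sort=False):
            nc = grp["chain"].nunique()
            pivot = grp.pivot(index="chain", columns="iteration", values="value")
            draws[name] = pivot.to_numpy()
            assert draws[name].shape[0] == nc
        return cls(draws, meta or {})

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "PosteriorDraws":
        return cls.from_frame(pd.read_csv(path), meta)


def run_mwg(
    logpost: Callable[[np.ndarray], float],
    init: Callable[[np.random.Generator], np.ndarray],
    n_params: int,
    cfg: MCMCConfig,
    joint_moves: Sequence[Callable[[np.ndarray, float, np.random.Generator], np.ndarray]] = (),
) -> np.ndarray:
    """Sample ``logpost`` with adaptive Metropolis-within-Gibbs.

    Returns post-warmup draws of shape (chains, draws, n_params). Proposal
    scales adapt in batches of 50 warmup sweeps; they are frozen afterwards
    so retained draws form a time-homogeneous Markov chain.

    ``joint_moves`` are optional symmetric proposals ``f(x, step, rng) ->
    x'`` applied once per sweep with their own adapted step, used to
    traverse posterior ridges (e.g. a location shift absorbed by a block of
    latent effects) that scalar updates cross slowly.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    out = np.empty((cfg.chains, cfg.draws, n_params))
    for c in range(cfg.chains):
        rng = np.random.default_rng(seeds[c])
        x = np.asarray(init(rng), dtype=float).copy()
        if x.shape != (n_params,):
            raise ValueError("init returned a vector of the wrong length")
        lp = float(logpost(x))
        if not np.isfinite(lp):
            raise ValueError("initial point has non-finite log posterior")
        log_scale = np.full(n_params, np.log(0.5))
        accepted = np.zeros(n_params)
        n_joint = len(joint_moves)
        jm_log_scale = np.full(n_joint, np.log(0.5))
        jm_accepted = np.zeros(n_joint)
        batch = 0
        total = cfg.warmup + cfg.draws
        for it in range(total):
            scale = np.exp(log_scale)
            z = rng.standard_normal(n_params)
            logu = np.log(rng.random(n_params))
            for j in range(n_params):
                old = x[j]
                x[j] = old + scale[j] * z[j]
                lpp = logpost(x)
                if logu[j] < lpp - lp:
                    lp = lpp
                    accepted[j] += 1
                else:
                    x[j] = old
            for j, move in enumerate(joint_moves):
                prop = move(x, float(np.exp(jm_log_scale[j])), rng)
                lpp = logpost(prop)
                if np.log(rng.random()) < lpp - lp:
                    x, lp = prop, lpp
                    jm_accepted[j] += 1
            if it < cfg.warmup and (it + 1) % 50 == 0:
                batch += 1
                rate = accepted / 50.0
                step = min(1.0, 4.0 / np.sqrt(batch))
                log_scale += step * (rate - cfg.adapt_target)
                log_scale = np.clip(log_scale, -12.0, 6.0)
                accepted[:] = 0.0
                if n_joint:
                    jm_log_scale += step * (jm_accepted / 50.0 - cfg.adapt_target)
                    jm_log_scale = np.clip(jm_log_scale, -12.0, 6.0)
                    jm_accepted[:] = 0.0
            if it >= cfg.warmup:
                out[c, it - cfg.warmup] = x
    return out
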
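"""Convergence diagnostics, narrowest-interval summaries, prior predictive.

R-hat is the rank-normalized split-chain potential scale reduction factor
and ESS the autocorrelation-adjusted bulk effective sample size, both
delegated to arviz (the reference implementation of the current versions of
these diagnostics). The highest-posterior-density interval is computed
in-package by exhaustive search over contiguous windows of the sorted draws,
because downstream summaries depend on its exact tie-breaking: among equal
narrowest windows the lower one is returned.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws

__all__ = [
    "DEFAULT_MASS",
    "rhat",
    "ess",
    "hpdi",
    "IntervalEstimate",
    "summarize_draws",
    "DiagnosticsReport",
    "diagnose",
    "prior_predictive",
]

#: Interval mass used throughout reporting.
DEFAULT_MASS = 0.89

#: Flag thresholds: current practice for the rank-normalized diagnostic.
RHAT_MAX = 1.01
ESS_MIN = 400.0


def _chain_matrix(draws: np.ndarray) -> np.ndarray:
    arr = np.asarray(draws, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected draws of shape (chains, iterations)")
    if arr.shape[0] < 2 or arr.shape[1] < 4:
        raise ValueError("need >= 2 chains of >= 4 draws")
    return arr


def rhat(draws: np.ndarray) -> float:
    """Rank-normalized split R-hat for one parameter; NaN for constant chains."""
    arr = _chain_matrix(draws)
    if np.allclose(arr, arr.flat[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(arr))


def ess(draws: np.ndarray) -> float:
    """Bulk effective sample size for one parameter; 0 for constant chains."""
    arr = _chain_matrix(draws)
    if np.allclose(arr, arr.flat[0]):
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(arr))


def hpdi(draws: np.ndarray, mass: float = DEFAULT_MASS) -> tuple[float, float]:
    """Narrowest contiguous interval holding ``mass`` of the sample.

    Among all windows of ceil(mass * N) consecutive sorted draws the one of
    minimal width is returned; ties break toward the lower window.
    """
    x = np.sort(np.asarray(draws, dtype=float).reshape(-1))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    w = math.ceil(mass * n)
    if w < 1:
        raise ValueError("mass * N < 1: no window exists")
    widths = x[w - 1 :] - x[: n - w + 1]
    i = int(np.argmin(widths))  # argmin returns the first (lowest) minimum
    return float(x[i]), float(x[i + w - 1])


@dataclass(frozen=True)
class IntervalEstimate:
    """Posterior mean with a narrowest interval of the stated mass."""

    mean: float
    lower: float
    upper: float
    mass: float = DEFAULT_MASS

    def covers(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def __iter__(self):
        return iter((self.mean, self.lower, self.upper))


def summarize_draws(draws: np.ndarray, mass: float = DEFAULT_MASS) -> IntervalEstimate:
    lo, hi = hpdi(draws, mass)
    return IntervalEstimate(float(np.mean(draws)), lo, hi, mass)


@dataclass
class DiagnosticsReport:
    """Per-parameter R-hat and ESS with the parameters failing thresholds."""

    table: pd.DataFrame  # columns: parameter, rhat, ess
    flags: list[str] = field(default_factory=list)
    rhat_max: float = RHAT_MAX
    ess_min: float = ESS_MIN

    @property
    def ok(self) -> bool:
        return not self.flags

    def as_text(self) -> str:
        lines = [self.table.to_string(index=False)]
        if self.flags:
            lines.append(f"FLAGGED ({len(self.flags)}): " + ", ".join(self.flags))
        else:
            lines.append("all parameters within thresholds")
        return "\n".join(lines)


def diagnose(
    post: PosteriorDraws,
    rhat_max: float = RHAT_MAX,
    ess_min: float = ESS_MIN,
) -> DiagnosticsReport:
    """Compute R-hat/ESS for every parameter and flag failures.

    Constant chains are reported as R-hat NaN / ESS 0 and flagged as
    not-applicable rather than raising. Pure: identical inputs give
    identical reports.
    """
    rows = []
    flags = []
    for name in post.parameters:
        arr = post.draws[name]
        if np.allclose(arr, arr.flat[0]):
            rows.append((name, float("nan"), 0.0))
            flags.append(name)
            continue
        r = rhat(arr)
        e = ess(arr)
        rows.append((name, r, e))
        if not np.isfinite(r) or r > rhat_max or e < ess_min:
            flags.append(name)
    table = pd.DataFrame(rows, columns=["parameter", "rhat", "ess"])
    return DiagnosticsReport(table=table, flags=flags, rhat_max=rhat_max, ess_min=ess_min)


def prior_predictive(
    model: str,
    priors=None,
    n_sims: int = 500,
    ages: np.ndarray | None = None,
    seed: int = 0,
):
    """Simulate parameters from the priors and the outcomes they imply.

    For ``model="stage1"`` (or ``"stage1_logistic"``) returns a DataFrame of
    drawn parameters together with the implied recovery probability on an
    age grid; for ``model="stages"`` the implied stage probability after
    integrating the paper effect. Used to check that regularizing priors
    imply recovery/reproduction probabilities spread over (0, 1) rather
    than piled on the boundaries.
    """
    from . import stage1 as _s1
    from . import stages as _st

    rng = np.random.default_rng(seed)
    if ages is None:
        ages = np.arange(0, 41, 5)
    ages = np.asarray(ages)

    if model == "stage1":
        pr = priors or _s1.Stage1Priors()
        if pr.alpha_fixed is not None:
            alpha = np.full(n_sims, pr.alpha_fixed)
        else:
            alpha = rng.beta(pr.alpha_a, pr.alpha_b, size=n_sims)
        if pr.lam_fixed is not None:
            lam = np.full(n_sims, pr.lam_fixed)
        else:
            lam = rng.exponential(1.0 / pr.lam_rate, size=n_sims)
        rows = {"alpha": alpha, "lam": lam, "half_life": np.log(2) / lam}
        for a in ages:
            rows[f"p_age{a}"] = alpha * np.exp(-lam * a)
        return pd.DataFrame(rows)
    if model == "stage1_logistic":
        pr = priors or _s1.LogisticPriors()
        a = rng.normal(0.0, pr.a_sd, size=n_sims)
        b = rng.normal(0.0, pr.b_sd, size=n_sims)
        rows = {"a": a, "b": b}
        for v in ages:
            rows[f"p_age{v}"] = 1.0 / (1.0 + np.exp(-(a + b * v)))
        return pd.DataFrame(rows)
    if model == "stages":
        pr = priors or _st.StagePriors()
        phi = rng.normal(0.0, pr.phi_sd, size=n_sims)
        sigma = rng.exponential(1.0 / pr.psi_rate, size=n_sims)
        p = np.array(
            [_st.marginal_probability(f, s**2) for f, s in zip(phi, sigma)]
        )
        return pd.DataFrame({"phi": phi, "psi": sigma**2, "p": p})
    raise ValueError(f"unknown model {model!r}")
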
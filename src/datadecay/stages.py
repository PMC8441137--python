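"""Stages 2-4: conditional hierarchical binomial models of reproducibility.

Given the data of paper ``i`` were recovered, each of its ``n_i`` results
passes stage ``s`` (2 = usable data, 3 = clear analysis, 4 = consistent
result) with probability

    logit(p_s,i) = phi_s + beta_s,i + gamma_s,v[i]

where ``phi_s`` is the stage intercept, ``beta_s,i ~ Normal(0, sqrt(psi_s))``
a paper-specific intercept capturing the correlation between results of one
paper (``psi_s`` is the variance of the paper effects), and
``gamma_s,v`` a smooth effect of publication age ``v`` given a
squared-exponential Gaussian-process prior — no parametric form for the age
trend is assumed. Stages are conditional: the stage-3 denominator for a
paper is its stage-2 success count, and the stage-4 denominator its stage-3
count, so papers emptied by an earlier stage contribute nothing downstream.
The three stage models are identical in form with independent parameters
and are fitted independently.

An unconditional-denominator variant (all stages over ``n_i``) is available
behind ``conditional=False`` for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, gammaln

from .audit import AuditDataset, MonotonicityError, ResultsRecord
from .diagnostics import DEFAULT_MASS, IntervalEstimate, diagnose, summarize_draws
from .mcmc import MCMCConfig, PosteriorDraws, run_mwg

__all__ = [
    "STAGES",
    "StageParams",
    "HierParams",
    "StagePriors",
    "gp_cov",
    "stages_loglik",
    "fit_stages",
    "marginal_probability",
    "marginal_stage_prob",
]

#: Downstream stages modelled here (stage 1 lives in datadecay.stage1).
STAGES = (2, 3, 4)


@dataclass(frozen=True)
class StageParams:
    """Parameters of one stage's hierarchical binomial model.

    ``psi`` is the variance of the paper effects; ``eta`` (marginal sd) and
    ``rho`` (lengthscale, years) govern the Gaussian-process age effect.
    ``beta`` maps paper_id -> effect and ``gamma`` age -> effect; missing
    keys mean zero, so ``beta={}`` encodes "no paper effects drawn yet".
    """

    phi: float
    psi: float
    eta: float = 0.0
    rho: float = 10.0
    beta: Mapping[str, float] = field(default_factory=dict)
    gamma: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.psi < 0 or self.eta < 0:
            raise ValueError("psi and eta must be non-negative")
        if self.rho <= 0:
            raise ValueError("rho must be positive")


@dataclass(frozen=True)
class HierParams:
    """Per-stage parameters for stages 2-4."""

    stages: Mapping[int, StageParams]

    def __post_init__(self) -> None:
        if set(self.stages) != set(STAGES):
            raise ValueError(f"stages must be exactly {STAGES}")

    def __getitem__(self, s: int) -> StageParams:
        return self.stages[s]


@dataclass(frozen=True)
class StagePriors:
    """phi ~ Normal(0, phi_sd); sqrt(psi) ~ Exponential(psi_rate);
    eta ~ Exponential(eta_rate); rho ~ LogNormal(rho_mu, rho_sd)."""

    phi_sd: float = 2.5
    psi_rate: float = 1.0
    eta_rate: float = 1.0
    rho_mu: float = float(np.log(10.0))
    rho_sd: float = 0.5


# ---------------------------------------------------------------------------
# Gaussian-process covariance


def gp_cov(
    years: np.ndarray, amplitude: float, lengthscale: float, jitter: float = 0.0
) -> np.ndarray:
    """Squared-exponential covariance over distinct ages.

    K[i, j] = amplitude^2 exp(-(v_i - v_j)^2 / (2 lengthscale^2)) + jitter 1{i=j}.
    """
    years = np.asarray(years, dtype=float)
    if years.ndim != 1:
        raise ValueError("years must be a vector")
    if np.unique(years).size != years.size:
        raise ValueError("ages must be distinct (collapse duplicates upstream)")
    if amplitude < 0 or lengthscale <= 0 or jitter < 0:
        raise ValueError("require amplitude >= 0, lengthscale > 0, jitter >= 0")
    d = years[:, None] - years[None, :]
    K = amplitude**2 * np.exp(-(d**2) / (2.0 * lengthscale**2))
    if jitter:
        K = K + jitter * np.eye(years.size)
    return K


# ---------------------------------------------------------------------------
# likelihood


def _stage_counts(rec: ResultsRecord, stage: int, conditional: bool) -> tuple[int, int]:
    """(trials, successes) of one paper at one stage."""
    if conditional:
        trials = {2: rec.n, 3: rec.x2, 4: rec.x3}[stage]
    else:
        trials = rec.n
    successes = {2: rec.x2, 3: rec.x3, 4: rec.x4}[stage]
    return trials, successes


def _binom_logpmf(x: np.ndarray, n: np.ndarray, logit_p: np.ndarray) -> np.ndarray:
    """log C(n, x) + x log p + (n - x) log(1 - p), stable in logit_p."""
    coef = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    return coef - x * np.logaddexp(0.0, -logit_p) - (n - x) * np.logaddexp(0.0, logit_p)


def stages_loglik(
    params: HierParams,
    results: Sequence[ResultsRecord],
    paper_ages: Mapping[str, int],
    conditional: bool = True,
) -> float:
    """Sum of the three conditional binomial stage log-likelihoods.

    A paper whose previous stage emptied (e.g. x2 = 0) contributes exactly
    zero to later stages. Raises :class:`MonotonicityError` before
    evaluation if any record violates the nesting.
    """
    for rec in results:
        if not 0 <= rec.x4 <= rec.x3 <= rec.x2 <= rec.n:
            raise MonotonicityError(
                f"paper {rec.paper_id!r} violates x4 <= x3 <= x2 <= n"
            )
    total = 0.0
    for s in STAGES:
        sp = params[s]
        for rec in results:
            trials, succ = _stage_counts(rec, s, conditional)
            if trials == 0:
                continue
            v = paper_ages[rec.paper_id]
            lin = sp.phi + sp.beta.get(rec.paper_id, 0.0) + sp.gamma.get(v, 0.0)
            total += float(
                _binom_logpmf(
                    np.asarray(float(succ)), np.asarray(float(trials)), np.asarray(lin)
                )
            )
    return total


# ---------------------------------------------------------------------------
# posterior inference (one independent fit per stage)


def _fit_one_stage(
    stage: int,
    m: np.ndarray,
    y: np.ndarray,
    ages: np.ndarray,
    paper_ids: list[str],
    priors: StagePriors,
    mcmc: MCMCConfig,
    jitter: float = 1e-8,
) -> dict[str, np.ndarray]:
    """Sample one stage's model; returns natural-scale draws keyed by name.

    Non-centred parameterization: beta = sqrt(psi) * z with z ~ N(0, I), and
    gamma = eta * L(rho) u with u ~ N(0, I), L the Cholesky factor of the
    unit-amplitude squared-exponential correlation over the distinct ages.
    """
    n = m.size
    uniq_ages, age_idx = np.unique(ages, return_inverse=True)
    k = uniq_ages.size
    dim = 4 + n + k  # phi, log sigma, z (n), log eta, log rho, u (k)

    coef = gammaln(m + 1) - gammaln(y + 1) - gammaln(m - y + 1)
    coef_sum = float(np.sum(coef))
    chol_cache: dict[float, np.ndarray] = {}

    def chol(rho: float) -> np.ndarray:
        L = chol_cache.get(rho)
        if L is None:
            K = gp_cov(uniq_ages, 1.0, rho, jitter)
            L = np.linalg.cholesky(K)
            chol_cache.clear()
            chol_cache[rho] = L
        return L

    pr = priors

    def logpost(theta: np.ndarray) -> float:
        phi = theta[0]
        log_sigma = theta[1]
        z = theta[2 : 2 + n]
        log_eta = theta[2 + n]
        log_rho = theta[3 + n]
        u = theta[4 + n :]
        sigma = np.exp(log_sigma)
        eta = np.exp(log_eta)
        rho = np.exp(log_rho)
        gamma = eta * (chol(rho) @ u)
        lin = phi + sigma * z + gamma[age_idx]
        loglik = coef_sum - float(
            np.sum(y * np.logaddexp(0.0, -lin) + (m - y) * np.logaddexp(0.0, lin))
        )
        lp = loglik
        lp += -0.5 * (phi / pr.phi_sd) ** 2
        lp += -pr.psi_rate * sigma + log_sigma  # Exponential prior + log Jacobian
        lp += -pr.eta_rate * eta + log_eta
        lp += -0.5 * ((log_rho - pr.rho_mu) / pr.rho_sd) ** 2
        lp += -0.5 * float(z @ z) - 0.5 * float(u @ u)
        return lp

    def init(rng: np.random.Generator) -> np.ndarray:
        theta = np.zeros(dim)
        theta[0] = rng.normal(1.0, 0.5)  # phi
        theta[1] = np.log(rng.uniform(0.3, 1.5))  # log sigma
        theta[2 : 2 + n] = rng.normal(0, 0.3, size=n)
        theta[2 + n] = np.log(rng.uniform(0.1, 0.8))  # log eta
        theta[3 + n] = pr.rho_mu + rng.normal(0, 0.2)  # log rho
        theta[4 + n :] = rng.normal(0, 0.3, size=k)
        return theta

    # Symmetric ridge moves: shift phi while absorbing the shift in the
    # paper effects (or the GP field), leaving the linear predictor
    # unchanged; scalar updates cross these ridges very slowly.
    from scipy.linalg import solve_triangular

    def ridge_papers(theta: np.ndarray, step: float, rng: np.random.Generator):
        eps = step * rng.standard_normal()
        prop = theta.copy()
        prop[0] += eps
        prop[2 : 2 + n] -= eps / np.exp(theta[1])
        return prop

    def ridge_years(theta: np.ndarray, step: float, rng: np.random.Generator):
        eps = step * rng.standard_normal()
        prop = theta.copy()
        prop[0] += eps
        L = chol(float(np.exp(theta[3 + n])))
        shift = solve_triangular(L, np.full(k, eps / np.exp(theta[2 + n])), lower=True)
        prop[4 + n :] -= shift
        return prop

    raw = run_mwg(
        logpost, init, dim, mcmc, joint_moves=(ridge_papers, ridge_years)
    )
    nc, nd, _ = raw.shape
    sigma = np.exp(raw[:, :, 1])
    eta = np.exp(raw[:, :, 2 + n])
    rho = np.exp(raw[:, :, 3 + n])
    draws = {
        f"phi[{stage}]": raw[:, :, 0],
        f"psi[{stage}]": sigma**2,
        f"eta[{stage}]": eta,
        f"rho[{stage}]": rho,
    }
    for i, pid in enumerate(paper_ids):
        draws[f"beta[{stage},{pid}]"] = sigma * raw[:, :, 2 + i]
    # gamma draws require the per-draw Cholesky; group draws by rho value.
    gam = np.empty((nc, nd, k))
    flat_rho = rho.reshape(-1)
    flat_u = raw[:, :, 4 + n :].reshape(-1, k)
    flat_eta = eta.reshape(-1)
    order = np.argsort(flat_rho, kind="stable")
    cache_rho, L = None, None
    gflat = np.empty((nc * nd, k))
    for idx in order:
        r = flat_rho[idx]
        if r != cache_rho:
            L = np.linalg.cholesky(gp_cov(uniq_ages, 1.0, r, 1e-8))
            cache_rho = r
        gflat[idx] = flat_eta[idx] * (L @ flat_u[idx])
    gam = gflat.reshape(nc, nd, k)
    for j, v in enumerate(uniq_ages.astype(int)):
        draws[f"gamma[{stage},{v}]"] = gam[:, :, j]
    return draws


def _stage_data(
    results: Sequence[ResultsRecord],
    paper_ages: Mapping[str, int],
    stage: int,
    conditional: bool,
):
    m, y, ages, pids = [], [], [], []
    for rec in results:
        trials, succ = _stage_counts(rec, stage, conditional)
        if trials == 0:
            continue  # conditioning emptied this paper at an earlier stage
        m.append(trials)
        y.append(succ)
        ages.append(paper_ages[rec.paper_id])
        pids.append(rec.paper_id)
    return (
        np.asarray(m, dtype=float),
        np.asarray(y, dtype=float),
        np.asarray(ages, dtype=float),
        pids,
    )


def fit_stages(
    results,
    paper_ages: Mapping[str, int] | None = None,
    priors: StagePriors = StagePriors(),
    mcmc: MCMCConfig = MCMCConfig(),
    conditional: bool = True,
    stages: Sequence[int] = STAGES,
) -> PosteriorDraws:
    """Fit the stage 2-4 hierarchical binomial models independently.

    ``results`` may be an :class:`AuditDataset` (ages taken from its papers
    table) or a sequence of :class:`ResultsRecord` with ``paper_ages``
    supplied. Draws are reported on the natural scale (phi, psi = paper
    effect variance, eta, rho, beta, gamma); diagnostics are attached to
    ``meta``.
    """
    if isinstance(results, AuditDataset):
        paper_ages = results.paper_ages()
        records = results.results_records()
    else:
        records = list(results)
        if paper_ages is None:
            raise ValueError("paper_ages is required when passing raw records")
    if len(records) < 2:
        raise ValueError(
            "at least two papers are required: paper-level effects are "
            "unidentifiable from a single paper"
        )
    for rec in records:
        if not 0 <= rec.x4 <= rec.x3 <= rec.x2 <= rec.n:
            raise MonotonicityError(
                f"paper {rec.paper_id!r} violates x4 <= x3 <= x2 <= n"
            )

    all_draws: dict[str, np.ndarray] = {}
    stage_meta: dict[int, dict] = {}
    for i, s in enumerate(stages):
        m, y, ages, pids = _stage_data(records, paper_ages, s, conditional)
        if m.size < 2:
            warnings.warn(f"stage {s}: fewer than 2 informative papers; skipped")
            continue
        sub = MCMCConfig(
            chains=mcmc.chains,
            draws=mcmc.draws,
            warmup=mcmc.warmup,
            seed=mcmc.seed + 1000 * (i + 1),
            adapt_target=mcmc.adapt_target,
        )
        all_draws.update(_fit_one_stage(s, m, y, ages, pids, priors, sub))
        stage_meta[s] = {
            "paper_ids": pids,
            "ages": ages.astype(int).tolist(),
            "trials": m.astype(int).tolist(),
            "successes": y.astype(int).tolist(),
        }
    meta = {
        "model": "stages_hierarchical",
        "conditional": conditional,
        "stages": stage_meta,
        "config": mcmc,
    }
    post = PosteriorDraws(all_draws, meta)
    report = diagnose(post)
    post.meta["diagnostics"] = report
    post.meta["converged"] = report.ok
    if not report.ok:
        warnings.warn(f"stage 2-4 fit flagged parameters: {report.flags}")
    return post


# ---------------------------------------------------------------------------
# marginal stage probabilities


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)


def marginal_probability(phi: float, psi: float, gamma: float = 0.0) -> float:
    """E[logistic(phi + gamma + sqrt(psi) Z)], Z ~ N(0, 1), by quadrature.

    ``psi`` is the variance of the paper effect. 64-node Gauss-Hermite
    quadrature; exact at psi = 0 and symmetric about 0.5 when
    phi + gamma = 0.
    """
    if psi < 0:
        raise ValueError("psi (a variance) must be non-negative")
    if psi == 0:
        return float(expit(phi + gamma))
    s = np.sqrt(psi)
    vals = expit(phi + gamma + s * np.sqrt(2.0) * _GH_NODES)
    return float(np.sum(_GH_WEIGHTS * vals) / np.sqrt(np.pi))


def _marginal_draws(
    post: PosteriorDraws,
    stage: int,
    age_distribution: Mapping[int, float] | None,
    average: str,
) -> np.ndarray:
    info = post.meta["stages"][stage]
    ages = np.asarray(info["ages"], dtype=int)
    uniq = np.unique(ages)
    if age_distribution is None:
        # empirical age mix of the papers informing this stage
        w = np.array([(ages == v).sum() for v in uniq], dtype=float)
        w /= w.sum()
        age_w = dict(zip(uniq.tolist(), w))
    else:
        tot = float(sum(age_distribution.values()))
        age_w = {int(v): p / tot for v, p in age_distribution.items()}
    phi = post.flat(f"phi[{stage}]")
    psi = post.flat(f"psi[{stage}]")
    out = np.zeros_like(phi)
    if average == "population":
        for v, w_ in age_w.items():
            key = f"gamma[{stage},{v}]"
            gam = post.flat(key) if key in post.draws else np.zeros_like(phi)
            s = np.sqrt(psi)[:, None]
            vals = expit(phi[:, None] + gam[:, None] + s * np.sqrt(2.0) * _GH_NODES)
            out += w_ * (vals @ _GH_WEIGHTS) / np.sqrt(np.pi)
        return out
    if average == "sample":
        pids = info["paper_ids"]
        cols = []
        for pid, v in zip(pids, ages):
            gam_key = f"gamma[{stage},{int(v)}]"
            gam = post.flat(gam_key) if gam_key in post.draws else 0.0
            beta = post.flat(f"beta[{stage},{pid}]")
            cols.append(expit(phi + beta + gam))
        return np.mean(np.column_stack(cols), axis=1)
    raise ValueError("average must be 'population' or 'sample'")


def stage_year_effect_draws(post: PosteriorDraws, stage: int, age: int) -> np.ndarray:
    """Draws of the year effect gamma_s at ``age``.

    For an age among the fitted papers the stored draws are returned; for
    any other age the Gaussian-process conditional mean
    eta * c*(rho)' C(rho)^{-1} gamma is evaluated per draw (conditional
    spread is not re-sampled, so unobserved years are summarized by the
    smoother's mean path).
    """
    from scipy.linalg import solve_triangular

    key = f"gamma[{stage},{int(age)}]"
    if key in post.draws:
        return post.flat(key)
    info = post.meta["stages"][stage]
    uniq = np.unique(np.asarray(info["ages"], dtype=float))
    k = uniq.size
    eta = post.flat(f"eta[{stage}]")
    rho = post.flat(f"rho[{stage}]")
    gam = np.column_stack([post.flat(f"gamma[{stage},{int(v)}]") for v in uniq])
    out = np.empty(eta.shape)
    order = np.argsort(rho, kind="stable")
    cache_rho, L = None, None
    for idx in order:
        r = rho[idx]
        if r != cache_rho:
            L = np.linalg.cholesky(gp_cov(uniq, 1.0, r, 1e-8))
            cache_rho = r
        cstar = np.exp(-((uniq - age) ** 2) / (2.0 * r**2))
        # conditional mean: c*' C^-1 gamma via two triangular solves
        w = solve_triangular(L, gam[idx], lower=True)
        w = solve_triangular(L.T, w, lower=False)
        out[idx] = float(cstar @ w)
    return out


def marginal_stage_prob(
    post: PosteriorDraws,
    stage: int,
    age_distribution: Mapping[int, float] | None = None,
    average: str = "population",
    mass: float = DEFAULT_MASS,
) -> IntervalEstimate:
    """Marginal probability of passing ``stage`` with its narrowest interval.

    Per posterior draw the paper effect is integrated out by Gauss-Hermite
    quadrature over beta ~ Normal(0, sqrt(psi)) and the year effect averaged
    over ``age_distribution`` (default: the empirical age mix of the fitted
    papers). ``average="population"`` describes a new paper from the
    population; ``average="sample"`` averages the fitted papers' own
    effects.
    """
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    return summarize_draws(_marginal_draws(post, stage, age_distribution, average), mass)
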
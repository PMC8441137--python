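"""Stage 1: exponential decay of data recoverability with publication age.

Recovery of the data behind paper ``i`` is Bernoulli with

    p1_i = alpha_Y[i] * exp(-lam_Y[i] * v_i)

where ``v_i`` is years since publication and each study type ``Y`` (species
crossed with design) has its own recovery probability at age zero
``alpha_Y`` in (0, 1) and decay rate ``lam_Y`` >= 0 per year. The
exponential form reflects failure by any of many independent hazards (files
lost, archives retired, formats obsolete), whose product yields a
multiplicative decline; under it the expected recovery probability halves
every ln(2)/lam years, at any age. A logistic-link alternative
(logit p = a_Y + b_Y v) serves as a robustness check and has no constant
half-life.

Priors are regularizing and are validated by prior predictive simulation
(see :func:`datadecay.diagnostics.prior_predictive`): alpha ~ Beta(2, 2),
lam ~ Exponential(2) (prior median half-life about 2 years with a heavy
right tail); logistic intercepts Normal(0, 1.5) and slopes Normal(0, 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
from scipy.special import betaln, expit, logit

from .audit import STUDY_TYPES, AuditDataset
from .diagnostics import DEFAULT_MASS, IntervalEstimate, diagnose, summarize_draws
from .mcmc import MCMCConfig, PosteriorDraws, run_mwg

__all__ = [
    "Stage1Params",
    "LogisticStage1Params",
    "Stage1Priors",
    "LogisticPriors",
    "stage1_loglik",
    "fit_stage1",
    "fit_stage1_logistic",
    "half_life",
    "predict_recovery",
    "compare_links",
]


@dataclass(frozen=True)
class Stage1Params:
    """Per-type recovery-at-publication probabilities and decay rates."""

    alpha: dict[str, float]  # study_type -> alpha in (0, 1)
    lam: dict[str, float]  # study_type -> decay rate >= 0 per year

    def __post_init__(self) -> None:
        for t, a in self.alpha.items():
            if not 0.0 < a < 1.0:
                raise ValueError(f"alpha[{t!r}] = {a} outside the open interval (0, 1)")
        for t, l in self.lam.items():
            if l < 0:
                raise ValueError(f"lam[{t!r}] = {l} is negative")

    @classmethod
    def uniform(cls, alpha: float, lam: float) -> "Stage1Params":
        return cls(
            alpha={t: alpha for t in STUDY_TYPES},
            lam={t: lam for t in STUDY_TYPES},
        )


@dataclass(frozen=True)
class LogisticStage1Params:
    """Logistic-link alternative: logit(p) = a_Y + b_Y * age."""

    a: dict[str, float]
    b: dict[str, float]

    def __post_init__(self) -> None:
        for d in (self.a, self.b):
            for t, v in d.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite logistic parameter for {t!r}")


@dataclass(frozen=True)
class Stage1Priors:
    """alpha ~ Beta(alpha_a, alpha_b); lam ~ Exponential(lam_rate).

    ``alpha_fixed``/``lam_fixed`` collapse a prior to a point (used by prior
    predictive checks and the reduced single-parameter model).
    """

    alpha_a: float = 2.0
    alpha_b: float = 2.0
    lam_rate: float = 2.0
    alpha_fixed: float | None = None
    lam_fixed: float | None = None


@dataclass(frozen=True)
class LogisticPriors:
    a_sd: float = 1.5
    b_sd: float = 0.5


# ---------------------------------------------------------------------------
# likelihood


def _prepare(papers) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Extract (age, outcome, type-index) arrays; drop absent types."""
    if isinstance(papers, AuditDataset):
        frame = papers.papers
    else:
        frame = papers
    ages = frame["age"].to_numpy(dtype=float)
    if (ages < 0).any():
        raise ValueError("ages must be non-negative")
    x = frame["recovered"].to_numpy(dtype=float)
    present = [t for t in STUDY_TYPES if (frame["study_type"] == t).any()]
    absent = [t for t in STUDY_TYPES if t not in present]
    if absent:
        warnings.warn(f"study types absent from data are dropped: {absent}")
    t_idx = frame["study_type"].map({t: i for i, t in enumerate(present)}).to_numpy()
    return ages, x, t_idx.astype(int), present


def stage1_loglik(params: Stage1Params, papers) -> float:
    """Bernoulli log-likelihood of recovery outcomes under the decay model.

    Returns -inf (never raises) when a probability rounds to 0 or 1 against
    the observed outcome.
    """
    ages, x, t_idx, present = _prepare(papers)
    alpha = np.array([params.alpha[t] for t in present])
    lam = np.array([params.lam[t] for t in present])
    logp = np.log(alpha)[t_idx] - lam[t_idx] * ages
    p = np.exp(logp)
    with np.errstate(divide="ignore"):
        log1mp = np.log1p(-p)
        ll = x * logp + (1.0 - x) * log1mp
    total = float(np.sum(ll))
    return total if np.isfinite(total) else float("-inf")


def half_life(lam) -> float | np.ndarray:
    """Years over which expected recovery probability halves: ln(2)/lam."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError(
            "half-life is defined only for a positive decay rate "
            "(the logistic link has no constant half-life)"
        )
    out = np.log(2.0) / lam
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# posterior inference


def _stage1_logpost_factory(ages, x, t_idx, n_types, priors: Stage1Priors):
    """Log posterior over the unconstrained vector [logit(alpha), log(lam)].

    Fixed-alpha variant (priors.alpha_fixed) reduces the vector to the decay
    rates only.
    """
    fixed_alpha = priors.alpha_fixed
    a_a, a_b, rate = priors.alpha_a, priors.alpha_b, priors.lam_rate
    beta_const = -betaln(a_a, a_b)

    def logpost(theta: np.ndarray) -> float:
        if fixed_alpha is None:
            la, ll_ = theta[:n_types], theta[n_types:]
            alpha = expit(la)
        else:
            ll_ = theta
            alpha = np.full(n_types, fixed_alpha)
        lam = np.exp(ll_)
        logalpha = np.log(alpha)
        logp = logalpha[t_idx] - lam[t_idx] * ages
        p = np.exp(logp)
        with np.errstate(divide="ignore"):
            loglik = np.sum(x * logp + (1.0 - x) * np.log1p(-p))
        if not np.isfinite(loglik):
            return float("-inf")
        # Beta prior on alpha with the logit Jacobian alpha(1-alpha):
        lp = loglik
        if fixed_alpha is None:
            lp += float(
                np.sum(
                    beta_const + a_a * np.log(alpha) + a_b * np.log1p(-alpha)
                )
            )
        # Exponential prior on lam with the log Jacobian lam:
        lp += float(np.sum(np.log(rate) - rate * lam + ll_))
        return lp

    return logpost


def fit_stage1(
    papers,
    priors: Stage1Priors = Stage1Priors(),
    mcmc: MCMCConfig = MCMCConfig(),
) -> PosteriorDraws:
    """Posterior draws of (alpha_Y, lam_Y) under the exponential decay model.

    Study types absent from the data are dropped with a warning. Convergence
    flags (R-hat > 1.01 or low ESS) are attached to ``meta['diagnostics']``
    and surfaced via ``meta['converged']``, never silently discarded.
    """
    ages, x, t_idx, present = _prepare(papers)
    n_types = len(present)
    if n_types == 0:
        raise ValueError("no papers to fit")
    logpost = _stage1_logpost_factory(ages, x, t_idx, n_types, priors)

    fixed = priors.alpha_fixed is not None
    dim = n_types if fixed else 2 * n_types

    def init(rng: np.random.Generator) -> np.ndarray:
        lam0 = np.log(rng.uniform(0.02, 0.5, size=n_types))
        if fixed:
            return lam0
        a0 = logit(rng.uniform(0.2, 0.8, size=n_types))
        return np.concatenate([a0, lam0])

    raw = run_mwg(logpost, init, dim, mcmc)
    draws: dict[str, np.ndarray] = {}
    if not fixed:
        for i, t in enumerate(present):
            draws[f"alpha[{t}]"] = expit(raw[:, :, i])
    for i, t in enumerate(present):
        draws[f"lam[{t}]"] = np.exp(raw[:, :, (0 if fixed else n_types) + i])

    type_counts = {t: int(np.sum(t_idx == i)) for i, t in enumerate(present)}
    meta = {
        "model": "stage1_exponential",
        "link": "exponential",
        "types": present,
        "type_counts": type_counts,
        "ages": ages.astype(int).tolist(),
        "type_index": t_idx.tolist(),
        "fixed_alpha": priors.alpha_fixed,
        "config": mcmc,
    }
    post = PosteriorDraws(draws, meta)
    report = diagnose(post)
    post.meta["diagnostics"] = report
    post.meta["converged"] = report.ok
    if not report.ok:
        warnings.warn(
            f"stage-1 fit flagged parameters: {report.flags} "
            "(inspect meta['diagnostics'])"
        )
    return post


def fit_stage1_logistic(
    papers,
    priors: LogisticPriors = LogisticPriors(),
    mcmc: MCMCConfig = MCMCConfig(),
) -> PosteriorDraws:
    """Posterior draws of the logistic-link alternative logit(p) = a_Y + b_Y v."""
    ages, x, t_idx, present = _prepare(papers)
    n_types = len(present)
    a_sd, b_sd = priors.a_sd, priors.b_sd

    def logpost(theta: np.ndarray) -> float:
        a, b = theta[:n_types], theta[n_types:]
        lin = a[t_idx] + b[t_idx] * ages
        # Bernoulli loglik via stable log-sigmoid terms.
        loglik = -np.sum(np.logaddexp(0.0, -lin) * x + np.logaddexp(0.0, lin) * (1 - x))
        lp = loglik
        lp += -0.5 * float(np.sum((a / a_sd) ** 2))
        lp += -0.5 * float(np.sum((b / b_sd) ** 2))
        return float(lp)

    def init(rng: np.random.Generator) -> np.ndarray:
        return np.concatenate(
            [rng.normal(0, 0.5, size=n_types), rng.normal(0, 0.1, size=n_types)]
        )

    raw = run_mwg(logpost, init, 2 * n_types, mcmc)
    draws = {}
    for i, t in enumerate(present):
        draws[f"a[{t}]"] = raw[:, :, i]
        draws[f"b[{t}]"] = raw[:, :, n_types + i]
    meta = {
        "model": "stage1_logistic",
        "link": "logistic",
        "types": present,
        "type_counts": {t: int(np.sum(t_idx == i)) for i, t in enumerate(present)},
        "ages": ages.astype(int).tolist(),
        "type_index": t_idx.tolist(),
        "config": mcmc,
    }
    post = PosteriorDraws(draws, meta)
    report = diagnose(post)
    post.meta["diagnostics"] = report
    post.meta["converged"] = report.ok
    if not report.ok:
        warnings.warn(f"logistic stage-1 fit flagged parameters: {report.flags}")
    return post


# ---------------------------------------------------------------------------
# predictions and model comparison


def _recovery_draw_matrix(post: PosteriorDraws, age: float) -> np.ndarray:
    """(total draws, n_types) matrix of p1 at ``age`` per study type."""
    types = post.meta["types"]
    if post.meta["link"] == "exponential":
        cols = []
        for t in types:
            lam = post.flat(f"lam[{t}]")
            if post.meta.get("fixed_alpha") is not None:
                alpha = np.full_like(lam, post.meta["fixed_alpha"])
            else:
                alpha = post.flat(f"alpha[{t}]")
            cols.append(alpha * np.exp(-lam * age))
        return np.column_stack(cols)
    cols = [
        expit(post.flat(f"a[{t}]") + post.flat(f"b[{t}]") * age) for t in types
    ]
    return np.column_stack(cols)


def recovery_draws(
    post: PosteriorDraws, age: float, study_type: str | None = None
) -> np.ndarray:
    """Draw vector of recovery probability at ``age``.

    ``study_type=None`` marginalizes over the fitted sample's type mix
    (weights proportional to the per-type paper counts).
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    mat = _recovery_draw_matrix(post, age)
    types = post.meta["types"]
    if study_type is not None:
        return mat[:, types.index(study_type)]
    counts = np.array([post.meta["type_counts"][t] for t in types], dtype=float)
    w = counts / counts.sum()
    return mat @ w


def predict_recovery(
    post: PosteriorDraws,
    age: float,
    study_type: str | None = None,
    mass: float = DEFAULT_MASS,
) -> IntervalEstimate:
    """Posterior-mean recovery probability at ``age`` with its narrowest interval."""
    return summarize_draws(recovery_draws(post, age, study_type), mass)


def _pointwise_loglik(post: PosteriorDraws) -> np.ndarray:
    """(total draws, n_papers) Bernoulli pointwise log-likelihood matrix."""
    ages = np.asarray(post.meta["ages"], dtype=float)
    t_idx = np.asarray(post.meta["type_index"], dtype=int)
    types = post.meta["types"]
    x = post.meta["outcomes"]
    x = np.asarray(x, dtype=float)
    n_draws = post.n_chains * post.n_draws
    ll = np.empty((n_draws, ages.size))
    if post.meta["link"] == "exponential":
        alpha = np.column_stack(
            [
                post.flat(f"alpha[{t}]")
                if post.meta.get("fixed_alpha") is None
                else np.full(n_draws, post.meta["fixed_alpha"])
                for t in types
            ]
        )
        lam = np.column_stack([post.flat(f"lam[{t}]") for t in types])
        logp = np.log(alpha[:, t_idx]) - lam[:, t_idx] * ages[None, :]
        with np.errstate(divide="ignore"):
            ll = x[None, :] * logp + (1 - x)[None, :] * np.log1p(-np.exp(logp))
    else:
        a = np.column_stack([post.flat(f"a[{t}]") for t in types])
        b = np.column_stack([post.flat(f"b[{t}]") for t in types])
        lin = a[:, t_idx] + b[:, t_idx] * ages[None, :]
        ll = -(
            np.logaddexp(0.0, -lin) * x[None, :]
            + np.logaddexp(0.0, lin) * (1 - x)[None, :]
        )
    return ll


def compare_links(papers, post_exp: PosteriorDraws, post_logit: PosteriorDraws) -> dict:
    """WAIC comparison of the exponential and logistic stage-1 links.

    Returns elpd estimates (higher is better) and the preferred model label.
    """
    _, x, _, _ = _prepare(papers)
    scores = {}
    for label, post in (("exponential", post_exp), ("logistic", post_logit)):
        post.meta["outcomes"] = x.tolist()
        ll = _pointwise_loglik(post)
        # WAIC: lppd - p_waic, computed pointwise.
        m = ll.max(axis=0)
        lppd = np.sum(m + np.log(np.mean(np.exp(ll - m), axis=0)))
        p_waic = np.sum(np.var(ll, axis=0, ddof=1))
        scores[label] = float(lppd - p_waic)
    preferred = max(scores, key=scores.get)
    return {"elpd": scores, "preferred": preferred}
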
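"""Combined reproducibility summaries and the end-to-end pipeline.

The overall probability that any particular result of a paper reproduces is
the product of the four stage probabilities, each conditional on passing
all previous stages:

    p(r) = p1 * p2 * p3 * p4

Draw-wise multiplication of the stage posteriors propagates uncertainty
into p(r); consequently p(r) never exceeds any single stage probability,
draw by draw. Pooled quantities average draw-wise over the empirical
(age, type) rows of the input dataset; year-specific quantities evaluate
the decay curve and the stage-model year effects at one publication year.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .audit import AuditDataset, read_audit_table, summarize_counts
from .diagnostics import DEFAULT_MASS, IntervalEstimate, summarize_draws
from .mcmc import MCMCConfig, PosteriorDraws
from .stage1 import fit_stage1, half_life, predict_recovery, recovery_draws
from .stages import STAGES, fit_stages, marginal_stage_prob, stage_year_effect_draws
from .simulate import SimulationConfig, TrueParams, simulate_dataset

__all__ = [
    "combined_rate",
    "success_by_year",
    "half_life_table",
    "SummaryReport",
    "PipelineResult",
    "run_pipeline",
]

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)


def combined_rate(p1, p2, p3, p4):
    """Element-wise product of the four stage probabilities.

    Accepts scalars or draw vectors (all of one length); vector inputs are
    multiplied draw-wise so posterior uncertainty propagates into p(r).
    """
    arrs = [np.asarray(p, dtype=float) for p in (p1, p2, p3, p4)]
    lengths = {a.shape for a in arrs if a.ndim > 0}
    if len(lengths) > 1:
        raise ValueError(f"draw vectors differ in length: {sorted(lengths)}")
    for a in arrs:
        if np.any((a < 0) | (a > 1)):
            raise ValueError("stage probabilities must lie in [0, 1]")
    out = arrs[0] * arrs[1] * arrs[2] * arrs[3]
    return float(out) if out.ndim == 0 else out


def _stage1_marginal_draws(post: PosteriorDraws) -> np.ndarray:
    """p1 averaged draw-wise over the fitted sample's (age, type) rows."""
    ages = np.asarray(post.meta["ages"], dtype=float)
    t_idx = np.asarray(post.meta["type_index"], dtype=int)
    types = post.meta["types"]
    lam = np.column_stack([post.flat(f"lam[{t}]") for t in types])
    if post.meta.get("fixed_alpha") is not None:
        alpha = np.full_like(lam, post.meta["fixed_alpha"])
    else:
        alpha = np.column_stack([post.flat(f"alpha[{t}]") for t in types])
    p = alpha[:, t_idx] * np.exp(-lam[:, t_idx] * ages[None, :])
    return p.mean(axis=1)


def _stage_prob_draws_at_age(post: PosteriorDraws, stage: int, age: int) -> np.ndarray:
    """Population-average stage probability at one age, per draw."""
    from scipy.special import expit

    phi = post.flat(f"phi[{stage}]")
    psi = post.flat(f"psi[{stage}]")
    gam = stage_year_effect_draws(post, stage, age)
    s = np.sqrt(psi)[:, None]
    vals = expit(phi[:, None] + gam[:, None] + s * np.sqrt(2.0) * _GH_NODES)
    return (vals @ _GH_WEIGHTS) / np.sqrt(np.pi)


def _align(*vecs: np.ndarray) -> list[np.ndarray]:
    n = min(v.size for v in vecs)
    return [v[:n] for v in vecs]


def success_by_year(
    stage1_post: PosteriorDraws,
    stages_post: PosteriorDraws,
    year: int,
    reference_year: int,
    mass: float = DEFAULT_MASS,
) -> IntervalEstimate:
    """Overall reproduction probability for a paper published in ``year``.

    Evaluates the decay curve at age = reference_year - year (marginal over
    the fitted type mix), the stage 2-4 probabilities at the matching year
    effect, and multiplies draw-wise. Warns when the year falls outside the
    fitted range (the Gaussian-process year effect is then an
    extrapolation).
    """
    if year > reference_year:
        raise ValueError("year must not exceed the reference year")
    age = reference_year - year
    fitted_ages = [
        a for s in STAGES for a in stages_post.meta["stages"].get(s, {}).get("ages", [])
    ]
    s1_ages = stage1_post.meta["ages"]
    if age > max(max(fitted_ages, default=0), max(s1_ages)) or age < min(
        min(fitted_ages, default=age), min(s1_ages)
    ):
        warnings.warn(
            f"year {year} (age {age}) lies outside the fitted range; "
            "the estimate is an extrapolation"
        )
    p1 = recovery_draws(stage1_post, age)
    stage_draws = [_stage_prob_draws_at_age(stages_post, s, age) for s in STAGES]
    p1, p2, p3, p4 = _align(p1, *stage_draws)
    return summarize_draws(combined_rate(p1, p2, p3, p4), mass)


def _pooled_half_life_draws(post: PosteriorDraws) -> np.ndarray:
    """Per-draw first halving time of the type-marginal decay curve."""
    types = post.meta["types"]
    counts = np.array([post.meta["type_counts"][t] for t in types], dtype=float)
    w = counts / counts.sum()
    lam = np.column_stack([post.flat(f"lam[{t}]") for t in types])
    if post.meta.get("fixed_alpha") is not None:
        alpha = np.full_like(lam, post.meta["fixed_alpha"])
    else:
        alpha = np.column_stack([post.flat(f"alpha[{t}]") for t in types])
    out = np.empty(lam.shape[0])
    for d in range(lam.shape[0]):
        a, l = alpha[d], lam[d]
        top = float(np.sum(w * a))

        def f(t):
            return float(np.sum(w * a * np.exp(-l * t))) - 0.5 * top

        if np.all(l <= 1e-12):
            out[d] = np.inf
            continue
        hi = 2.0
        while f(hi) > 0 and hi < 1e6:
            hi *= 2.0
        out[d] = brentq(f, 0.0, hi)
    return out


def half_life_table(post: PosteriorDraws, mass: float = DEFAULT_MASS) -> pd.DataFrame:
    """Per-type and pooled data half-lives with narrowest intervals.

    Requires an exponential-link posterior; the logistic robustness model
    has no constant half-life and is rejected.
    """
    if post.meta.get("link") != "exponential":
        raise ValueError(
            "half-lives are defined only for the exponential decay model"
        )
    rows = []
    for t in post.meta["types"]:
        hl = half_life(post.flat(f"lam[{t}]"))
        iv = summarize_draws(hl, mass)
        rows.append((t, iv.mean, iv.lower, iv.upper))
    pooled = _pooled_half_life_draws(post)
    finite = pooled[np.isfinite(pooled)]
    iv = summarize_draws(finite, mass)
    rows.append(("pooled", iv.mean, iv.lower, iv.upper))
    return pd.DataFrame(rows, columns=["study_type", "half_life", "lower", "upper"])


# ---------------------------------------------------------------------------
# summary report and pipeline


def _iv_dict(iv: IntervalEstimate | None, ndigits: int = 4) -> dict | None:
    if iv is None:
        return None
    return {
        "mean": round(iv.mean, ndigits),
        "lower": round(iv.lower, ndigits),
        "upper": round(iv.upper, ndigits),
        "mass": iv.mass,
    }


@dataclass
class SummaryReport:
    """Headline quantities of one audit analysis."""

    p1: IntervalEstimate
    p2: IntervalEstimate | None
    p3: IntervalEstimate | None
    p4: IntervalEstimate | None
    p_r: IntervalEstimate | None
    half_lives: pd.DataFrame
    p_r_by_year: dict[int, IntervalEstimate] = field(default_factory=dict)
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "p1": _iv_dict(self.p1),
            "p2": _iv_dict(self.p2),
            "p3": _iv_dict(self.p3),
            "p4": _iv_dict(self.p4),
            "p_r": _iv_dict(self.p_r),
            "half_lives": self.half_lives.round(4).to_dict(orient="records"),
            "p_r_by_year": {
                str(y): _iv_dict(iv) for y, iv in self.p_r_by_year.items()
            },
            "seed": self.seed,
            "config": self.config,
        }
        # display block rounded the way audit reports print them:
        # probabilities to 2 decimals, half-lives to 1.
        d["display"] = {
            "p1": round(self.p1.mean, 2),
            "p2": None if self.p2 is None else round(self.p2.mean, 2),
            "p3": None if self.p3 is None else round(self.p3.mean, 2),
            "p4": None if self.p4 is None else round(self.p4.mean, 2),
            "p_r": None if self.p_r is None else round(self.p_r.mean, 2),
            "half_lives": {
                r["study_type"]: round(r["half_life"], 1)
                for r in self.half_lives.to_dict(orient="records")
            },
        }
        return d

    def as_text(self) -> str:
        def fmt(name, iv):
            if iv is None:
                return f"{name}: unavailable"
            return (
                f"{name}: {iv.mean:.2f} "
                f"({iv.mass:.0%} HPDI {iv.lower:.2f}-{iv.upper:.2f})"
            )

        lines = [
            fmt("p1 (data recovery)", self.p1),
            fmt("p2 (data usability | recovery)", self.p2),
            fmt("p3 (analytical clarity | usability)", self.p3),
            fmt("p4 (results agreement | clarity)", self.p4),
            fmt("p(r) overall", self.p_r),
            "half-lives (years):",
        ]
        for r in self.half_lives.itertuples(index=False):
            lines.append(
                f"  {r.study_type}: {r.half_life:.1f} "
                f"({r.lower:.1f}-{r.upper:.1f})"
            )
        for y in sorted(self.p_r_by_year):
            iv = self.p_r_by_year[y]
            lines.append(
                f"p(r) for {y}: {iv.mean:.2f} ({iv.lower:.2f}-{iv.upper:.2f})"
            )
        return "\n".join(lines)


@dataclass
class PipelineResult:
    report: SummaryReport
    stage1_post: PosteriorDraws
    stages_post: PosteriorDraws | None
    dataset: AuditDataset
    flagged: list[str]
    outputs: dict[str, str] = field(default_factory=dict)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def build_report(
    dataset: AuditDataset,
    stage1_post: PosteriorDraws,
    stages_post: PosteriorDraws | None,
    years: list[int] | None = None,
    mass: float = DEFAULT_MASS,
    seed: int | None = None,
    config: dict | None = None,
) -> SummaryReport:
    """Assemble the summary report from fitted posteriors."""
    p1_draws = _stage1_marginal_draws(stage1_post)
    p1 = summarize_draws(p1_draws, mass)
    hl = half_life_table(stage1_post, mass)
    p2 = p3 = p4 = p_r = None
    by_year: dict[int, IntervalEstimate] = {}
    if stages_post is not None and stages_post.draws:
        ps = {s: marginal_stage_prob(stages_post, s, mass=mass) for s in STAGES}
        p2, p3, p4 = ps[2], ps[3], ps[4]
        stage_draws = {
            s: np.asarray(
                _marginal_population_draws(stages_post, s), dtype=float
            )
            for s in STAGES
        }
        a, b, c, d = _align(p1_draws, *stage_draws.values())
        p_r = summarize_draws(combined_rate(a, b, c, d), mass)
        if years is None:
            ref = dataset.reference_year
            ages = sorted(
                {a for s in STAGES for a in stages_post.meta["stages"][s]["ages"]}
            )
            years = [ref - a for a in ages]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for y in years:
                by_year[y] = success_by_year(
                    stage1_post, stages_post, y, dataset.reference_year, mass
                )
    return SummaryReport(
        p1=p1,
        p2=p2,
        p3=p3,
        p4=p4,
        p_r=p_r,
        half_lives=hl,
        p_r_by_year=by_year,
        seed=seed,
        config=config or {},
    )


def _marginal_population_draws(post: PosteriorDraws, stage: int) -> np.ndarray:
    from .stages import _marginal_draws

    return _marginal_draws(post, stage, None, "population")


def run_pipeline(config) -> PipelineResult:
    """Execute read/simulate -> fit stage 1 -> fit stages 2-4 -> report.

    ``config`` is a dict or YAML path with keys::

        seed: int
        reference_year: int (default 2019)
        inputs: {papers: path, results: path (optional)}   # or:
        simulate: {n_papers: ..., results_subsample_size: ...}  # generator knobs
        mcmc: {chains: 4, draws: 2500, warmup: 1000}
        out_dir: path (optional; artifacts written when present)
        figures: bool (default false)

    Every artifact echoes the seed and configuration. When results data are
    absent a stage-1-only report is produced. Convergence flags never stop
    the pipeline; they are surfaced in ``flagged`` (the CLI exits non-zero
    on them).
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    reference_year = int(cfg.get("reference_year", 2019))
    mcfg = cfg.get("mcmc", {})
    mcmc = MCMCConfig(
        chains=int(mcfg.get("chains", 4)),
        draws=int(mcfg.get("draws", 2500)),
        warmup=int(mcfg.get("warmup", 1000)),
        seed=seed,
    )

    if "inputs" in cfg:
        inputs = cfg["inputs"]
        results_path = inputs.get("results")
        dataset = read_audit_table(
            inputs["papers"], results_path, reference_year=reference_year
        )
    else:
        sim = cfg.get("simulate") or {}
        sim_cfg = SimulationConfig(
            n_papers=int(sim.get("n_papers", 560)),
            results_subsample_size=int(sim.get("results_subsample_size", 40)),
            reference_year=reference_year,
            seed=seed,
        )
        dataset, _ = simulate_dataset(sim_cfg, TrueParams())

    stage1_post = fit_stage1(dataset.papers, mcmc=mcmc)
    stages_post = None
    if len(dataset.results) >= 2:
        stages_post = fit_stages(dataset, mcmc=mcmc)

    report = build_report(
        dataset, stage1_post, stages_post, seed=seed, config=cfg
    )
    flagged = []
    if not stage1_post.meta["converged"]:
        flagged += [f"stage1:{p}" for p in stage1_post.meta["diagnostics"].flags]
    if stages_post is not None and not stages_post.meta["converged"]:
        flagged += [f"stages:{p}" for p in stages_post.meta["diagnostics"].flags]

    outputs: dict[str, str] = {}
    out_dir = cfg.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        stage1_post.to_csv(out / "post_stage1.csv")
        outputs["summary"] = str(out / "summary.json")
        outputs["post_stage1"] = str(out / "post_stage1.csv")
        diag_text = [stage1_post.meta["diagnostics"].as_text()]
        if stages_post is not None:
            stages_post.to_csv(out / "post_stages.csv")
            outputs["post_stages"] = str(out / "post_stages.csv")
            diag_text.append(stages_post.meta["diagnostics"].as_text())
        (out / "diagnostics.txt").write_text("\n\n".join(diag_text) + "\n")
        outputs["diagnostics"] = str(out / "diagnostics.txt")
        counts = summarize_counts(dataset)
        (out / "counts.txt").write_text(counts.as_text() + "\n")
        outputs["counts"] = str(out / "counts.txt")
        if cfg.get("figures"):
            try:
                figs = _write_figures(out, dataset, stage1_post, report)
                outputs.update(figs)
            except Exception as exc:  # plotting backend absent: degrade to tables
                warnings.warn(f"figure generation skipped: {exc}")
    return PipelineResult(
        report=report,
        stage1_post=stage1_post,
        stages_post=stages_post,
        dataset=dataset,
        flagged=flagged,
        outputs=outputs,
    )


def _write_figures(out: Path, dataset, stage1_post, report) -> dict[str, str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outputs = {}
    # decay curve: the plotted expectation IS predict_recovery on a grid
    ages = np.arange(0, 41)
    est = [predict_recovery(stage1_post, a) for a in ages]
    means = [e.mean for e in est]
    los = [e.lower for e in est]
    his = [e.upper for e in est]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ages, means, color="k")
    ax.fill_between(ages, los, his, alpha=0.25, color="grey")
    obs = dataset.papers.groupby("age")["recovered"].agg(["mean", "size"])
    ax.scatter(
        obs.index,
        obs["mean"],
        s=4 * np.sqrt(obs["size"]) * 4,
        facecolors="none",
        edgecolors="steelblue",
    )
    ax.set_xlabel("years since publication")
    ax.set_ylabel("probability of data recovery")
    fig.tight_layout()
    fig.savefig(out / "decay_curve.png", dpi=120)
    plt.close(fig)
    outputs["fig_decay"] = str(out / "decay_curve.png")

    fig, ax = plt.subplots(figsize=(6, 4))
    tbl = report.half_lives
    ax.errorbar(
        tbl["half_life"],
        np.arange(len(tbl)),
        xerr=[tbl["half_life"] - tbl["lower"], tbl["upper"] - tbl["half_life"]],
        fmt="o",
        color="k",
    )
    ax.set_yticks(np.arange(len(tbl)))
    ax.set_yticklabels(tbl["study_type"])
    ax.set_xlabel("data half-life (years)")
    fig.tight_layout()
    fig.savefig(out / "half_lives.png", dpi=120)
    plt.close(fig)
    outputs["fig_half_lives"] = str(out / "half_lives.png")
    return outputs
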
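"""Decay-model likelihood, half-life transforms, fits and the logistic check."""

import warnings

import numpy as np
import pandas as pd
import pytest

from datadecay.audit import STUDY_TYPES
from datadecay.mcmc import MCMCConfig, PosteriorDraws
from datadecay.simulate import SimulationConfig, TrueParams, simulate_dataset
from datadecay.stage1 import (
    LogisticPriors,
    Stage1Params,
    Stage1Priors,
    compare_links,
    fit_stage1,
    fit_stage1_logistic,
    half_life,
    predict_recovery,
    stage1_loglik,
)


def _papers(rows):
    frame = pd.DataFrame(rows, columns=["age", "study_type", "recovered"])
    frame["paper_id"] = [f"p{i}" for i in range(len(frame))]
    return frame


HE = "human_experimental"


def test_loglik_age_zero_is_log_alpha():
    params = Stage1Params.uniform(0.5, 0.3)
    papers = _papers([(0, HE, 1)])
    assert stage1_loglik(params, papers) == pytest.approx(np.log(0.5), abs=1e-4)


def test_loglik_symmetric_bernoulli():
    params = Stage1Params.uniform(0.5, 0.0)
    papers = _papers([(0, HE, 1), (0, HE, 0)])
    assert stage1_loglik(params, papers) == pytest.approx(2 * np.log(0.5), abs=1e-4)


def test_alpha_on_boundary_rejected():
    with pytest.raises(ValueError, match="open interval"):
        Stage1Params.uniform(1.0, 0.1)
    with pytest.raises(ValueError, match="negative"):
        Stage1Params.uniform(0.5, -0.1)


def test_loglik_contradiction_returns_neg_inf_not_crash():
    """When the recovery probability saturates to 1.0 against an observed
    failure the log posterior is -inf, never an exception."""
    from datadecay.stage1 import _prepare, _stage1_logpost_factory

    papers = _papers([(0, HE, 0)])
    ages, x, t_idx, _ = _prepare(papers)
    logpost = _stage1_logpost_factory(ages, x, t_idx, 1, Stage1Priors())
    # logit(alpha) = 50 saturates expit to exactly 1.0 in double precision
    assert logpost(np.array([50.0, np.log(0.1)])) == -np.inf


def test_half_life_closed_form():
    assert half_life(np.log(2)) == pytest.approx(1.0)
    assert half_life(0.1216) == pytest.approx(5.70, abs=0.005)
    with pytest.raises(ValueError):
        half_life(0.0)
    with pytest.raises(ValueError):
        half_life(-1.0)


def test_half_life_identity_on_grid():
    for lam in (0.01, 0.1216, 0.7, 2.0):
        t_half = half_life(lam)
        for v in (0.0, 1.0, 7.5, 40.0):
            p = 0.8 * np.exp(-lam * v)
            p_shift = 0.8 * np.exp(-lam * (v + t_half))
            assert abs(p_shift - p / 2) < 1e-12


def _degenerate_post(alpha, lam):
    draws = {}
    for t in STUDY_TYPES:
        draws[f"alpha[{t}]"] = np.full((2, 4), alpha)
        draws[f"lam[{t}]"] = np.full((2, 4), lam)
    meta = {
        "model": "stage1_exponential",
        "link": "exponential",
        "types": list(STUDY_TYPES),
        "type_counts": {t: 1 for t in STUDY_TYPES},
        "ages": [0, 5, 10, 20],
        "type_index": [0, 1, 2, 3],
    }
    return PosteriorDraws(draws, meta)


def test_predict_recovery_degenerate_draws():
    post = _degenerate_post(0.6, 0.1)
    assert predict_recovery(post, 0.0).mean == pytest.approx(0.6)
    assert predict_recovery(post, np.log(2) / 0.1).mean == pytest.approx(0.3)
    with pytest.raises(ValueError):
        predict_recovery(post, -1.0)


def test_posterior_mean_prediction_decreases_with_age(stage1_post):
    grid = np.arange(0, 41)
    means = np.array([predict_recovery(stage1_post, a).mean for a in grid])
    assert np.all(np.diff(means) < 0)
    assert ((means > 0) & (means < 1)).all()


def test_fit_recovers_truth_roughly(stage1_post, sim_audit):
    _, _, truth = sim_audit
    for t in STUDY_TYPES:
        a = stage1_post.flat(f"alpha[{t}]").mean()
        assert 0.5 < a < 1.0  # truth alpha = 0.85
    assert stage1_post.meta["diagnostics"] is not None


def test_mwg_and_emcee_agree_on_single_type_posterior():
    """Independent samplers must agree on the same stage-1 posterior."""
    import emcee

    from datadecay.stage1 import _prepare, _stage1_logpost_factory

    truth = TrueParams(stage1=Stage1Params.uniform(0.8, 0.12))
    cfg = SimulationConfig(
        n_papers=500,
        results_subsample_size=1,
        type_probabilities={t: float(t == HE) for t in STUDY_TYPES},
        seed=13,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds, _ = simulate_dataset(cfg, truth)
        ages, x, t_idx, present = _prepare(ds.papers)
        logpost = _stage1_logpost_factory(ages, x, t_idx, 1, Stage1Priors())
        post = fit_stage1(
            ds.papers, mcmc=MCMCConfig(chains=4, draws=1500, warmup=800, seed=5)
        )

    rng = np.random.default_rng(17)
    nwalkers = 16
    p0 = np.column_stack(
        [rng.normal(0.5, 0.3, nwalkers), np.log(rng.uniform(0.05, 0.3, nwalkers))]
    )
    sampler = emcee.EnsembleSampler(nwalkers, 2, lambda th: logpost(th))
    sampler.run_mcmc(p0, 2000, progress=False)
    chain = sampler.get_chain(discard=500, flat=True)
    from scipy.special import expit

    em_alpha = expit(chain[:, 0]).mean()
    em_lam = np.exp(chain[:, 1]).mean()

    a = post.flat(f"alpha[{HE}]")
    l = post.flat(f"lam[{HE}]")
    tab = post.meta["diagnostics"].table.set_index("parameter")
    for mine, other, name in (
        (a, em_alpha, f"alpha[{HE}]"),
        (l, em_lam, f"lam[{HE}]"),
    ):
        mcse = mine.std() / np.sqrt(tab.loc[name, "ess"])
        em_mcse = mine.std() / np.sqrt(500)  # conservative floor for emcee
        assert abs(mine.mean() - other) < 3 * np.hypot(mcse, em_mcse)


def test_logistic_fit_recovers_negative_slope():
    """Data decaying exponentially must yield a negative logistic age slope."""
    truth = TrueParams(stage1=Stage1Params.uniform(0.8, 0.15))
    hits = 0
    reps = 20
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(reps):
            cfg = SimulationConfig(
                n_papers=400,
                results_subsample_size=1,
                type_probabilities={t: float(t == HE) for t in STUDY_TYPES},
                seed=100 + r,
            )
            ds, _ = simulate_dataset(cfg, truth)
            post = fit_stage1_logistic(
                ds.papers, mcmc=MCMCConfig(chains=2, draws=400, warmup=400, seed=r)
            )
            hits += post.flat(f"b[{HE}]").mean() < 0
    assert hits >= 18


def test_logistic_null_slope_interval_covers_zero():
    truth = TrueParams(stage1=Stage1Params.uniform(0.6, 0.0))
    cfg = SimulationConfig(
        n_papers=600,
        results_subsample_size=1,
        type_probabilities={t: float(t == HE) for t in STUDY_TYPES},
        seed=23,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds, _ = simulate_dataset(cfg, truth)
        post = fit_stage1_logistic(
            ds.papers, mcmc=MCMCConfig(chains=2, draws=800, warmup=600, seed=2)
        )
    from datadecay.diagnostics import summarize_draws

    iv = summarize_draws(post.flat(f"b[{HE}]"))
    assert iv.covers(0.0)


def test_model_comparison_returns_finite_scores(stage1_post, sim_audit):
    ds, _, _ = sim_audit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post_logit = fit_stage1_logistic(
            ds.papers, mcmc=MCMCConfig(chains=2, draws=400, warmup=400, seed=3)
        )
    cmp = compare_links(ds.papers, stage1_post, post_logit)
    assert np.isfinite(cmp["elpd"]["exponential"])
    assert np.isfinite(cmp["elpd"]["logistic"])
    assert cmp["preferred"] in {"exponential", "logistic"}


def test_all_failures_push_alpha_low_without_crash():
    rng = np.random.default_rng(0)
    frame = pd.DataFrame(
        {
            "paper_id": [f"p{i}" for i in range(120)],
            "age": rng.integers(0, 30, 120),
            "study_type": HE,
            "recovered": 0,
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = fit_stage1(
            frame, mcmc=MCMCConfig(chains=2, draws=500, warmup=500, seed=4)
        )
    assert post.flat(f"alpha[{HE}]").mean() < 0.4
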
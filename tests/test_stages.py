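"""GP covariance, conditional binomial likelihood, hierarchical fits."""

import warnings

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import binom

from datadecay.audit import MonotonicityError, ResultsRecord
from datadecay.mcmc import MCMCConfig
from datadecay.simulate import SimulationConfig, TrueParams, simulate_dataset
from datadecay.stages import (
    HierParams,
    StageParams,
    fit_stages,
    gp_cov,
    marginal_probability,
    marginal_stage_prob,
    stage_year_effect_draws,
    stages_loglik,
)


# -- gp_cov -----------------------------------------------------------------


def test_gp_cov_flat_limit():
    K = gp_cov(np.array([0.0, 5.0, 30.0]), amplitude=1.0, lengthscale=1e6)
    assert np.allclose(K, 1.0, atol=1e-6)


def test_gp_cov_zero_amplitude_is_jitter_diagonal():
    K = gp_cov(np.array([0.0, 3.0, 9.0]), amplitude=0.0, lengthscale=5.0, jitter=0.1)
    assert np.allclose(K, 0.1 * np.eye(3))


def test_gp_cov_positive_semidefinite_random_grid():
    rng = np.random.default_rng(0)
    years = np.sort(rng.choice(np.arange(64), size=15, replace=False)).astype(float)
    K = gp_cov(years, amplitude=1.3, lengthscale=8.0)
    eig = np.linalg.eigvalsh(K)
    assert eig.min() >= -1e-8
    assert np.allclose(K, K.T)


def test_gp_cov_duplicate_ages_rejected():
    with pytest.raises(ValueError, match="distinct"):
        gp_cov(np.array([1.0, 1.0, 2.0]), 1.0, 5.0)


# -- likelihood -------------------------------------------------------------


def _flat_params(phi2=0.0, phi3=0.0, phi4=0.0, **kw):
    return HierParams(
        stages={
            2: StageParams(phi=phi2, psi=0.0, **kw),
            3: StageParams(phi=phi3, psi=0.0, **kw),
            4: StageParams(phi=phi4, psi=0.0, **kw),
        }
    )


def test_loglik_fair_coin_binomial():
    rec = ResultsRecord("a", n=3, x2=3, x3=3, x4=3)
    params = _flat_params(phi2=0.0, phi3=10.0, phi4=10.0)
    ll = stages_loglik(params, [rec], {"a": 5})
    # stage 2 term: Binom(3 | 3, 0.5) = 0.5^3; stages 3-4 nearly certain
    assert ll == pytest.approx(3 * np.log(0.5), abs=1e-3)


def test_loglik_conditioning_empties_later_stages():
    rec = ResultsRecord("a", n=2, x2=0, x3=0, x4=0)
    base = stages_loglik(_flat_params(phi2=0.3), [rec], {"a": 1})
    # stage 3/4 parameters must not matter when x2 = 0
    moved = stages_loglik(
        _flat_params(phi2=0.3, phi3=5.0, phi4=-5.0), [rec], {"a": 1}
    )
    assert base == pytest.approx(moved)
    assert base == pytest.approx(float(binom.logpmf(0, 2, expit(0.3))))


def test_loglik_matches_brute_force_oracle():
    """Sum of independently computed per-stage binomial log-masses."""
    rng = np.random.default_rng(42)
    recs = [
        ResultsRecord("a", n=4, x2=3, x3=2, x4=1),
        ResultsRecord("b", n=6, x2=6, x3=5, x4=5),
        ResultsRecord("c", n=2, x2=1, x3=0, x4=0),
    ]
    ages = {"a": 3, "b": 11, "c": 25}
    params = HierParams(
        stages={
            s: StageParams(
                phi=rng.normal(),
                psi=1.0,
                beta={p: rng.normal() for p in "abc"},
                gamma={v: rng.normal() * 0.3 for v in ages.values()},
            )
            for s in (2, 3, 4)
        }
    )
    expected = 0.0
    for rec in recs:
        trials = {2: rec.n, 3: rec.x2, 4: rec.x3}
        succ = {2: rec.x2, 3: rec.x3, 4: rec.x4}
        for s in (2, 3, 4):
            if trials[s] == 0:
                continue
            sp = params[s]
            p = expit(sp.phi + sp.beta[rec.paper_id] + sp.gamma[ages[rec.paper_id]])
            expected += float(binom.logpmf(succ[s], trials[s], p))
    assert stages_loglik(params, recs, ages) == pytest.approx(expected)


def test_loglik_rejects_nesting_violation():
    bad = ResultsRecord("a", n=3, x2=1, x3=2, x4=0)
    with pytest.raises(MonotonicityError):
        stages_loglik(_flat_params(), [bad], {"a": 1})


# -- marginal probability ---------------------------------------------------


def test_marginal_probability_exact_cases():
    assert marginal_probability(0.0, 0.0) == 0.5
    # symmetry of the logit-normal about 0.5 at phi = 0, any variance
    assert marginal_probability(0.0, 4.0) == pytest.approx(0.5, abs=1e-12)
    with pytest.raises(ValueError):
        marginal_probability(0.0, -1.0)


def test_marginalization_contracts_toward_half():
    """For phi != 0 the marginal lies strictly between logistic(phi) and 0.5."""
    for phi in (-2.0, -1.0, -0.5, 0.5, 1.0, 2.0):
        for psi in (0.5, 1.0, 4.0):
            m = marginal_probability(phi, psi)
            lo, hi = sorted((expit(phi), 0.5))
            assert lo < m < hi


def test_marginal_probability_matches_monte_carlo():
    rng = np.random.default_rng(123)
    z = rng.standard_normal(1_000_000)
    mc = expit(1.0 + 2.0 * z)
    se = mc.std() / 1000.0
    assert abs(marginal_probability(1.0, 4.0) - mc.mean()) < 3 * se


# -- fits -------------------------------------------------------------------


def test_single_paper_rejected():
    rec = [ResultsRecord("a", n=3, x2=2, x3=2, x4=1)]
    with pytest.raises(ValueError, match="unidentifiable"):
        fit_stages(rec, paper_ages={"a": 3})


def test_psi_zero_truth_shrinks_toward_null():
    """With no true paper heterogeneity the psi posterior shrinks: its
    median stays below 1 in most replicates and it is stochastically
    smaller than under a heterogeneous (psi = 1.5) truth. Stage counts of
    1-6 results near the success ceiling cannot bound psi much harder."""
    reps = 5
    med_null, mean_null, mean_het = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(reps):
            for psi, med_list, mean_list in (
                (0.0, med_null, mean_null),
                (1.5, None, mean_het),
            ):
                ds, _ = simulate_dataset(
                    SimulationConfig(seed=300 + r), TrueParams.flat_gamma(psi=psi)
                )
                post = fit_stages(
                    ds,
                    mcmc=MCMCConfig(chains=2, draws=500, warmup=500, seed=600 + r),
                    stages=(2,),
                )
                draws = post.flat("psi[2]")
                if med_list is not None:
                    med_list.append(np.median(draws))
                mean_list.append(draws.mean())
    assert sum(m < 1.0 for m in med_null) >= 4
    assert np.mean(mean_null) < np.mean(mean_het)


def test_marginal_stage_prob_both_averages(stages_post):
    for avg in ("population", "sample"):
        for s in (2, 3, 4):
            iv = marginal_stage_prob(stages_post, s, average=avg)
            assert 0.0 < iv.lower <= iv.mean <= iv.upper < 1.0
    with pytest.raises(ValueError):
        marginal_stage_prob(stages_post, 5)


def test_stage_probabilities_ordered_plausibly(stages_post, sim_audit):
    """Fitted marginals should sit near the generative stage probabilities."""
    _, _, truth = sim_audit
    for s in (2, 3, 4):
        truth_p = marginal_probability(truth.hier[s].phi, truth.hier[s].psi)
        iv = marginal_stage_prob(stages_post, s)
        assert abs(iv.mean - truth_p) < 0.15


def test_year_effect_draws_fitted_and_conditional(stages_post):
    ages = stages_post.meta["stages"][2]["ages"]
    v0 = int(ages[0])
    stored = stage_year_effect_draws(stages_post, 2, v0)
    assert np.array_equal(stored, stages_post.flat(f"gamma[2,{v0}]"))
    unfitted = 61
    assert unfitted not in set(ages)
    cond = stage_year_effect_draws(stages_post, 2, unfitted)
    assert np.all(np.isfinite(cond))
    # far from all observed years the smoother reverts toward its zero mean
    assert abs(cond.mean()) <= abs(stored.mean()) + 0.5
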
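"""Combined-rate arithmetic, year summaries, half-life tables, pipeline."""

import warnings

import numpy as np
import pytest

from datadecay.audit import STUDY_TYPES, write_audit_table
from datadecay.mcmc import MCMCConfig, PosteriorDraws
from datadecay.report import (
    build_report,
    combined_rate,
    half_life_table,
    run_pipeline,
    success_by_year,
)
from datadecay.simulate import SimulationConfig, TrueParams, simulate_dataset
from datadecay.stage1 import Stage1Params, fit_stage1


def test_combined_rate_scalar_cases():
    assert combined_rate(1, 1, 1, 1) == 1.0
    assert combined_rate(0.5, 0.5, 0.5, 0.5) == pytest.approx(0.0625)
    value = combined_rate(0.29, 0.87, 0.97, 0.96)
    assert value == pytest.approx(0.2349, abs=1e-4)
    assert round(value, 2) == 0.23


def test_combined_rate_vector_and_errors():
    rng = np.random.default_rng(0)
    draws = [rng.uniform(0, 1, 100) for _ in range(4)]
    pr = combined_rate(*draws)
    stacked = np.column_stack(draws)
    assert np.all(pr <= stacked.min(axis=1) + 1e-15)
    with pytest.raises(ValueError, match="length"):
        combined_rate(draws[0], draws[1][:50], draws[2], draws[3])
    with pytest.raises(ValueError, match="lie in"):
        combined_rate(0.5, 1.2, 0.5, 0.5)


def _degenerate_stage1(alpha, lam, shape=(2, 6)):
    draws, meta_types = {}, list(STUDY_TYPES)
    for t in meta_types:
        draws[f"alpha[{t}]"] = np.full(shape, alpha)
        draws[f"lam[{t}]"] = np.full(shape, lam)
    meta = {
        "model": "stage1_exponential",
        "link": "exponential",
        "types": meta_types,
        "type_counts": {t: 1 for t in meta_types},
        "ages": [0, 1, 5, 10],
        "type_index": [0, 1, 2, 3],
    }
    return PosteriorDraws(draws, meta)


def _degenerate_stages(p, shape=(2, 6), ages=(0, 1, 5, 10)):
    from scipy.special import logit

    draws = {}
    meta_stages = {}
    for s in (2, 3, 4):
        draws[f"phi[{s}]"] = np.full(shape, float(logit(p)))
        draws[f"psi[{s}]"] = np.zeros(shape)
        draws[f"eta[{s}]"] = np.full(shape, 1e-6)
        draws[f"rho[{s}]"] = np.full(shape, 10.0)
        for v in ages:
            draws[f"gamma[{s},{v}]"] = np.zeros(shape)
        meta_stages[s] = {
            "paper_ids": [f"p{i}" for i in range(len(ages))],
            "ages": list(ages),
            "trials": [3] * len(ages),
            "successes": [3] * len(ages),
        }
    return PosteriorDraws(draws, {"model": "stages_hierarchical", "stages": meta_stages})


def test_success_by_year_certainty_limit():
    s1 = _degenerate_stage1(alpha=1.0 - 1e-12, lam=0.0)
    st = _degenerate_stages(p=1.0 - 1e-12)
    for year in (2019, 2014, 2009):
        iv = success_by_year(s1, st, year, reference_year=2019)
        assert iv.mean == pytest.approx(1.0, abs=1e-9)


def test_success_by_year_monotone_decline_with_flat_gamma(stage1_post):
    st = _degenerate_stages(p=0.9, shape=(2, 1600), ages=(0, 1, 5, 10))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vals = [
            success_by_year(stage1_post, st, y, reference_year=2019).mean
            for y in range(2019, 1989, -1)
        ]
    assert np.all(np.diff(vals) < 0)  # receding years only lose recoverability


def test_success_by_year_validates_and_warns():
    s1 = _degenerate_stage1(0.8, 0.1)
    st = _degenerate_stages(0.9)
    with pytest.raises(ValueError):
        success_by_year(s1, st, 2030, reference_year=2019)
    with pytest.warns(UserWarning, match="extrapolation"):
        success_by_year(s1, st, 1950, reference_year=2019)


def test_half_life_table_degenerate_posterior():
    post = _degenerate_stage1(0.8, 0.1216)
    tbl = half_life_table(post).set_index("study_type")
    for t in STUDY_TYPES:
        assert tbl.loc[t, "half_life"] == pytest.approx(5.70, abs=0.005)
        assert tbl.loc[t, "upper"] - tbl.loc[t, "lower"] == pytest.approx(0.0)
    # equal rates across types make the pooled curve share the same half-life
    assert tbl.loc["pooled", "half_life"] == pytest.approx(5.70, abs=0.01)


def test_half_life_table_rejects_logistic_posterior():
    post = _degenerate_stage1(0.8, 0.1)
    post.meta["link"] = "logistic"
    with pytest.raises(ValueError, match="exponential"):
        half_life_table(post)


def test_half_life_recovery_from_typed_truth():
    """Posterior mean half-lives land within 20% of ln2/lam truths."""
    lam = dict(zip(STUDY_TYPES, (0.072, 0.114, 0.154, 0.107)))
    truth = TrueParams(
        stage1=Stage1Params(alpha={t: 0.8 for t in STUDY_TYPES}, lam=lam)
    )
    cfg = SimulationConfig(n_papers=2000, results_subsample_size=10, seed=31)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds, _ = simulate_dataset(cfg, truth)
        post = fit_stage1(
            ds.papers, mcmc=MCMCConfig(chains=2, draws=800, warmup=600, seed=3)
        )
    tbl = half_life_table(post).set_index("study_type")
    for t in STUDY_TYPES:
        expected = np.log(2) / lam[t]
        assert abs(tbl.loc[t, "half_life"] - expected) / expected < 0.20


def test_pipeline_deterministic_at_fixed_seed(tmp_path):
    cfg = {
        "seed": 5,
        "simulate": {"n_papers": 250, "results_subsample_size": 15},
        "mcmc": {"chains": 2, "draws": 150, "warmup": 150},
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = run_pipeline(cfg).report.to_dict()
        b = run_pipeline(cfg).report.to_dict()
    assert a == b


def test_pipeline_stage1_only_without_results(tmp_path):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds, _ = simulate_dataset(SimulationConfig(n_papers=250, seed=7))
        write_audit_table(ds, tmp_path / "papers.csv", tmp_path / "results.csv")
        cfg = {
            "seed": 1,
            "inputs": {"papers": str(tmp_path / "papers.csv")},
            "mcmc": {"chains": 2, "draws": 150, "warmup": 150},
        }
        result = run_pipeline(cfg)
    rep = result.report
    assert rep.p1 is not None
    assert rep.p2 is None and rep.p_r is None
    assert "unavailable" in rep.as_text()


def test_pipeline_writes_artifacts(tmp_path):
    out = tmp_path / "run"
    cfg = {
        "seed": 2,
        "simulate": {"n_papers": 300, "results_subsample_size": 12},
        "mcmc": {"chains": 2, "draws": 150, "warmup": 150},
        "out_dir": str(out),
        "figures": True,
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(cfg)
    assert (out / "summary.json").exists()
    assert (out / "post_stage1.csv").exists()
    assert (out / "diagnostics.txt").exists()
    assert (out / "counts.txt").exists()
    d = result.report.to_dict()
    assert d["display"]["p1"] is not None
    # draw-wise product bound holds in the posterior means too
    if d["p_r"] is not None:
        stage_means = [d[k]["mean"] for k in ("p1", "p2", "p3", "p4")]
        assert d["p_r"]["mean"] <= min(stage_means) + 1e-9


def test_report_product_bound_drawwise(stage1_post, stages_post, sim_audit):
    ds, _, _ = sim_audit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = build_report(ds, stage1_post, stages_post)
    assert rep.p_r.mean <= min(rep.p1.mean, rep.p2.mean, rep.p3.mean, rep.p4.mean)
    assert 0 < rep.p_r.mean < 1
    for y, iv in rep.p_r_by_year.items():
        assert 0 <= iv.lower <= iv.upper <= 1
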
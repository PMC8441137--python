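import warnings

import numpy as np
import pandas as pd
import pytest

from datadecay.audit import AuditDataset
from datadecay.mcmc import MCMCConfig, PosteriorDraws
from datadecay.simulate import SimulationConfig, TrueParams, simulate_dataset
from datadecay.stage1 import Stage1Params, fit_stage1
from datadecay.stages import fit_stages


@pytest.fixture
def tiny_dataset() -> AuditDataset:
    """Hand-written 5-paper, 2-results audit."""
    papers = pd.DataFrame(
        {
            "paper_id": ["a", "b", "c", "d", "e"],
            "pub_year": [2018, 2010, 1999, 2015, 2005],
            "study_type": [
                "human_experimental",
                "human_observational",
                "nonhuman_experimental",
                "nonhuman_observational",
                "human_experimental",
            ],
            "recovery_category": ["online", "received", "no_response", "online", "lost"],
        }
    )
    results = pd.DataFrame(
        {
            "paper_id": ["a", "b"],
            "n_results": [3, 5],
            "n_data_usable": [3, 4],
            "n_analysis_clear": [2, 4],
            "n_results_agree": [2, 3],
        }
    )
    return AuditDataset(reference_year=2019, papers=papers, results=results)


@pytest.fixture(scope="session")
def fast_mcmc() -> MCMCConfig:
    return MCMCConfig(chains=2, draws=800, warmup=600, seed=314)


@pytest.fixture(scope="session")
def sim_audit():
    """One paper-shaped synthetic audit with known truth."""
    truth = TrueParams.flat_gamma(psi=1.5)
    ds, latents = simulate_dataset(SimulationConfig(seed=2024), truth)
    return ds, latents, truth


@pytest.fixture(scope="session")
def stage1_post(sim_audit, fast_mcmc) -> PosteriorDraws:
    ds, _, _ = sim_audit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_stage1(ds.papers, mcmc=fast_mcmc)


@pytest.fixture(scope="session")
def stages_post(sim_audit, fast_mcmc) -> PosteriorDraws:
    ds, _, _ = sim_audit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_stages(ds, mcmc=fast_mcmc)
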
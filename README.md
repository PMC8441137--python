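# datadecay

Staged Bayesian models of **data decay** and **results reproducibility**
for literature audits.

Audits of empirical literatures repeatedly find that most published results
cannot be reproduced — usually not because re-analysis disagrees, but
because the underlying data can no longer be obtained. This package
implements, as a reusable and tested pipeline, the statistical core of such
an audit: given a table of surveyed papers (publication year, study type,
data-recovery outcome) and a table of per-paper result counts for a
reproduction subsample, it estimates where reproduction attempts fail and
how fast data disappear. It is aimed at meta-scientists running
reproducibility audits and at methodologists studying data availability.

## The model

Reproduction is a staged, conditional process. For paper *i* of study type
*Y* (human/non-human × experimental/observational) and age *v_i* years:

* **Stage 1, data recovery** — Bernoulli with exponentially decaying
  probability

  ```
  x1_i ~ Bernoulli(p1_i),   p1_i = alpha_Y exp(-lam_Y v_i)
  ```

  so the expected probability of finding the data halves every
  `ln(2)/lam_Y` years (the *data half-life*). A logistic-link alternative
  is fitted as a robustness check and compared by WAIC.

* **Stages 2–4** (data usable; analysis clear; results agree) — for the
  `n_i` results of each subsampled paper, conditional binomials with

  ```
  x_s,i ~ Binomial(m_s,i, p_s,i),  logit(p_s,i) = phi_s + beta_s,i + gamma_s,v[i]
  ```

  with paper-specific intercepts `beta_s,i ~ Normal(0, sqrt(psi_s))` and a
  Gaussian-process year effect `gamma_s,v`. Denominators are conditional:
  `m_3 = x_2,i`, `m_4 = x_3,i`.

* **Overall** — `p(r) = p1 p2 p3 p4`, multiplied draw-wise across the
  posteriors.

Inference is MCMC (adaptive Metropolis-within-Gibbs with ridge moves; 4
chains × 2500 retained draws by default) with rank-normalized split R-hat,
bulk ESS and narrowest 89% highest-density intervals. A synthetic-audit
generator simulates the full generative process so every estimator is
testable against known truth. See `docs/methods.md` for assumptions,
priors and limitations.

## Worked example

The `analysis/` scripts run the full study on a seeded synthetic audit
(560 papers, 40-paper reproduction subsample, generative truth documented
in `docs/methods.md`):

```bash
python analysis/01_simulate.py    # write the audit tables
python analysis/02_fit_stage1.py  # decay model + logistic robustness check
python analysis/03_fit_stages.py  # hierarchical stage 2-4 models
python analysis/04_report.py      # combined report + figures
```

The final report prints (seeds fixed in the scripts):

```
p1 (data recovery): 0.32 (89% HPDI 0.29-0.34)
p2 (data usability | recovery): 0.84 (89% HPDI 0.78-0.91)
p3 (analytical clarity | usability): 0.96 (89% HPDI 0.93-0.99)
p4 (results agreement | clarity): 0.91 (89% HPDI 0.87-0.96)
p(r) overall: 0.23 (89% HPDI 0.21-0.27)
half-lives (years):
  human_experimental: 12.2 (7.8-15.9)
  ...
  pooled: 7.2 (6.1-8.2)
p(r) for 2018: 0.50 (0.42-0.58)
```

Read: data for about one paper in three can still be recovered; once data
are recovered, the downstream stages succeed at 0.84–0.96, so the overall
reproduction probability of 0.23 is driven almost entirely by data
unavailability. The pooled half-life says recoverability halves every ~7
years, and the year decomposition shows a paper published in 2018 is far
more reproducible (0.50) than the sample-wide average — data decay, not
research quality, dominates. `02_fit_stage1.py` also prints the robustness comparison
(`preferred link: exponential`).

The same pipeline runs on real audit tables via the CLI:

```bash
datadecay run --config audit.yaml        # inputs: papers.csv [+ results.csv]
datadecay simulate --out-dir sim/ --seed 1
datadecay fit-stage1 --papers papers.csv --link exponential --out post1.csv
datadecay diagnose --draws post1.csv     # non-zero exit on convergence flags
```

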
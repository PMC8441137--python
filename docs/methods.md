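# Methods

`datadecay` models the staged, conditional process by which a published
result can be reproduced from its underlying data. The pipeline has four
stages, each conditional on all previous ones:

1. **data recovery** — the data behind the paper can be obtained (online or
   from the authors);
2. **data usability** — the recovered data are complete and documented well
   enough to evaluate a given result;
3. **analytical clarity** — the published description (plus any code)
   suffices to repeat the analysis;
4. **results consistency** — the re-computed result agrees with the
   published one.

The overall probability that a result reproduces is the product
`p(r) = p1 p2 p3 p4`.

## Stage 1: exponential data decay

Recovery of paper *i* is Bernoulli with

```
p1_i = alpha_Y[i] * exp(-lam_Y[i] * v_i)
```

where `v_i` is the integer age in years (ages are calendar-year
differences; publication dates carry no finer resolution), and each of the
four study types `Y` (human/non-human crossed with
experimental/observational) has its own recovery-at-publication probability
`alpha_Y` in (0, 1) and decay rate `lam_Y >= 0` per year. The exponential
form encodes failure by many independent hazards — lost files, retired
archives, obsolete formats — whose joint survival declines
multiplicatively. Under it the expected recovery probability halves every
`ln(2)/lam` years at any age; `half_life` and `half_life_table` report this
per type, and a *pooled* half-life as the first halving time of the
type-mixture curve `sum_Y w_Y alpha_Y exp(-lam_Y t)` (weights = the fitted
sample's type mix), found by bracketed root-finding per posterior draw.

A logistic-link alternative `logit(p) = a_Y + b_Y v` serves as a robustness
check; it has no constant half-life (`half_life_table` refuses it) and is
compared to the exponential model by WAIC computed from the pointwise
Bernoulli log-likelihoods.

**Priors.** `alpha ~ Beta(2, 2)`, `lam ~ Exponential(2)` (prior median
half-life 2 years, heavy right tail); logistic `a ~ Normal(0, 1.5)`,
`b ~ Normal(0, 0.5)`. All configurable. Prior predictive simulation
(`datadecay.diagnostics.prior_predictive`) confirms the implied recovery
probability spreads over (0, 1) with no boundary piling at age 0 and no
upper-boundary piling at age 10. Substantial prior mass *near zero* at old
ages is intended, not a defect: any decay model implies near-zero recovery
for old papers, and the fitted curve itself drops below 0.01 past roughly
two decades.

## Stages 2–4: conditional hierarchical binomials

For papers whose data were recovered, the `n_i` identified results pass
stage `s` with probability

```
x_s,i ~ Binomial(m_s,i, p_s,i),   logit(p_s,i) = phi_s + beta_s,i + gamma_s,v[i]
```

The three stage models are identical in form with independent parameters.
The primary model uses **conditional denominators**: `m_2 = n_i`,
`m_3 = x_2,i`, `m_4 = x_3,i`, so each stage is evaluated only on survivors
of the previous stage and papers emptied upstream contribute nothing
downstream. An unconditional-denominator variant (`conditional=False`) is
available for sensitivity analysis.

* `phi_s` — stage intercept, prior `Normal(0, 2.5)`. The stage
  probabilities of interest sit near logit 2–3.5, where a `Normal(0, 1.5)`
  prior would be actively informative toward 0.5 rather than merely
  regularizing; 2.5 is the standard weakly-informative scale for binomial
  intercepts.
* `beta_s,i ~ Normal(0, sqrt(psi_s))` — paper-specific intercepts capturing
  the strong correlation between results of one paper (shared data files,
  shared code quality). **`psi_s` is the variance** of the paper effects;
  its square root has an `Exponential(1)` prior. Large `psi` produces the
  empirically observed bimodality of per-paper success fractions.
* `gamma_s,v` — a smooth publication-year effect with a squared-exponential
  Gaussian-process prior over the distinct integer ages,
  `K = eta_s^2 exp(-(v-v')^2 / (2 rho_s^2))`, assuming no parametric form
  for how reproducibility varies with age. Hyperpriors
  `eta_s ~ Exponential(1)` (marginal sd on the logit scale) and
  `rho_s ~ LogNormal(log 10, 0.5)` (lengthscales on the decade scale).
  A `1e-8` diagonal jitter stabilizes the Cholesky factorization.

**Marginal stage probabilities.** `marginal_stage_prob` integrates the
paper effect out of `logistic(phi + beta + gamma_v)` per posterior draw
with 64-node Gauss–Hermite quadrature (absolute error far below the
Monte-Carlo noise of any check at 10^6 draws; exact at `psi = 0` and at
`phi + gamma = 0` by node symmetry) and averages `gamma` over an age
distribution (default: the empirical age mix of the fitted papers). The
default `average="population"` describes a *new* paper (`beta` integrated
over its population); `average="sample"` instead averages the fitted
papers' own `beta` draws. The printed audit-style marginal uses the
population average.

**Year effects at unobserved ages** are summarized by the GP conditional
mean `eta c*(rho)' C(rho)^{-1} gamma` evaluated per draw; the conditional
spread is not re-sampled, so year-specific summaries at unobserved ages are
mildly under-dispersed. Year-by-year reports therefore default to observed
ages, and requesting a year outside the fitted range raises an
extrapolation warning.

## Inference

No gradient-based PPL is part of the stack, so the package carries its own
sampler (`datadecay.mcmc.run_mwg`): adaptive random-walk
Metropolis-within-Gibbs over an unconstrained vector (logit/log transforms
with their Jacobians), per-coordinate proposal scales tuned in warmup
batches of 50 toward 0.44 acceptance and frozen afterwards. Two symmetric
*ridge moves* — shifting `phi` while absorbing the shift in the
non-centred paper effects, or in the GP field — traverse the
location/random-effect ridge that scalar updates cross slowly; without
them the effective sample size of `phi` drops an order of magnitude. The
hierarchical models sample a non-centred parameterization
(`beta = sqrt(psi) z`, `gamma = eta L(rho) u`) to avoid the funnel at
small `psi`/`eta`; draws are reported on the natural scale.

Correctness of the sampler is established against independent routes: a
closed-form correlated-Gaussian target, a 10,000-point grid posterior for
the one-parameter decay model, and an emcee ensemble fit of the identical
posterior.

Defaults mirror audit practice: 4 chains x 2500 retained draws (10,000
summarized) after 1000 warmup sweeps. Convergence is checked with the
rank-normalized split-chain R-hat and bulk effective sample size (arviz
implementations; flags at R-hat > 1.01 or total ESS < 400), and every fit
attaches its diagnostics report — flagged fits warn, reports surface the
flags, and the CLI exits non-zero on them. Intervals are narrowest 89%
highest-density intervals computed by exhaustive search over contiguous
windows of `ceil(0.89 N)` sorted draws, ties broken toward the lower
window.

## Synthetic audits

The generator (`datadecay.simulate`) emulates an audit of 560 papers
published over six decades with a 40-paper reproduction subsample
(sampling without replacement among recovered papers) of 1–6 results per
paper (median 3, ~108 results in expectation). Defaults were fixed once
from the audited sample's reported margins:

* ages `~` truncated Geometric(0.05) on 0..63 — literature growth is
  roughly exponential, so a geometric age profile is the natural shape; the
  implied marginal recovery under the default truth is ~0.30;
* study-type probabilities (150, 45, 296, 69)/560 — the unique allocation
  consistent with the published experimental/observational and
  human/non-human margins once the 12 mixed-species experiments are
  assigned to human-experimental;
* truth `alpha = 0.85` for every type (recent-year recovery near 0.85 is
  what the reported year-2018 overall success implies) and per-type `lam`
  equal to `ln 2` over half-lives 9.6, 6.1, 6.5 and 4.5 years;
* stage intercepts `logit(0.87), logit(0.97), logit(0.96)` with paper
  effect variance `psi = 1.5` and a mild year effect (`eta = 0.3`,
  `rho = 10`).

Latent `beta`/`gamma` draws are returned in a separate record — real
audits never observe them — enabling parameter-recovery tests.

What the generator does **not** emulate: author-response behaviour beyond
the recovery outcome (categories are bookkeeping only), correlation between
recovery and downstream stages beyond age, per-result covariates, and the
messiness of real category coding. Passing tests therefore demonstrate
that the estimator recovers the model's own generative process at the
audit's sample sizes — not that the model is correct for any real
literature.

`adequacy_simulation` repeats simulate-and-fit at the 40-paper subsample
size and reports coverage and width of the 89% intervals for each stage
intercept and marginal probability, the in-package analogue of a
pre-registered power check. At these sample sizes the intercept intervals
achieve nominal-level coverage, but the paper-effect variance is only
weakly identified: with at most six near-ceiling binomial trials per
paper, `psi = 0` truth yields posterior *medians* below 1 in most
replicates while 89% upper bounds often exceed 1 — bounding heterogeneity
tightly is beyond what 111 results can do.

## Numerical and design choices

* Ages are integers; duplicate ages are collapsed before building GP
  covariances (distinctness is enforced).
* Binomial log-masses are computed from `gammaln` with logit-stable
  `logaddexp` terms; saturated probabilities against contradicting
  outcomes yield `-inf` log posteriors, never exceptions.
* `combined_rate` multiplies stage draws element-wise, so `p(r)` is
  draw-wise bounded by every stage probability.
* Reports round probabilities to 2 decimals and half-lives to 1, the
  precision audit reports print; serialized CSV/JSON artifacts keep full
  precision.
* Reference year defaults to 2019 (the audit closed after the 2018
  publication year); it is configurable everywhere.
* Fits drop study types absent from the data (with a warning) rather than
  imputing them; a single-paper results table is rejected as
  unidentifiable.
* Replicate studies (coverage, adequacy) use 2 chains x 800 draws after
  600 warmup per fit; headline fits use the full 4 x 2500. The problem
  sizes of every simulation-backed test are stated in the tests
  themselves.

## Known limitations

* The random-walk sampler needs many sweeps per effective draw compared
  with gradient-based samplers; very high ESS targets on the GP
  hyperparameters require patience or fewer knots.
* The GP year effect at unobserved ages uses the conditional mean only
  (see above).
* Stage models include no study-type effects (the audit modelled none) and
  no per-result covariates.
* Selection into the reproduction subsample is modelled as purely random
  among recovered papers; any real association between recoverability and
  downstream reproducibility is out of scope, and estimates of stages 2–4
  are conditional on recovery by construction.
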
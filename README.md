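# pebwe

Statistical toolkit for the **Poisson entropy-based weighted exponential
distribution (PEBWED)** — a one-parameter discrete distribution for
asymmetric, right-skewed, heavy-tailed count data, with maximum-likelihood
and Bayesian estimation for complete, right-censored and cure-fraction
samples.

## The model

Classical Poisson regression of counts cannot absorb over-dispersion
(variance exceeding the mean), which dominates epidemiological count
series such as daily death tallies. A standard remedy is a mixed-Poisson
construction: let the Poisson rate λ itself be random,

```
X | λ ~ Poisson(λ),      λ | β ~ EBWE(β),
```

where EBWE is the entropy-based weighted exponential law with density
f(λ; β) = β(βλ − ln β)e^{−βλ}/(1 − ln β). Integrating λ out gives the
closed-form pmf

```
p(x; β) = β((1+β)ln β − (1+x)β) / ((1+β)^{2+x}(ln β − 1)),   x = 0, 1, 2, …
```

with a single parameter β ∈ (0, β_max), β_max ≈ 1.9329 (the root of
(1+β)ln β = β, beyond which p(0) turns negative). The distribution has
closed-form cdf, survival and increasing hazard (limit β), closed-form
factorial and raw moments, pgf/mgf/cf, and covers under-, equi- and
over-dispersion as β sweeps its domain.

The package provides:

- `PEBWE` / `EBWE` — exact pmf/cdf/survival/hazard, moments, generating
  functions, mode, quantiles, seeded inversion sampling;
- `fit_complete`, `fit_censored`, `fit_cure` — ML estimation with
  standard errors from the observed information; censored likelihoods use
  density terms for events and survival terms for censored times, and the
  cure model mixes in an immune fraction η via S(x) = η + (1−η)S₀(x);
- `sample_posterior`, `summarize` — random-walk Metropolis on log β
  (and logit η) with gamma/beta priors, HPD intervals, Geweke and ESS
  diagnostics;
- `gof_report` — AIC/BIC, discrete Kolmogorov–Smirnov distance, PP series;
- `run_grid` — Monte-Carlo bias/MSE study of the MLE;
- three packaged datasets (`covid_china`, `leukemia_remission`,
  `pelvic_tumor`), a seeded synthetic-sample generator, CSV I/O and a thin
  `pebwe` command-line interface.

## Worked example

```python
from pebwe import load_dataset, fit_complete, gof_report

ds = load_dataset("covid_china")          # 66 daily COVID-19 death counts
fit = fit_complete(ds.sample)             # ML fit of the count model
rep = gof_report(ds.sample, fit)
print(fit.beta, fit.std_errors["beta"], -fit.loglik, rep.aic, rep.ks_stat)
```

prints

```
0.02446  0.00306  324.30  650.60  0.0871
```

i.e. the fitted rate-like parameter is β̂ = 0.02446 (SE 0.00306), the
negative maximized log-likelihood is 324.30 (AIC 650.60), and the maximal
ECDF–model-cdf gap is 0.087 — an adequate one-parameter fit to a series
whose variance is an order of magnitude above its mean. The scripts in
`examples/` walk through each capability the same way: distribution
summaries, censored and cure-fraction fits (the pelvic-tumor data yield a
cured fraction η̂ = 0.516), Bayesian posterior summaries (posterior mean
0.0245, 95% HPD 0.0187–0.0305 under a vague prior) and the estimator
study.

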
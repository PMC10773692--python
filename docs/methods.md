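# Methods

## Model

The PEBWE distribution is the mixed-Poisson law obtained by placing the
entropy-based weighted exponential (EBWE) density
f(λ; β) = β(βλ − ln β)e^{−βλ}/(1 − ln β) on the Poisson rate. All
quantities used by the package are closed-form:

- pmf p(x; β) = β((1+β)ln β − (1+x)β)/((1+β)^{2+x}(ln β − 1));
- survival S(x; β) = (1 + β(2+x) − (1+β)ln β)/((1+β)^{2+x}(1 − ln β)),
  cdf F = 1 − S;
- discrete hazard h(x) = p(x)/P(X > x) (note the strict inequality in the
  denominator; with this convention h is strictly increasing with limit β);
- factorial moments μ₍ᵣ₎ = Γ(1+r)(ln β − r − 1)/(βʳ(ln β − 1)), from which
  the four raw moments and all shape measures follow;
- pgf G(s) = β(−β + (1−s+β)ln β)/((1−s+β)²(ln β − 1)); the mgf is G(eᵗ)
  on the full convergence strip t < ln(1+β), and the cf is G(e^{it}).

The variance is computed as μ₂′ − μ₁′², never from a single collapsed
formula; this is the combination that matches direct pmf summation and
the package's reference moment table to all printed digits.

### Parameter domain

p(0; β) ≥ 0 requires (1+β)ln β ≤ β. The package computes the upper bound
β_max ≈ 1.93295 once as the Brent root of (1+β)ln β − β on (1, e) and
rejects β outside (0, β_max) by default. An `unsafe=True` escape hatch
evaluates the closed forms formally outside the domain (where the "pmf"
can be negative); it exists for exploratory work only and is never used by
the fitting code. β = e is excluded because the normalising constant
1 − ln β vanishes there.

For β > 1 the EBWE density is negative on [0, ln β/β). The compound count
distribution remains a proper distribution on the whole valid domain, but
the continuous law is not, so `EBWE.rvs`/`EBWE.ppf` refuse β > 1 while
pdf/cdf evaluate the closed forms as written.

## Numerics

- All likelihood code consumes `logpmf`/`logsf`/`logpdf`; cdf values come
  from `-expm1(logsf)`. No pmf ratios are formed.
- Sampling is exact inversion of the closed-form cdf: a cdf table is
  precomputed out to survival < 1e−12 (capped at 10⁶ terms) and inverted
  by `searchsorted`; uniforms beyond the table fall back to integer
  bisection on the closed-form cdf, so truncation never biases a draw.
- Series oracles in the tests truncate where survival < ~1e−13, which
  retains all mass to well below every asserted tolerance.
- 1-D fits use bounded Brent minimisation on (1e−8, β_max); the 2-D cure
  fit uses Nelder–Mead on the box transform (β, η) = (β_max·expit(a),
  expit(w)), with the censored-fit β and the censored fraction as starting
  values. Parameter tolerance 1e−10.
- Standard errors invert the observed information estimated by central
  finite differences with step max(1e−5, 1e−4·|θ̂|); if the information
  matrix is not positive definite the estimates are returned and the SEs
  withheld with a warning.
- The mode's continuous critical point comes from the closed-form
  stationarity equation; the reported integer mode is always a brute-force
  pmf comparison around it (and 0), so no hard-coded unimodality threshold
  enters any output.

## Likelihood variants

Count data recorded as non-negative integers can be fit either with the
discrete pmf/survival ("discrete", the default everywhere) or with the
continuous EBWE density/survival ("ebwe"). The discrete composition is
the default because integer-recorded data are genuinely discrete and
because it is the variant under which the packaged application fits and
their information criteria are internally consistent; the continuous
variant gives estimates a fraction of a standard error away. The same
flag governs the censored and cure likelihoods, which compose the chosen
f/S as d·log f(xᵢ) + (1−d)·log S(xᵢ), and the cure model mixes
S(x) = η + (1−η)S₀(x) with events contributing (1−η)f₀.

## Bayesian estimation

Priors default to vague gamma(0.01, 0.01) on β and beta(1, 1) on η — the
cure fraction is a proportion, so a beta prior is the natural conjugate
family for it. Sampling is random-walk Metropolis on log β (and logit η
in a second Metropolis-within-Gibbs block for the cure model) with the
Jacobian folded into the target. Proposal scales start at 0.1 and are
multiplicatively adapted every 200 burn-in iterations toward a 25–45%
acceptance window, then frozen, so the retained draws form a valid
Markov chain. The desk-scale default is 106,000 iterations with 6,000
burn-in (~5 s on the packaged datasets); a ten-fold longer chain changes
the reported posterior means by less than Monte-Carlo error.

HPD intervals are true highest-density intervals: the shortest window
containing ⌈level·N⌉ sorted draws (equal-tailed intervals can be wider
for skewed posteriors). The Geweke statistic compares the means of the
first 10% and last 50% of the chain, with window variances estimated by
Bartlett-windowed autocovariances (Newey–West style lag
⌊4(n/100)^{2/9}⌋). ESS uses the initial-positive-sequence cutoff on the
autocorrelation sum.

## Goodness of fit

AIC = −2ℓ + 2k and BIC = −2ℓ + k ln n. The KS distance builds the ECDF
over all recorded times — censoring flags are deliberately ignored for
this diagnostic — and takes
D = max over observed support points of max(|Fₙ(x) − F(x)|, |Fₙ(x⁻) − F(x)|)
against the fitted marginal cdf (for the cure model,
F(x) = (1−η)F₀(x)). Caveat: because the lower comparison uses the model's
right-continuous F, D is floored near the largest pmf atom for discrete
fits — it measures adequacy on wide-support data but does not converge to
zero for a perfectly specified narrow-support model. The p-value is the
asymptotic Kolmogorov tail at √n·D and is conservative for discrete fits;
both caveats are why D, not the p-value, is the primary diagnostic.

## Synthetic-data generator

`generate_fixture` emulates the sampling schemes the estimators target:
event times from the PEBWE count model (or continuous EBWE lifetimes for
survival-style fixtures), an immune sub-population of expected fraction η
whose members are always censored, and independent uniform censoring on
[0, c] among susceptibles, with c calibrated by root-finding so the
expected susceptible censoring probability equals the requested rate.
Uniform censoring is a modelling convention chosen for transparency; real
studies censor administratively or by staggered entry, so recovery tests
on these fixtures demonstrate estimator correctness under the assumed
independent-censoring mechanism, not robustness to informative censoring,
covariate structure or recording error.

## Monte-Carlo estimator study

Each (β, n) cell draws `n_reps` samples, refits by ML and reports
AB = |mean(β̂) − β| (absolute bias of the average estimate),
MRE = AB/β and MSE = mean(β̂ − β)², each with Monte-Carlo standard
errors. A master `SeedSequence` spawns one independent substream per
cell, so any cell is reproducible in isolation. Failed fits are counted,
excluded from the averages and flagged when they exceed 5% of a cell.
Defaults mirror the reference design (β ∈ {0.1, 0.5, 0.8, 0.9, 1.5, 1.8},
n ∈ {10, 20, 50, 100, 200}, 10,000 replications); the test suite runs
2,000 replications per cell, which resolves the reference cells well
inside three Monte-Carlo standard errors. Estimates are constrained to
the validity domain (0, β_max); at small n and β near the upper bound
this truncates the estimator's spread, which an unconstrained optimiser
would not — a deliberate choice, since values above β_max do not define a
probability distribution.

## Known limitations

- Single-parameter baseline only; no covariates, interval censoring or
  left truncation.
- The KS p-value is asymptotic and conservative for discrete models; no
  exact discrete null distribution is implemented.
- One chain per run; convergence monitoring is Geweke/ESS/trace-based,
  with no cross-chain R-hat.
- The EBWE continuous law is usable as a sampling model only for β ≤ 1.
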
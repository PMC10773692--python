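"""Maximum-likelihood estimation for the PEBWE model.

Three sampling schemes are supported:

* complete samples of counts (or continuous EBWE lifetimes),
* right-censored samples ``(x_i, d_i)`` with ``d_i = 1`` for an observed
  event and ``d_i = 0`` for a right-censored time, and
* right-censored samples with a cure fraction ``eta``, where the population
  survival is the mixture ``S(x) = eta + (1 - eta) * S0(x)`` and only the
  susceptible fraction ``1 - eta`` ever experiences the event.

Each likelihood takes a ``model`` flag choosing the baseline law: the
``"discrete"`` PEBWE pmf/survival (the default, appropriate for counts and
integer-recorded lifetimes) or the continuous ``"ebwe"`` mixing density.
All likelihoods are evaluated on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize, minimize_scalar

from .distribution import BETA_MAX, EBWE, PEBWE, validate_beta

__all__ = [
    "CensoredSample",
    "CureParams",
    "FitResult",
    "loglik_complete",
    "fit_complete",
    "loglik_censored",
    "fit_censored",
    "loglik_cure",
    "fit_cure",
    "moment_estimate",
]

_BETA_LO = 1e-8
_BETA_HI = BETA_MAX - 1e-9


@dataclass(frozen=True)
class CensoredSample:
    """Paired observation times and event indicators.

    ``events[i] = 1`` means the i-th time is an observed event;
    ``events[i] = 0`` means it is right-censored (the true time exceeds it).
    """

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.events)
        if t.ndim != 1 or d.ndim != 1 or len(t) != len(d):
            raise ValueError("times and events must be 1-D sequences of equal length")
        if len(t) < 2:
            raise ValueError("a censored sample needs at least 2 observations")
        if np.any(t < 0) or not np.all(np.isfinite(t)):
            raise ValueError("times must be finite and non-negative")
        if not np.all(np.isin(d, (0, 1))):
            raise ValueError("events must be 0 (censored) or 1 (observed)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", d.astype(np.int64))

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def n_censored(self) -> int:
        return len(self) - self.n_events


@dataclass(frozen=True)
class CureParams:
    """Baseline parameter and cure fraction of the mixture-cure model."""

    beta: float
    eta: float

    def __post_init__(self):
        validate_beta(self.beta)
        if not 0.0 < self.eta < 1.0:
            raise ValueError(f"cure fraction eta must lie in (0,1), got {self.eta!r}")


@dataclass
class FitResult:
    """Point estimates, standard errors and optimizer metadata for one fit."""

    estimates: dict[str, float]
    std_errors: dict[str, float] | None
    loglik: float
    n: int
    converged: bool
    model: str
    message: str = ""
    optimizer_trace: list = field(default_factory=list)

    @property
    def beta(self) -> float:
        return self.estimates["beta"]

    @property
    def k_params(self) -> int:
        return len(self.estimates)


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1 or len(arr) == 0:
        raise ValueError("counts must be a non-empty 1-D sequence")
    flt = arr.astype(float)
    if np.any(flt < 0) or not np.all(np.isfinite(flt)):
        raise ValueError("counts must be finite and non-negative")
    return flt


# -- complete-data likelihood -------------------------------------------------


def loglik_complete(counts, beta: float, model: str = "discrete") -> float:
    """Log-likelihood of an uncensored sample.

    model="discrete": sum of log pmf over the counts.
    model="ebwe": the continuous EBWE log-density
    ``n log b - n log(1 - ln b) + sum log(b x_i - ln b) - b sum x_i``.
    """
    x = _as_counts(counts)
    if model == "discrete":
        val = float(np.sum(PEBWE(beta).logpmf(x)))
    elif model == "ebwe":
        val = float(np.sum(EBWE(beta).logpdf(x)))
    else:
        raise ValueError(f"model must be 'discrete' or 'ebwe', got {model!r}")
    if not np.isfinite(val):
        bad = int(np.flatnonzero(~np.isfinite(_pointwise(x, beta, model)))[0])
        raise ValueError(
            f"non-finite log-likelihood contribution at observation index {bad} "
            f"(x={x[bad]:g}, beta={beta:g})"
        )
    return val


def _pointwise(x, beta, model):
    return PEBWE(beta).logpmf(x) if model == "discrete" else EBWE(beta).logpdf(x)


def moment_estimate(counts) -> float:
    """Moment-matching start value: solve mean(beta) = sample mean.

    The model mean is decreasing in beta down to ~1.79 near beta = 1.5; if
    the sample mean is below the attainable range the mid-domain value is
    returned instead.
    """
    xbar = float(np.mean(_as_counts(counts)))

    def gap(b):
        return PEBWE(b, unsafe=True).mean - xbar

    try:
        return brentq(gap, _BETA_LO, 1.5)
    except ValueError:
        return 0.5 * BETA_MAX


def _fit_1d(negll, n: int, model: str) -> FitResult:
    trace: list = []

    def wrapped(b):
        v = negll(b)
        trace.append((float(b), float(v)))
        return v if np.isfinite(v) else 1e300

    res = minimize_scalar(
        wrapped, bounds=(_BETA_LO, _BETA_HI), method="bounded", options={"xatol": 1e-10}
    )
    beta_hat = float(res.x)
    ll = -float(res.fun)
    se, msg = _se_1d(negll, beta_hat)
    converged = bool(res.success) and bool(np.isfinite(ll))
    return FitResult(
        estimates={"beta": beta_hat},
        std_errors={"beta": se} if se is not None else None,
        loglik=ll,
        n=n,
        converged=converged,
        model=model,
        message=msg or res.message,
        optimizer_trace=trace,
    )


def _se_1d(negll, beta_hat):
    h = max(1e-5, 1e-4 * abs(beta_hat))
    try:
        d2 = (negll(beta_hat + h) - 2.0 * negll(beta_hat) + negll(beta_hat - h)) / h**2
    except ValueError:
        return None, "observed information not computable at the optimum"
    if not np.isfinite(d2) or d2 <= 0:
        return None, "observed information not positive definite; SE withheld"
    return float(1.0 / np.sqrt(d2)), ""


def fit_complete(counts, model: str = "discrete") -> FitResult:
    """ML fit of beta to an uncensored sample by bounded 1-D maximization."""
    x = _as_counts(counts)
    if np.all(x == 0):
        warnings.warn("all observations are zero: the MLE sits at the domain boundary")
    negll = lambda b: -loglik_complete(x, b, model=model)
    return _fit_1d(_guarded(negll), len(x), model)


def _guarded(negll):
    def f(b):
        try:
            return negll(b)
        except (ValueError, FloatingPointError):
            return np.inf

    return f


# -- right-censored likelihood -------------------------------------------------


def loglik_censored(sample: CensoredSample, beta: float, model: str = "discrete") -> float:
    """Censored-data log-likelihood: events contribute log f, censored
    observations contribute log S (survival beyond the recorded time)."""
    t, d = sample.times, sample.events
    if model == "discrete":
        dist = PEBWE(beta)
        lf, ls = dist.logpmf(t), dist.logsf(t)
    elif model == "ebwe":
        dist = EBWE(beta)
        lf, ls = dist.logpdf(t), dist.logsf(t)
    else:
        raise ValueError(f"model must be 'discrete' or 'ebwe', got {model!r}")
    contrib = np.where(d == 1, lf, ls)
    if not np.all(np.isfinite(contrib)):
        bad = int(np.flatnonzero(~np.isfinite(contrib))[0])
        raise ValueError(
            f"non-finite likelihood contribution at observation index {bad} "
            f"(t={t[bad]:g}, d={d[bad]}, beta={beta:g})"
        )
    return float(np.sum(contrib))


def fit_censored(sample: CensoredSample, model: str = "discrete") -> FitResult:
    """ML fit of beta under right censoring."""
    if sample.n_events == 0:
        raise ValueError("censored fit requires at least one observed event")
    negll = _guarded(lambda b: -loglik_censored(sample, b, model=model))
    return _fit_1d(negll, len(sample), model)


# -- cure-fraction likelihood ---------------------------------------------------


def loglik_cure(sample: CensoredSample, params: CureParams, model: str = "discrete") -> float:
    """Mixture-cure log-likelihood.

    Events: ``log[(1 - eta) f0(x_i)]``; censored: ``log[eta + (1-eta) S0(x_i)]``
    with f0/S0 the baseline density and survival of the susceptibles.
    """
    beta, eta = params.beta, params.eta
    t, d = sample.times, sample.events
    if model == "discrete":
        dist = PEBWE(beta)
        lf0, s0 = dist.logpmf(t), dist.sf(t)
    elif model == "ebwe":
        dist = EBWE(beta)
        lf0, s0 = dist.logpdf(t), dist.sf(t)
    else:
        raise ValueError(f"model must be 'discrete' or 'ebwe', got {model!r}")
    contrib = np.where(
        d == 1,
        np.log1p(-eta) + lf0,
        np.log(eta + (1.0 - eta) * s0),
    )
    if not np.all(np.isfinite(contrib)):
        bad = int(np.flatnonzero(~np.isfinite(contrib))[0])
        raise ValueError(
            f"non-finite likelihood contribution at observation index {bad} "
            f"(t={t[bad]:g}, d={d[bad]}, beta={beta:g}, eta={eta:g})"
        )
    return float(np.sum(contrib))


def fit_cure(sample: CensoredSample, model: str = "discrete") -> FitResult:
    """Joint ML fit of (beta, eta) by Nelder-Mead on (log beta, logit eta)."""
    if sample.n_events == 0 or sample.n_censored == 0:
        raise ValueError("cure-fraction fit requires at least one event and one censored time")

    def negll_raw(beta, eta):
        try:
            return -loglik_cure(sample, CureParams(beta, eta), model=model)
        except (ValueError, FloatingPointError):
            return np.inf

    # box transform: beta = BETA_MAX * expit(a), eta = expit(w)
    from scipy.special import expit, logit

    def negll_t(z):
        beta = _BETA_HI * expit(z[0])
        eta = expit(z[1])
        return negll_raw(beta, eta)

    beta0 = fit_censored(sample, model=model).beta
    eta0 = np.clip(sample.n_censored / len(sample), 0.05, 0.95)
    z0 = np.array([logit(np.clip(beta0 / _BETA_HI, 1e-9, 1 - 1e-9)), logit(eta0)])
    res = minimize(
        negll_t, z0, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    beta_hat = float(_BETA_HI * expit(res.x[0]))
    eta_hat = float(expit(res.x[1]))
    ll = -float(res.fun)
    se, msg = _se_2d(negll_raw, beta_hat, eta_hat)
    return FitResult(
        estimates={"beta": beta_hat, "eta": eta_hat},
        std_errors=se,
        loglik=ll,
        n=len(sample),
        converged=bool(res.success),
        model=model,
        message=msg or res.message,
    )


def _se_2d(negll, beta_hat, eta_hat):
    hb = max(1e-5, 1e-4 * abs(beta_hat))
    he = max(1e-5, 1e-4 * abs(eta_hat))
    f = negll
    try:
        dbb = (f(beta_hat + hb, eta_hat) - 2 * f(beta_hat, eta_hat) + f(beta_hat - hb, eta_hat)) / hb**2
        dee = (f(beta_hat, eta_hat + he) - 2 * f(beta_hat, eta_hat) + f(beta_hat, eta_hat - he)) / he**2
        dbe = (
            f(beta_hat + hb, eta_hat + he)
            - f(beta_hat + hb, eta_hat - he)
            - f(beta_hat - hb, eta_hat + he)
            + f(beta_hat - hb, eta_hat - he)
        ) / (4 * hb * he)
    except (ValueError, FloatingPointError):
        return None, "observed information not computable at the optimum"
    info = np.array([[dbb, dbe], [dbe, dee]])
    if not np.all(np.isfinite(info)):
        return None, "observed information not computable at the optimum"
    eigvals = np.linalg.eigvalsh(info)
    if np.any(eigvals <= 0):
        warnings.warn("observed information matrix not positive definite; SEs withheld")
        return None, "observed information not positive definite; SEs withheld"
    cov = np.linalg.inv(info)
    return {"beta": float(np.sqrt(cov[0, 0])), "eta": float(np.sqrt(cov[1, 1]))}, ""
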
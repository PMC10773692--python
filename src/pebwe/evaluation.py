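"""Model selection and goodness-of-fit metrics.

AIC/BIC from the maximized log-likelihood, a two-sided Kolmogorov-Smirnov
distance between the empirical cdf and the fitted model cdf, and the
point series behind PP plots.

KS convention: the ECDF is built over all recorded times -- censoring flags
are ignored for this diagnostic -- and compared with the fitted marginal
cdf at every observed support point, taking the larger of the deviations
just before and at each point.  The p-value uses the asymptotic Kolmogorov
distribution at sqrt(n)*D, which is conservative for discrete models.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import kolmogorov

from .distribution import EBWE, PEBWE
from .inference import CensoredSample, FitResult

__all__ = [
    "GofReport",
    "information_criteria",
    "ks_statistic",
    "ks_pvalue",
    "pp_points",
    "gof_report",
]


@dataclass(frozen=True)
class GofReport:
    """Fit metrics for one fitted model on one sample."""

    loglik: float
    aic: float
    bic: float
    ks_stat: float
    ks_pvalue: float
    n: int
    k_params: int

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), sort_keys=True, **kwargs)


def information_criteria(loglik: float, k_params: int, n: int) -> tuple[float, float]:
    """AIC = -2l + 2k and BIC = -2l + k ln(n)."""
    if n < 1 or k_params < 1:
        raise ValueError("need n >= 1 and k_params >= 1")
    aic = -2.0 * loglik + 2.0 * k_params
    bic = -2.0 * loglik + k_params * np.log(n)
    return float(aic), float(bic)


def _times(sample) -> np.ndarray:
    if isinstance(sample, CensoredSample):
        return sample.times
    arr = np.asarray(sample, dtype=float)
    if arr.ndim != 1 or len(arr) == 0:
        raise ValueError("sample must be a non-empty 1-D sequence")
    return arr


def _fitted_cdf(model: str, beta: float, eta: float | None):
    if model == "discrete":
        base = PEBWE(beta).cdf
    elif model == "ebwe":
        base = EBWE(beta).cdf
    else:
        raise ValueError(f"model must be 'discrete' or 'ebwe', got {model!r}")
    if eta is None:
        return base
    # mixture-cure marginal cdf: F(x) = (1 - eta) * F0(x)
    return lambda x: (1.0 - eta) * np.asarray(base(x))


def ks_statistic(sample, beta: float, model: str = "discrete", eta: float | None = None) -> float:
    """Two-sided KS distance D between the ECDF and the fitted cdf."""
    t = _times(sample)
    n = len(t)
    ts = np.sort(t)
    xs = np.unique(ts)
    fn_hi = np.searchsorted(ts, xs, side="right") / n   # F_n(x)
    fn_lo = np.searchsorted(ts, xs, side="left") / n    # F_n(x-)
    f = np.asarray(_fitted_cdf(model, beta, eta)(xs), dtype=float)
    return float(max(np.max(np.abs(fn_hi - f)), np.max(np.abs(fn_lo - f))))


def ks_pvalue(d: float, n: int) -> float:
    """Asymptotic Kolmogorov p-value at sqrt(n) * D (conservative for
    discrete fitted models)."""
    return float(kolmogorov(np.sqrt(n) * d))


def pp_points(sample, beta: float, model: str = "discrete", eta: float | None = None) -> np.ndarray:
    """Sorted (empirical_prob, theoretical_prob) pairs for a PP plot."""
    t = _times(sample)
    n = len(t)
    ts = np.sort(t)
    emp = np.searchsorted(ts, ts, side="right") / n
    theo = np.asarray(_fitted_cdf(model, beta, eta)(ts), dtype=float)
    return np.column_stack([emp, theo])


def gof_report(sample, fit: FitResult) -> GofReport:
    """Assemble the full metric set for a completed fit."""
    t = _times(sample)
    n = len(t)
    k = fit.k_params
    aic, bic = information_criteria(fit.loglik, k, n)
    eta = fit.estimates.get("eta")
    d = ks_statistic(sample, fit.beta, model=fit.model, eta=eta)
    return GofReport(
        loglik=fit.loglik, aic=aic, bic=bic,
        ks_stat=d, ks_pvalue=ks_pvalue(d, n), n=n, k_params=k,
    )
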
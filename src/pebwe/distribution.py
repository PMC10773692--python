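"""Poisson entropy-based weighted exponential distribution (PEBWE).

The PEBWE distribution is a one-parameter mixed-Poisson count model: the
Poisson rate ``lambda`` is itself random, following the continuous
entropy-based weighted exponential (EBWE) law with density

    f(lam; beta) = beta * (beta*lam - ln(beta)) * exp(-beta*lam) / (1 - ln(beta)),

which yields the closed-form pmf

    p(x; beta) = beta * ((1+beta)*ln(beta) - (1+x)*beta)
                 / ((1+beta)^(2+x) * (ln(beta) - 1)),   x = 0, 1, 2, ...

The single rate-like parameter ``beta > 0`` controls both location and
dispersion: small beta gives heavy-tailed, strongly over-dispersed counts,
while beta near the upper end of the valid domain gives under-dispersion.
The pmf is non-negative at x = 0 only while (1+beta)*ln(beta) <= beta, so
the valid parameter domain is (0, BETA_MAX) with BETA_MAX ~ 1.93 the root
of (1+beta)*ln(beta) = beta.  ln(beta) = 1 (beta = e) is excluded by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

__all__ = [
    "BETA_MAX",
    "validate_beta",
    "MomentSummary",
    "ModeResult",
    "PEBWE",
    "EBWE",
]


def _beta_max() -> float:
    # root of (1+b)*ln(b) - b on (1, e); above it the pmf is negative at x=0
    return brentq(lambda b: (1.0 + b) * math.log(b) - b, 1.0 + 1e-12, math.e - 1e-12, xtol=1e-14)


BETA_MAX: float = _beta_max()


def validate_beta(beta: float, *, unsafe: bool = False) -> float:
    """Validate the PEBWE/EBWE parameter.

    Parameters
    ----------
    beta
        Candidate parameter value.
    unsafe
        When True only ``beta > 0`` and ``beta != e`` are enforced, allowing
        formal evaluation of the closed forms outside the pmf non-negativity
        domain (used for exploratory work only).
    """
    beta = float(beta)
    if not np.isfinite(beta) or beta <= 0.0:
        raise ValueError(f"beta must be a positive finite real, got {beta!r}")
    if abs(math.log(beta) - 1.0) < 1e-12:
        raise ValueError("beta = e is excluded: the normalising constant 1 - ln(beta) vanishes")
    if not unsafe and beta >= BETA_MAX:
        raise ValueError(
            f"beta={beta:g} is outside the validity domain (0, {BETA_MAX:.6f}): "
            "the pmf at x=0 becomes negative; pass unsafe=True to evaluate the "
            "closed forms formally anyway"
        )
    return beta


@dataclass(frozen=True)
class MomentSummary:
    """Mean, variance and shape measures of a PEBWE distribution."""

    mean: float
    variance: float
    dispersion_index: float
    skewness: float
    kurtosis: float
    cv: float


@dataclass(frozen=True)
class ModeResult:
    """Continuous critical point of the pmf and the integer argmax."""

    critical_point: float
    integer_mode: int


class PEBWE:
    """Frozen PEBWE distribution with parameter ``beta``.

    All distributional quantities are closed-form; array arguments are
    broadcast element-wise.  Likelihood code should consume :meth:`logpmf`
    / :meth:`logsf`, which are evaluated on the log scale throughout.
    """

    def __init__(self, beta: float, *, unsafe: bool = False):
        self.beta = validate_beta(beta, unsafe=unsafe)

    # -- helpers -----------------------------------------------------------

    def _check_x(self, x) -> np.ndarray:
        arr = np.asarray(x)
        if not np.issubdtype(arr.dtype, np.integer):
            flt = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(flt)) or np.any(flt != np.floor(flt)):
                raise ValueError("x must contain non-negative integers")
            arr = flt.astype(np.int64)
        if np.any(arr < 0):
            raise ValueError("x must be non-negative")
        return arr

    # -- pmf / cdf / hazard ------------------------------------------------

    def logpmf(self, x) -> np.ndarray | float:
        x = self._check_x(x).astype(float)
        b, lb = self.beta, math.log(self.beta)
        # p(x) = b*((1+x)b - (1+b)lb) / ((1+b)^(2+x) * (1-lb)); inner factor
        # is positive on the whole valid domain
        inner = (1.0 + x) * b - (1.0 + b) * lb
        with np.errstate(divide="ignore"):
            out = (
                math.log(b)
                + np.log(inner)
                - math.log(1.0 - lb)
                - (2.0 + x) * math.log1p(b)
            )
        return out if out.ndim else float(out)

    def pmf(self, x) -> np.ndarray | float:
        # direct closed form: stays meaningful (possibly negative) under
        # unsafe evaluation outside the non-negativity domain
        x = self._check_x(x).astype(float)
        b, lb = self.beta, math.log(self.beta)
        num = (1.0 + b) * lb - (1.0 + x) * b
        out = b * num / (lb - 1.0) * np.exp(-(2.0 + x) * math.log1p(b))
        return out if out.ndim else float(out)

    def logsf(self, x) -> np.ndarray | float:
        """log P(X > x); x = -1 is allowed and gives 0."""
        arr = np.asarray(x)
        special = np.any(arr == -1)
        if special:
            arr = np.where(arr == -1, 0, arr)
        xf = self._check_x(arr).astype(float)
        b, lb = self.beta, math.log(self.beta)
        out = (
            np.log(1.0 + b * (2.0 + xf) - (1.0 + b) * lb)
            - math.log(1.0 - lb)
            - (2.0 + xf) * math.log1p(b)
        )
        if special:
            out = np.where(np.asarray(x) == -1, 0.0, out)
        return out if out.ndim else float(out)

    def sf(self, x) -> np.ndarray | float:
        return np.exp(self.logsf(x))

    def cdf(self, x) -> np.ndarray | float:
        out = -np.expm1(self.logsf(x))
        return out if np.ndim(out) else float(out)

    def hazard(self, x) -> np.ndarray | float:
        """Discrete hazard p(x) / P(X > x); increasing in x with limit beta."""
        out = np.exp(np.asarray(self.logpmf(x)) - np.asarray(self.logsf(x)))
        return out if out.ndim else float(out)

    # -- moments -----------------------------------------------------------

    def factorial_moment(self, r: int) -> float:
        """E[X(X-1)...(X-r+1)] = Gamma(1+r)*(ln b - r - 1) / (b^r (ln b - 1))."""
        if not float(r).is_integer() or r < 0:
            raise ValueError("r must be a non-negative integer")
        r = int(r)
        b, lb = self.beta, math.log(self.beta)
        return math.exp(gammaln(1 + r)) * (lb - r - 1.0) / (b**r * (lb - 1.0))

    def raw_moments(self) -> tuple[float, float, float, float]:
        """First four moments about the origin, in closed form."""
        b, lb = self.beta, math.log(self.beta)
        d = lb - 1.0
        m1 = (lb - 2.0) / (b * d)
        m2 = (-2.0 * (3.0 + b) + (2.0 + b) * lb) / (b**2 * d)
        m3 = (-2.0 * (12.0 + b * (9.0 + b)) + (6.0 + b * (6.0 + b)) * lb) / (b**3 * d)
        m4 = (
            -2.0 * (60.0 + b * (72.0 + b * (21.0 + b)))
            + (2.0 + b) * (12.0 + b * (12.0 + b)) * lb
        ) / (b**4 * d)
        return m1, m2, m3, m4

    @property
    def mean(self) -> float:
        return self.raw_moments()[0]

    @property
    def var(self) -> float:
        # variance as mu2' - mu1'^2; reproduces the published numerical table
        m1, m2, _, _ = self.raw_moments()
        return m2 - m1 * m1

    def moment_summary(self) -> MomentSummary:
        m1, m2, m3, m4 = self.raw_moments()
        var = m2 - m1 * m1
        sd = math.sqrt(var)
        skew = (m3 - 3.0 * m2 * m1 + 2.0 * m1**3) / sd**3
        kurt = (m4 - 4.0 * m3 * m1 + 6.0 * m2 * m1**2 - 3.0 * m1**4) / var**2
        return MomentSummary(
            mean=m1,
            variance=var,
            dispersion_index=var / m1,
            skewness=skew,
            kurtosis=kurt,
            cv=sd / m1,
        )

    # -- generating functions ----------------------------------------------

    def pgf(self, s):
        """Probability generating function E[s^X], for s in (-1, 1]."""
        s = np.asarray(s, dtype=float)
        if np.any((s <= -1.0) | (s > 1.0)):
            raise ValueError("pgf argument must lie in (-1, 1]")
        out = self._gf(s)
        return out if out.ndim else float(out)

    def mgf(self, t):
        """Moment generating function, convergent for t < ln(1 + beta)."""
        t = np.asarray(t, dtype=float)
        if np.any(t >= math.log1p(self.beta)):
            raise ValueError(f"mgf diverges for t >= ln(1+beta) = {math.log1p(self.beta):.6f}")
        out = self._gf(np.exp(t))
        return out if out.ndim else float(out)

    def cf(self, t):
        """Characteristic function, defined for all real t."""
        t = np.asarray(t, dtype=float)
        out = self._gf(np.exp(1j * t))
        return out if out.ndim else complex(out)

    def _gf(self, s):
        b, lb = self.beta, math.log(self.beta)
        u = 1.0 - s + b
        return b * (-b + u * lb) / (u**2 * (lb - 1.0))

    def generating_function(self, kind: str, arg):
        """Dispatch to :meth:`pgf`, :meth:`mgf` or :meth:`cf` by name."""
        try:
            fn = {"pgf": self.pgf, "mgf": self.mgf, "cf": self.cf}[kind]
        except KeyError:
            raise ValueError(f"kind must be one of pgf|mgf|cf, got {kind!r}") from None
        return fn(arg)

    # -- mode / quantiles / sampling ----------------------------------------

    def mode(self) -> ModeResult:
        b = self.beta
        lb, l1b = math.log(b), math.log1p(b)
        xhat = (b - b * l1b + lb * l1b + b * lb * l1b) / (b * l1b)
        crit = max(xhat, 0.0)
        candidates = sorted({0, int(math.floor(crit)), int(math.ceil(crit))})
        integer_mode = max(candidates, key=lambda k: self.pmf(k))
        return ModeResult(critical_point=crit, integer_mode=int(integer_mode))

    def quantile(self, q) -> np.ndarray | int:
        """Smallest integer x with cdf(x) >= q, for q in [0, 1)."""
        qa = np.asarray(q, dtype=float)
        if np.any((qa < 0.0) | (qa >= 1.0)):
            raise ValueError("q must lie in [0, 1)")
        scalar = qa.ndim == 0
        qa = np.atleast_1d(qa)
        out = np.empty(qa.shape, dtype=np.int64)
        for i, qi in np.ndenumerate(qa):
            out[i] = self._quantile_scalar(qi)
        return int(out[0]) if scalar else out

    def _quantile_scalar(self, q: float) -> int:
        if q <= self.cdf(0):
            return 0
        hi = 1
        while self.cdf(hi) < q:
            hi *= 2
        lo = hi // 2  # cdf(lo) < q <= cdf(hi)
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if self.cdf(mid) < q:
                lo = mid
            else:
                hi = mid
        return hi

    def support_table(self, tail_mass: float = 1e-12, max_terms: int = 1_000_000) -> np.ndarray:
        """cdf values on 0..K where K is the first x with sf(x) < tail_mass."""
        # geometric tail: sf shrinks by ~1/(1+beta) per step
        k_guess = int(-math.log(tail_mass) / math.log1p(self.beta)) + 10
        k_guess = min(k_guess, max_terms)
        x = np.arange(k_guess + 1)
        cdf = np.asarray(self.cdf(x))
        cut = np.argmax(cdf > 1.0 - tail_mass)
        if cdf[cut] <= 1.0 - tail_mass:  # never exceeded within the guess
            cut = k_guess
        return cdf[: cut + 1]

    def rvs(self, n: int, seed=None, rng: np.random.Generator | None = None) -> np.ndarray:
        """i.i.d. draws by inversion of the closed-form cdf."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        u = rng.random(int(n))
        table = self.support_table()
        out = np.searchsorted(table, u, side="left").astype(np.int64)
        beyond = u > table[-1]
        if np.any(beyond):  # resolve the truncated far tail exactly
            for i in np.flatnonzero(beyond):
                out[i] = self._quantile_scalar(u[i])
        return out


class EBWE:
    """Entropy-based weighted exponential distribution, the continuous
    mixing law of the PEBWE model.

    Density: ``beta * (beta*x - ln beta) * exp(-beta*x) / (1 - ln beta)`` on
    x > 0.  For beta > 1 the printed density is negative on
    ``[0, ln(beta)/beta)``; it is evaluated as written, and sampling is only
    supported for beta <= 1 where the density is a proper one.
    """

    def __init__(self, beta: float, *, unsafe: bool = False):
        self.beta = validate_beta(beta, unsafe=unsafe)

    def _check_x(self, x) -> np.ndarray:
        arr = np.asarray(x, dtype=float)
        if np.any(arr < 0):
            raise ValueError("x must be non-negative")
        return arr

    def logpdf(self, x) -> np.ndarray | float:
        x = self._check_x(x)
        b, lb = self.beta, math.log(self.beta)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = math.log(b) + np.log(b * x - lb) - math.log(1.0 - lb) - b * x
        return out if out.ndim else float(out)

    def pdf(self, x) -> np.ndarray | float:
        x = self._check_x(x)
        b, lb = self.beta, math.log(self.beta)
        out = b * (b * x - lb) * np.exp(-b * x) / (1.0 - lb)
        return out if out.ndim else float(out)

    def cdf(self, x) -> np.ndarray | float:
        x = self._check_x(x)
        b, lb = self.beta, math.log(self.beta)
        out = 1.0 - (1.0 + b * x - lb) * np.exp(-b * x) / (1.0 - lb)
        return out if out.ndim else float(out)

    def sf(self, x) -> np.ndarray | float:
        x = self._check_x(x)
        b, lb = self.beta, math.log(self.beta)
        out = (1.0 + b * x - lb) * np.exp(-b * x) / (1.0 - lb)
        return out if out.ndim else float(out)

    def logsf(self, x) -> np.ndarray | float:
        x = self._check_x(x)
        b, lb = self.beta, math.log(self.beta)
        out = np.log(1.0 + b * x - lb) - math.log(1.0 - lb) - b * x
        return out if out.ndim else float(out)

    @property
    def mean(self) -> float:
        # first raw moment of the mixing law = mean of the count distribution
        b, lb = self.beta, math.log(self.beta)
        return (lb - 2.0) / (b * (lb - 1.0))

    def ppf(self, q) -> np.ndarray | float:
        qa = np.atleast_1d(np.asarray(q, dtype=float))
        if np.any((qa < 0.0) | (qa >= 1.0)):
            raise ValueError("q must lie in [0, 1)")
        if self.beta > 1.0:
            raise ValueError("ppf/rvs require beta <= 1 (density is negative near 0 otherwise)")
        out = np.empty(qa.shape)
        for i, qi in np.ndenumerate(qa):
            if qi == 0.0:
                out[i] = 0.0
                continue
            hi = 1.0
            while self.cdf(hi) < qi:
                hi *= 2.0
            out[i] = brentq(lambda t: self.cdf(t) - qi, 0.0, hi, xtol=1e-12)
        return float(out[0]) if np.ndim(q) == 0 else out

    def rvs(self, n: int, seed=None, rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None:
            rng = np.random.default_rng(seed)
        return self.ppf(rng.random(int(n)))
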
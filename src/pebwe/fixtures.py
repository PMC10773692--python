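"""Synthetic-sample generator for tests and estimator studies.

``generate_fixture`` draws event times from the PEBWE count model (or the
continuous EBWE mixing law for survival-style fixtures), optionally marks
a cured/immune sub-population of expected fraction ``eta`` (immunes never
experience the event and are always censored), and applies independent
uniform censoring on [0, c] to the susceptibles, with c calibrated so the
realised susceptible censoring probability matches ``censor_rate``.  The
uniform-censoring mechanism is a test convention, not a claim about any
particular study design.  Everything is driven by an explicit seed.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .distribution import EBWE, PEBWE
from .inference import CensoredSample

__all__ = ["generate_fixture"]


def _calibrate_horizon(t_event: np.ndarray, censor_rate: float) -> float:
    """Find c such that mean(P(U(0,c) < T)) = censor_rate over the drawn times.

    P(censored | T=t) = min(t/c, 1) under uniform censoring on [0, c].
    """
    t = t_event.astype(float)

    def gap(c):
        return float(np.mean(np.minimum(t / c, 1.0))) - censor_rate

    hi = max(t.max(), 1.0)
    # gap is decreasing in c; gap(->0) = P(T>0), gap(->inf) -> 0
    if gap(hi) > 0:
        while gap(hi) > 0:
            hi *= 2.0
    lo = hi / 2.0
    while gap(lo) < 0:
        lo /= 2.0
        if lo < 1e-12:
            break
    return brentq(gap, lo, hi)


def generate_fixture(
    beta: float,
    n: int,
    censor_rate: float = 0.0,
    eta: float = 0.0,
    seed: int | None = None,
    mode: str = "discrete",
) -> CensoredSample:
    """Draw a synthetic (possibly censored, possibly cure-fraction) sample.

    Parameters
    ----------
    beta
        PEBWE/EBWE parameter of the susceptible population.
    n
        Sample size.
    censor_rate
        Target censoring probability among susceptibles, in [0, 1).
    eta
        Expected immune (cured) fraction, in [0, 1).  Immunes are recorded
        at a censoring time with event = 0.
    seed
        Seed for the random generator; identical seeds give identical samples.
    mode
        "discrete" draws integer PEBWE counts; "ebwe" draws continuous
        EBWE lifetimes (requires beta <= 1).
    """
    if not 0.0 <= censor_rate < 1.0 or not 0.0 <= eta < 1.0:
        raise ValueError("censor_rate and eta must lie in [0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    if mode == "discrete":
        t_event = PEBWE(beta).rvs(n, rng=rng).astype(float)
    elif mode == "ebwe":
        t_event = EBWE(beta).rvs(n, rng=rng)
    else:
        raise ValueError(f"mode must be 'discrete' or 'ebwe', got {mode!r}")

    if censor_rate > 0.0:
        positive = t_event[t_event > 0]
        if len(positive) == 0:
            raise ValueError("cannot calibrate censoring: all event times are zero")
        horizon = _calibrate_horizon(positive, censor_rate)
    else:
        # immunes still need a censoring clock; use the observed range
        horizon = float(max(t_event.max(), 1.0))

    c_times = rng.uniform(0.0, horizon, size=n)
    immune = rng.random(n) < eta

    times = np.where(immune, c_times, t_event)
    events = (~immune).astype(np.int64)
    if censor_rate > 0.0:
        censored = ~immune & (c_times < t_event)
        times = np.where(censored, c_times, times)
        events = np.where(censored, 0, events)
    if mode == "discrete":
        times = np.floor(times)
    return CensoredSample(times, events)
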
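"""Exact stochastic simulation of the four-reaction siRNA kinetic model.

After short interfering RNAs escape the endosome into the cytosol, their
copy number ``S(t)`` evolves as a continuous-time Markov jump process with
four reaction channels:

====================  =============  ==========  =============
reaction              propensity     effect      meaning
====================  =============  ==========  =============
amplification         ``alpha * S``  ``S + 1``   RdRP-driven synthesis of new siRNA
degradation           ``lam * S``    ``S - 1``   lysosomal degradation
immigration           ``mu``         ``S + 1``   influx from neighbouring cells
emigration            ``sigma * S``  ``S - 1``   efflux to neighbouring cells
====================  =============  ==========  =============

The process is linear (birth-death with immigration/emigration), so its
mean obeys ``dE/dt = (alpha - lam - sigma) E + mu``, which
:func:`expected_count` evaluates in closed form; that closed form is the
moment oracle used by the test suite.

Simulation uses the exact Gillespie direct method: the waiting time to the
next event is exponential with rate equal to the total propensity, and the
event channel is chosen with probability proportional to its propensity.
The inner loop is compiled with numba and consumes a NumPy ``Generator``
directly, so a given seed reproduces a trajectory bit for bit.

When several siRNA species are co-injected they are assumed not to interact:
each type evolves as an independent copy of the single-type process with the
shared rate set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "RateSet",
    "PAPER_THETA",
    "Trajectory",
    "simulate_single",
    "simulate_endpoints",
    "simulate_multi",
    "simulate_trajectory",
    "expected_count",
    "endpoint_table",
]


@dataclass(frozen=True)
class RateSet:
    """The four kinetic rates governing one siRNA species.

    Parameters
    ----------
    alpha : float
        Amplification rate, per molecule per hour.
    lam : float
        Degradation rate, per molecule per hour.
    mu : float
        Immigration rate, per hour (zeroth order: independent of the state).
    sigma : float
        Emigration rate, per molecule per hour.
    """

    alpha: float
    lam: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        for name in ("alpha", "lam", "mu", "sigma"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"rate {name!r} must be finite and >= 0, got {value}")

    @property
    def net_growth(self) -> float:
        """Net per-molecule growth rate ``alpha - lam - sigma``."""
        return self.alpha - self.lam - self.sigma


#: Default rate set used by all worked examples: alpha=0.6, lam=0.3, mu=0.6,
#: sigma=0.23 (all per hour), giving a mild net growth of 0.07 per hour.
PAPER_THETA = RateSet(alpha=0.6, lam=0.3, mu=0.6, sigma=0.23)

#: Default elapsed time between escape and observation, in hours.
DEFAULT_DT = 12.0


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    """Coerce ``rng`` (Generator, integer seed, or None) to a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _check_dt(dt: float) -> float:
    dt = float(dt)
    if not math.isfinite(dt) or dt < 0:
        raise ValueError(f"elapsed time must be finite and >= 0, got {dt}")
    return dt


def _check_count(value: int, name: str = "count") -> int:
    count = int(value)
    if count != value or count < 0:
        raise ValueError(f"{name} must be a nonnegative integer, got {value!r}")
    return count


@njit(cache=True)
def _ssa_endpoint(s, dt, alpha, lam, mu, sigma, rng):
    """One exact direct-method realization; returns the state at time dt."""
    t = 0.0
    while True:
        a_amp = alpha * s
        a_deg = lam * s
        a_emi = sigma * s
        total = a_amp + a_deg + a_emi + mu
        if total <= 0.0:
            return s  # absorbing: zero molecules, no immigration
        # exponential waiting time; log1p keeps u=0 safe since random() < 1
        t += -np.log1p(-rng.random()) / total
        if t > dt:
            return s
        u = rng.random() * total
        if u < a_amp:
            s += 1
        elif u < a_amp + a_deg:
            s -= 1
        elif u < a_amp + a_deg + a_emi:
            s -= 1
        else:
            s += 1


@njit(cache=True)
def _ssa_endpoints_batch(s1, dt, alpha, lam, mu, sigma, out, rng):
    for i in range(out.shape[0]):
        out[i] = _ssa_endpoint(s1, dt, alpha, lam, mu, sigma, rng)


def simulate_single(
    s1: int,
    dt: float,
    theta: RateSet,
    rng: np.random.Generator | int | None = None,
) -> int:
    """Simulate one endpoint ``S(dt)`` of the four-reaction process.

    Parameters
    ----------
    s1 : int
        Initial molecule count (the escaped amount).
    dt : float
        Elapsed time in hours.
    theta : RateSet
        Kinetic rates.
    rng : numpy.random.Generator, int, or None
        Random stream; the same seed gives a bit-identical endpoint.

    Returns
    -------
    int
        The molecule count after ``dt`` hours.
    """
    s1 = _check_count(s1, "s1")
    dt = _check_dt(dt)
    if not isinstance(theta, RateSet):
        theta = RateSet(*theta)
    rng = as_rng(rng)
    return int(_ssa_endpoint(s1, dt, theta.alpha, theta.lam, theta.mu, theta.sigma, rng))


def simulate_endpoints(
    s1: int,
    dt: float,
    theta: RateSet,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate ``n`` independent endpoints from the same start ``s1``.

    This is the batch primitive behind every likelihood estimate; the loop
    runs entirely inside compiled code.
    """
    s1 = _check_count(s1, "s1")
    dt = _check_dt(dt)
    if not isinstance(theta, RateSet):
        theta = RateSet(*theta)
    if n < 1:
        raise ValueError(f"number of replicates must be >= 1, got {n}")
    rng = as_rng(rng)
    out = np.empty(int(n), dtype=np.int64)
    _ssa_endpoints_batch(s1, dt, theta.alpha, theta.lam, theta.mu, theta.sigma, out, rng)
    return out


def simulate_multi(
    v1: Sequence[int],
    dt: float,
    theta: RateSet,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Simulate the endpoint vector for ``m`` independent siRNA types.

    Each component evolves as an independent single-type process with the
    shared rate set; every type consumes its own child stream spawned from
    ``rng``, so the per-type dynamics are statistically independent while the
    whole vector stays reproducible from one seed.
    """
    v1 = np.asarray(v1, dtype=np.int64)
    if v1.ndim != 1 or v1.size < 1:
        raise ValueError("v1 must be a 1-D sequence with at least one type")
    if (v1 < 0).any():
        raise ValueError("all initial counts must be >= 0")
    dt = _check_dt(dt)
    if not isinstance(theta, RateSet):
        theta = RateSet(*theta)
    rng = as_rng(rng)
    streams = rng.spawn(v1.size)
    out = np.empty(v1.size, dtype=np.int64)
    for i, sub in enumerate(streams):
        out[i] = _ssa_endpoint(
            int(v1[i]), dt, theta.alpha, theta.lam, theta.mu, theta.sigma, sub
        )
    return out


@dataclass(frozen=True)
class Trajectory:
    """A fully recorded SSA path for ``m`` siRNA types.

    Attributes
    ----------
    times : numpy.ndarray
        Strictly increasing event times in hours, starting at 0.  The final
        entry is the elapsed time ``elapsed`` itself, so the last row of
        ``states`` is the state at the observation time.
    states : numpy.ndarray
        Integer array of shape ``(len(times), m)``; row ``j`` is the count
        vector immediately after the event at ``times[j]``.
    elapsed : float
        Total simulated duration in hours.
    """

    times: np.ndarray
    states: np.ndarray
    elapsed: float

    @property
    def endpoint(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        """Tab-friendly table: time_hours, count_type_1 .. count_type_m."""
        m = self.states.shape[1]
        data = {"time_hours": self.times}
        for i in range(m):
            data[f"count_type_{i + 1}"] = self.states[:, i]
        return pd.DataFrame(data)


def simulate_trajectory(
    v1: Sequence[int] | int,
    dt: float,
    theta: RateSet,
    rng: np.random.Generator | int | None = None,
) -> Trajectory:
    """Simulate and record a full event-by-event path.

    Intended for visual inspection of the dynamics; inference loops use the
    endpoint-only kernels.  A scalar ``v1`` is treated as a single type.
    """
    scalar = np.isscalar(v1)
    v1_arr = np.atleast_1d(np.asarray(v1, dtype=np.int64))
    if (v1_arr < 0).any():
        raise ValueError("all initial counts must be >= 0")
    dt = _check_dt(dt)
    if not isinstance(theta, RateSet):
        theta = RateSet(*theta)
    rng = as_rng(rng)
    streams = rng.spawn(v1_arr.size) if not scalar or v1_arr.size > 1 else [rng]

    events: list[tuple[float, int, int]] = []  # (time, type index, +/-1)
    for i, sub in enumerate(streams):
        s = int(v1_arr[i])
        t = 0.0
        while True:
            a_amp = theta.alpha * s
            a_deg = theta.lam * s
            a_emi = theta.sigma * s
            total = a_amp + a_deg + a_emi + theta.mu
            if total <= 0.0:
                break
            t += sub.exponential(1.0 / total)
            if t > dt:
                break
            u = sub.random() * total
            delta = 1 if (u < a_amp or u >= a_amp + a_deg + a_emi) else -1
            s += delta
            events.append((t, i, delta))

    events.sort(key=lambda e: e[0])
    n_rows = len(events) + 2
    times = np.empty(n_rows)
    states = np.empty((n_rows, v1_arr.size), dtype=np.int64)
    times[0] = 0.0
    states[0] = v1_arr
    state = v1_arr.copy()
    for j, (t, i, delta) in enumerate(events, start=1):
        state[i] += delta
        times[j] = t
        states[j] = state
    times[-1] = dt
    states[-1] = state
    if len(events) > 0 and times[-2] == dt:  # vanishingly unlikely tie
        times, states = times[:-1], states[:-1]
    return Trajectory(times=times, states=states, elapsed=dt)


def expected_count(s1: int, t: float, theta: RateSet) -> float:
    """Closed-form mean of the process: ``(s1 + mu/r) e^{rt} - mu/r``.

    Here ``r = alpha - lam - sigma``; when ``r == 0`` the limiting form
    ``s1 + mu t`` applies.  Used as the independent moment oracle for the
    stochastic simulator.
    """
    s1 = _check_count(s1, "s1")
    t = _check_dt(t)
    if not isinstance(theta, RateSet):
        theta = RateSet(*theta)
    r = theta.net_growth
    if abs(r) < 1e-12:
        return s1 + theta.mu * t
    ratio = theta.mu / r
    return (s1 + ratio) * math.exp(r * t) - ratio


def invert_expected_total(
    total: float, m: int, t: float, theta: RateSet
) -> float:
    """Method-of-moments inverse of the mean map for an ``m``-type total.

    Solves ``(s1 + m mu/r) e^{rt} - m mu/r = total`` for ``s1`` (with the
    ``r -> 0`` limit ``total - m mu t``); the result may be negative when
    immigration alone explains the observation.  Used to seed the MCMC
    chains at a crude but deterministic estimate of the escape amount.
    """
    t = _check_dt(t)
    if not isinstance(theta, RateSet):
        theta = RateSet(*theta)
    r = theta.net_growth
    if abs(r) < 1e-12:
        return float(total) - m * theta.mu * t
    c = m * theta.mu / r
    return (float(total) + c) * math.exp(-r * t) - c


def endpoint_table(endpoints: np.ndarray) -> pd.DataFrame:
    """Tidy table of an endpoint ensemble: replicate, endpoint (per type).

    Accepts a 1-D array (single type) or a 2-D ``(replicates, types)`` array.
    """
    endpoints = np.asarray(endpoints)
    if endpoints.ndim == 1:
        return pd.DataFrame(
            {"replicate": np.arange(1, endpoints.size + 1), "endpoint": endpoints}
        )
    data = {"replicate": np.arange(1, endpoints.shape[0] + 1)}
    for i in range(endpoints.shape[1]):
        data[f"endpoint_type_{i + 1}"] = endpoints[:, i]
    return pd.DataFrame(data)
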
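"""Single-type inference of the escaped amount ``s1`` from the observed
post-amplification amount ``s2``.

Two routes are provided:

* :func:`posterior_grid_single` — grid Bayes: for every candidate
  ``s1 = 1..smax`` simulate ``n_sims`` endpoints, estimate the likelihood
  ``p(s2 | s1)`` with the k-NN density, and normalize across the grid under
  a uniform prior (``smax <= s2`` since amplification plus immigration can
  only grow the expected count).
* :func:`mh_sample_single` — ABC Metropolis-Hastings: a random walk on
  ``s1`` where each proposal is scored by one fresh endpoint simulation and
  accepted with probability ``min{1, e^{d - d'}}``; the distance of the
  current state is retained until a proposal is accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .kinetics import (
    RateSet,
    as_rng,
    invert_expected_total,
    simulate_endpoints,
    simulate_single,
)
from .likelihood import log_knn_density, distance

__all__ = [
    "InferenceConfig",
    "PosteriorGrid",
    "Chain",
    "posterior_grid_single",
    "accept_probability",
    "mh_sample_single",
    "summarize",
]


def default_k_nn(n_sims: int) -> int:
    """Consistency-motivated default neighbour count ``ceil(sqrt(n))``."""
    return math.ceil(math.sqrt(n_sims))


@dataclass(frozen=True)
class InferenceConfig:
    """Algorithm settings for single-type inference.

    Attributes
    ----------
    smax : int or None
        Upper bound of the candidate grid / chain support; defaults to the
        observed ``s2`` (the escaped amount cannot exceed the amplified one).
    n_sims : int
        Simulated endpoints per grid point for the k-NN likelihood.
    k_nn : int or None
        Neighbour count; defaults to ``ceil(sqrt(n_sims))``.
    N : int
        Chain length (number of MH iterations; the chain holds N+1 states).
    proposal_width : int or None
        Half-width ``w`` of the symmetric integer random-walk proposal;
        defaults to ``max(1, round(0.05 * s2))``.
    burn_in_fraction : float
        Leading fraction of the chain discarded before summaries.
    s1_init : int or None
        Chain start; defaults to a method-of-moments estimate (the inverse
        of the closed-form mean map at the observation, clipped to the
        support).  The retained-distance sampler accepts rarely, so a
        deterministic, data-driven start beats an arbitrary one.
    window : (int, int) or None
        Optional sub-range ``[lo, hi]`` of the grid for scaled-down runs.
    seed : int or None
        Convenience seed used when no generator is passed to a routine.
    """

    smax: Optional[int] = None
    n_sims: int = 100
    k_nn: Optional[int] = None
    N: int = 10_000
    proposal_width: Optional[int] = None
    burn_in_fraction: float = 0.2
    s1_init: Optional[int] = None
    window: Optional[tuple[int, int]] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_sims < 1 or self.N < 1:
            raise ValueError("n_sims and N must be >= 1")
        if self.k_nn is not None and not 1 <= self.k_nn <= self.n_sims:
            raise ValueError("need n_sims >= k_nn >= 1")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must lie in [0, 1)")

    def resolved(self, s2: int) -> "InferenceConfig":
        """Fill the data-dependent defaults for an observed ``s2``."""
        smax = self.smax if self.smax is not None else int(s2)
        if smax < 1:
            raise ValueError("smax must be >= 1")
        if smax > s2:
            raise ValueError(f"smax={smax} exceeds the observed s2={s2}")
        k_nn = self.k_nn if self.k_nn is not None else default_k_nn(self.n_sims)
        width = (
            self.proposal_width
            if self.proposal_width is not None
            else max(1, round(0.05 * s2))
        )
        return replace(self, smax=smax, k_nn=k_nn, proposal_width=width)


@dataclass(frozen=True)
class PosteriorGrid:
    """Normalized posterior over candidate escape amounts."""

    support: np.ndarray  # integer candidates, increasing
    probs: np.ndarray  # same length, sums to 1

    def __post_init__(self) -> None:
        if self.support.shape != self.probs.shape:
            raise ValueError("support and probs must have identical shape")
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probs must be nonnegative and sum to 1")

    @property
    def mode(self) -> int:
        """Argmax of the posterior; ties go to the smallest candidate."""
        return int(self.support[int(np.argmax(self.probs))])

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.probs))

    @property
    def variance(self) -> float:
        m = self.mean
        return float(np.dot((self.support - m) ** 2, self.probs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"s1": self.support, "probability": self.probs})


@dataclass(frozen=True)
class Chain:
    """An MH chain of candidate escape amounts with acceptance bookkeeping."""

    samples: np.ndarray  # length N+1, integer states s1^(0..N)
    distances: np.ndarray  # retained distance after each step
    accepted: np.ndarray  # whether the proposal at each step was accepted
    burn_in: int  # number of leading samples discarded by summaries

    @property
    def post_burn_in(self) -> np.ndarray:
        return self.samples[self.burn_in :]

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean())

    def to_frame(self) -> pd.DataFrame:
        n = self.samples.size
        return pd.DataFrame(
            {
                "iteration": np.arange(n),
                "s1": self.samples,
                # step 0 is the initial state: no proposal, distance as computed
                "distance": self.distances,
                "accepted": self.accepted,
            }
        )


def posterior_grid_single(
    s2: int,
    dt: float,
    theta: RateSet,
    config: InferenceConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> PosteriorGrid:
    """Grid-Bayes posterior ``p(s1 | s2)`` over ``s1 = 1..smax``.

    For each candidate, ``n_sims`` endpoints are simulated and the k-NN
    density at the observed ``s2`` serves as the likelihood; a uniform prior
    makes the posterior the normalized likelihood profile.  Log-likelihoods
    are accumulated and normalized by their maximum, so the grid never
    underflows even for large observations.
    """
    s2 = int(s2)
    if s2 < 1:
        raise ValueError(f"observed s2 must be >= 1, got {s2}")
    config = (config or InferenceConfig()).resolved(s2)
    if config.seed is not None and rng is None:
        rng = config.seed
    rng = as_rng(rng)

    lo, hi = 1, config.smax
    if config.window is not None:
        lo, hi = config.window
        if not 1 <= lo <= hi <= config.smax:
            raise ValueError(f"window {config.window} not within [1, {config.smax}]")
    support = np.arange(lo, hi + 1)

    log_like = np.empty(support.size)
    for i, s1 in enumerate(support):
        sims = simulate_endpoints(int(s1), dt, theta, config.n_sims, rng)
        log_like[i] = log_knn_density(sims, s2, config.k_nn)
    log_like -= log_like.max()
    probs = np.exp(log_like)
    probs /= probs.sum()
    return PosteriorGrid(support=support, probs=probs)


def accept_probability(d_current: float, d_proposed: float) -> float:
    """MH acceptance ``min{1, e^{-d'} / e^{-d}}`` for the distance kernel."""
    for d in (d_current, d_proposed):
        if not math.isfinite(d) or d < 0:
            raise ValueError(f"distances must be finite and >= 0, got {d}")
    return min(1.0, math.exp(d_current - d_proposed))


def _propose(s1: int, width: int, lo: int, hi: int, rng: np.random.Generator):
    """Symmetric integer random-walk step; None when outside [lo, hi]."""
    delta = int(rng.integers(1, width + 1))
    if rng.random() < 0.5:
        delta = -delta
    proposal = s1 + delta
    if lo <= proposal <= hi:
        return proposal
    return None  # out-of-support proposals are rejected, preserving balance


def mh_sample_single(
    s2: int,
    dt: float,
    theta: RateSet,
    config: InferenceConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> Chain:
    """ABC Metropolis-Hastings sampler for the single-type escape amount.

    Implements the retained-distance scheme: one endpoint simulation per
    proposal, acceptance probability ``min{1, e^{d - d'}}``, and the stored
    distance is replaced only when a proposal is accepted.
    """
    s2 = int(s2)
    if s2 < 1:
        raise ValueError(f"observed s2 must be >= 1, got {s2}")
    config = (config or InferenceConfig()).resolved(s2)
    if config.seed is not None and rng is None:
        rng = config.seed
    rng = as_rng(rng)

    smax, width, N = config.smax, config.proposal_width, config.N
    if config.s1_init is not None:
        state = int(config.s1_init)
        if not 1 <= state <= smax:
            raise ValueError(f"initial state {state} outside [1, {smax}]")
    else:
        moment = invert_expected_total(s2, 1, dt, theta)
        state = int(np.clip(round(moment), 1, smax))

    samples = np.empty(N + 1, dtype=np.int64)
    distances = np.empty(N + 1)
    accepted = np.zeros(N + 1, dtype=bool)

    d = distance(simulate_single(state, dt, theta, rng), s2)
    samples[0], distances[0] = state, d
    for k in range(1, N + 1):
        proposal = _propose(state, width, 1, smax, rng)
        if proposal is not None:
            d_prop = distance(simulate_single(proposal, dt, theta, rng), s2)
            if rng.random() <= accept_probability(d, d_prop):
                state, d = proposal, d_prop
                accepted[k] = True
        samples[k], distances[k] = state, d

    burn_in = int(config.burn_in_fraction * (N + 1))
    return Chain(samples=samples, distances=distances, accepted=accepted, burn_in=burn_in)


def summarize(obj: PosteriorGrid | Chain) -> dict:
    """Point estimates from a posterior grid or an MH chain.

    Grids report the argmax (smallest candidate on ties) plus the grid mean
    and variance; chains report the mean, variance, and histogram mode of
    the post-burn-in samples.
    """
    if isinstance(obj, PosteriorGrid):
        return {"mode": obj.mode, "mean": obj.mean, "variance": obj.variance}
    if isinstance(obj, Chain):
        kept = obj.post_burn_in
        if kept.size == 0:
            raise ValueError("chain is empty after burn-in")
        counts = np.bincount(kept)
        return {
            "mode": int(np.argmax(counts)),
            "mean": float(kept.mean()),
            "variance": float(kept.var()),
            "burn_in": obj.burn_in,
            "acceptance_rate": obj.acceptance_rate,
        }
    raise TypeError(f"cannot summarize object of type {type(obj).__name__}")
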
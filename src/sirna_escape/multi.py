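"""Multi-type inference of the total escape amount under a hypergeometric
bottleneck.

When ``m`` siRNA types are co-injected with composition ``v0`` and all
types are phenotypically identical, the composition ``v1`` of the ``s1``
molecules that escape the endosome is a draw without replacement from
``v0`` — a multivariate hypergeometric bottleneck.  Each escaped type then
amplifies independently, producing the observed composition ``v2``.

The posterior over the *total* ``s1`` requires summing the per-composition
posterior over every ``v1`` with ``sum(v1) = s1``; the number of such
compositions grows superexponentially, so the grid route replaces the sum
with a Monte-Carlo average over ``K`` hypergeometric draws per grid point
(:func:`posterior_grid_multi`).  The ABC-MCMC route
(:func:`mh_sample_multi`) sidesteps the sum entirely: each proposal draws a
fresh composition, simulates one endpoint vector and scores it with the
exponential distance kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_hypergeom

from .kinetics import (
    RateSet,
    as_rng,
    invert_expected_total,
    simulate_endpoints,
    simulate_multi,
)
from .likelihood import log_knn_density, distance
from .single import Chain, PosteriorGrid, accept_probability, default_k_nn, _propose

__all__ = [
    "MultiInferenceConfig",
    "mvhg_pmf",
    "mvhg_logpmf",
    "mvhg_sample",
    "mvhg_mode",
    "posterior_grid_multi",
    "mh_sample_multi",
]


@dataclass(frozen=True)
class MultiInferenceConfig:
    """Algorithm settings for multi-type inference.

    ``K`` is the number of hypergeometric compositions averaged per grid
    point and ``n_sims`` the simulated endpoints per type per composition.
    The remaining fields mirror the single-type configuration.  Two named
    presets are shipped: ``"paper"`` (K=1000, n_sims=100) and ``"fast"``
    (K=50, n_sims=30) for desk-scale runs.
    """

    smax: Optional[int] = None
    K: int = 1000
    n_sims: int = 100
    k_nn: Optional[int] = None
    N: int = 10_000
    proposal_width: Optional[int] = None
    burn_in_fraction: float = 0.2
    s1_init: Optional[int] = None
    norm: str = "l2"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_sims < 1 or self.N < 1:
            raise ValueError("K, n_sims and N must all be >= 1")
        if self.k_nn is not None and not 1 <= self.k_nn <= self.n_sims:
            raise ValueError("need n_sims >= k_nn >= 1")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must lie in [0, 1)")

    @classmethod
    def preset(cls, name: str, **overrides) -> "MultiInferenceConfig":
        presets = {"paper": dict(K=1000, n_sims=100), "fast": dict(K=50, n_sims=30)}
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
        return cls(**{**presets[name], **overrides})

    def resolved(self, v0: np.ndarray, v2: np.ndarray) -> "MultiInferenceConfig":
        total_obs = int(v2.sum())
        smax = self.smax if self.smax is not None else min(total_obs, int(v0.sum()))
        if smax < 1:
            raise ValueError("smax must be >= 1 (observed totals too small)")
        k_nn = self.k_nn if self.k_nn is not None else default_k_nn(self.n_sims)
        width = (
            self.proposal_width
            if self.proposal_width is not None
            else max(1, round(0.05 * total_obs))
        )
        return replace(self, smax=smax, k_nn=k_nn, proposal_width=width)


def _check_compositions(v1, v0) -> tuple[np.ndarray, np.ndarray]:
    v1 = np.asarray(v1, dtype=np.int64)
    v0 = np.asarray(v0, dtype=np.int64)
    if v1.shape != v0.shape or v1.ndim != 1:
        raise ValueError(f"v1 and v0 must be 1-D with equal length, got {v1.shape} vs {v0.shape}")
    if (v1 < 0).any() or (v0 < 0).any():
        raise ValueError("counts must be >= 0")
    return v1, v0


def mvhg_logpmf(v1: Sequence[int], v0: Sequence[int]) -> float:
    """Log-probability of drawing composition ``v1`` from population ``v0``.

    ``prod_i C(v0[i], v1[i]) / C(sum v0, sum v1)``; ``-inf`` when some
    component exceeds its population.
    """
    v1, v0 = _check_compositions(v1, v0)
    if (v1 > v0).any():
        return -math.inf
    return float(multivariate_hypergeom.logpmf(x=v1, m=v0, n=int(v1.sum())))


def mvhg_pmf(v1: Sequence[int], v0: Sequence[int]) -> float:
    """Multivariate hypergeometric pmf; 0 when ``v1`` is inadmissible."""
    lp = mvhg_logpmf(v1, v0)
    return 0.0 if lp == -math.inf else math.exp(lp)


def _check_draw_size(s1: int, v0: np.ndarray) -> int:
    s1 = int(s1)
    if not 0 <= s1 <= int(v0.sum()):
        raise ValueError(f"s1 must lie in [0, sum(v0)={int(v0.sum())}], got {s1}")
    return s1


def mvhg_sample(
    s1: int,
    v0: Sequence[int],
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw one composition of size ``s1`` without replacement from ``v0``."""
    v0 = np.asarray(v0, dtype=np.int64)
    s1 = _check_draw_size(s1, v0)
    rng = as_rng(rng)
    return rng.multivariate_hypergeometric(v0, s1).astype(np.int64)


def mvhg_mode(s1: int, v0: Sequence[int]) -> np.ndarray:
    """A most probable composition of size ``s1`` drawn from ``v0``.

    Greedy proportional allocation followed by single-unit exchanges until
    no transfer increases the pmf.  Because ``log C(v0[i], v1[i])`` is
    concave in ``v1[i]``, local exchange optimality implies the global
    maximum.  Ties between symmetric optima are broken toward the
    lexicographically smallest vector.
    """
    v0 = np.asarray(v0, dtype=np.int64)
    s1 = _check_draw_size(s1, v0)
    total = int(v0.sum())
    if s1 == 0:
        return np.zeros_like(v0)
    if s1 == total:
        return v0.copy()

    v1 = np.minimum((s1 * v0) // total, v0)

    def gain_add(j):  # log-pmf change from adding one unit to type j
        return math.log(v0[j] - v1[j]) - math.log(v1[j] + 1) if v1[j] < v0[j] else -math.inf

    def gain_remove(i):  # log-pmf change from removing one unit from type i
        return math.log(v1[i]) - math.log(v0[i] - v1[i] + 1) if v1[i] > 0 else -math.inf

    while int(v1.sum()) < s1:
        gains = [gain_add(j) for j in range(v0.size)]
        best = max(gains)
        # among tied best additions, add to the last index: earlier
        # components stay small, keeping the vector lexicographically minimal
        j = max(i for i, g in enumerate(gains) if g == best)
        v1[j] += 1

    while v0.size > 1:
        removals = np.array([gain_remove(i) for i in range(v0.size)])
        additions = np.array([gain_add(j) for j in range(v0.size)])
        order_r = np.argsort(removals)
        order_a = np.argsort(additions)
        i, j = int(order_r[-1]), int(order_a[-1])
        if i == j:  # best removal and addition collide; try the runner-ups
            alt1 = (int(order_r[-2]), j)
            alt2 = (i, int(order_a[-2]))
            i, j = max(
                (alt1, alt2), key=lambda p: removals[p[0]] + additions[p[1]]
            )
        if removals[i] + additions[j] <= 1e-12:
            break
        v1[i] -= 1
        v1[j] += 1

    # canonicalize symmetric plateaus: within groups of equal population the
    # pmf is permutation-invariant, so sort those allocations ascending
    for pop in np.unique(v0):
        idx = np.flatnonzero(v0 == pop)
        if idx.size > 1:
            v1[idx] = np.sort(v1[idx])
    return v1


def posterior_grid_multi(
    v0: Sequence[int],
    v2: Sequence[int],
    dt: float,
    theta: RateSet,
    config: MultiInferenceConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> PosteriorGrid:
    """Grid-Bayes posterior over the total escape amount ``s1``.

    The posterior numerator for a total ``s1`` is the bottleneck-weighted
    sum over compositions, ``sum_{v1: sum=s1} p(v1|v0) prod_i p(v2[i]|v1[i])``
    — exactly the expectation of the likelihood product under the
    hypergeometric bottleneck.  It is therefore estimated by drawing ``K``
    compositions from that distribution and averaging the per-type k-NN
    likelihood products (log space); the bottleneck pmf must *not* be
    multiplied in again, since the draws already come from it.  Per-type
    likelihoods use ``n_sims`` fresh simulations each; the averaged weights
    are normalized across the grid.
    """
    v2_arr, v0_arr = _check_compositions(v2, v0)
    config = (config or MultiInferenceConfig()).resolved(v0_arr, v2_arr)
    if config.seed is not None and rng is None:
        rng = config.seed
    rng = as_rng(rng)

    support = np.arange(1, config.smax + 1)
    log_post = np.empty(support.size)
    log_weights = np.empty(config.K)
    for idx, s1 in enumerate(support):
        for k in range(config.K):
            v1 = mvhg_sample(int(s1), v0_arr, rng)
            lw = 0.0
            for i in range(v0_arr.size):
                sims = simulate_endpoints(int(v1[i]), dt, theta, config.n_sims, rng)
                lw += log_knn_density(sims, int(v2_arr[i]), config.k_nn)
            log_weights[k] = lw
        log_post[idx] = logsumexp(log_weights) - math.log(config.K)

    if not np.isfinite(log_post).any():
        raise RuntimeError(
            "posterior stage: every Monte-Carlo weight vanished; "
            "increase K or n_sims"
        )
    log_post -= log_post.max()
    probs = np.exp(log_post)
    probs /= probs.sum()
    return PosteriorGrid(support=support, probs=probs)


def mh_sample_multi(
    v0: Sequence[int],
    v2: Sequence[int],
    dt: float,
    theta: RateSet,
    config: MultiInferenceConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> Chain:
    """ABC Metropolis-Hastings sampler for the total escape amount.

    Per step: propose ``s1'`` by a symmetric integer random walk, draw a
    composition ``v1'`` from the bottleneck, simulate one endpoint vector,
    measure its distance to the observation and accept with probability
    ``min{1, e^{d - d'}}``.  The retained distance is replaced only on
    acceptance, exactly as in the single-type sampler.
    """
    v2_arr, v0_arr = _check_compositions(v2, v0)
    config = (config or MultiInferenceConfig()).resolved(v0_arr, v2_arr)
    if config.seed is not None and rng is None:
        rng = config.seed
    rng = as_rng(rng)

    smax, width, N = config.smax, config.proposal_width, config.N
    if config.s1_init is not None:
        state = int(config.s1_init)
        if not 1 <= state <= smax:
            raise ValueError(f"initial state {state} outside [1, {smax}]")
    else:
        moment = invert_expected_total(int(v2_arr.sum()), v0_arr.size, dt, theta)
        state = int(np.clip(round(moment), 1, smax))

    samples = np.empty(N + 1, dtype=np.int64)
    distances = np.empty(N + 1)
    accepted = np.zeros(N + 1, dtype=bool)

    def score(s1: int) -> float:
        v1 = mvhg_sample(s1, v0_arr, rng)
        sim = simulate_multi(v1, dt, theta, rng)
        return distance(sim, v2_arr, norm=config.norm)

    d = score(state)
    samples[0], distances[0] = state, d
    for k in range(1, N + 1):
        proposal = _propose(state, width, 1, smax, rng)
        if proposal is not None:
            d_prop = score(proposal)
            if rng.random() <= accept_probability(d, d_prop):
                state, d = proposal, d_prop
                accepted[k] = True
        samples[k], distances[k] = state, d

    burn_in = int(config.burn_in_fraction * (N + 1))
    return Chain(samples=samples, distances=distances, accepted=accepted, burn_in=burn_in)
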
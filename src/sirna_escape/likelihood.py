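"""Simulation-based likelihood pieces shared by both inference routes.

The endpoint distribution of the kinetic model has no closed form, so the
grid-Bayes route estimates ``p(s2 | s1)`` nonparametrically from simulated
endpoints with a k-nearest-neighbour density estimate, and the ABC-MCMC
route replaces the likelihood ratio with an exponential kernel of the
distance between one simulated endpoint and the observation.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["knn_density", "log_knn_density", "pseudo_likelihood", "distance"]

# Endpoints live on the integer lattice, so the k-th neighbour radius can be
# exactly zero; flooring it at half the lattice spacing attributes each
# integer a unit-width cell and keeps the estimate finite.
RADIUS_FLOOR = 0.5


def _knn_radius(samples: np.ndarray, x: float, k: int) -> float:
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 1 or samples.size == 0:
        raise ValueError("samples must be a nonempty 1-D sequence")
    n = samples.size
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n={n}, got {k}")
    dists = np.abs(samples - x)
    # k-th smallest distance *value* counted with multiplicity: ties at the
    # radius are handled by the ordinary order statistic.
    r_k = np.partition(dists, k - 1)[k - 1]
    return max(float(r_k), RADIUS_FLOOR)


def knn_density(samples: np.ndarray, x: float, k: int) -> float:
    """k-NN density estimate ``k / (2 n r_k)`` at the query point ``x``.

    ``r_k`` is the distance from ``x`` to its k-th nearest sample value,
    floored at 0.5 (half the integer lattice spacing).  Always finite and
    strictly positive.
    """
    n = np.asarray(samples).size
    return k / (2.0 * n * _knn_radius(samples, x, k))


def log_knn_density(samples: np.ndarray, x: float, k: int) -> float:
    """``log(knn_density)``; the grid posteriors accumulate in log space."""
    n = np.asarray(samples).size
    return math.log(k) - math.log(2.0 * n * _knn_radius(samples, x, k))


def pseudo_likelihood(d: float) -> float:
    """Exponential distance kernel ``e^{-d}`` used as the ABC likelihood.

    Equals 1 exactly when the simulated endpoint reproduces the observation
    and decays strictly as the distance grows; there is no bandwidth.
    """
    d = float(d)
    if not math.isfinite(d) or d < 0:
        raise ValueError(f"distance must be finite and >= 0, got {d}")
    return math.exp(-d)


def distance(sim, obs, norm: str = "l2") -> float:
    """Discrepancy between a simulated and an observed endpoint.

    Scalars (or length-1 vectors) use the absolute difference; longer
    vectors use the Euclidean norm by default, or the L1 norm with
    ``norm="l1"`` for sensitivity checks.
    """
    sim = np.atleast_1d(np.asarray(sim, dtype=np.float64))
    obs = np.atleast_1d(np.asarray(obs, dtype=np.float64))
    if sim.shape != obs.shape:
        raise ValueError(f"shape mismatch: sim {sim.shape} vs obs {obs.shape}")
    diff = sim - obs
    if sim.size == 1:
        return float(abs(diff[0]))
    if norm == "l2":
        return float(np.linalg.norm(diff))
    if norm == "l1":
        return float(np.abs(diff).sum())
    raise ValueError(f"norm must be 'l1' or 'l2', got {norm!r}")
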
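"""End-to-end in-silico experiments: generate observed data from a known
escape target, run an estimator, and summarize.

The validation workflow is fully synthetic.  A "true" escape amount
``s1*`` is fixed, observed data are manufactured by the simulator — the
observation is the median of an odd number of independent endpoints
(101 by default), which tames the heavy right tail of the endpoint
distribution — and the chosen estimator is asked to recover ``s1*``.
For multi-type experiments the escaped composition fed to the simulator is
the mode of the hypergeometric bottleneck, so the synthetic data correspond
to the single most probable split of ``s1*`` across types.

Every experiment is reproducible bit for bit from its
:class:`ExperimentSpec` and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .kinetics import DEFAULT_DT, PAPER_THETA, RateSet, as_rng, simulate_endpoints, simulate_multi
from .single import (
    Chain,
    InferenceConfig,
    PosteriorGrid,
    mh_sample_single,
    posterior_grid_single,
    summarize,
)
from .multi import (
    MultiInferenceConfig,
    mh_sample_multi,
    mvhg_mode,
    posterior_grid_multi,
)

__all__ = [
    "ExperimentSpec",
    "ExperimentResult",
    "generate_observed_single",
    "generate_observed_multi",
    "run_experiment",
    "write_result",
    "DEFAULT_V0",
    "DEFAULT_N_OBS",
]

logger = logging.getLogger("sirna_escape")

#: Default multi-type injection: seven siRNA types at 600 copies each.
DEFAULT_V0 = (600,) * 7

#: Default number of observed replicates whose median is the observation.
DEFAULT_N_OBS = 101

ALGORITHMS = ("bayes-single", "mcmc-single", "bayes-multi", "mcmc-multi")


def _check_n_obs(n_obs: int) -> int:
    n_obs = int(n_obs)
    if n_obs < 1 or n_obs % 2 == 0:
        raise ValueError(
            f"observe stage: n_obs must be odd and >= 1 so the integer median "
            f"is well defined, got {n_obs}"
        )
    return n_obs


def generate_observed_single(
    true_s1: int,
    dt: float,
    theta: RateSet,
    n_obs: int = DEFAULT_N_OBS,
    rng: np.random.Generator | int | None = None,
) -> int:
    """Median of ``n_obs`` independent endpoints started from ``true_s1``."""
    n_obs = _check_n_obs(n_obs)
    rng = as_rng(rng)
    endpoints = simulate_endpoints(true_s1, dt, theta, n_obs, rng)
    return int(np.median(endpoints))


def generate_observed_multi(
    true_s1: int,
    v0: Sequence[int],
    dt: float,
    theta: RateSet,
    n_obs: int = DEFAULT_N_OBS,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Componentwise median of ``n_obs`` endpoint vectors from the modal split.

    The escaped composition is ``v1* = mvhg_mode(true_s1, v0)``; each of the
    ``n_obs`` replicates simulates every type independently over ``dt``.
    """
    n_obs = _check_n_obs(n_obs)
    rng = as_rng(rng)
    v1_star = mvhg_mode(true_s1, v0)
    reps = np.stack([simulate_multi(v1_star, dt, theta, rng) for _ in range(n_obs)])
    return np.median(reps, axis=0).astype(np.int64)


@dataclass(frozen=True)
class ExperimentSpec:
    """Complete description of one in-silico experiment.

    ``s0`` (the initially injected single-type amount) appears in the
    biological narrative but in no formula; it is recorded for documentation
    only and never used computationally.
    """

    algorithm: str
    true_s1: int
    theta: RateSet = PAPER_THETA
    dt: float = DEFAULT_DT
    v0: Optional[tuple[int, ...]] = None
    n_obs: int = DEFAULT_N_OBS
    config: Union[InferenceConfig, MultiInferenceConfig, None] = None
    seed: int = 0
    s0: Optional[int] = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"spec stage: unknown algorithm {self.algorithm!r}; "
                f"choose from {ALGORITHMS}"
            )
        if self.true_s1 < 1:
            raise ValueError("spec stage: true_s1 must be >= 1")
        _check_n_obs(self.n_obs)
        if self.is_multi:
            v0 = self.v0 if self.v0 is not None else DEFAULT_V0
            object.__setattr__(self, "v0", tuple(int(x) for x in v0))
            if self.true_s1 > sum(self.v0):
                raise ValueError("spec stage: true_s1 exceeds the injected total")

    @property
    def is_multi(self) -> bool:
        return self.algorithm.endswith("-multi")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["theta"] = asdict(self.theta)
        if self.config is not None:
            d["config"] = asdict(self.config)
        return d

    def digest(self) -> str:
        """Short stable hash of the full configuration, for log lines."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class ExperimentResult:
    """Everything an experiment produced, reproducible from (spec, seed)."""

    spec: ExperimentSpec
    observed: np.ndarray  # scalar observation stored as a length-1 array
    posterior: Optional[PosteriorGrid]
    chain: Optional[Chain]
    summary: dict
    runtime_seconds: float = field(compare=False)


def run_experiment(spec: ExperimentSpec) -> ExperimentResult:
    """Generate observed data, run the selected estimator, and summarize."""
    rng = np.random.default_rng(spec.seed)
    logger.info(
        "experiment start: algorithm=%s true_s1=%d seed=%d config=%s",
        spec.algorithm,
        spec.true_s1,
        spec.seed,
        spec.digest(),
    )
    t0 = time.perf_counter()

    if spec.is_multi:
        observed = generate_observed_multi(
            spec.true_s1, spec.v0, spec.dt, spec.theta, spec.n_obs, rng
        )
        config = spec.config or MultiInferenceConfig.preset("fast")
        if spec.algorithm == "bayes-multi":
            posterior = posterior_grid_multi(spec.v0, observed, spec.dt, spec.theta, config, rng)
            chain = None
            summary = summarize(posterior)
        else:
            posterior = None
            chain = mh_sample_multi(spec.v0, observed, spec.dt, spec.theta, config, rng)
            summary = summarize(chain)
    else:
        observed_s2 = generate_observed_single(
            spec.true_s1, spec.dt, spec.theta, spec.n_obs, rng
        )
        observed = np.array([observed_s2], dtype=np.int64)
        config = spec.config or InferenceConfig()
        if spec.algorithm == "bayes-single":
            posterior = posterior_grid_single(observed_s2, spec.dt, spec.theta, config, rng)
            chain = None
            summary = summarize(posterior)
        else:
            posterior = None
            chain = mh_sample_single(observed_s2, spec.dt, spec.theta, config, rng)
            summary = summarize(chain)

    runtime = time.perf_counter() - t0
    summary = {**summary, "seed": spec.seed, "observed": observed.tolist()}
    logger.info(
        "experiment done in %.1fs: mode=%s mean=%.2f",
        runtime,
        summary.get("mode"),
        summary.get("mean", float("nan")),
    )
    return ExperimentResult(
        spec=spec,
        observed=observed,
        posterior=posterior,
        chain=chain,
        summary=summary,
        runtime_seconds=runtime,
    )


def write_result(result: ExperimentResult, outdir: str | Path) -> dict[str, Path]:
    """Serialize an experiment: posterior/chain TSV plus a summary JSON.

    Returns the paths written, keyed by artifact name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    echo = {"spec": result.spec.to_dict(), "summary": result.summary}
    if result.posterior is not None:
        path = outdir / "posterior.tsv"
        result.posterior.to_frame().to_csv(path, sep="\t", index=False)
        paths["posterior"] = path
    if result.chain is not None:
        path = outdir / "chain.tsv"
        result.chain.to_frame().to_csv(path, sep="\t", index=False)
        paths["chain"] = path
    path = outdir / "summary.json"
    path.write_text(json.dumps(echo, indent=2, default=str) + "\n")
    paths["summary"] = path
    return paths
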
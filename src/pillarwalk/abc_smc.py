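"""Sequential Monte Carlo ABC with adaptive acceptance thresholds.

The sampler follows the standard SMC-ABC scheme: an initial generation is
accepted from the prior under a threshold calibrated as the median
distance of a pre-calibration sample; each later generation resamples the
previous particles by weight, perturbs them with a multivariate normal
kernel (covariance = 2x the weighted empirical covariance of the previous
population), rejects proposals outside the prior box, and accepts a
particle iff its simulated distance is at or below the current threshold.
The threshold of generation g is the median of the accepted distances of
generation g-1 (infinite distances excluded).  The run stops when the
acceptance rate falls below ``min_acceptance_rate`` or after
``max_generations`` generations.

Distance backends are pluggable: the weighted Wasserstein distance on
hand-crafted summaries, or an L1 distance on learned summary vectors
(inference-tailored or posterior-mean summaries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .params import BoxPrior
from .summaries import DistanceWeights, calibrated_distance, summarize
from .tracks import TrackSet

logger = logging.getLogger(__name__)


@dataclass
class AbcConfig:
    population_size: int = 1000
    max_generations: int = 15
    min_acceptance_rate: float = 0.01
    #: size of the pre-calibration sample used for the initial threshold
    precalibration_size: int | None = None
    #: hard cap on proposal attempts per generation (guards runaway runs)
    max_attempts_per_generation: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if not (0.0 < self.min_acceptance_rate < 1.0):
            raise ValueError("min_acceptance_rate must lie in (0, 1)")
        if self.precalibration_size is None:
            self.precalibration_size = self.population_size


@dataclass
class Population:
    """One accepted SMC-ABC generation."""

    particles: np.ndarray  # (n, dim)
    weights: np.ndarray  # normalized importance weights
    distances: np.ndarray
    epsilon: float
    acceptance_rate: float
    n_simulations: int

    def __post_init__(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be normalized")
        if (self.distances > self.epsilon + 1e-12).any():
            raise ValueError("accepted distances exceed epsilon")

    def effective_sample_size(self) -> float:
        return float(1.0 / np.sum(self.weights**2))

    def mean(self) -> np.ndarray:
        return self.weights @ self.particles

    def resample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(len(self.particles), size=n, p=self.weights)
        return self.particles[idx]

    def to_dataframe(self, names: Sequence[str]) -> pd.DataFrame:
        df = pd.DataFrame(self.particles, columns=list(names))
        df["weight"] = self.weights
        df["distance"] = self.distances
        return df


class DistanceBackend(Protocol):
    """Maps raw simulator output to a distance from the observed data."""

    def prepare(self, observed) -> None: ...

    def __call__(self, simulated) -> float: ...


class WassersteinBackend:
    """Weighted Wasserstein-1 distance on the hand-crafted summaries."""

    def __init__(self, weights: DistanceWeights, strict: bool = False):
        self.weights = weights
        self.strict = strict
        self._obs_table: pd.DataFrame | None = None

    def prepare(self, observed: TrackSet) -> None:
        self._obs_table = summarize(observed, strict=self.strict)
        if self._obs_table.empty:
            raise ValueError("observed data contain no summarizable tracks")

    def __call__(self, simulated: TrackSet) -> float:
        if self._obs_table is None:
            raise RuntimeError("backend not prepared with observed data")
        return calibrated_distance(
            summarize(simulated, strict=self.strict), self._obs_table, self.weights
        )


def l1_summary_distance(s_a: np.ndarray, s_b: np.ndarray) -> float:
    """L1 distance between two summary vectors of equal dimension."""
    s_a = np.asarray(s_a, dtype=float)
    s_b = np.asarray(s_b, dtype=float)
    if s_a.shape != s_b.shape:
        raise ValueError(f"summary dimensions differ: {s_a.shape} vs {s_b.shape}")
    return float(np.abs(s_a - s_b).sum())


class LearnedSummaryBackend:
    """L1 distance on a learned summary embedding of the raw data."""

    def __init__(self, embed: Callable[[object], np.ndarray]):
        self.embed = embed
        self._obs_summary: np.ndarray | None = None

    def prepare(self, observed) -> None:
        self._obs_summary = np.asarray(self.embed(observed), dtype=float)

    def __call__(self, simulated) -> float:
        if self._obs_summary is None:
            raise RuntimeError("backend not prepared with observed data")
        return l1_summary_distance(self.embed(simulated), self._obs_summary)


def adaptive_epsilon(previous: Population | np.ndarray) -> float:
    """Next-generation threshold: median of the previous accepted
    distances, infinite entries excluded."""
    distances = previous.distances if isinstance(previous, Population) else previous
    finite = np.asarray(distances, dtype=float)
    finite = finite[np.isfinite(finite)]
    if finite.size == 0:
        raise ValueError("all distances are infinite; cannot set epsilon")
    return float(np.median(finite))


def run_abc(
    observed,
    simulator: Callable[[np.ndarray, int], object],
    distance_backend: DistanceBackend,
    prior: BoxPrior,
    config: AbcConfig,
    rng: np.random.Generator,
) -> list[Population]:
    """Run SMC-ABC and return the accepted populations, last one final.

    ``simulator(phi, seed)`` must return the raw simulator output consumed
    by the distance backend; per-particle seeds are derived from ``rng``.
    Simulator failures discard the particle and are logged.
    """
    distance_backend.prepare(observed)
    dim = prior.dim
    n_sims_total = 0

    def _simulate_distance(phi: np.ndarray) -> float:
        nonlocal n_sims_total
        seed = int(rng.integers(2**31 - 1))
        n_sims_total += 1
        try:
            return float(distance_backend(simulator(phi, seed)))
        except Exception:  # noqa: BLE001 - a failed particle is discarded
            logger.exception("simulation failed at phi=%s; particle discarded", phi)
            return float("inf")

    # pre-calibration round: prior sample fixes the initial threshold
    precal_phis = prior.sample(config.precalibration_size, rng)
    precal_d = np.array([_simulate_distance(p) for p in precal_phis])
    if not np.isfinite(precal_d).any():
        raise RuntimeError("pre-calibration produced only infinite distances")
    epsilon = adaptive_epsilon(precal_d)

    populations: list[Population] = []
    max_attempts = config.max_attempts_per_generation or int(
        np.ceil(config.population_size / config.min_acceptance_rate)
    )

    prev: Population | None = None
    for gen in range(config.max_generations):
        if prev is not None:
            epsilon = adaptive_epsilon(prev)
            cov = 2.0 * np.cov(prev.particles.T, aweights=prev.weights)
            cov = np.atleast_2d(cov) + 1e-12 * np.eye(dim)
            chol = np.linalg.cholesky(cov)
        accepted: list[np.ndarray] = []
        dists: list[float] = []
        attempts = 0
        while len(accepted) < config.population_size and attempts < max_attempts:
            attempts += 1
            if prev is None:
                phi = prior.sample(1, rng)[0]
            else:
                base = prev.resample(1, rng)[0]
                phi = base + chol @ rng.standard_normal(dim)
                if not prior.in_support(phi)[0]:
                    continue
            d = _simulate_distance(phi)
            if d <= epsilon:
                accepted.append(phi)
                dists.append(d)
        if not accepted:
            raise RuntimeError(f"generation {gen}: no particle accepted")
        particles = np.array(accepted)
        dist_arr = np.array(dists)
        if not np.isfinite(dist_arr).any():
            raise RuntimeError(f"generation {gen}: all accepted distances infinite")
        if prev is None:
            weights = np.full(len(particles), 1.0 / len(particles))
        else:
            weights = _importance_weights(particles, prev, chol, prior)
        rate = len(particles) / attempts
        pop = Population(particles, weights, dist_arr, epsilon, rate, n_sims_total)
        populations.append(pop)
        logger.info(
            "generation %d: eps=%.4g rate=%.3f ess=%.1f sims=%d",
            gen, epsilon, rate, pop.effective_sample_size(), n_sims_total,
        )
        if rate < config.min_acceptance_rate or len(particles) < config.population_size:
            break
        prev = pop
    return populations


def _importance_weights(
    particles: np.ndarray, prev: Population, chol: np.ndarray, prior: BoxPrior
) -> np.ndarray:
    """Standard SMC-ABC weights: prior density over the kernel mixture.

    With a uniform prior the numerator is constant inside the support, so
    the weight reduces to the inverse mixture density of the perturbation
    kernel centered at the previous particles.
    """
    dim = particles.shape[1]
    inv = np.linalg.inv(chol)
    log_norm = -0.5 * dim * np.log(2 * np.pi) - np.sum(np.log(np.diag(chol)))
    # (n_new, n_prev, dim) standardized residuals
    diff = particles[:, None, :] - prev.particles[None, :, :]
    z = np.einsum("ij,nkj->nki", inv, diff)
    logk = log_norm - 0.5 * np.sum(z**2, axis=2)
    mix = np.einsum("k,nk->n", prev.weights, np.exp(logk - logk.max(axis=1, keepdims=True)))
    log_mix = np.log(mix) + logk.max(axis=1)
    w = np.exp(prior.logpdf(particles) - log_mix)
    return w / w.sum()
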
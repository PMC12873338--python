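"""Model parameters and the log10-uniform prior of the migration model.

Four parameters are inferred, all on the log10 scale:

* ``m_dir``  -- chemotactic attraction strength,
* ``m_rand`` -- intrinsic persistent-motion strength,
* ``lambda`` -- rate (1/s) of the exponential waiting time between
  direction changes of the persistent random walk,
* ``a``      -- target cell area (um^2).

The remaining Potts constants (adhesion coefficient J, volume-constraint
strength lambda_v, fluctuation temperature T) are fixed model constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

PARAM_NAMES = ("log10_m_dir", "log10_m_rand", "log10_lambda", "log10_a")
PRIOR_LOW = np.array([0.0, 0.0, -4.0, 0.0])
PRIOR_HIGH = np.array([4.0, 2.0, 1.5, 2.5])
N_PARAMS = 4


@dataclass
class FixedConstants:
    """Potts constants that are not inferred."""

    J_cell_cell: float = 4.0
    J_cell_medium: float = 4.0
    #: strong enough to keep volumes bounded against the persistence drive,
    #: whose magnitude reaches m_rand * v_c ~ 2400 at the top of the prior
    lambda_v: float = 50.0
    temperature: float = 10.0
    #: the chemotaxis energy uses the field in units of ``field_unit`` um^-2
    field_unit: float = 1.0e6


@dataclass
class ModelParameters:
    """Inferred parameters (log10 scale) plus the fixed Potts constants."""

    log10_m_dir: float
    log10_m_rand: float
    log10_lambda: float
    log10_a: float
    fixed: FixedConstants = field(default_factory=FixedConstants)

    # linear-scale views -------------------------------------------------
    @property
    def m_dir(self) -> float:
        return 10.0**self.log10_m_dir

    @property
    def m_rand(self) -> float:
        return 10.0**self.log10_m_rand

    @property
    def lambda_rate(self) -> float:
        """Direction-switch rate in 1/s."""
        return 10.0**self.log10_lambda

    @property
    def target_area_um2(self) -> float:
        return 10.0**self.log10_a

    def target_area_nodes(self, resolution: float) -> int:
        """Target area converted to lattice nodes (>= 1)."""
        return max(int(round(self.target_area_um2 / resolution**2)), 1)

    # vector interface ---------------------------------------------------
    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.log10_m_dir, self.log10_m_rand, self.log10_lambda, self.log10_a]
        )

    @classmethod
    def from_vector(
        cls, phi: np.ndarray, fixed: FixedConstants | None = None
    ) -> "ModelParameters":
        phi = np.asarray(phi, dtype=float)
        if phi.shape != (N_PARAMS,):
            raise ValueError(f"expected a length-{N_PARAMS} vector, got {phi.shape}")
        return cls(*phi, fixed=fixed or FixedConstants())

    def with_overrides(self, **kwargs: float) -> "ModelParameters":
        return replace(self, **kwargs)


class BoxPrior:
    """Independent uniform prior on a box (used on the log10 scale)."""

    def __init__(self, low: np.ndarray = PRIOR_LOW, high: np.ndarray = PRIOR_HIGH):
        self.low = np.asarray(low, dtype=float)
        self.high = np.asarray(high, dtype=float)
        if self.low.shape != self.high.shape or (self.low >= self.high).any():
            raise ValueError("invalid prior box")

    @property
    def dim(self) -> int:
        return self.low.size

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=(n, self.dim))

    def in_support(self, phi: np.ndarray) -> np.ndarray:
        phi = np.atleast_2d(phi)
        return np.all((phi >= self.low) & (phi <= self.high), axis=1)

    def logpdf(self, phi: np.ndarray) -> np.ndarray:
        const = -np.sum(np.log(self.high - self.low))
        inside = self.in_support(phi)
        return np.where(inside, const, -np.inf)


DEFAULT_PRIOR = BoxPrior()


def sample_prior(
    n: int, rng: np.random.Generator, fixed: FixedConstants | None = None
) -> list[ModelParameters]:
    """Draw ``n`` parameter sets from the log10-uniform prior box."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    draws = DEFAULT_PRIOR.sample(n, rng)
    return [ModelParameters.from_vector(phi, fixed=fixed) for phi in draws]
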
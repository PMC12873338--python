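"""Static chemokine field with an optional temporal pulse.

The gradient is a time-independent 2D Gaussian centered at the chemokine
hole (peak 7e6 um^-2, sigma 550 um by default).  A pulsed profile switches
the field off after ``t_off`` seconds, emulating a transient chemokine
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry

DEFAULT_PEAK = 7.0e6  # um^-2
DEFAULT_SIGMA_UM = 550.0


@dataclass
class ChemokineField:
    """Per-node chemoattractant concentration (um^-2) and time profile.

    ``t_off = None`` means a constant field; otherwise the field is active
    only for ``t < t_off`` seconds (indicator time profile).
    """

    values: np.ndarray
    t_off: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < 0).any():
            raise ValueError("chemokine concentrations must be non-negative")

    def factor(self, t_seconds: float) -> float:
        """Temporal activity indicator at simulation time ``t_seconds``."""
        if self.t_off is None:
            return 1.0
        return 1.0 if t_seconds < self.t_off else 0.0

    def with_pulse(self, t_off: float) -> "ChemokineField":
        return ChemokineField(self.values, t_off=t_off)

    def zeroed(self) -> "ChemokineField":
        """No-chemokine control field of the same shape."""
        return ChemokineField(np.zeros_like(self.values), self.t_off)


def gaussian_gradient(
    geometry: Geometry,
    peak: float = DEFAULT_PEAK,
    sigma_um: float = DEFAULT_SIGMA_UM,
    center: tuple[float, float] | None = None,
) -> ChemokineField:
    """Gaussian concentration profile ``peak * exp(-r^2 / (2 sigma^2))``.

    ``center`` is given in physical um coordinates ``(x, y)``; by default it
    is the center of the geometry's target region (the chemokine hole).
    """
    if peak <= 0:
        raise ValueError("peak concentration must be positive")
    if sigma_um <= 0:
        raise ValueError("sigma must be positive")
    h, w = geometry.shape
    res = geometry.resolution
    if center is None:
        ccol, crow = geometry.target_region.center
        center = (ccol * res, crow * res)
    cx, cy = center
    if not (0 <= cx <= w * res and 0 <= cy <= h * res):
        raise ValueError(f"gradient center {center} lies outside the raster")
    x, y = geometry.node_centers_um()
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    return ChemokineField(peak * np.exp(-r2 / (2.0 * sigma_um**2)))
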
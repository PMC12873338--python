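"""Hand-crafted per-cell trajectory summaries and the weighted
Wasserstein-1 distance used by classical ABC.

Four per-cell statistics describe a track X_1..X_T observed at the fixed
interval dt:

* displacement  D = |X_T - X_1| / sqrt(T)            (um per sqrt(step))
* velocity      V = mean step speed                   (um/s)
* turning angle TA = mean signed heading change       (radians)
* angle degree  AD = mean heading theta = atan2(dx, dy), i.e. the angle
  from the +y axis, which points up the chemokine gradient (radians)

Headings of zero-length steps are undefined and are skipped (with their
term count).  Heading differences in TA are wrapped into (-pi, pi].
The means are normalized by the number of summed terms; ``strict=True``
reproduces the as-printed normalizers (T-2 for V and AD, T-3 for TA),
which are off by one relative to the number of terms in the sums.

Distributions of each statistic over the cells of a dataset are compared
with the Wasserstein-1 distance, each statistic weighted by the inverse
range observed in a pre-calibration population, and the four weighted
distances are summed.  An empty simulated table has distance +inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance

from .tracks import Track, TrackSet

STAT_NAMES = ("D", "V", "TA", "AD")


class UndefinedStatisticError(ValueError):
    """Raised when a track is too short (or degenerate) for a statistic."""


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    w = (a + np.pi) % (2.0 * np.pi) - np.pi
    return np.where(np.isclose(w, -np.pi), np.pi, w)


def _headings(track: Track) -> np.ndarray:
    """Step headings theta_i = atan2(dx, dy) (angle from the +y axis),
    with zero-length steps dropped."""
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    moved = (dx != 0) | (dy != 0)
    return np.arctan2(dx[moved], dy[moved])


def displacement(track: Track) -> float:
    """Net displacement normalized by sqrt(track length)."""
    T = len(track)
    if T < 2:
        raise UndefinedStatisticError("displacement needs at least 2 points")
    d = math.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0])
    return d / math.sqrt(T)


def velocity(track: Track, dt: float = 30.0, strict: bool = False) -> float:
    """Mean step speed in um/s."""
    T = len(track)
    min_T = 3 if strict else 2
    if T < min_T:
        raise UndefinedStatisticError("velocity needs a longer track")
    steps = np.hypot(np.diff(track.x), np.diff(track.y)) / dt
    denom = (T - 2) if strict else len(steps)
    return float(steps.sum() / denom)


def turning_angle(track: Track, strict: bool = False) -> float:
    """Mean signed heading change between consecutive steps, each
    difference wrapped into (-pi, pi]."""
    T = len(track)
    if T < 3:
        raise UndefinedStatisticError("turning angle needs at least 3 points")
    theta = _headings(track)
    if len(theta) < 2:
        raise UndefinedStatisticError("turning angle undefined for a degenerate track")
    diffs = _wrap_angle(np.diff(theta))
    denom = (T - 3) if strict else len(diffs)
    if denom <= 0:
        raise UndefinedStatisticError("turning angle normalizer is empty")
    return float(diffs.sum() / denom)


def angle_degree(track: Track, strict: bool = False) -> float:
    """Mean heading relative to the gradient direction (+y axis)."""
    T = len(track)
    min_T = 3 if strict else 2
    if T < min_T:
        raise UndefinedStatisticError("angle degree needs a longer track")
    theta = _headings(track)
    if len(theta) == 0:
        raise UndefinedStatisticError("angle degree undefined for a stationary track")
    denom = (T - 2) if strict else len(theta)
    return float(theta.sum() / denom)


def summarize(trackset: TrackSet, strict: bool = False) -> pd.DataFrame:
    """Per-cell summary table with columns cell_id, D, V, TA, AD.

    Tracks too short (or too degenerate) for a statistic get NaN in that
    column; each statistic's empirical distribution is the column with
    NaNs dropped.  An empty track set yields an empty table.
    """
    rows = []
    for tr in trackset:
        row: dict[str, float] = {"cell_id": tr.cell_id}
        for name, fn in (
            ("D", lambda t: displacement(t)),
            ("V", lambda t: velocity(t, trackset.dt_obs, strict)),
            ("TA", lambda t: turning_angle(t, strict)),
            ("AD", lambda t: angle_degree(t, strict)),
        ):
            try:
                row[name] = fn(tr)
            except UndefinedStatisticError:
                row[name] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["cell_id", *STAT_NAMES])


@dataclass(frozen=True)
class DistanceWeights:
    """Inverse-range weights of the four statistics, from a
    pre-calibration population."""

    w_D: float
    w_V: float
    w_TA: float
    w_AD: float

    def as_dict(self) -> dict[str, float]:
        return {"D": self.w_D, "V": self.w_V, "TA": self.w_TA, "AD": self.w_AD}


def wasserstein1(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Wasserstein-1 distance between two 1D empirical distributions."""
    sample_a = np.asarray(sample_a, dtype=float)
    sample_b = np.asarray(sample_b, dtype=float)
    if sample_a.size == 0 or sample_b.size == 0:
        return float("inf")
    return float(wasserstein_distance(sample_a, sample_b))


def calibrate_weights(precal_tables: list[pd.DataFrame]) -> DistanceWeights:
    """Weights 1/(max - min) per statistic, pooled over all cells of all
    pre-calibration simulations."""
    if not precal_tables:
        raise ValueError("need at least one pre-calibration table")
    pooled = pd.concat(precal_tables, ignore_index=True)
    weights = {}
    for name in STAT_NAMES:
        vals = pooled[name].dropna().to_numpy()
        if vals.size < 2:
            raise ValueError(f"statistic {name} has fewer than 2 values")
        rng = float(vals.max() - vals.min())
        if rng <= 0:
            raise ValueError(f"statistic {name} has zero range; weight undefined")
        weights[name] = 1.0 / rng
    return DistanceWeights(weights["D"], weights["V"], weights["TA"], weights["AD"])


def calibrated_distance(
    sim_table: pd.DataFrame, obs_table: pd.DataFrame, weights: DistanceWeights
) -> float:
    """Sum of weighted per-statistic Wasserstein-1 distances.

    A simulation with no observed cells is maximally discrepant: +inf.
    """
    if len(obs_table) == 0:
        raise ValueError("observed summary table is empty")
    if len(sim_table) == 0:
        return float("inf")
    total = 0.0
    for name, w in weights.as_dict().items():
        a = sim_table[name].dropna().to_numpy()
        b = obs_table[name].dropna().to_numpy()
        total += w * wasserstein1(a, b)
    return float(total)
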
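"""Extended 2D Cellular Potts model of chemotactic, persistent migration.

Cells are connected-ish domains of lattice sites evolving by Metropolis
copy attempts.  The effective energy combines four terms:

* adhesion: ``sum_<i,j> J_(sigma_i, sigma_j) (1 - delta)`` over neighbor
  pairs, penalizing cell-cell and cell-medium interfaces;
* volume: ``lambda_v sum_c (v_c - a)^2`` soft area constraint;
* chemotaxis: ``m_dir (f_source - f_target)``, favoring boundary advances
  up the chemokine gradient;
* persistence: ``-m_rand v_c <(cos a, sin a), s>``, a run-and-tumble bias
  toward a preferred angle that is resampled uniformly after exponential
  waiting times with rate ``lambda``.

A copy attempt is accepted with probability ``min(1, exp(-dH / T))``;
attempts onto pillar nodes are rejected unconditionally.  One Monte Carlo
step (MCS, one sweep of as many attempts as lattice sites) corresponds to
one second of simulated time by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .chemokine import ChemokineField
from .geometry import Geometry
from .params import ModelParameters
from .tracks import Track, TrackSet

__all__ = [
    "LatticeState",
    "ProposedMove",
    "SimulationConfig",
    "delta_adhesion",
    "delta_volume",
    "delta_chemotaxis",
    "delta_persistence",
    "metropolis_step",
    "update_direction",
    "simulate",
    "initialize_state",
]


def neighborhood_offsets(name: str = "moore") -> np.ndarray:
    if name == "moore":
        return _kernels.MOORE
    if name == "von_neumann":
        return _kernels.VON_NEUMANN
    raise ValueError(f"unknown neighborhood {name!r}")


def _unit_displacements(neigh: np.ndarray) -> np.ndarray:
    """Unit displacement (x, y) from source j to target i per offset.

    ``neigh[k]`` maps the target site i to its neighbor j, so the copy
    displacement is the negated offset, in (col, row) = (x, y) order.
    """
    s = np.empty((neigh.shape[0], 2))
    for k, (dr, dc) in enumerate(neigh):
        n = float(np.hypot(dr, dc))
        s[k] = (-dc / n, -dr / n)
    return s


@dataclass
class ProposedMove:
    """A copy attempt sigma(j) -> sigma(i) between neighboring sites."""

    source: tuple[int, int]  # (row, col) of j
    target: tuple[int, int]  # (row, col) of i
    source_id: int
    target_id: int

    @property
    def displacement(self) -> np.ndarray:
        """Unit vector from source to target in (x, y) order."""
        dr = self.target[0] - self.source[0]
        dc = self.target[1] - self.source[1]
        n = float(np.hypot(dr, dc))
        if n == 0:
            raise ValueError("source and target coincide")
        return np.array([dc / n, dr / n])


@dataclass
class LatticeState:
    """Discrete CPM world state with per-cell bookkeeping.

    Per-cell arrays are indexed by cell id (1..n_cells); slot 0 is unused.
    ``sum_row``/``sum_col`` hold the running sums of occupied site indices
    so centroids are available in O(1).
    """

    grid: np.ndarray  # int32 (H, W); 0 = medium
    volumes: np.ndarray  # float64 (n+1,)
    sum_row: np.ndarray
    sum_col: np.ndarray
    alpha: np.ndarray  # preferred angle, radians in [0, 2pi)
    next_switch: np.ndarray  # absolute time (s) of the next angle resampling
    sim_time: float = 0.0

    @property
    def n_cells(self) -> int:
        return len(self.volumes) - 1

    def cell_ids(self) -> np.ndarray:
        return np.arange(1, self.n_cells + 1)

    def centroid_nodes(self, cell_id: int) -> tuple[float, float]:
        """Centroid in fractional node coordinates (col, row)."""
        v = self.volumes[cell_id]
        if v <= 0:
            raise ValueError(f"cell {cell_id} has no sites")
        return (self.sum_col[cell_id] / v, self.sum_row[cell_id] / v)

    def centroid_um(self, cell_id: int, resolution: float) -> tuple[float, float]:
        c, r = self.centroid_nodes(cell_id)
        return ((c + 0.5) * resolution, (r + 0.5) * resolution)

    def check_consistency(self, geometry: Geometry | None = None) -> None:
        """Verify the bookkeeping invariants (volumes, centroids, obstacles)."""
        for cid in self.cell_ids():
            sites = np.argwhere(self.grid == cid)
            if len(sites) != self.volumes[cid]:
                raise AssertionError(f"volume bookkeeping broken for cell {cid}")
            if len(sites):
                if not np.isclose(sites[:, 0].sum(), self.sum_row[cid]):
                    raise AssertionError(f"row sum broken for cell {cid}")
                if not np.isclose(sites[:, 1].sum(), self.sum_col[cid]):
                    raise AssertionError(f"col sum broken for cell {cid}")
        if geometry is not None and (self.grid[geometry.obstacle_mask] != 0).any():
            raise AssertionError("cell occupies an obstacle node")

    def copy(self) -> "LatticeState":
        return LatticeState(
            self.grid.copy(),
            self.volumes.copy(),
            self.sum_row.copy(),
            self.sum_col.copy(),
            self.alpha.copy(),
            self.next_switch.copy(),
            self.sim_time,
        )


# ---------------------------------------------------------------------------
# energy terms (thin wrappers over the shared numba kernels)
# ---------------------------------------------------------------------------
def delta_adhesion(
    state: LatticeState,
    move: ProposedMove,
    j_cell_cell: float,
    j_cell_medium: float | None = None,
    obstacle: np.ndarray | None = None,
    neighborhood: str = "moore",
) -> float:
    """Adhesion-term change of the interface sum if the copy were applied."""
    if j_cell_medium is None:
        j_cell_medium = j_cell_cell
    if obstacle is None:
        obstacle = np.zeros(state.grid.shape, dtype=bool)
    ri, ci = move.target
    return float(
        _kernels.delta_adhesion_raw(
            state.grid, obstacle, ri, ci, move.source_id,
            neighborhood_offsets(neighborhood), j_cell_cell, j_cell_medium,
        )
    )


def delta_volume(
    state: LatticeState, move: ProposedMove, lambda_v: float, a_nodes: int
) -> float:
    """Volume-constraint change: the target cell shrinks, the source grows."""
    if a_nodes <= 0:
        raise ValueError("target area in nodes must be positive")
    vt = state.volumes[move.target_id] if move.target_id > 0 else -1.0
    vs = state.volumes[move.source_id] if move.source_id > 0 else -1.0
    return float(_kernels.delta_volume_raw(vt, vs, lambda_v, a_nodes))


def delta_chemotaxis(field: ChemokineField, move: ProposedMove, m_dir: float) -> float:
    """Chemotaxis change ``m_dir (f_source - f_target)``; negative
    (favored) when the boundary advances toward higher concentration."""
    f = field.values
    return float(
        _kernels.delta_chemotaxis_raw(f[move.source], f[move.target], m_dir)
    )


def delta_persistence(state: LatticeState, move: ProposedMove, m_rand: float) -> float:
    """Persistent-motion change for the cell(s) whose domain changes."""
    sx, sy = move.displacement
    cos_a = np.cos(state.alpha)
    sin_a = np.sin(state.alpha)
    return float(
        _kernels.delta_persistence_raw(
            move.source_id, move.target_id, state.volumes, cos_a, sin_a, m_rand, sx, sy
        )
    )


def total_delta(
    state: LatticeState,
    move: ProposedMove,
    params: ModelParameters,
    field: ChemokineField,
    geometry: Geometry,
    neighborhood: str = "moore",
) -> float:
    """Total energy change of a move (adhesion + volume + chemotaxis +
    persistence), with the chemotaxis term on the model's field scale."""
    fx = params.fixed
    a_nodes = params.target_area_nodes(geometry.resolution)
    scaled = ChemokineField(
        field.values / fx.field_unit * field.factor(state.sim_time), t_off=None
    )
    return (
        delta_adhesion(
            state, move, fx.J_cell_cell, fx.J_cell_medium,
            geometry.obstacle_mask, neighborhood,
        )
        + delta_volume(state, move, fx.lambda_v, a_nodes)
        + delta_chemotaxis(scaled, move, params.m_dir)
        + delta_persistence(state, move, params.m_rand)
    )


# ---------------------------------------------------------------------------
# single-step dynamics (inspectable; the fast path lives in _kernels)
# ---------------------------------------------------------------------------
def metropolis_step(
    state: LatticeState,
    params: ModelParameters,
    field: ChemokineField,
    geometry: Geometry,
    rng: np.random.Generator,
    neighborhood: str = "moore",
) -> tuple[bool, ProposedMove | None]:
    """One copy attempt: pick a random site and neighbor, evaluate the
    energy change, accept with ``min(1, exp(-dH/T))`` and update the state
    in place.  Attempts involving pillar nodes are rejected."""
    h, w = state.grid.shape
    neigh = neighborhood_offsets(neighborhood)
    idx = int(rng.integers(h * w))
    ri, ci = divmod(idx, w)
    k = int(rng.integers(len(neigh)))
    rj, cj = ri + int(neigh[k, 0]), ci + int(neigh[k, 1])
    if not (0 <= rj < h and 0 <= cj < w):
        return False, None
    if geometry.obstacle_mask[ri, ci] or geometry.obstacle_mask[rj, cj]:
        return False, None
    move = ProposedMove(
        (rj, cj), (ri, ci), int(state.grid[rj, cj]), int(state.grid[ri, ci])
    )
    if move.source_id == move.target_id:
        return False, move
    if move.target_id > 0 and state.volumes[move.target_id] <= 1:
        return False, move  # annihilation moves are rejected (no cell death)
    d = total_delta(state, move, params, field, geometry, neighborhood)
    if d > 0 and rng.random() >= np.exp(-d / params.fixed.temperature):
        return False, move
    _apply_move(state, move)
    return True, move


def _apply_move(state: LatticeState, move: ProposedMove) -> None:
    ri, ci = move.target
    state.grid[ri, ci] = move.source_id
    if move.target_id > 0:
        state.volumes[move.target_id] -= 1
        state.sum_row[move.target_id] -= ri
        state.sum_col[move.target_id] -= ci
    if move.source_id > 0:
        state.volumes[move.source_id] += 1
        state.sum_row[move.source_id] += ri
        state.sum_col[move.source_id] += ci


def update_direction(
    alpha: float,
    next_switch: float,
    lambda_rate: float,
    now: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Waiting-time direction process for one cell.

    If ``now`` has reached the scheduled switch time, resample the
    preferred angle uniformly on [0, 2pi) and draw the next exponential
    waiting time with rate ``lambda_rate``; otherwise return unchanged.
    """
    if lambda_rate <= 0:
        raise ValueError("lambda_rate must be positive")
    while next_switch <= now:
        alpha = rng.uniform(0.0, 2.0 * np.pi)
        next_switch += rng.exponential(1.0 / lambda_rate)
    return alpha, next_switch


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------
@dataclass
class SimulationConfig:
    """Run-length and observation settings of a forward simulation."""

    n_cells: int = 20
    total_time_s: float = 1800.0
    dt_obs_s: float = 30.0
    mcs_per_second: float = 1.0
    burn_in_mcs: int = 100
    neighborhood: str = "moore"
    #: observe the whole arena instead of only the visible window
    record_full_arena: bool = False

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        if self.dt_obs_s <= 0 or self.total_time_s < 0:
            raise ValueError("invalid timing settings")
        mcs = self.dt_obs_s * self.mcs_per_second
        if abs(mcs - round(mcs)) > 1e-9:
            raise ValueError("dt_obs must map to an integer number of MCS")

    def to_yaml(self, path) -> None:
        import yaml
        from dataclasses import asdict

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def initialize_state(
    params: ModelParameters,
    geometry: Geometry,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> LatticeState:
    """Seed single-node cells uniformly in the entry region (no overlap)
    and initialize the direction process at t = 0."""
    h, w = geometry.shape
    grid = np.zeros((h, w), dtype=np.int32)
    entry = geometry.entry_region
    free = np.argwhere(~geometry.obstacle_mask[entry.row0 : entry.row1,
                                               entry.col0 : entry.col1])
    if len(free) < config.n_cells:
        raise ValueError("entry region too small to seed all cells")
    pick = rng.choice(len(free), size=config.n_cells, replace=False)
    n = config.n_cells
    volumes = np.zeros(n + 1)
    sum_row = np.zeros(n + 1)
    sum_col = np.zeros(n + 1)
    for cid, sel in enumerate(pick, start=1):
        r = int(free[sel][0]) + entry.row0
        c = int(free[sel][1]) + entry.col0
        grid[r, c] = cid
        volumes[cid] = 1
        sum_row[cid] = r
        sum_col[cid] = c
    alpha = rng.uniform(0.0, 2.0 * np.pi, size=n + 1)
    lam = params.lambda_rate
    next_switch = rng.exponential(1.0 / lam, size=n + 1)
    return LatticeState(grid, volumes, sum_row, sum_col, alpha, next_switch, 0.0)


def _run_chunk(
    state: LatticeState,
    params: ModelParameters,
    field: ChemokineField,
    geometry: Geometry,
    config: SimulationConfig,
    n_mcs: int,
    t0: float,
    motility: bool = True,
) -> float:
    fx = params.fixed
    neigh = neighborhood_offsets(config.neighborhood)
    s_unit = _unit_displacements(neigh)
    cos_a = np.cos(state.alpha)
    sin_a = np.sin(state.alpha)
    t_off = -1.0 if field.t_off is None else float(field.t_off)
    t = _kernels.run_mcs_chunk(
        state.grid,
        geometry.obstacle_mask,
        field.values / fx.field_unit,
        state.volumes,
        state.sum_row,
        state.sum_col,
        cos_a,
        sin_a,
        state.alpha,
        state.next_switch,
        t0,
        n_mcs,
        1.0 / config.mcs_per_second,
        params.lambda_rate,
        t_off,
        neigh,
        s_unit,
        fx.J_cell_cell,
        fx.J_cell_medium,
        fx.lambda_v,
        float(params.target_area_nodes(geometry.resolution)),
        params.m_dir if motility else 0.0,
        params.m_rand if motility else 0.0,
        fx.temperature,
    )
    state.sim_time = t
    return t


def simulate(
    params: ModelParameters,
    geometry: Geometry,
    field: ChemokineField,
    config: SimulationConfig,
    seed: int,
) -> TrackSet:
    """Run the Metropolis loop and emit observed centroid trajectories.

    Cells are seeded in the entry region, grown during a burn-in of
    ``config.burn_in_mcs`` MCS (observation clock starts afterwards at
    t = 0) and observed every ``dt_obs_s`` seconds.  A sample is retained
    iff the centroid lies in the visible window (or anywhere in the arena
    with ``record_full_arena``); each maximal contiguous retained run
    becomes one track with times re-zeroed to its first observation.
    Cells never retained contribute no track.  Deterministic given `seed`.
    """
    rng = np.random.default_rng(seed)
    state = initialize_state(params, geometry, config, rng)
    _kernels._seed(int(rng.integers(2**31 - 1)))

    # burn-in: grow seeds toward the target area before t = 0, with the
    # motility terms off so growth is governed by volume + adhesion alone
    if config.burn_in_mcs > 0:
        _run_chunk(state, params, field, geometry, config,
                   config.burn_in_mcs, -config.burn_in_mcs / config.mcs_per_second,
                   motility=False)
    state.sim_time = 0.0
    state.next_switch = np.maximum(state.next_switch, 0.0)

    n_frames = int(np.floor(config.total_time_s / config.dt_obs_s + 1e-9)) + 1
    mcs_per_obs = int(round(config.dt_obs_s * config.mcs_per_second))
    n = config.n_cells
    pos = np.full((n_frames, n, 2), np.nan)  # (x_um, y_um)
    alive = np.zeros((n_frames, n), dtype=bool)
    res = geometry.resolution
    t = 0.0
    for frame in range(n_frames):
        for cid in range(1, n + 1):
            if state.volumes[cid] > 0:
                x, y = state.centroid_um(cid, res)
                pos[frame, cid - 1] = (x, y)
                alive[frame, cid - 1] = True
        if frame < n_frames - 1:
            t = _run_chunk(state, params, field, geometry, config, mcs_per_obs, t)

    window = None if config.record_full_arena else geometry.visible_window
    return _extract_tracks(pos, alive, window, res, config.dt_obs_s)


def _extract_tracks(
    pos: np.ndarray,
    alive: np.ndarray,
    window,
    resolution: float,
    dt_obs: float,
) -> TrackSet:
    n_frames, n_cells, _ = pos.shape
    tracks: list[Track] = []
    track_id = 0
    for c in range(n_cells):
        if window is None:
            keep = alive[:, c]
        else:
            keep = np.array(
                [
                    alive[f, c]
                    and window.contains_xy(pos[f, c, 0], pos[f, c, 1], resolution)
                    for f in range(n_frames)
                ]
            )
        # maximal contiguous retained runs; re-entries start a new track
        f = 0
        while f < n_frames:
            if not keep[f]:
                f += 1
                continue
            g = f
            while g < n_frames and keep[g]:
                g += 1
            track_id += 1
            ts = (np.arange(f, g) - f) * dt_obs
            tracks.append(Track(track_id, ts, pos[f:g, c, 0].copy(), pos[f:g, c, 1].copy()))
            f = g
    return TrackSet(tracks, dt_obs=dt_obs)
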
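"""Independent brute-force oracles shared by the unit and acceptance
tests.  These deliberately re-derive quantities from first principles
(full-lattice recounts, elementwise sums) rather than reusing the package
implementations they check."""

from __future__ import annotations

import numpy as np

from pillarwalk.cpm import LatticeState, ProposedMove

MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def make_state(grid: np.ndarray, alpha=None) -> LatticeState:
    grid = np.asarray(grid, dtype=np.int32)
    n = int(grid.max())
    volumes = np.zeros(n + 1)
    sum_row = np.zeros(n + 1)
    sum_col = np.zeros(n + 1)
    for cid in range(1, n + 1):
        sites = np.argwhere(grid == cid)
        volumes[cid] = len(sites)
        if len(sites):
            sum_row[cid] = sites[:, 0].sum()
            sum_col[cid] = sites[:, 1].sum()
    if alpha is None:
        alpha = np.zeros(n + 1)
    return LatticeState(grid, volumes, sum_row, sum_col,
                        np.asarray(alpha, float), np.full(n + 1, np.inf), 0.0)


def full_hamiltonian(grid, j_cc, j_cm, lambda_v, a_nodes) -> float:
    """Brute-force adhesion + volume energy of the whole lattice.

    Each unordered neighbor pair is counted once; sites beyond the raster
    count as medium, matching a medium-filled boundary.
    """
    h, w = grid.shape

    def sigma(r, c):
        if 0 <= r < h and 0 <= c < w:
            return int(grid[r, c])
        return 0

    def j(a, b):
        if a == b:
            return 0.0
        return j_cm if (a == 0 or b == 0) else j_cc

    adhesion = 0.0
    for r in range(-1, h + 1):
        for c in range(-1, w + 1):
            for dr, dc in MOORE:
                r2, c2 = r + dr, c + dc
                if (r2, c2) > (r, c):  # count each unordered pair once
                    adhesion += j(sigma(r, c), sigma(r2, c2))
    volume = 0.0
    for cid in range(1, int(grid.max()) + 1):
        volume += lambda_v * ((grid == cid).sum() - a_nodes) ** 2
    return adhesion + volume


def random_state(rng, shape=(10, 10), n_cells=3) -> LatticeState:
    grid = rng.integers(0, n_cells + 1, size=shape).astype(np.int32)
    alpha = rng.uniform(0, 2 * np.pi, n_cells + 1)
    return make_state(grid, alpha)


def random_move(state, rng) -> ProposedMove:
    h, w = state.grid.shape
    while True:
        ri, ci = int(rng.integers(h)), int(rng.integers(w))
        dr, dc = MOORE[int(rng.integers(8))]
        rj, cj = ri + dr, ci + dc
        if not (0 <= rj < h and 0 <= cj < w):
            continue
        if state.grid[ri, ci] == state.grid[rj, cj]:
            continue
        return ProposedMove((rj, cj), (ri, ci), int(state.grid[rj, cj]),
                            int(state.grid[ri, ci]))


def apply_move(grid, move):
    out = grid.copy()
    out[move.target] = move.source_id
    return out


def brute_force_nrmse(true, samples) -> np.ndarray:
    """Independent re-implementation of the recovery error metric."""
    n, L, p = samples.shape
    out = np.empty(p)
    for j in range(p):
        rmses = [
            np.sqrt(np.mean((true[:, j] - samples[:, l, j]) ** 2))
            for l in range(L)
        ]
        out[j] = np.median(rmses) / (true[:, j].max() - true[:, j].min())
    return out
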
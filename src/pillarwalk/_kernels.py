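"""Numba kernels for the Cellular Potts Metropolis dynamics.

All energy terms are implemented here once, as scalar functions on raw
arrays; the Python-level API in :mod:`pillarwalk.cpm` wraps the same
functions so that the fast simulation loop and the inspectable single-step
interface share one definition of the physics.

Grid encoding: ``grid[row, col]`` holds 0 for medium and positive integers
for cell ids.  Obstacles live in a separate boolean mask and never carry a
cell id.  Out-of-raster sites and obstacle sites count as medium in the
adhesion sum.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Moore neighborhood offsets (row, col)
MOORE = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)
VON_NEUMANN = np.array([(-1, 0), (0, -1), (0, 1), (1, 0)], dtype=np.int64)


@njit(cache=False)
def _seed(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=False)
def _pair_j(a, b, j_cc, j_cm):
    """Adhesion coefficient of the (a, b) interface; 0 for identical ids."""
    if a == b:
        return 0.0
    if a == 0 or b == 0:
        return j_cm
    return j_cc


@njit(cache=False)
def delta_adhesion_raw(grid, obstacle, ri, ci, new_id, neigh, j_cc, j_cm):
    """Adhesion energy change if site (ri, ci) switched to ``new_id``.

    Only pairs involving the target site change, so the local sum over its
    neighborhood equals the full-lattice interface-sum difference.
    """
    h, w = grid.shape
    old_id = grid[ri, ci]
    d = 0.0
    for k in range(neigh.shape[0]):
        r = ri + neigh[k, 0]
        c = ci + neigh[k, 1]
        if r < 0 or r >= h or c < 0 or c >= w or obstacle[r, c]:
            nb = 0  # boundary and pillars behave as medium
        else:
            nb = grid[r, c]
        d += _pair_j(new_id, nb, j_cc, j_cm) - _pair_j(old_id, nb, j_cc, j_cm)
    return d


@njit(cache=False)
def delta_volume_raw(vol_target_cell, vol_source_cell, lambda_v, a_nodes):
    """Volume energy change: target cell loses one site, source gains one.

    Either id may be 0 (medium) in which case a volume of -1 is passed and
    that side contributes nothing.
    """
    d = 0.0
    if vol_target_cell >= 0:
        v = vol_target_cell
        d += lambda_v * ((v - 1.0 - a_nodes) ** 2 - (v - a_nodes) ** 2)
    if vol_source_cell >= 0:
        v = vol_source_cell
        d += lambda_v * ((v + 1.0 - a_nodes) ** 2 - (v - a_nodes) ** 2)
    return d


@njit(cache=False)
def delta_chemotaxis_raw(f_source, f_target, m_dir):
    """Chemotaxis energy change; negative when the boundary advances
    toward higher concentration (up-gradient moves are favored)."""
    return m_dir * (f_source - f_target)


@njit(cache=False)
def delta_persistence_raw(
    source_id, target_id, vols, cos_a, sin_a, m_rand, sx, sy
):
    """Persistence energy for the cells whose domain changes.

    ``(sx, sy)`` is the unit displacement from the source to the target
    site; when the boundary advances along s both the expanding and the
    retracting cell centroids move along +s, so each involved cell
    contributes ``-m_rand * v_c * <dir_c, s>``.
    """
    d = 0.0
    if source_id > 0:
        d += -m_rand * vols[source_id] * (cos_a[source_id] * sx + sin_a[source_id] * sy)
    if target_id > 0:
        d += -m_rand * vols[target_id] * (cos_a[target_id] * sx + sin_a[target_id] * sy)
    return d


@njit(cache=False)
def total_delta_raw(
    grid,
    obstacle,
    field_scaled,
    vols,
    cos_a,
    sin_a,
    ri,
    ci,
    rj,
    cj,
    neigh,
    j_cc,
    j_cm,
    lambda_v,
    a_nodes,
    m_dir_eff,
    m_rand,
    sx,
    sy,
):
    """Total energy change of the copy attempt sigma(j) -> sigma(i)."""
    tid = grid[ri, ci]
    sid = grid[rj, cj]
    d = delta_adhesion_raw(grid, obstacle, ri, ci, sid, neigh, j_cc, j_cm)
    vt = vols[tid] if tid > 0 else -1.0
    vs = vols[sid] if sid > 0 else -1.0
    d += delta_volume_raw(vt, vs, lambda_v, a_nodes)
    d += delta_chemotaxis_raw(field_scaled[rj, cj], field_scaled[ri, ci], m_dir_eff)
    d += delta_persistence_raw(sid, tid, vols, cos_a, sin_a, m_rand, sx, sy)
    return d


@njit(cache=False)
def run_mcs_chunk(
    grid,
    obstacle,
    field_scaled,
    vols,
    sum_r,
    sum_c,
    cos_a,
    sin_a,
    alpha,
    next_switch,
    t0,
    n_mcs,
    mcs_dt,
    lam,
    t_off,
    neigh,
    s_unit,
    j_cc,
    j_cm,
    lambda_v,
    a_nodes,
    m_dir,
    m_rand,
    temperature,
):
    """Advance the lattice by ``n_mcs`` Monte Carlo steps.

    One MCS performs as many copy attempts as there are lattice sites and
    advances simulated time by ``mcs_dt`` seconds.  Direction switches of
    the persistent random walk are resolved at the start of each MCS from
    the per-cell exponential waiting-time clocks.  Returns the simulation
    time after the chunk.
    """
    h, w = grid.shape
    n_sites = h * w
    n_neigh = neigh.shape[0]
    n_cells = vols.shape[0] - 1
    t = t0
    for _ in range(n_mcs):
        # waiting-time process: resample preferred angles that are due
        for cid in range(1, n_cells + 1):
            while next_switch[cid] <= t:
                alpha[cid] = np.random.uniform(0.0, 2.0 * np.pi)
                cos_a[cid] = np.cos(alpha[cid])
                sin_a[cid] = np.sin(alpha[cid])
                next_switch[cid] += np.random.exponential(1.0 / lam)
        m_dir_eff = m_dir if (t_off < 0.0 or t < t_off) else 0.0
        for _a in range(n_sites):
            u = np.random.randint(0, n_sites * n_neigh)
            idx = u // n_neigh
            k = u - idx * n_neigh
            ri = idx // w
            ci = idx - ri * w
            rj = ri + neigh[k, 0]
            cj = ci + neigh[k, 1]
            if rj < 0 or rj >= h or cj < 0 or cj >= w:
                continue
            if obstacle[ri, ci] or obstacle[rj, cj]:
                continue  # steps onto (or from) pillars are rejected
            tid = grid[ri, ci]
            sid = grid[rj, cj]
            if tid == sid:
                continue
            if tid > 0 and vols[tid] <= 1:
                continue  # cell death is not modeled: keep every cell alive
            sx = s_unit[k, 0]
            sy = s_unit[k, 1]
            d = total_delta_raw(
                grid, obstacle, field_scaled, vols, cos_a, sin_a,
                ri, ci, rj, cj, neigh, j_cc, j_cm, lambda_v, a_nodes,
                m_dir_eff, m_rand, sx, sy,
            )
            if d <= 0.0 or np.random.random() < np.exp(-d / temperature):
                grid[ri, ci] = sid
                if tid > 0:
                    vols[tid] -= 1
                    sum_r[tid] -= ri
                    sum_c[tid] -= ci
                if sid > 0:
                    vols[sid] += 1
                    sum_r[sid] += ri
                    sum_c[sid] += ci
        t += mcs_dt
    return t
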
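"""Method-comparison metrics and posterior diagnostics.

Covers the normalized root-mean-squared recovery error (NRMSE),
simulation-based-calibration ECDF bands, UMAP-space cosine similarity
between simulated and observed tracks, LASSO interpretation of the learned
summary space, and two analytic unit conversions (effective circular
diameter of the inferred cell area; mean waiting time of the
direction-switch process).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import PARAM_NAMES
from .tracks import TrackSet


# ---------------------------------------------------------------------------
# parameter-recovery error
# ---------------------------------------------------------------------------
@dataclass
class RecoveryReport:
    """Per-parameter and aggregate NRMSE plus posterior point summaries."""

    nrmse_per_parameter: np.ndarray  # (P,)
    nrmse: float  # mean over parameters
    posterior_median: np.ndarray  # (N, P)
    posterior_mad: np.ndarray  # (N, P) median absolute deviation

    def to_frame(self, names=PARAM_NAMES) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": list(names), "nrmse": self.nrmse_per_parameter}
        )


def nrmse(
    true_params: np.ndarray,
    posterior_samples: np.ndarray,
    median_over: str = "samples",
) -> RecoveryReport:
    """Normalized RMSE of posterior samples against ground truth.

    ``true_params``: (N, P) truths for N datasets; ``posterior_samples``:
    (N, L, P) with an equal number L of posterior draws per dataset.

    Default aggregation, per parameter: for each posterior-sample index l
    the RMSE across the N datasets is computed, the median over l is
    taken, and the result is normalized by the range of the true values.
    ``median_over="datasets"`` instead computes each dataset's RMSE over
    its own draws and takes the median across datasets (sensitivity
    variant).  The reported scalar is the mean over parameters.
    """
    true = np.asarray(true_params, dtype=float)
    samp = np.asarray(posterior_samples, dtype=float)
    if true.ndim != 2 or samp.ndim != 3:
        raise ValueError("expected true (N,P) and samples (N,L,P)")
    n, p = true.shape
    if samp.shape[0] != n or samp.shape[2] != p:
        raise ValueError("shape mismatch between truths and samples")
    if n < 2:
        raise ValueError("need at least 2 datasets for a range normalization")
    rng_true = true.max(axis=0) - true.min(axis=0)
    if (rng_true <= 0).any():
        raise ValueError("zero range of true values; NRMSE undefined")
    err = samp - true[:, None, :]  # (N, L, P)
    if median_over == "samples":
        rmse_l = np.sqrt(np.mean(err**2, axis=0))  # (L, P)
        med = np.median(rmse_l, axis=0)  # (P,)
    elif median_over == "datasets":
        rmse_n = np.sqrt(np.mean(err**2, axis=1))  # (N, P)
        med = np.median(rmse_n, axis=0)
    else:
        raise ValueError("median_over must be 'samples' or 'datasets'")
    per_param = med / rng_true
    post_median = np.median(samp, axis=1)
    post_mad = np.median(np.abs(samp - post_median[:, None, :]), axis=1)
    return RecoveryReport(per_param, float(per_param.mean()), post_median, post_mad)


# ---------------------------------------------------------------------------
# simulation-based calibration diagnostics
# ---------------------------------------------------------------------------
def sbc_ecdf_diff(ranks: np.ndarray, n_draws: int, grid_size: int = 101):
    """ECDF-difference curves of SBC ranks.

    Returns ``(u, diff)`` where ``diff[:, p] = ECDF_p(u) - u`` for the
    normalized ranks of parameter p; flat curves indicate calibration.
    """
    ranks = np.atleast_2d(np.asarray(ranks, dtype=float))
    u = np.linspace(0.0, 1.0, grid_size)
    norm = (ranks + 1.0) / (n_draws + 1.0)  # ranks uniform on {0..L}
    diff = np.empty((grid_size, ranks.shape[1]))
    for p in range(ranks.shape[1]):
        diff[:, p] = np.searchsorted(np.sort(norm[:, p]), u, side="right") / len(
            norm
        ) - u
    return u, diff


def sbc_simultaneous_band(
    n_datasets: int,
    n_draws: int,
    confidence: float = 0.95,
    n_monte_carlo: int = 2000,
    grid_size: int = 101,
    rng: np.random.Generator | None = None,
) -> float:
    """Simultaneous confidence band for the SBC ECDF difference.

    Monte-Carlo estimate of the ``confidence`` quantile of
    ``sup_u |ECDF(u) - u|`` under the uniform null with ``n_datasets``
    rank statistics on {0, ..., n_draws}.
    """
    rng = rng or np.random.default_rng(0)
    u = np.linspace(0.0, 1.0, grid_size)
    sups = np.empty(n_monte_carlo)
    for m in range(n_monte_carlo):
        r = rng.integers(0, n_draws + 1, size=n_datasets)
        norm = np.sort((r + 1.0) / (n_draws + 1.0))
        ecdf = np.searchsorted(norm, u, side="right") / n_datasets
        sups[m] = np.abs(ecdf - u).max()
    return float(np.quantile(sups, confidence))


def sbc_within_band(
    ranks: np.ndarray, n_draws: int, confidence: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[bool, np.ndarray, float]:
    """Check all per-parameter ECDF-difference curves against the
    simultaneous band; returns (ok, per-parameter sup deviations, band)."""
    ranks = np.atleast_2d(ranks)
    _, diff = sbc_ecdf_diff(ranks, n_draws)
    band = sbc_simultaneous_band(len(ranks), n_draws, confidence, rng=rng)
    sup = np.abs(diff).max(axis=0)
    return bool((sup <= band).all()), sup, band


# ---------------------------------------------------------------------------
# UMAP cosine similarity between simulated and observed tracks
# ---------------------------------------------------------------------------
def _vectorize_tracks(tracksets: list[TrackSet], pad_value: float = -1.0) -> np.ndarray:
    """Fixed-length (x, y) interleaved track vectors, padded with -1."""
    t_max = max((ts.max_length() for ts in tracksets), default=0)
    rows = []
    for ts in tracksets:
        for tr in ts:
            v = np.full(2 * t_max, pad_value)
            v[0 : 2 * len(tr) : 2] = tr.x
            v[1 : 2 * len(tr) : 2] = tr.y
            rows.append(v)
    return np.array(rows)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ZeroDivisionError("zero-norm vector in cosine similarity")
    return float(a @ b / (na * nb))


def umap_cosine(
    observed_tracks: TrackSet,
    simulated_tracks: TrackSet,
    n_components: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Cosine similarities between simulated and observed cells after a
    joint UMAP embedding of padded track vectors.

    Both track sets are vectorized to a common fixed length (pad -1),
    co-embedded into ``n_components`` dimensions with standard UMAP
    settings and a fixed seed, and the pairwise cosine similarity between
    every (simulated, observed) embedding pair is returned.  Zero-norm
    embeddings are skipped with a warning.
    """
    import umap

    n_obs = len(observed_tracks)
    n_sim = len(simulated_tracks)
    if n_obs + n_sim < 2:
        raise ValueError("need at least two tracks for an embedding")
    vecs = _vectorize_tracks([observed_tracks, simulated_tracks])
    n_neighbors = min(15, len(vecs) - 1)
    reducer = umap.UMAP(
        n_components=n_components, n_neighbors=n_neighbors, random_state=seed
    )
    emb = reducer.fit_transform(vecs)
    obs_emb, sim_emb = emb[:n_obs], emb[n_obs:]
    sims = []
    for se in sim_emb:
        for oe in obs_emb:
            try:
                sims.append(cosine_similarity(se, oe))
            except ZeroDivisionError:
                warnings.warn("zero-norm embedded vector; pair skipped")
    return np.array(sims)


# ---------------------------------------------------------------------------
# latent-space interpretation
# ---------------------------------------------------------------------------
def lasso_latent(
    true_params: np.ndarray, summaries: np.ndarray, alpha: float = 0.1
) -> np.ndarray:
    """L1-regularized regression of each parameter onto the learned
    summary space; returns the (n_params, summary_dim) coefficient matrix
    used for latent-space heatmaps and latent predictions."""
    from sklearn.linear_model import Lasso

    phi = np.asarray(true_params, dtype=float)
    s = np.asarray(summaries, dtype=float)
    if phi.ndim != 2 or s.ndim != 2 or len(phi) != len(s):
        raise ValueError("expected matching 2D arrays")
    if len(s) < 10 * s.shape[1]:
        raise ValueError("need at least 10x more samples than latent dims")
    if np.linalg.matrix_rank(s - s.mean(axis=0)) == 0:
        raise ValueError("degenerate design matrix")
    coefs = np.empty((phi.shape[1], s.shape[1]))
    for p in range(phi.shape[1]):
        model = Lasso(alpha=alpha, max_iter=50_000)
        model.fit(s, phi[:, p])
        coefs[p] = model.coef_
    return coefs


# ---------------------------------------------------------------------------
# analytic unit conversions
# ---------------------------------------------------------------------------
def effective_diameter(area_um2: float) -> float:
    """Diameter (um) of the circle with the given area: 2 sqrt(A / pi)."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    return 2.0 * math.sqrt(area_um2 / math.pi)


def mean_waiting_time(lambda_per_s: float) -> float:
    """Mean of the exponential waiting time with rate lambda, in minutes."""
    if lambda_per_s <= 0:
        raise ValueError("rate must be positive")
    return (1.0 / lambda_per_s) / 60.0
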
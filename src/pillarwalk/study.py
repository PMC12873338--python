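"""Seeded experiment harness: study profiles, in-silico perturbation
conditions, and the method-comparison table.

A :class:`StudySetup` bundles the arena geometry, chemokine field and
simulation settings, and exposes seeded helpers for generating
simulation-parameter pairs.  Two profiles exist:

* ``desk``: a reduced arena (3x4 pillar forest, 20 cells, 450 s runs)
  sized so that the full inference study runs on a single workstation;
* ``full``: the experiment-scale arena (~36x30 pillars, 143 cells, 2 h
  runs, 30 s frames) matching the reference study design.

The perturbation conditions mirror the in-silico study: baseline,
no chemokine, pulsed chemokine, no persistence, and no pillars, all
simulated from a common base parameter set, sampled at 10-s intervals and
recorded over the whole arena.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .abc_smc import (
    AbcConfig,
    LearnedSummaryBackend,
    Population,
    WassersteinBackend,
    run_abc,
)
from .chemokine import ChemokineField, gaussian_gradient
from .cpm import SimulationConfig, simulate
from .geometry import Geometry, build_pillar_forest
from .npe import (
    NPEPosterior,
    PosteriorMeanNet,
    TrainConfig,
    build_input_tensor,
    train_joint,
    train_posterior_mean,
)
from .params import DEFAULT_PRIOR, BoxPrior, ModelParameters
from .summaries import calibrate_weights, summarize
from .evaluation import nrmse
from .tracks import TrackSet


# ---------------------------------------------------------------------------
# study profiles
# ---------------------------------------------------------------------------
@dataclass
class StudySetup:
    """Geometry + field + simulation settings of one study profile."""

    geometry: Geometry
    field: ChemokineField
    sim_config: SimulationConfig
    t_max: int
    n_cells_max: int
    name: str = "desk"

    @classmethod
    def desk(cls) -> "StudySetup":
        geo = build_pillar_forest(3, 4, pillar_diameter_um=5.0, gap_um=10.0,
                                  clearing_um=20.0)
        cfg = SimulationConfig(n_cells=20, total_time_s=450.0, dt_obs_s=30.0,
                               burn_in_mcs=100)
        t_max = int(cfg.total_time_s // cfg.dt_obs_s) + 1
        return cls(geo, gaussian_gradient(geo), cfg, t_max=t_max,
                   n_cells_max=cfg.n_cells + 8, name="desk")

    @classmethod
    def full(cls) -> "StudySetup":
        geo = build_pillar_forest(30, 36, pillar_diameter_um=5.0, gap_um=10.0,
                                  clearing_um=90.0)
        cfg = SimulationConfig(n_cells=143, total_time_s=7200.0, dt_obs_s=30.0,
                               burn_in_mcs=100)
        t_max = int(cfg.total_time_s // cfg.dt_obs_s) + 1
        return cls(geo, gaussian_gradient(geo), cfg, t_max=t_max,
                   n_cells_max=cfg.n_cells + 30, name="full")

    # ------------------------------------------------------------------
    def simulate_tracks(self, phi: np.ndarray, seed: int) -> TrackSet:
        params = ModelParameters.from_vector(np.asarray(phi, dtype=float))
        return simulate(params, self.geometry, self.field, self.sim_config, seed)

    def simulate_tensor(self, phi: np.ndarray, seed: int) -> np.ndarray:
        return build_input_tensor(
            self.simulate_tracks(phi, seed), self.t_max, self.n_cells_max
        )

    def generate_pairs(
        self, n: int, rng: np.random.Generator, prior: BoxPrior = DEFAULT_PRIOR
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw n prior-predictive simulation-parameter pairs."""
        phis = prior.sample(n, rng)
        xs = np.empty((n, self.n_cells_max, self.t_max, 4))
        for i, phi in enumerate(phis):
            xs[i] = self.simulate_tensor(phi, int(rng.integers(2**31 - 1)))
        return xs, phis


# ---------------------------------------------------------------------------
# in-silico perturbation conditions
# ---------------------------------------------------------------------------
CONDITION_NAMES = (
    "baseline",
    "no_chemokine",
    "pulsed_chemokine",
    "no_persistence",
    "no_pillars",
)


@dataclass(frozen=True)
class Condition:
    """One perturbation of the base setup.

    ``pulse_fraction`` only applies to the pulsed condition and gives the
    fraction of the simulated time during which the chemokine is active.
    """

    name: str
    pulse_fraction: float | None = None
    dt_obs_s: float = 10.0

    def __post_init__(self) -> None:
        if self.name not in CONDITION_NAMES:
            raise ValueError(f"unknown condition {self.name!r}")

    def apply(
        self,
        base_params: ModelParameters,
        geometry: Geometry,
        field: ChemokineField,
        sim_config: SimulationConfig,
    ) -> tuple[ModelParameters, Geometry, ChemokineField, SimulationConfig]:
        params, geo, fld = base_params, geometry, field
        if self.name == "no_chemokine":
            fld = field.zeroed()
        elif self.name == "pulsed_chemokine":
            frac = self.pulse_fraction if self.pulse_fraction is not None else 0.5
            fld = field.with_pulse(frac * sim_config.total_time_s)
        elif self.name == "no_persistence":
            params = replace(base_params, log10_m_rand=-np.inf)
        elif self.name == "no_pillars":
            geo = geometry.without_pillars()
        cfg = replace(sim_config, dt_obs_s=self.dt_obs_s, record_full_arena=True)
        return params, geo, fld, cfg


@dataclass
class ConditionResult:
    condition: Condition
    tracksets: list[TrackSet]
    summary_median: pd.Series
    summary_mad: pd.Series
    arrival_fractions: np.ndarray

    @property
    def pooled_summaries(self) -> pd.DataFrame:
        return pd.concat([summarize(ts) for ts in self.tracksets],
                         ignore_index=True)


def fraction_reaching_target(trackset: TrackSet, geometry: Geometry) -> float:
    """Fraction of cells whose trajectory ever enters the target region
    (the chemokine hole).  NaN for an empty track set."""
    if len(trackset) == 0:
        return float("nan")
    res = geometry.resolution
    target = geometry.target_region
    hits = sum(
        any(target.contains_xy(x, y, res) for x, y in zip(tr.x, tr.y))
        for tr in trackset
    )
    return hits / len(trackset)


def run_condition(
    condition: Condition,
    base_params: ModelParameters,
    setup: StudySetup,
    n_replicates: int,
    seed: int,
) -> ConditionResult:
    """Simulate one perturbation condition over seeded replicates.

    Trajectories are sampled at the condition's (higher) frame rate and
    recorded over the whole arena.  Returns the per-replicate track sets,
    the median and median absolute deviation of the pooled per-cell
    summaries, and the per-replicate fraction of cells reaching the
    chemokine hole.
    """
    params, geo, fld, cfg = condition.apply(
        base_params, setup.geometry, setup.field, setup.sim_config
    )
    rng = np.random.default_rng(seed)
    tracksets, fractions = [], []
    for _ in range(n_replicates):
        ts = simulate(params, geo, fld, cfg, int(rng.integers(2**31 - 1)))
        tracksets.append(ts)
        fractions.append(fraction_reaching_target(ts, geo))
    pooled = pd.concat([summarize(ts) for ts in tracksets], ignore_index=True)
    stats = pooled[["D", "V", "TA", "AD"]]
    med = stats.median()
    mad = (stats - med).abs().median()
    return ConditionResult(condition, tracksets, med, mad, np.array(fractions))


def default_base_parameters() -> ModelParameters:
    """Base parameter set for the perturbation study: the analytically
    anchored medians a = 41.73 um^2 and lambda = 2.1e-3 1/s, with
    motility strengths chosen so both chemotaxis and persistence visibly
    shape the desk-scale trajectories."""
    return ModelParameters(
        log10_m_dir=2.5,
        log10_m_rand=1.0,
        log10_lambda=float(np.log10(2.1e-3)),
        log10_a=float(np.log10(41.73)),
    )


# ---------------------------------------------------------------------------
# method comparison (Table-style)
# ---------------------------------------------------------------------------
@dataclass
class BudgetProfile:
    """Simulation/training budgets of the comparison harness."""

    n_train: int
    n_val: int
    abc: AbcConfig
    n_truths: int
    n_posterior_draws: int
    train: TrainConfig

    @classmethod
    def desk(cls) -> "BudgetProfile":
        return cls(
            n_train=2000,
            n_val=100,
            abc=AbcConfig(population_size=50, max_generations=4,
                          min_acceptance_rate=0.02),
            n_truths=3,
            n_posterior_draws=100,
            train=TrainConfig(max_epochs=30, patience=6),
        )

    @classmethod
    def full(cls) -> "BudgetProfile":
        return cls(
            n_train=32_000,
            n_val=300,
            abc=AbcConfig(population_size=1000, max_generations=15,
                          min_acceptance_rate=0.01),
            n_truths=3,
            n_posterior_draws=1000,
            train=TrainConfig(max_epochs=50, patience=8),
        )


def _select_ground_truths(
    setup: StudySetup,
    prior: BoxPrior,
    n_truths: int,
    rng: np.random.Generator,
    n_candidates: int = 40,
    min_tracks: int = 3,
):
    """Greedy maximin selection of spread-out, observable ground truths.

    From a pool of prior draws, truths are added one at a time maximizing
    the smallest per-coordinate range of the selected set (in prior-box
    units); candidates whose simulated dataset has fewer than
    ``min_tracks`` summarizable tracks are discarded.
    """
    pool = list(prior.sample(n_candidates, rng))
    width = prior.high - prior.low
    chosen: list[np.ndarray] = []
    observed: list[TrackSet] = []

    def observable(phi):
        ts = setup.simulate_tracks(phi, int(rng.integers(2**31 - 1)))
        table = summarize(ts)
        ok = len(table.dropna(subset=["D"])) >= min_tracks if len(table) else False
        return ok, ts

    while len(chosen) < n_truths:
        if not pool:
            pool = list(prior.sample(n_candidates, rng))
        if not chosen:
            order = list(rng.permutation(len(pool)))
        else:
            stack = np.array(chosen)

            def spread(phi):
                pts = np.vstack([stack, phi]) / width
                return (pts.max(axis=0) - pts.min(axis=0)).min()

            order = sorted(range(len(pool)),
                           key=lambda i: -spread(pool[i]))
        placed = False
        for i in order:
            ok, ts = observable(pool[i])
            phi = pool.pop(i)
            if ok:
                chosen.append(phi)
                observed.append(ts)
                placed = True
                break
        if not placed and not pool:
            raise RuntimeError("no observable ground truths found in pool")
    return np.array(chosen), observed


def _abc_posterior_draws(
    populations: list[Population], n: int, rng: np.random.Generator
) -> np.ndarray:
    return populations[-1].resample(n, rng)


def run_method_comparison(
    budget_profile: str | BudgetProfile = "desk",
    seed: int = 0,
    setup: StudySetup | None = None,
    npe_posterior: NPEPosterior | None = None,
    pm_net: PosteriorMeanNet | None = None,
    train_pairs: tuple[np.ndarray, np.ndarray] | None = None,
    val_pairs: tuple[np.ndarray, np.ndarray] | None = None,
    prior: BoxPrior = DEFAULT_PRIOR,
) -> tuple[pd.DataFrame, dict]:
    """Compare ABC (hand-crafted), ABC-PM, ABC-NPE and NPE on shared
    synthetic ground truths.

    All ABC variants consume the same per-particle seeding contract; NPE
    reuses its amortized networks across ground truths without
    retraining.  Returns the comparison table (one row per method with
    simulation counts, generations and NRMSE) plus a detail dict with the
    posterior draws.
    """
    profile = (
        budget_profile
        if isinstance(budget_profile, BudgetProfile)
        else {"desk": BudgetProfile.desk, "full": BudgetProfile.full}[budget_profile]()
    )
    setup = setup or (StudySetup.desk() if profile.n_train <= 4000 else StudySetup.full())
    rng = np.random.default_rng(seed)

    # shared training data for the learned-summary methods
    if train_pairs is None:
        train_pairs = setup.generate_pairs(profile.n_train, rng, prior)
    if val_pairs is None:
        val_pairs = setup.generate_pairs(profile.n_val, rng, prior)
    t0 = time.time()
    if npe_posterior is None:
        npe_posterior = train_joint(train_pairs, val_pairs, profile.train,
                                    np.random.default_rng(seed + 1))
    if pm_net is None:
        pm_net = train_posterior_mean(train_pairs, val_pairs, profile.train,
                                      np.random.default_rng(seed + 2))
    train_time = time.time() - t0

    # Ground truths are prior draws subject to two conditions: the
    # observed dataset must contain summarizable tracks (cells must appear
    # in the visible window — the criterion behind the prior's lower
    # bounds), and the selected set must be spread in every coordinate so
    # the range normalization of the NRMSE is well conditioned at small N.
    truths, observed = _select_ground_truths(setup, prior, profile.n_truths, rng)

    # hand-crafted distance weights from a pre-calibration population
    precal_tables = []
    for phi in prior.sample(profile.abc.precalibration_size or 50, rng):
        precal_tables.append(
            summarize(setup.simulate_tracks(phi, int(rng.integers(2**31 - 1))))
        )
    weights = calibrate_weights([t for t in precal_tables if len(t)])

    def tracks_simulator(phi, seed_):
        return setup.simulate_tracks(phi, seed_)

    def to_tensor(ts: TrackSet) -> np.ndarray:
        return build_input_tensor(ts, setup.t_max, setup.n_cells_max)

    backends: dict[str, Callable] = {
        "ABC": lambda: WassersteinBackend(weights),
        "ABC-PM": lambda: LearnedSummaryBackend(
            lambda ts: pm_net.predict(to_tensor(ts))
        ),
        "ABC-NPE": lambda: LearnedSummaryBackend(
            lambda ts: npe_posterior.summarize(to_tensor(ts))
        ),
    }

    rows = []
    draws: dict[str, np.ndarray] = {}
    L = profile.n_posterior_draws
    for method, make_backend in backends.items():
        samples = np.empty((profile.n_truths, L, prior.dim))
        sims = 0
        gens = []
        for i, ts_obs in enumerate(observed):
            pops = run_abc(
                ts_obs, tracks_simulator, make_backend(), prior, profile.abc,
                np.random.default_rng(seed * 1000 + i),
            )
            samples[i] = _abc_posterior_draws(pops, L, rng)
            sims += pops[-1].n_simulations
            gens.append(len(pops))
        report = nrmse(truths, samples)
        rows.append((method, sims, f"{min(gens)}-{max(gens)}", np.nan, report.nrmse))
        draws[method] = samples

    # amortized NPE: no per-dataset simulation or retraining
    samples = np.empty((profile.n_truths, L, prior.dim))
    for i, ts_obs in enumerate(observed):
        samples[i] = npe_posterior.sample(to_tensor(ts_obs), L,
                                          np.random.default_rng(seed * 77 + i))
    report = nrmse(truths, samples)
    rows.append(("NPE", profile.n_train + profile.n_val, "-", train_time,
                 report.nrmse))
    draws["NPE"] = samples

    table = pd.DataFrame(
        rows, columns=["method", "n_simulations", "generations",
                       "training_time_s", "nrmse"]
    )
    details = {"truths": truths, "draws": draws, "observed": observed,
               "weights": weights}
    return table, details
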
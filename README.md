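# pillarwalk

Simulation-based inference of cell-migration dynamics in structured
microenvironments. `pillarwalk` models dendritic cells navigating a
micro-fabricated pillar forest under a chemokine gradient with an
extended 2D Cellular Potts model, and infers the migration parameters
from trajectory data with likelihood-free methods: sequential Monte
Carlo ABC on hand-crafted summary statistics, and amortized neural
posterior estimation (NPE) with learned summaries.

It is aimed at quantitative cell biologists and modellers who have
per-cell trajectory tables (cell id, frame, time, x/y in um) from
confined-migration assays and want mechanistic parameters — chemotactic
sensitivity, persistence, direction-switch rate, cell size — with full
posterior uncertainty.

## Model

Cells are extended domains on a lattice (1.31 um/node) evolving by
Metropolis copy attempts with energy

```
dH = dH_adhesion + dH_volume + dH_chemotaxis + dH_persistence
H_classic = sum_<i,j> J_(s_i,s_j) (1 - delta) + lambda_v sum_c (v_c - a)^2
dH_chemotaxis  = m_dir (f_source - f_target)
dH_persistence = -m_rand v_c <(cos a, sin a), s>
```

accepted with probability `min(1, exp(-dH/T))`; moves onto pillars are
rejected. Each cell's preferred angle `a` is resampled uniformly after
exponential waiting times with rate `lambda`, giving a persistent random
walk. The four inferred parameters, on the log10 scale, are

| parameter | meaning | prior |
|---|---|---|
| `log10 m_dir` | chemotactic attraction strength | U[0, 4] |
| `log10 m_rand` | persistent-motion strength | U[0, 2] |
| `log10 lambda` | direction-switch rate (1/s) | U[-4, 1.5] |
| `log10 a` | target cell area (um^2) | U[0, 2.5] |

Simulated cells are observed like the experiment: centroids every 30 s,
only while inside the visible window of the pillar forest, with track
times re-zeroed at first observation.

Inference routes: **ABC** (weighted Wasserstein-1 distance on per-cell
displacement / velocity / turning-angle / heading distributions),
**ABC-NPE** and **ABC-PM** (L1 distance on learned summaries from the
jointly trained or posterior-mean-trained network), and **NPE** (a
conditional normalizing flow over a permutation-invariant
conv-GRU-attention summary network; training is amortized, so new
datasets are analyzed in about a second without re-simulation).

## Worked example

Simulate a desk-scale dataset, summarize it, and look at the statistics:

```sh
pillarwalk simulate --profile desk --seed 3 \
    --phi 2.5 1.0 -2.7 1.6 --out tracks.csv
pillarwalk evaluate tracks.csv --out report.json
```

prints (seed 3):

```json
{
  "n_tracks": 12,
  "median": {
    "D": 12.451, "V": 0.2190, "TA": 0.0071, "AD": -0.0483
  },
  "mad": {
    "D": 4.724, "V": 0.0641, "TA": 0.0411, "AD": 0.1459
  }
}
```

Twelve tracks crossed the visible window. The large median normalized
displacement (~12.5 um per sqrt-frame at ~0.22 um/s median speed), the
near-zero median turning angle and the small median heading (`AD`,
radians from the gradient axis) describe fast, straight, up-gradient
migration, as expected at `m_dir = 10^2.5` with strong persistence.
ABC inference on such a dataset then runs

```sh
pillarwalk abc tracks.csv --summaries handcrafted \
    --population-size 40 --max-generations 3 --seed 1 --out posterior.csv
```

and writes weighted posterior particles with an adaptive epsilon
schedule in the manifest. `pillarwalk train-npe` / `infer` provide the
amortized route, `sbc` checks calibration, and `pillarwalk study` runs
the full method comparison plus the perturbation-condition study
(no chemokine, pulsed chemokine, no persistence, no pillars).

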
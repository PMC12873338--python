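# Methods

`pillarwalk` models chemotactic dendritic-cell migration through a
micro-fabricated pillar forest and infers the migration parameters from
trajectory data with likelihood-free methods. This note documents the
model, the numerical and design choices, and what the synthetic studies
do and do not establish.

## Forward model

### Cellular Potts dynamics

Cells are domains of sites on a 2D lattice (resolution 1.31 um per node).
A Metropolis copy attempt picks a random site i and a random Moore
neighbor j and proposes copying the occupant of j onto i. The energy
change combines four terms:

* **Adhesion** `sum_<i,j> J_(a,b) (1 - delta_ab)` over neighbor pairs.
  Distinct cells meet at cost `J_cc`; cell-medium (and cell-pillar)
  interfaces cost `J_cm`. Defaults `J_cc = J_cm = 4`.
* **Volume** `lambda_v (v_c - a)^2` per cell, with the target area `a`
  (um^2) converted to nodes by `round(a / 1.31^2)` (floor 1 node).
* **Chemotaxis** `m_dir (f_j - f_i) / u`, negative (favored) when the
  boundary advances up the gradient. `f` is the chemokine concentration
  in um^-2 and `u = 1e6 um^-2` is the model's field unit: with the
  Gaussian gradient used here (peak 7e6 um^-2, sigma 550 um) the per-node
  concentration increments divided by `u` are of order 1e-3..1e-2, so the
  prior range of `m_dir` (1..1e4) sweeps chemotaxis from negligible to
  dominant relative to the fluctuation temperature.
* **Persistence** `-m_rand v_c <(cos a, sin a), s>` where `alpha` is the
  cell's preferred angle and `s` the unit displacement from the source to
  the target site. The term applies to every cell whose domain changes
  (both the expanding and the retracting cell move along `+s` when the
  boundary advances). Each cell's angle is resampled uniformly on
  [0, 2pi) after exponential waiting times with rate `lambda` (1/s),
  giving run-and-tumble behavior.

Moves are accepted with probability `min(1, exp(-dH / T))`; attempts onto
or from pillar nodes are rejected outright, as are moves that would
remove a cell's last site (cell death is not modeled). One Monte Carlo
step (one sweep of as many attempts as lattice sites) equals one second
of simulated time by default; both are configurable.

**Potts constants.** `T = 10` and `J = 4` are conventional magnitudes.
The volume stiffness defaults to `lambda_v = 50`: the persistence drive
scales with cell volume (up to `m_rand * v_c ~ 2400` at the top of the
prior) and a soft volume term cannot bound cell volumes against it —
with a weak constraint, volumes random-walk and cells dissolve mid-run.
`lambda_v = 50` keeps cells cohesive and mobile over the whole prior box.

**Initialization.** Cells are seeded as single nodes uniformly in the
entry clearing and grown for a 100-MCS burn-in with the motility terms
off (growth governed by volume + adhesion alone); the observation clock
and the chemokine pulse clock start at t = 0 afterwards. Preferred angles
are drawn at t = 0 with the first switch time `~ Exp(lambda)`.

**Observation model.** Centroids are recorded every 30 s (10 s in the
perturbation study). A sample is retained iff the centroid lies in the
visible window; each maximal contiguous retained run becomes one track
with times re-zeroed to its first frame, and a re-entry opens a new
track. Cells never seen in the window contribute nothing.

The Metropolis inner loop is JIT-compiled (numba); the single-step
Python API wraps the same compiled energy kernels, so the inspectable and
the fast paths share one definition of the physics.

## Hand-crafted summaries and the ABC distance

Per track of length T at interval dt (defaults in parentheses):
normalized displacement `D = |X_T - X_1| / sqrt(T)`; mean speed `V`
(um/s); mean signed turning angle `TA`, with heading
`theta = atan2(dx, dy)` (angle from the +y axis, which points up the
gradient) and differences wrapped to (-pi, pi]; and the mean heading
`AD`. Zero-length steps have no heading and are skipped together with
their normalizer share. Sums are normalized by the number of summed
terms; a strict mode with the off-by-one normalizers (T-2 terms for a
T-1-term sum, etc.) exists for sensitivity checks. Minimum lengths:
D needs T >= 2; V, AD need T >= 2 (T >= 3 strict); TA needs T >= 3.
Ineligible tracks are dropped per statistic, not globally.

Datasets are compared by the Wasserstein-1 distance between the per-cell
distributions of each statistic, weighted by the inverse range of that
statistic over a pre-calibration population of prior-predictive
simulations, and summed. A simulation with no observed cell is infinitely
distant.

## SMC-ABC

Standard adaptive SMC-ABC: the initial threshold is the median distance
of a pre-calibration prior sample; each generation resamples the previous
particles by weight, perturbs with a multivariate normal kernel
(covariance twice the weighted empirical covariance), rejects proposals
outside the prior box, and accepts at the median-of-previous-distances
threshold (infinite distances excluded, so the threshold is always
finite and non-increasing). Importance weights are the uniform prior
density over the kernel mixture density. Stopping: acceptance rate below
a floor (0.01 at full scale) or a generation cap (15 at full scale).
Variants differ only in the distance: hand-crafted Wasserstein (ABC),
L1 on the NPE summary embedding (ABC-NPE), or L1 on the posterior-mean
prediction (ABC-PM).

## Neural posterior estimation

Trajectories enter as padded tensors (n_cells, t_max, 4) with channels
(x, y, t, observed-indicator); unobserved entries are zero. Channels and
parameters are standardized with constants computed on the validation
set and frozen into the artifact.

The summary network processes each cell with a same-padded 1D convolution
(kernel 3, 32 filters, ReLU) and a 32-unit GRU; a global query vector
(the masked mean of GRU outputs over all cells and times) attends over
each cell's time steps (scaled dot-product, masked softmax), the
attended vectors are mean-pooled over observed cells, and a dense head
yields an 8-dimensional summary. All per-cell operations are shared, so
the summary is invariant to cell order.

The conditional normalizing flow maps parameters to a standard-normal
latent through affine coupling layers (6 by default) whose scale and
shift come from a conditioner MLP fed with the pass-through coordinates
and the summary vector; scales are tanh-bounded for stability. Affine
couplings were chosen over spline couplings as the flow family: they
invert in closed form, their Jacobian is exact, and for a 4-dimensional,
mostly unimodal posterior their flexibility (stacked over alternating
masks) is sufficient; the toy and calibration checks below quantify this.
Both networks are trained jointly by minimizing the mean negative log
posterior density (the Monte-Carlo forward-KL objective) plus a
Gaussian-kernel MMD penalty (weight 1) that pulls the batch summaries
toward a standard normal. Optimization: Adam, initial learning rate
5e-4, cosine decay, batch 32, early stopping on validation loss with
restoration of the best epoch. The networks and the training loop run on
an in-package reverse-mode autodiff core whose gradients are pinned
against finite differences in the test suite.

The posterior-mean network is the same summary architecture with output
dimension 4 trained under squared error; it serves as a direct point
estimator and as the ABC-PM summary.

Ensembles pool equal shares of draws from independently trained members
(remainders to the first members). Model misspecification is flagged by
the squared Mahalanobis distance of an observation's summary from the
training summary cloud, thresholded at a chi-square quantile (default
99.9%); the latent-normality regularizer is what makes this reference
distribution approximately Gaussian.

Simulation-based calibration draws prior-predictive datasets, ranks the
true parameter within the posterior draws, and compares the rank ECDF
against a simultaneous band obtained by Monte-Carlo simulation of the
uniform null.

## Evaluation metrics

The recovery error is the range-normalized RMSE: per parameter, the RMSE
across datasets is computed for each posterior-sample index, the median
over sample indices is taken and divided by the range of the true values;
the aggregate is the mean over the four parameters. The alternative
aggregation (median over per-dataset RMSEs) is available as a sensitivity
variant. Posterior predictive similarity between simulated and observed
tracks is measured as cosine similarity after a joint 10-dimensional UMAP
embedding of fixed-length, (-1)-padded, (x, y)-interleaved track vectors
with standard UMAP settings and a fixed seed. The learned summary space
is interpreted by LASSO regression (alpha = 0.1) of the true parameters
onto the 8-dimensional summaries. Two analytic conversions anchor the
units: a 41.73 um^2 area corresponds to an effective circular diameter
`2 sqrt(A/pi) = 7.29 um`, and a switch rate of 2.1e-3 1/s to a mean
waiting time of 7.9 min.

## Study profiles and problem sizes

The `full` profile matches the reference design: ~36x30 pillar forest at
1.31 um/node, 143 cells, 2 h runs at 30-s frames, ABC with 1000
particles and up to 15 generations, NPE on 32,000/300 training/validation
pairs. It is provided for cluster-scale runs.

The `desk` profile is sized for a single workstation and is what the
test suite and the acceptance script run: a 3x4 pillar forest (5 um
pillars, 10 um gaps, 46x64 nodes), 20 cells, 450 s runs at 30-s frames;
NPE trained on 2,000/100 pairs (up to ~24 epochs); ABC with 40 particles
and up to 3 generations on 2 ground truths; perturbation conditions with
20 replicates at 10-s frames recorded over the whole arena. Ground
truths for the comparison are prior draws conditioned on producing at
least three summarizable tracks — the same observability requirement
that motivates the prior's lower bounds.

The perturbation study's base parameters use the two analytically
anchored values (a = 41.73 um^2, lambda = 2.1e-3 1/s) and set
log10 m_dir = 2.5, log10 m_rand = 1, chosen once so that both chemotaxis
and persistence visibly shape desk-scale trajectories.

## What the synthetic studies show — and what they do not

The generator emulates the structure of the experimental data (variable
track counts and lengths, window truncation, 30-s cadence, pillar
geometry, a static Gaussian gradient) but not its full physics: no
chemokine diffusion or depletion, no cell-cell signaling, no
z-movement or tracking noise, and cells are plain Potts domains without
a connectivity constraint (volume + adhesion keep them compact in
practice). Passing the recovery and calibration checks therefore shows
the inference machinery is correct and well calibrated *for this model
at desk scale*; it does not validate the model against real cells.

Ground truths for the method comparison are prior draws selected
greedily for maximin per-coordinate spread (from a 40-draw pool, subject
to observability): the recovery error is normalized by the range of the
true values, and with only three datasets an unconditioned draw can make
that range nearly zero in a coordinate and the error meaningless.

Three desk-scale limitations are known and deliberate:

* The desk arena is small relative to the gradient's 550-um width, so
  the steepest achievable per-node concentration increment is ~1% of the
  field unit, and chemotactic pinning against pillars stays below ~1.5 T
  even at the top of the m_dir prior. The pulse-versus-constant
  chemokine arrival advantage reported for the full-scale system relies
  on such trapping and does not emerge at desk scale (the measured
  difference is zero to slightly negative); the corresponding
  directional check is expected to fail at this scale and is retained
  unweakened.
* The chemotactic dose-response check runs with persistence off, because
  at desk scale the persistence energy (~240 at mid-prior) exceeds the
  chemotaxis term by two orders of magnitude and buries the dose
  response in noise.
* The desk-budget method comparison does not separate the four inference
  routes: at 40-particle, 3-generation ABC and 2,000-pair NPE training
  all posteriors remain weakly informative (aggregate NRMSE ~0.5-0.6,
  near the prior-predictive level, essentially unchanged at 5
  generations), chiefly because m_dir is close to unidentifiable on the
  flat desk-scale gradient. The full-scale ordering of the methods —
  and in particular the collapse of posterior-mean summaries — only
  emerges once ABC concentrates over many more generations and
  simulations; the corresponding desk-profile check is expected to fail
  and is retained unweakened.

## Numerical details

* Energy deltas are computed incrementally; equality with a full-lattice
  recount is enforced to 1e-9 in the tests.
* Boundary sites and pillars count as medium in the adhesion sum.
* The waiting-time clock resolves at MCS boundaries (1 s), well below
  the mean waits of interest (minutes).
* Wasserstein distances use the exact 1D order-statistics form.
* Flow scales are bounded to |log s| <= 3 per layer; standardization
  guards against zero variances.
* UMAP runs with a fixed random state; with a fixed seed reductions are
  reproducible but values depend on the UMAP version.
* All randomness flows from user-supplied integer seeds through
  `numpy.random.Generator`; per-particle and per-replicate seeds are
  drawn from the parent generator, and simulations are bit-reproducible
  given (seed, config).
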
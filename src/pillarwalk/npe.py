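"""Amortized neural posterior estimation with learned summary statistics.

Simulation-parameter pairs train a trajectory summary network jointly with
a conditional normalizing flow by minimizing the mean negative log
posterior density (the Monte-Carlo form of the forward KL divergence),
plus a maximum-mean-discrepancy penalty that pulls the summary latent
space toward a standard normal so that out-of-distribution observations
can be flagged.  A posterior-mean variant trains the same summary
architecture with output dimension dim(phi) under a mean-squared-error
objective; its predictions serve either as direct point estimates or as
ABC summary statistics.

Inputs are padded tensors of shape (n_cells, t_max, 4) with channels
(x, y, t, observed-indicator); all channels are zero where the indicator
is zero.  Standardization constants are computed from the validation set
and frozen into the artifact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .autodiff import Tensor
from .nn import (
    Adam,
    AffineCouplingFlow,
    Module,
    TrajectorySummaryNet,
    VectorSummaryNet,
    cosine_lr,
    gaussian_mmd,
)
from .params import N_PARAMS
from .tracks import TrackSet


# ---------------------------------------------------------------------------
# input encoding
# ---------------------------------------------------------------------------
def build_input_tensor(
    trackset: TrackSet, t_max: int, n_cells_max: int
) -> np.ndarray:
    """Encode a track set as a padded (n_cells_max, t_max, 4) array.

    Channels are (x_um, y_um, t_seconds, indicator); missing observations
    (padding, truncation) carry indicator 0 and zeroed channels.  An empty
    track set is the all-zeros tensor (indicator sums to zero).
    Deterministic: tracks fill rows in their stored order.
    """
    out = np.zeros((n_cells_max, t_max, 4))
    for row, tr in enumerate(trackset):
        if row >= n_cells_max:
            break
        n = min(len(tr), t_max)
        out[row, :n, 0] = tr.x[:n]
        out[row, :n, 1] = tr.y[:n]
        out[row, :n, 2] = tr.t[:n]
        out[row, :n, 3] = 1.0
    return out


@dataclass
class Standardizer:
    """Standardization constants estimated from the validation set.

    For trajectory tensors the first three channels are standardized over
    observed entries only and re-masked afterwards; flat (toy) data are
    standardized per feature.
    """

    x_mean: np.ndarray
    x_sd: np.ndarray
    phi_mean: np.ndarray
    phi_sd: np.ndarray
    kind: str = "tracks"  # or "flat"

    @classmethod
    def fit(cls, x: np.ndarray, phi: np.ndarray) -> "Standardizer":
        phi_mean = phi.mean(axis=0)
        phi_sd = np.where(phi.std(axis=0) > 1e-12, phi.std(axis=0), 1.0)
        if x.ndim == 4:
            mask = x[..., 3] > 0
            if mask.any():
                vals = x[mask][:, :3]
                x_mean = vals.mean(axis=0)
                x_sd = np.where(vals.std(axis=0) > 1e-12, vals.std(axis=0), 1.0)
            else:
                x_mean, x_sd = np.zeros(3), np.ones(3)
            return cls(x_mean, x_sd, phi_mean, phi_sd, "tracks")
        x_mean = x.mean(axis=0)
        x_sd = np.where(x.std(axis=0) > 1e-12, x.std(axis=0), 1.0)
        return cls(x_mean, x_sd, phi_mean, phi_sd, "flat")

    def transform_x(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "tracks":
            ind = x[..., 3:4]
            z = (x[..., :3] - self.x_mean) / self.x_sd
            return np.concatenate([z * ind, ind], axis=-1)
        return (x - self.x_mean) / self.x_sd

    def transform_phi(self, phi: np.ndarray) -> np.ndarray:
        return (phi - self.phi_mean) / self.phi_sd

    def inverse_phi(self, z: np.ndarray) -> np.ndarray:
        return z * self.phi_sd + self.phi_mean

    def to_dict(self) -> dict:
        return {
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "phi_mean": self.phi_mean.tolist(),
            "phi_sd": self.phi_sd.tolist(),
            "kind": self.kind,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(
            np.array(d["x_mean"]), np.array(d["x_sd"]),
            np.array(d["phi_mean"]), np.array(d["phi_sd"]), d["kind"],
        )


@dataclass
class TrainConfig:
    batch_size: int = 32
    max_epochs: int = 50
    learning_rate: float = 5e-4
    patience: int = 8
    mmd_weight: float = 1.0
    flow_layers: int = 6
    summary_dim: int = 8
    hidden: int = 32


def _default_summary_net(
    x: np.ndarray, summary_dim: int, hidden: int, rng: np.random.Generator
) -> Module:
    if x.ndim == 4:
        return TrajectorySummaryNet(
            summary_dim=summary_dim, conv_filters=hidden, gru_units=hidden, rng=rng
        )
    return VectorSummaryNet(x.shape[1], summary_dim, hidden=hidden, rng=rng)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


class NPEPosterior:
    """Trained summary network + conditional flow with frozen
    standardization; amortized sampling on new datasets."""

    def __init__(
        self,
        summary_net: Module,
        flow: AffineCouplingFlow,
        standardizer: Standardizer,
        history: TrainingHistory | None = None,
    ):
        self.summary_net = summary_net
        self.flow = flow
        self.standardizer = standardizer
        self.history = history or TrainingHistory()
        #: summaries of the training set (reference cloud for
        #: misspecification checks); set by train_joint
        self.reference_summaries: np.ndarray | None = None

    def summarize(self, x_raw: np.ndarray) -> np.ndarray:
        x = self.standardizer.transform_x(np.asarray(x_raw, dtype=float))
        if x.ndim in (2, 3):
            x = x[None]
        s = self.summary_net(x).data
        return s[0] if s.shape[0] == 1 else s

    def sample(self, x_raw: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` posterior samples on the original (log10) scale."""
        if n == 0:
            return np.empty((0, self.flow.dim))
        s = np.atleast_2d(self.summarize(x_raw))
        z = self.flow.sample(n, s[0], rng)
        return self.standardizer.inverse_phi(z)

    def log_prob(self, phi: np.ndarray, x_raw: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(self.summarize(x_raw))
        phi_std = self.standardizer.transform_phi(np.atleast_2d(phi))
        ctx = np.broadcast_to(s[0], (len(phi_std), s.shape[1]))
        lp = self.flow.log_prob(Tensor(phi_std), Tensor(ctx)).data
        return lp - np.log(self.standardizer.phi_sd).sum()

    # ------------------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        net = self.summary_net
        if isinstance(net, TrajectorySummaryNet):
            summary_cfg = {
                "type": "tracks",
                "summary_dim": net.summary_dim,
                "conv_filters": net.conv.lin.W.shape[1],
                "gru_units": net.gru_units,
                "kernel": net.conv.kernel,
            }
        elif isinstance(net, VectorSummaryNet):
            summary_cfg = {
                "type": "flat",
                "summary_dim": net.summary_dim,
                "n_in": net.net.layers[0].W.shape[0],
                "hidden": net.net.layers[0].W.shape[1],
            }
        else:
            raise TypeError("cannot serialize custom summary networks")
        cfg = {
            "standardizer": self.standardizer.to_dict(),
            "summary": summary_cfg,
            "flow_layers": len(self.flow.masks),
            "flow_dim": self.flow.dim,
            "flow_hidden": self.flow.conditioners[0].layers[0].W.shape[1],
            "context_dim": self.flow.context_dim,
            "history": {
                "train_loss": self.history.train_loss,
                "val_loss": self.history.val_loss,
                "best_epoch": self.history.best_epoch,
            },
        }
        (directory / "config.json").write_text(json.dumps(cfg, indent=2))
        arrays = self.summary_net.state_arrays() + self.flow.state_arrays()
        np.savez(directory / "weights.npz", *arrays)
        if self.reference_summaries is not None:
            np.savetxt(directory / "reference_summaries.csv",
                       self.reference_summaries, delimiter=",")

    @classmethod
    def load(cls, directory: str | Path) -> "NPEPosterior":
        directory = Path(directory)
        cfg = json.loads((directory / "config.json").read_text())
        rng = np.random.default_rng(0)
        s = cfg["summary"]
        if s["type"] == "tracks":
            net: Module = TrajectorySummaryNet(
                summary_dim=s["summary_dim"], conv_filters=s["conv_filters"],
                gru_units=s["gru_units"], kernel=s["kernel"], rng=rng,
            )
        else:
            net = VectorSummaryNet(s["n_in"], s["summary_dim"],
                                   hidden=s["hidden"], rng=rng)
        flow = AffineCouplingFlow(
            cfg["flow_dim"], cfg["context_dim"], n_layers=cfg["flow_layers"],
            hidden=cfg["flow_hidden"], rng=rng,
        )
        with np.load(directory / "weights.npz") as z:
            arrays = [z[k] for k in z.files]
        n_sum = len(net.state_arrays())
        net.load_state_arrays(arrays[:n_sum])
        flow.load_state_arrays(arrays[n_sum:])
        hist = TrainingHistory(**cfg.get("history", {}))
        post = cls(net, flow, Standardizer.from_dict(cfg["standardizer"]), hist)
        ref = directory / "reference_summaries.csv"
        if ref.exists():
            post.reference_summaries = np.loadtxt(ref, delimiter=",")
        return post


def _iterate_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _nll_loss(
    summary_net: Module,
    flow: AffineCouplingFlow,
    x: np.ndarray,
    phi_std: np.ndarray,
    mmd_weight: float,
    rng: np.random.Generator | None,
) -> Tensor:
    s = summary_net(x)
    loss = (-flow.log_prob(Tensor(phi_std), s)).mean()
    if mmd_weight > 0 and rng is not None:
        ref = rng.standard_normal((len(phi_std), s.shape[1]))
        loss = loss + mmd_weight * gaussian_mmd(s, ref)
    return loss


def train_joint(
    train_pairs: tuple[np.ndarray, np.ndarray],
    val_pairs: tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
    rng: np.random.Generator | None = None,
    summary_net: Module | None = None,
    flow: AffineCouplingFlow | None = None,
) -> NPEPosterior:
    """Jointly train the summary network and conditional flow.

    ``train_pairs``/``val_pairs`` are ``(X, phi)`` with X of shape
    (S, n_cells, t_max, 4) for trajectory data or (S, F) for flat data.
    Standardization constants come from the validation set; early stopping
    restores the weights of the best validation epoch.
    """
    config = config or TrainConfig()
    rng = rng or np.random.default_rng(0)
    x_train, phi_train = train_pairs
    x_val, phi_val = val_pairs
    if len(x_train) < config.batch_size:
        raise ValueError("training set smaller than one batch")

    std = Standardizer.fit(np.asarray(x_val, float), np.asarray(phi_val, float))
    xt = std.transform_x(np.asarray(x_train, float))
    xv = std.transform_x(np.asarray(x_val, float))
    pt = std.transform_phi(np.asarray(phi_train, float))
    pv = std.transform_phi(np.asarray(phi_val, float))

    summary_net = summary_net or _default_summary_net(
        xt, config.summary_dim, config.hidden, rng
    )
    flow = flow or AffineCouplingFlow(
        pt.shape[1], config.summary_dim, n_layers=config.flow_layers,
        hidden=config.hidden, rng=rng,
    )
    params = summary_net.parameters() + flow.parameters()
    opt = Adam(params, lr=config.learning_rate)
    history = TrainingHistory()
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    bad_epochs = 0

    for epoch in range(config.max_epochs):
        lr = cosine_lr(config.learning_rate, epoch, config.max_epochs)
        ep_losses = []
        for idx in _iterate_batches(len(xt), config.batch_size, rng):
            for p in params:
                p.zero_grad()
            loss = _nll_loss(summary_net, flow, xt[idx], pt[idx],
                             config.mmd_weight, rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            loss.backward()
            opt.step(lr=lr)
            ep_losses.append(float(loss.data))
        val_nll = float(
            _nll_loss(summary_net, flow, xv, pv, 0.0, None).data
        )
        history.train_loss.append(float(np.mean(ep_losses)))
        history.val_loss.append(val_nll)
        if val_nll < best_val - 1e-6:
            best_val = val_nll
            best_state = [a.copy() for a in summary_net.state_arrays()] + [
                a.copy() for a in flow.state_arrays()
            ]
            history.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    if best_state is not None:
        n_sum = len(summary_net.state_arrays())
        summary_net.load_state_arrays(best_state[:n_sum])
        flow.load_state_arrays(best_state[n_sum:])

    post = NPEPosterior(summary_net, flow, std, history)
    # reference summary cloud for misspecification checks
    chunks = [
        summary_net(xt[i : i + 256]).data for i in range(0, len(xt), 256)
    ]
    post.reference_summaries = np.concatenate(chunks, axis=0)
    return post


class PosteriorMeanNet:
    """MSE-trained point predictor; output = posterior-mean estimate of
    phi, also usable as ABC summary statistics (ABC-PM)."""

    def __init__(self, summary_net: Module, standardizer: Standardizer,
                 history: TrainingHistory):
        self.summary_net = summary_net
        self.standardizer = standardizer
        self.history = history

    def predict(self, x_raw: np.ndarray) -> np.ndarray:
        x = self.standardizer.transform_x(np.asarray(x_raw, dtype=float))
        if x.ndim in (2, 3):
            x = x[None]
        out = self.standardizer.inverse_phi(self.summary_net(x).data)
        return out[0] if out.shape[0] == 1 else out

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        net = self.summary_net
        if isinstance(net, TrajectorySummaryNet):
            summary_cfg = {
                "type": "tracks", "summary_dim": net.summary_dim,
                "conv_filters": net.conv.lin.W.shape[1],
                "gru_units": net.gru_units, "kernel": net.conv.kernel,
            }
        elif isinstance(net, VectorSummaryNet):
            summary_cfg = {
                "type": "flat", "summary_dim": net.summary_dim,
                "n_in": net.net.layers[0].W.shape[0],
                "hidden": net.net.layers[0].W.shape[1],
            }
        else:
            raise TypeError("cannot serialize custom summary networks")
        cfg = {"standardizer": self.standardizer.to_dict(),
               "summary": summary_cfg}
        (directory / "config.json").write_text(json.dumps(cfg, indent=2))
        np.savez(directory / "weights.npz", *net.state_arrays())

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorMeanNet":
        directory = Path(directory)
        cfg = json.loads((directory / "config.json").read_text())
        s = cfg["summary"]
        rng = np.random.default_rng(0)
        if s["type"] == "tracks":
            net: Module = TrajectorySummaryNet(
                summary_dim=s["summary_dim"], conv_filters=s["conv_filters"],
                gru_units=s["gru_units"], kernel=s["kernel"], rng=rng,
            )
        else:
            net = VectorSummaryNet(s["n_in"], s["summary_dim"],
                                   hidden=s["hidden"], rng=rng)
        with np.load(directory / "weights.npz") as z:
            net.load_state_arrays([z[k] for k in z.files])
        return cls(net, Standardizer.from_dict(cfg["standardizer"]),
                   TrainingHistory())


def train_posterior_mean(
    train_pairs: tuple[np.ndarray, np.ndarray],
    val_pairs: tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
    rng: np.random.Generator | None = None,
    summary_net: Module | None = None,
) -> PosteriorMeanNet:
    """Train the standalone summary network on the mean-squared-error
    objective (output dimension = dim(phi))."""
    config = config or TrainConfig()
    rng = rng or np.random.default_rng(0)
    x_train, phi_train = train_pairs
    x_val, phi_val = val_pairs
    std = Standardizer.fit(np.asarray(x_val, float), np.asarray(phi_val, float))
    xt = std.transform_x(np.asarray(x_train, float))
    xv = std.transform_x(np.asarray(x_val, float))
    pt = std.transform_phi(np.asarray(phi_train, float))
    pv = std.transform_phi(np.asarray(phi_val, float))
    dim = pt.shape[1]
    summary_net = summary_net or _default_summary_net(xt, dim, config.hidden, rng)
    params = summary_net.parameters()
    opt = Adam(params, lr=config.learning_rate)
    history = TrainingHistory()
    best_val, best_state, bad = np.inf, None, 0

    def mse(x, p):
        diff = summary_net(x) - Tensor(p)
        return (diff**2).sum(axis=1).mean()

    for epoch in range(config.max_epochs):
        lr = cosine_lr(config.learning_rate, epoch, config.max_epochs)
        ep = []
        for idx in _iterate_batches(len(xt), config.batch_size, rng):
            for p in params:
                p.zero_grad()
            loss = mse(xt[idx], pt[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite training loss")
            loss.backward()
            opt.step(lr=lr)
            ep.append(float(loss.data))
        val = float(mse(xv, pv).data)
        history.train_loss.append(float(np.mean(ep)))
        history.val_loss.append(val)
        if val < best_val - 1e-6:
            best_val, bad = val, 0
            best_state = [a.copy() for a in summary_net.state_arrays()]
            history.best_epoch = epoch
        else:
            bad += 1
            if bad >= config.patience:
                break
    if best_state is not None:
        summary_net.load_state_arrays(best_state)
    return PosteriorMeanNet(summary_net, std, history)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------
class NPEEnsemble:
    """Pool of independently trained NPE members (default 3).

    Samples are pooled with equal shares (remainders go to the first
    members), yielding more conservative posterior estimates.
    """

    def __init__(self, members: list[NPEPosterior]):
        if len(members) < 2:
            raise ValueError("an ensemble needs at least 2 members")
        self.members = members

    def member_counts(self, n: int) -> list[int]:
        m = len(self.members)
        base, rem = divmod(n, m)
        return [base + (1 if i < rem else 0) for i in range(m)]

    def sample(self, x_raw: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
        draws = [
            member.sample(x_raw, k, rng)
            for member, k in zip(self.members, self.member_counts(n))
            if k > 0
        ]
        return np.concatenate(draws, axis=0) if draws else np.empty((0, N_PARAMS))


def ensemble_sample(
    ensemble: NPEEnsemble, x_raw: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    return ensemble.sample(x_raw, n, rng)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------
def sbc(
    posterior_sampler,
    simulator,
    prior,
    n_datasets: int,
    posterior_draws_per_dataset: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulation-based calibration rank table.

    For each of ``n_datasets`` prior-predictive draws, the rank of the
    true parameter among ``posterior_draws_per_dataset`` posterior samples
    is recorded per coordinate.  Under a well-calibrated posterior the
    ranks are uniform on {0, ..., L}.
    ``posterior_sampler(x_raw, n, rng)`` must return an (n, dim) array.
    """
    ranks = np.empty((n_datasets, prior.dim), dtype=int)
    for i in range(n_datasets):
        phi = prior.sample(1, rng)[0]
        x = simulator(phi, int(rng.integers(2**31 - 1)))
        draws = posterior_sampler(x, posterior_draws_per_dataset, rng)
        ranks[i] = (draws < phi).sum(axis=0)
    return ranks


def misspecification_check(
    summary: np.ndarray,
    reference_summaries: np.ndarray,
    quantile: float = 0.999,
) -> tuple[bool, float]:
    """Flag observations whose summary lies far outside the training
    summary cloud.

    The score is the squared Mahalanobis distance of ``summary`` from the
    reference cloud; under the latent-normality regularizer it is
    approximately chi-square with d degrees of freedom, and the flag
    raises when the score exceeds the configured quantile.
    """
    ref = np.asarray(reference_summaries, dtype=float)
    mu = ref.mean(axis=0)
    cov = np.cov(ref.T) + 1e-9 * np.eye(ref.shape[1])
    diff = np.asarray(summary, dtype=float) - mu
    score = float(diff @ np.linalg.solve(cov, diff))
    threshold = float(stats.chi2.ppf(quantile, df=ref.shape[1]))
    return score > threshold, score
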
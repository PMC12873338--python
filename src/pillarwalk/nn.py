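"""Neural building blocks for the posterior estimator.

Layers are thin containers of :class:`~pillarwalk.autodiff.Tensor`
parameters: dense layers, a same-padded 1D convolution, a gated recurrent
unit, the trajectory summary network (conv -> GRU -> temporal attention ->
cell pooling -> linear head) and a conditional affine-coupling normalizing
flow.  Training uses Adam with a cosine-decayed learning rate.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat


class Module:
    """Base class: recursively collects trainable parameters."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # ------------------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            p.data = np.asarray(a, dtype=np.float64).reshape(p.data.shape)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP(Module):
    """Dense network with ReLU hidden activations and a linear head."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        return self.layers[-1](x)


class Conv1dSame(Module):
    """Same-padded 1D convolution over the time axis of (B, T, C) input.

    The input is raw data (never requires gradients), so the convolution
    is a dense layer applied to a zero-padded stack of shifted frames.
    """

    def __init__(self, n_in: int, n_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.kernel = kernel
        self.lin = Linear(kernel * n_in, n_out, rng)

    def __call__(self, x: np.ndarray) -> Tensor:
        b, t, c = x.shape
        half = self.kernel // 2
        shifts = []
        for offset in range(-half, half + 1):
            sh = np.zeros_like(x)
            if offset < 0:
                sh[:, -offset:, :] = x[:, :offset, :]
            elif offset > 0:
                sh[:, :-offset, :] = x[:, offset:, :]
            else:
                sh = x
            shifts.append(sh)
        stacked = np.concatenate(shifts, axis=-1).reshape(b * t, self.kernel * c)
        return self.lin(Tensor(stacked)).relu().reshape(b, t, -1)


class GRU(Module):
    """Gated recurrent unit; processes (B, T, F) sequences step by step.

    The input projections of the three gates are fused into one matrix
    and applied to the whole sequence in a single matmul; the recurrent
    projections of the update and reset gates are likewise fused.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        # column blocks: [update z | reset r | candidate h]
        self.W = Tensor(_glorot(rng, n_in, 3 * n_hidden), requires_grad=True)
        self.b = Tensor(np.zeros(3 * n_hidden), requires_grad=True)
        # column blocks: [update z | reset r]
        self.U_zr = Tensor(_glorot(rng, n_hidden, 2 * n_hidden), requires_grad=True)
        self.Uh = Tensor(_glorot(rng, n_hidden, n_hidden), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        """Return the full hidden sequence (B, T, H)."""
        b, t, f = x.shape
        nh = self.n_hidden
        pre = (x.reshape(b * t, f) @ self.W + self.b).reshape(b, t, 3 * nh)
        return _gru_sequence(pre, self.U_zr, self.Uh, nh)


def _gru_sequence(pre: Tensor, U_zr: Tensor, Uh: Tensor, nh: int) -> Tensor:
    """Run the GRU recurrence over pre-projected inputs.

    ``pre`` has shape (B, T, 3H) with column blocks [z | r | candidate].
    Forward and backward (truncated-nothing BPTT) are hand-vectorized as a
    single graph node, which avoids building T sub-graphs per call.
    """
    p = pre.data
    b, t, _ = p.shape
    uzr = U_zr.data
    uh = Uh.data
    h = np.zeros((b, nh))
    hs = np.empty((b, t, nh))
    cache = []
    for step in range(t):
        zr = 1.0 / (1.0 + np.exp(-(p[:, step, : 2 * nh] + h @ uzr)))
        z, r = zr[:, :nh], zr[:, nh:]
        rh = r * h
        hb = np.tanh(p[:, step, 2 * nh :] + rh @ uh)
        h_prev = h
        h = (1.0 - z) * h + z * hb
        hs[:, step] = h
        cache.append((h_prev, zr, hb, rh))

    def backward(g):
        dpre = np.empty_like(p) if pre.requires_grad else None  # fully overwritten
        duzr = np.zeros_like(uzr)
        duh = np.zeros_like(uh)
        dh = np.zeros((b, nh))
        for step in range(t - 1, -1, -1):
            h_prev, zr, hb, rh = cache[step]
            z, r = zr[:, :nh], zr[:, nh:]
            dh = dh + g[:, step]
            dz = dh * (hb - h_prev)
            dhb = dh * z
            dh_prev = dh * (1.0 - z)
            da_h = dhb * (1.0 - hb**2)
            drh = da_h @ uh.T
            duh += rh.T @ da_h
            dr = drh * h_prev
            dh_prev += drh * r
            da_zr = np.concatenate([dz, dr], axis=1) * zr * (1.0 - zr)
            duzr += h_prev.T @ da_zr
            dh_prev += da_zr @ uzr.T
            if dpre is not None:
                dpre[:, step, : 2 * nh] = da_zr
                dpre[:, step, 2 * nh :] = da_h
            dh = dh_prev
        if pre.requires_grad:
            pre._accum(dpre)
        if U_zr.requires_grad:
            U_zr._accum(duzr)
        if Uh.requires_grad:
            Uh._accum(duh)

    return Tensor._make(hs, (pre, U_zr, Uh), backward)


class TrajectorySummaryNet(Module):
    """Permutation-invariant summary network for trajectory tensors.

    Input: standardized arrays ``x`` of shape (B, N, T, 4) with channels
    (x, y, t, observed-indicator); channels are zero wherever the
    indicator is zero.  Per cell: conv (kernel 3) -> GRU.  A global query
    vector (the masked average of GRU outputs across all cells and times)
    attends over each cell's time steps; attention-pooled cell vectors are
    mean-pooled across observed cells and mapped to ``summary_dim``.
    """

    def __init__(
        self,
        summary_dim: int = 8,
        n_channels: int = 4,
        conv_filters: int = 32,
        gru_units: int = 32,
        kernel: int = 3,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.summary_dim = summary_dim
        self.conv = Conv1dSame(n_channels, conv_filters, kernel, rng)
        self.gru = GRU(conv_filters, gru_units, rng)
        self.head = MLP([gru_units, gru_units, summary_dim], rng)
        self.gru_units = gru_units

    def __call__(self, x: np.ndarray) -> Tensor:
        if x.ndim == 3:
            x = x[None]
        b, n, t, c = x.shape
        mask = x[..., -1]  # (B, N, T) observation indicator
        feats = self.conv(x.reshape(b * n, t, c))  # (B*N, T, F)
        hidden = self.gru(feats)  # (B*N, T, U)
        u = self.gru_units
        hidden = hidden.reshape(b, n, t, u)

        counts = np.maximum(mask.sum(axis=(1, 2)), 1.0)  # (B,)
        mask4 = mask[..., None]
        query = (hidden * mask4).sum(axis=2).sum(axis=1) * Tensor(
            1.0 / counts[:, None]
        )  # (B, U)

        scores = (hidden * query.reshape(b, 1, 1, u)).sum(axis=3) * (
            1.0 / math.sqrt(u)
        )  # (B, N, T)
        neg = (1.0 - mask) * (-1e9)
        attn = (scores + neg).softmax(axis=2)
        pooled = (hidden * attn.reshape(b, n, t, 1)).sum(axis=2)  # (B, N, U)

        alive = (mask.sum(axis=2) > 0).astype(float)  # (B, N)
        n_alive = np.maximum(alive.sum(axis=1), 1.0)
        cells = (pooled * alive[..., None]).sum(axis=1) * Tensor(
            1.0 / n_alive[:, None]
        )  # (B, U)
        return self.head(cells)


class VectorSummaryNet(Module):
    """Dense summary network for flat (B, F) data (toy problems)."""

    def __init__(self, n_in: int, summary_dim: int, hidden: int = 32,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.summary_dim = summary_dim
        self.net = MLP([n_in, hidden, hidden, summary_dim], rng)

    def __call__(self, x: np.ndarray) -> Tensor:
        if x.ndim == 1:
            x = x[None]
        return self.net(Tensor(x))


class AffineCouplingFlow(Module):
    """Conditional normalizing flow with affine coupling layers.

    Each layer leaves a binary-masked half of the coordinates unchanged
    and applies an affine map to the complement whose scale and shift are
    produced by a conditioner network fed with the masked half and the
    conditioning summary vector.  The scale is tanh-bounded for stability.
    The forward map sends parameters to a standard-normal latent;
    inversion is exact, so sampling is a closed-form inverse pass.
    """

    LOG_SCALE_CAP = 3.0

    def __init__(
        self,
        dim: int,
        context_dim: int,
        n_layers: int = 6,
        hidden: int = 32,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.dim = dim
        self.context_dim = context_dim
        self.masks = [
            (np.arange(dim) % 2 == (layer % 2)).astype(float)
            for layer in range(n_layers)
        ]
        self.conditioners = [
            MLP([dim + context_dim, hidden, hidden, 2 * dim], rng)
            for _ in range(n_layers)
        ]

    def _scale_shift(self, x_masked: Tensor, context: Tensor, layer: int,
                     mask: np.ndarray) -> tuple[Tensor, Tensor]:
        h = self.conditioners[layer](concat([x_masked, context], axis=1))
        raw_s = h[:, : self.dim]
        t = h[:, self.dim :]
        cap = self.LOG_SCALE_CAP
        log_s = raw_s.tanh() * cap * (1.0 - mask)
        t = t * (1.0 - mask)
        return log_s, t

    def forward(self, phi: Tensor, context: Tensor) -> tuple[Tensor, Tensor]:
        """Map parameters to latent; returns (z, log_det) with log_det of
        shape (B,)."""
        x = phi
        logdet = Tensor(np.zeros(phi.shape[0]))
        for layer, mask in enumerate(self.masks):
            x_masked = x * mask
            log_s, t = self._scale_shift(x_masked, context, layer, mask)
            x = x_masked + (1.0 - mask) * (x * log_s.exp() + t)
            logdet = logdet + log_s.sum(axis=1)
        return x, logdet

    def inverse(self, z: np.ndarray, context: np.ndarray) -> np.ndarray:
        """Exact inverse pass (pure numpy; no gradients needed)."""
        x = np.asarray(z, dtype=float)
        ctx = Tensor(np.asarray(context, dtype=float))
        for layer in reversed(range(len(self.masks))):
            mask = self.masks[layer]
            x_masked = x * mask
            log_s, t = self._scale_shift(Tensor(x_masked), ctx, layer, mask)
            x = x_masked + (1.0 - mask) * ((x - t.data) * np.exp(-log_s.data))
        return x

    def log_prob(self, phi: Tensor, context: Tensor) -> Tensor:
        """log q(phi | context) via the change of variables formula."""
        z, logdet = self.forward(phi, context)
        log_base = (z**2).sum(axis=1) * (-0.5) - 0.5 * self.dim * math.log(
            2 * math.pi
        )
        return log_base + logdet

    def sample(self, n: int, context: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        context = np.asarray(context, dtype=float)
        if context.ndim == 1:
            context = np.broadcast_to(context, (n, context.size))
        z = rng.standard_normal((n, self.dim))
        return self.inverse(z, context)


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------
class Adam:
    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(initial_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine-decayed learning rate."""
    frac = min(epoch / max(total_epochs, 1), 1.0)
    return initial_lr * 0.5 * (1.0 + math.cos(math.pi * frac))


def gaussian_mmd(samples: Tensor, reference: np.ndarray) -> Tensor:
    """Biased Gaussian-kernel MMD^2 between a batch of summary vectors and
    reference draws (used to regularize the summary latent space toward a
    standard normal).  Kernel bandwidth = summary dimension."""
    d = samples.shape[1]
    sigma2 = float(d)

    def _k(a: Tensor, b: Tensor) -> Tensor:
        a2 = (a**2).sum(axis=1)  # (n,)
        b2 = (b**2).sum(axis=1)  # (m,)
        ab = a @ b.transpose()
        sq = a2.reshape(-1, 1) + b2.reshape(1, -1) - 2.0 * ab
        return (sq * (-1.0 / (2.0 * sigma2))).exp()

    ref = Tensor(np.asarray(reference, dtype=float))
    kxx = _k(samples, samples).mean()
    kyy = _k(ref, ref).mean()
    kxy = _k(samples, ref).mean()
    return kxx + kyy - 2.0 * kxy
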
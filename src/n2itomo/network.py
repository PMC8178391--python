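"""Simplified mixed-scale dense (MS-D) denoising network, CPU-native.

The architecture follows the mixed-scale dense design in a reduced form that
is fully specified here: every hidden layer produces a *single* feature map
from a 3x3 dilated convolution over *all* previous feature maps plus the
input channels (dense connectivity), adds a bias and applies a ReLU; the
dilation of hidden layer ``i`` cycles through ``1..dilation_cycle``.  The
output layer is a 1x1 linear map over every feature map and input channel.
Dense connectivity with width-1 layers keeps the parameter count tiny
(~5.5e4 at depth 100 with 11 input channels) while the cycled dilations give
a large receptive field, which is what makes the architecture hard to
overfit to noise.

Convolutions use reflection padding (mirror about the boundary pixel,
excluding the edge itself); a ``periodic`` padding mode exists as a test
hook for translation-equivariance checks, and ``linear_activations`` turns
every ReLU into the identity, making the whole forward pass a linear
operator.

Forward and backward passes are hand-written and compiled with numba; the
backward pass is the exact transpose of the forward computation including
the padding (border gradients are folded back onto their interior sources),
verified against finite differences in the test suite.  Applied with a fixed
thread count (numba kernels here are single-threaded), the forward pass is
bitwise deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "ModelConfig",
    "NormalizationStats",
    "DenoisingModel",
    "build_msd",
    "count_parameters",
    "msd_parameter_count",
    "assemble_25d_input",
    "apply_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture knobs: depth, channel counts, dilation cycle, init seed."""

    depth: int
    in_channels: int = 1
    out_channels: int = 1
    dilation_cycle: int = 10
    weight_init_seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.dilation_cycle < 1:
            raise ValueError("dilation_cycle must be >= 1")

    def dilation(self, layer: int) -> int:
        """Dilation of hidden layer ``layer`` (1-based): cycles 1..dilation_cycle."""
        return (layer - 1) % self.dilation_cycle + 1


@dataclass
class NormalizationStats:
    """Affine maps applied around the network (robust 1%-99% range to [0,1])."""

    input_offset: float = 0.0
    input_scale: float = 1.0
    output_offset: float = 0.0
    output_scale: float = 1.0

    def __post_init__(self):
        if self.input_scale == 0 or self.output_scale == 0:
            raise ValueError("normalization scales must be nonzero")

    @classmethod
    def from_data(cls, inputs: np.ndarray, targets: np.ndarray) -> "NormalizationStats":
        i_lo, i_hi = np.percentile(inputs, [1.0, 99.0])
        o_lo, o_hi = np.percentile(targets, [1.0, 99.0])
        return cls(
            input_offset=float(i_lo),
            input_scale=float(max(i_hi - i_lo, 1e-12)),
            output_offset=float(o_lo),
            output_scale=float(max(o_hi - o_lo, 1e-12)),
        )


# ---------------------------------------------------------------------------
# numba kernels (float32, contiguous padded buffers)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _conv_fwd(Z, n_prev, W, b, d, P, out):
    """out[b,i,j] = bias + sum_m sum_ky,kx W[m,ky,kx] * Z[b,m,P+i+(ky-1)d, P+j+(kx-1)d]."""
    B = Z.shape[0]
    N = out.shape[1]
    for bb in range(B):
        for i in range(N):
            for j in range(N):
                out[bb, i, j] = b
    for bb in range(B):
        for m in range(n_prev):
            w00 = W[m, 0, 0]
            w01 = W[m, 0, 1]
            w02 = W[m, 0, 2]
            w10 = W[m, 1, 0]
            w11 = W[m, 1, 1]
            w12 = W[m, 1, 2]
            w20 = W[m, 2, 0]
            w21 = W[m, 2, 1]
            w22 = W[m, 2, 2]
            for i in range(N):
                r0 = Z[bb, m, P + i - d]
                r1 = Z[bb, m, P + i]
                r2 = Z[bb, m, P + i + d]
                o = out[bb, i]
                for j in range(N):
                    jj = P + j
                    o[j] += (
                        w00 * r0[jj - d]
                        + w01 * r0[jj]
                        + w02 * r0[jj + d]
                        + w10 * r1[jj - d]
                        + w11 * r1[jj]
                        + w12 * r1[jj + d]
                        + w20 * r2[jj - d]
                        + w21 * r2[jj]
                        + w22 * r2[jj + d]
                    )


@njit(cache=True, fastmath=True)
def _conv_bwd_w(Z, n_prev, d, P, gs, dW):
    """dW[m,ky,kx] += sum_{b,i,j} gs[b,i,j] * Z[b,m,P+i+(ky-1)d, P+j+(kx-1)d]."""
    B = Z.shape[0]
    N = gs.shape[1]
    for m in range(n_prev):
        a00 = a01 = a02 = a10 = a11 = a12 = a20 = a21 = a22 = 0.0
        for bb in range(B):
            for i in range(N):
                r0 = Z[bb, m, P + i - d]
                r1 = Z[bb, m, P + i]
                r2 = Z[bb, m, P + i + d]
                g = gs[bb, i]
                for j in range(N):
                    gv = g[j]
                    jj = P + j
                    a00 += gv * r0[jj - d]
                    a01 += gv * r0[jj]
                    a02 += gv * r0[jj + d]
                    a10 += gv * r1[jj - d]
                    a11 += gv * r1[jj]
                    a12 += gv * r1[jj + d]
                    a20 += gv * r2[jj - d]
                    a21 += gv * r2[jj]
                    a22 += gv * r2[jj + d]
        dW[m, 0, 0] += a00
        dW[m, 0, 1] += a01
        dW[m, 0, 2] += a02
        dW[m, 1, 0] += a10
        dW[m, 1, 1] += a11
        dW[m, 1, 2] += a12
        dW[m, 2, 0] += a20
        dW[m, 2, 1] += a21
        dW[m, 2, 2] += a22


@njit(cache=True, fastmath=True)
def _conv_bwd_g(G, n_prev, W, d, P, gsp):
    """G[b,m,pi,pj] += sum_ky,kx W[m,ky,kx] * gs[pi-P-(ky-1)d, pj-P-(kx-1)d].

    gsp is gs embedded in a zero buffer of shape (B, N+4P, N+4P) at offset
    2P, so all reads are in-bounds and the loop vectorizes (gather form of
    the transposed convolution, covering the padded buffer incl. borders).
    """
    B = G.shape[0]
    M = G.shape[2]
    for bb in range(B):
        for m in range(n_prev):
            w00 = W[m, 0, 0]
            w01 = W[m, 0, 1]
            w02 = W[m, 0, 2]
            w10 = W[m, 1, 0]
            w11 = W[m, 1, 1]
            w12 = W[m, 1, 2]
            w20 = W[m, 2, 0]
            w21 = W[m, 2, 1]
            w22 = W[m, 2, 2]
            for pi in range(M):
                r0 = gsp[bb, pi + P + d]
                r1 = gsp[bb, pi + P]
                r2 = gsp[bb, pi + P - d]
                grow = G[bb, m, pi]
                for pj in range(M):
                    v = pj + P
                    grow[pj] += (
                        w00 * r0[v + d]
                        + w01 * r0[v]
                        + w02 * r0[v - d]
                        + w10 * r1[v + d]
                        + w11 * r1[v]
                        + w12 * r1[v - d]
                        + w20 * r2[v + d]
                        + w21 * r2[v]
                        + w22 * r2[v - d]
                    )


@njit(cache=True)
def _fill_borders(Z, c, iy, jx, P, N):
    """Fill the padded border of channel c from its interior via index maps."""
    B = Z.shape[0]
    M = N + 2 * P
    for bb in range(B):
        for pi in range(M):
            si = iy[pi]
            inside_i = (pi >= P) and (pi < M - P)
            for pj in range(M):
                if inside_i and (pj >= P) and (pj < M - P):
                    continue
                Z[bb, c, pi, pj] = Z[bb, c, P + si, P + jx[pj]]


@njit(cache=True)
def _fold_borders(G, c, iy, jx, P, N, out):
    """Transpose of _fill_borders: fold padded gradients onto interior sources."""
    B = G.shape[0]
    M = N + 2 * P
    for bb in range(B):
        for i in range(N):
            for j in range(N):
                out[bb, i, j] = G[bb, c, P + i, P + j]
        for pi in range(M):
            si = iy[pi]
            inside_i = (pi >= P) and (pi < M - P)
            for pj in range(M):
                if inside_i and (pj >= P) and (pj < M - P):
                    continue
                out[bb, si, jx[pj]] += G[bb, c, pi, pj]


def _index_maps(N: int, P: int, mode: str) -> np.ndarray:
    """Map padded coordinate -> interior source index, for one axis."""
    p = np.arange(N + 2 * P) - P
    if mode == "reflect":
        # mirror about the boundary excluding the edge: -1 -> 1, N -> N-2
        p = np.abs(p)
        p = np.where(p >= N, 2 * (N - 1) - p, p)
        if np.any(p < 0) or np.any(p >= N):
            raise ValueError("padding exceeds what reflection can supply")
    elif mode == "periodic":
        p = p % N
    else:
        raise ValueError(f"unknown padding mode {mode!r}")
    return p.astype(np.int64)


@dataclass
class DenoisingModel:
    """Trainable image-to-image denoiser plus its normalization statistics."""

    config: ModelConfig
    hidden_weights: list[np.ndarray]  # layer i: (in_channels + i - 1, 3, 3)
    hidden_biases: np.ndarray  # (depth,)
    out_weights: np.ndarray  # (out_channels, in_channels + depth)
    out_bias: np.ndarray  # (out_channels,)
    stats: NormalizationStats = field(default_factory=NormalizationStats)
    padding: str = "reflect"
    linear_activations: bool = False  # test hook: ReLU -> identity
    provenance: dict = field(default_factory=dict)

    # -- forward ----------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected input of shape (batch, {self.config.in_channels}, N, N), "
                f"got {x.shape}"
            )
        return np.ascontiguousarray(x)

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """Raw network forward pass on normalized data, shape (B, C_in, N, N)."""
        x = self._check_input(x)
        cfg = self.config
        B, _, N, _ = x.shape
        P = min(cfg.depth, cfg.dilation_cycle)  # largest dilation actually used
        if P > N - 1:
            raise ValueError("image too small for the configured dilations")
        C_tot = cfg.in_channels + cfg.depth
        Z = np.zeros((B, C_tot, N + 2 * P, N + 2 * P), dtype=np.float32)
        iy = _index_maps(N, P, self.padding)
        Z[:, : cfg.in_channels, P : P + N, P : P + N] = x
        for c in range(cfg.in_channels):
            _fill_borders(Z, c, iy, iy, P, N)
        for i in range(1, cfg.depth + 1):
            c = cfg.in_channels + i - 1
            d = cfg.dilation(i)
            out = np.empty((B, N, N), dtype=np.float32)
            _conv_fwd(
                Z,
                c,
                self.hidden_weights[i - 1],
                np.float32(self.hidden_biases[i - 1]),
                d,
                P,
                out,
            )
            if not self.linear_activations:
                np.maximum(out, 0.0, out=out)
            Z[:, c, P : P + N, P : P + N] = out
            _fill_borders(Z, c, iy, iy, P, N)
        interior = Z[:, :, P : P + N, P : P + N]
        y = (
            np.einsum("om,bmij->boij", self.out_weights, interior, optimize=True)
            + self.out_bias[None, :, None, None]
        ).astype(np.float32)
        if keep_cache:
            return y, (Z, iy, P)
        return y

    def backward(self, cache, grad_out: np.ndarray):
        """Gradients of a scalar loss w.r.t. all parameters.

        ``grad_out`` is dLoss/d(network output), shape (B, out_channels, N, N).
        Returns (grad_hidden_W, grad_hidden_b, grad_out_W, grad_out_b).
        """
        Z, iy, P = cache
        cfg = self.config
        B = Z.shape[0]
        N = Z.shape[2] - 2 * P
        grad_out = np.ascontiguousarray(grad_out, dtype=np.float32)
        interior = Z[:, :, P : P + N, P : P + N]
        dWout = np.einsum("boij,bmij->om", grad_out, interior, optimize=True).astype(
            np.float32
        )
        dbout = grad_out.sum(axis=(0, 2, 3)).astype(np.float32)
        G = np.zeros_like(Z)
        G[:, :, P : P + N, P : P + N] = np.einsum(
            "om,boij->bmij", self.out_weights, grad_out, optimize=True
        )
        dWh = [np.zeros_like(w) for w in self.hidden_weights]
        dbh = np.zeros(cfg.depth, dtype=np.float32)
        gbuf = np.empty((B, N, N), dtype=np.float32)
        gsp = np.zeros((B, N + 4 * P, N + 4 * P), dtype=np.float32)
        for i in range(cfg.depth, 0, -1):
            c = cfg.in_channels + i - 1
            d = cfg.dilation(i)
            _fold_borders(G, c, iy, iy, P, N, gbuf)
            if not self.linear_activations:
                act = Z[:, c, P : P + N, P : P + N]
                gbuf *= act > 0
            dbh[i - 1] = gbuf.sum()
            _conv_bwd_w(Z, c, d, P, gbuf, dWh[i - 1])
            gsp[:, 2 * P : 2 * P + N, 2 * P : 2 * P + N] = gbuf
            _conv_bwd_g(G, c, self.hidden_weights[i - 1], d, P, gsp)
        return dWh, dbh, dWout, dbout

    def parameters(self) -> list[np.ndarray]:
        return [*self.hidden_weights, self.hidden_biases, self.out_weights, self.out_bias]

    def copy(self) -> "DenoisingModel":
        return DenoisingModel(
            config=self.config,
            hidden_weights=[w.copy() for w in self.hidden_weights],
            hidden_biases=self.hidden_biases.copy(),
            out_weights=self.out_weights.copy(),
            out_bias=self.out_bias.copy(),
            stats=replace(self.stats),
            padding=self.padding,
            linear_activations=self.linear_activations,
            provenance=dict(self.provenance),
        )


def build_msd(config: ModelConfig) -> DenoisingModel:
    """Build a simplified MS-D model with deterministic He-style initialization."""
    rng = np.random.default_rng(config.weight_init_seed)
    hidden_weights = []
    for i in range(1, config.depth + 1):
        n_prev = config.in_channels + i - 1
        fan_in = 9 * n_prev
        hidden_weights.append(
            (rng.standard_normal((n_prev, 3, 3)) * np.sqrt(2.0 / fan_in)).astype(
                np.float32
            )
        )
    n_tot = config.in_channels + config.depth
    out_weights = (
        rng.standard_normal((config.out_channels, n_tot)) * np.sqrt(1.0 / n_tot)
    ).astype(np.float32)
    return DenoisingModel(
        config=config,
        hidden_weights=hidden_weights,
        hidden_biases=np.zeros(config.depth, dtype=np.float32),
        out_weights=out_weights,
        out_bias=np.zeros(config.out_channels, dtype=np.float32),
    )


def msd_parameter_count(config: ModelConfig) -> int:
    """Closed-form parameter count of the simplified MS-D architecture.

    Hidden layer i: 9*(in_channels + i - 1) weights + 1 bias; output layer:
    out_channels * (in_channels + depth) weights + out_channels biases.
    """
    c, d, o = config.in_channels, config.depth, config.out_channels
    hidden = sum(9 * (c + i - 1) + 1 for i in range(1, d + 1))
    return hidden + o * (c + d) + o


def count_parameters(model: DenoisingModel) -> int:
    """Exact count of trainable scalars in a built model."""
    return int(sum(p.size for p in model.parameters()))


def assemble_25d_input(
    volume: np.ndarray, slice_index: int, context: int
) -> np.ndarray:
    """Stack slices ``slice_index - context .. slice_index + context``.

    Out-of-range slice indices are mirror-reflected about the boundary
    excluding the edge (index -1 -> 1, index depth -> depth-2), so edge
    slices never see duplicated copies of themselves.
    """
    volume = np.asarray(volume)
    depth = volume.shape[0]
    if not (0 <= slice_index < depth):
        raise ValueError("slice_index out of range")
    if context < 0:
        raise ValueError("context must be non-negative")
    if context >= depth:
        raise ValueError("context must be smaller than the volume depth")
    idx = np.arange(slice_index - context, slice_index + context + 1)
    idx = np.abs(idx)
    idx = np.where(idx >= depth, 2 * (depth - 1) - idx, idx)
    return volume[idx]


def apply_model(model: DenoisingModel, x: np.ndarray) -> np.ndarray:
    """Normalize -> forward pass -> de-normalize; input shape (C_in, N, N)."""
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if x.shape[1] != model.config.in_channels:
        raise ValueError(
            f"input has {x.shape[1]} channels, model expects "
            f"{model.config.in_channels}"
        )
    s = model.stats
    xn = (x - s.input_offset) / s.input_scale
    y = model.forward(xn.astype(np.float32)).astype(np.float64)
    out = y * s.output_scale + s.output_offset
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite network output")
    return out[0] if squeeze else out
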
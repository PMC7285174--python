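"""Configurable end-to-end fully-convolutional 1D network.

Architecture: a raw single-lead ECG window of length ``L1`` is processed by
``N`` convolutional blocks (Conv1D with valid padding and ReLU -> max-pool of
size ``MP`` -> dropout at rate ``alpha`` during training), followed by global
max pooling (each of the ``F_N`` feature maps collapses to its maximum) and a
dense sigmoid unit emitting the diagnostic probability ``p`` with the
convention ``p -> 0`` for shockable and ``p -> 1`` for nonshockable rhythms.
Optional dense hidden layers (ReLU) between the global pool and the output
unit support comparative architectures from the literature.

Valid padding makes each block shrink the time axis: ``conv_len = L - K + 1``
and ``pooled_len = ceil(conv_len / MP)`` — a trailing remainder window
shorter than ``MP`` is pooled on its own, matching Keras same-padding
pooling; this is what keeps the deepest reference architectures (whose final
block reaches a length-1 feature map) feasible.  Global max pooling makes
the trainable-parameter count independent of ``L1``:

    params = sum_i F_i (K_i F_{i-1} + 1) + dense head,     F_0 = 1,

where the plain head contributes ``F_N + 1`` and each dense hidden layer of
width ``h`` after width ``u`` contributes ``h (u + 1)``.

All numerics are plain numpy; the forward/backward pair below is the
reference implementation used for both training and inference.  Training
runs in float32 (the customary deep-learning precision), while the public
single-op entry points default to float64 so they can be checked against
high-precision oracles.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

INIT_RANGE = 0.05  # uniform kernel initializer bound


@dataclasses.dataclass(frozen=True)
class HPConfig:
    """Hyperparameter configuration of one network."""

    n_blocks: int
    filters: tuple[int, ...]
    kernels: tuple[int, ...]
    pool_size: int = 2
    dropout: float = 0.3
    input_len: int = 625          # L1 in samples (5 s at 125 Hz)
    dense_hidden: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "filters", tuple(int(f) for f in self.filters))
        object.__setattr__(self, "kernels", tuple(int(k) for k in self.kernels))
        object.__setattr__(self, "dense_hidden", tuple(int(h) for h in self.dense_hidden))
        if len(self.filters) != self.n_blocks or len(self.kernels) != self.n_blocks:
            raise ValueError("filters and kernels must each have n_blocks entries")
        if any(f < 1 for f in self.filters) or any(k < 1 for k in self.kernels):
            raise ValueError("filter counts and kernel sizes must be >= 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.input_len < 1:
            raise ValueError("input_len must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "HPConfig":
        d = json.loads(s)
        d["filters"] = tuple(d["filters"])
        d["kernels"] = tuple(d["kernels"])
        d["dense_hidden"] = tuple(d.get("dense_hidden", ()))
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class LayerShapes:
    """Per-block feature-map lengths under valid padding and pooling."""

    conv_len: tuple[int, ...]
    pooled_len: tuple[int, ...]
    feasible: bool


def layer_shapes(config: HPConfig) -> LayerShapes:
    """Propagate the length recurrence; infeasibility is a flag, not an error."""
    conv, pooled = [], []
    length = config.input_len
    feasible = True
    for k in config.kernels:
        c = length - k + 1
        p = -(-c // config.pool_size) if c >= 1 else 0  # ceil division
        conv.append(c)
        pooled.append(p)
        if c < 1 or p < 1:
            feasible = False
        length = max(p, 0)
    return LayerShapes(tuple(conv), tuple(pooled), feasible)


def count_params(config: HPConfig) -> int:
    """Exact trainable-parameter count (independent of input length)."""
    total = 0
    prev = 1  # single ECG channel
    for f, k in zip(config.filters, config.kernels):
        total += f * (k * prev + 1)
        prev = f
    for h in config.dense_hidden:
        total += h * (prev + 1)
        prev = h
    total += prev + 1  # single sigmoid output unit
    return total


@dataclasses.dataclass
class ModelParams:
    """All trainable scalars: per-block kernels/biases and the dense head."""

    conv_w: list[np.ndarray]   # block i: (F_i, F_{i-1}, K_i)
    conv_b: list[np.ndarray]   # block i: (F_i,)
    dense_w: list[np.ndarray]  # hidden layers (h, u) then output (1, u)
    dense_b: list[np.ndarray]  # matching biases; output bias shape (1,)

    def n_scalars(self) -> int:
        arrays = self.conv_w + self.conv_b + self.dense_w + self.dense_b
        return int(sum(a.size for a in arrays))

    def copy(self) -> "ModelParams":
        return ModelParams(
            [w.copy() for w in self.conv_w],
            [b.copy() for b in self.conv_b],
            [w.copy() for w in self.dense_w],
            [b.copy() for b in self.dense_b],
        )

    def flat(self) -> list[np.ndarray]:
        return self.conv_w + self.conv_b + self.dense_w + self.dense_b


def init_params(config: HPConfig, seed: int = 0, dtype=np.float64) -> ModelParams:
    """Uniform-random kernel initialization in [-0.05, 0.05]; zero biases.

    The underlying random draw is always made in float64 so the same seed
    yields the same initialization regardless of the requested ``dtype``.
    """
    rng = np.random.default_rng(seed)
    conv_w, conv_b = [], []
    prev = 1
    for f, k in zip(config.filters, config.kernels):
        conv_w.append(rng.uniform(-INIT_RANGE, INIT_RANGE, size=(f, prev, k)).astype(dtype))
        conv_b.append(np.zeros(f, dtype=dtype))
        prev = f
    dense_w, dense_b = [], []
    for h in config.dense_hidden:
        dense_w.append(rng.uniform(-INIT_RANGE, INIT_RANGE, size=(h, prev)).astype(dtype))
        dense_b.append(np.zeros(h, dtype=dtype))
        prev = h
    dense_w.append(rng.uniform(-INIT_RANGE, INIT_RANGE, size=(1, prev)).astype(dtype))
    dense_b.append(np.zeros(1, dtype=dtype))
    return ModelParams(conv_w, conv_b, dense_w, dense_b)


# ---------------------------------------------------------------------------
# numerics
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _ws_buffer(ws: dict | None, key, shape, dtype, zero: bool = False) -> np.ndarray:
    """Fetch (or allocate) a reusable scratch array from a workspace dict.

    Fresh multi-megabyte allocations every batch are dominated by page
    faults on first touch; a per-training-run workspace amortizes them.
    """
    if ws is None:
        return np.zeros(shape, dtype=dtype) if zero else np.empty(shape, dtype=dtype)
    buf = ws.get(key)
    if buf is None or buf.shape != tuple(shape) or buf.dtype != dtype:
        buf = np.empty(shape, dtype=dtype)
        ws[key] = buf
    if zero:
        buf.fill(0)
    return buf


def _conv_forward(
    x: np.ndarray, w: np.ndarray, b: np.ndarray,
    ws: dict | None = None, block: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-activation valid convolution: (B, L, C) x (F, C, K) -> (B, Lout, F).

    One GEMM over the tap-major patch tensor; returns (z, patches) so
    backprop can reuse them.
    """
    f, c, k = w.shape
    bsz, length = x.shape[0], x.shape[1]
    lout = length - k + 1
    cols = _ws_buffer(ws, ("cols", block, bsz), (bsz, lout, k, c), x.dtype)
    for tap in range(k):
        cols[:, :, tap, :] = x[:, tap:tap + lout, :]
    wt = np.ascontiguousarray(w.transpose(0, 2, 1)).reshape(f, k * c)  # (F, K*C)
    z = cols.reshape(bsz * lout, k * c) @ wt.T
    z = z.reshape(bsz, lout, f)
    z += b
    return z, cols


def _conv_backward(
    cols: np.ndarray, w: np.ndarray, dz: np.ndarray, need_dx: bool, in_len: int,
    ws: dict | None = None, block: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Gradients of the valid convolution w.r.t. weights, bias and input."""
    bsz, lout, k, c = cols.shape
    f = w.shape[0]
    dz2 = np.ascontiguousarray(dz).reshape(bsz * lout, f)
    dw_t = (dz2.T @ cols.reshape(bsz * lout, k * c)).reshape(f, k, c)
    dw = np.ascontiguousarray(dw_t.transpose(0, 2, 1))  # back to (F, C, K)
    db = dz.sum(axis=(0, 1))
    dx = None
    if need_dx:
        wt = np.ascontiguousarray(w.transpose(0, 2, 1)).reshape(f, k * c)
        d = _ws_buffer(ws, ("dcols", block, bsz), (bsz * lout, k * c), cols.dtype)
        np.matmul(dz2, wt, out=d)
        d = d.reshape(bsz, lout, k, c)
        dx = _ws_buffer(ws, ("dx", block, bsz), (bsz, in_len, c), cols.dtype, zero=True)
        for tap in range(k):
            dx[:, tap:tap + lout, :] += d[:, :, tap, :]
    return dw, db, dx


def conv1d_block(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid-padding 1D convolution + ReLU, channels last.

    ``x``: (batch, L, C_in); ``w``: (F, C_in, K); ``b``: (F,).
    Returns (batch, L - K + 1, F).  The kernel slides without flipping
    (cross-correlation), matching the usual Conv1D convention.
    """
    k = w.shape[2]
    if x.shape[1] < k:
        raise ValueError(f"input length {x.shape[1]} shorter than kernel {k}")
    return np.maximum(_conv_forward(x, w, b)[0], 0.0)


def maxpool(x: np.ndarray, pool_size: int = 2) -> np.ndarray:
    """Nonoverlapping max pooling along the last axis.

    Output length is ``ceil(len / pool_size)``: a trailing remainder window
    shorter than ``pool_size`` contributes its own maximum (same-padding
    pooling convention).
    """
    length = x.shape[-1]
    if length < 1:
        raise ValueError("cannot pool an empty feature map")
    n_out = -(-length // pool_size)
    padded = length if length == n_out * pool_size else n_out * pool_size
    if padded != length:
        pad = np.full((*x.shape[:-1], padded - length), -np.inf, dtype=x.dtype)
        x = np.concatenate([x, pad], axis=-1)
    return x.reshape(*x.shape[:-1], n_out, pool_size).max(axis=-1)


def _pool_cl(x: np.ndarray, mp: int) -> np.ndarray:
    """Max pooling along axis 1 of a channels-last (B, L, F) map."""
    b, lc, f = x.shape
    n_out = -(-lc // mp)
    if n_out * mp != lc:
        pad = np.full((b, n_out * mp - lc, f), -np.inf, dtype=x.dtype)
        x = np.concatenate([x, pad], axis=1)
    return x.reshape(b, n_out, mp, f).max(axis=2)


def forward(config: HPConfig, params: ModelParams, windows: np.ndarray,
            chunk: int = 256) -> np.ndarray:
    """Inference pass: windows (n, L1) -> probabilities (n,) in (0, 1).

    Computed in ``chunk``-sized slices to bound intermediate memory;
    arithmetic follows the common dtype of the windows and parameters.
    """
    x = np.asarray(windows)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != config.input_len:
        raise ValueError(f"window length {x.shape[1]} != configured L1 {config.input_len}")
    shapes = layer_shapes(config)
    if not shapes.feasible:
        raise ValueError("configuration is infeasible at this input length")
    out = []
    for start in range(0, len(x), chunk):
        a = x[start:start + chunk, :, None]  # channels last: (n, L, 1)
        for w, b in zip(params.conv_w, params.conv_b):
            a = _pool_cl(conv1d_block(a, w, b), config.pool_size)
        g = a.max(axis=1)  # global max pooling -> (n, F_N)
        for wd, bd in zip(params.dense_w[:-1], params.dense_b[:-1]):
            g = np.maximum(g @ wd.T + bd, 0.0)
        z = g @ params.dense_w[-1].T + params.dense_b[-1]
        out.append(_sigmoid(z[:, 0]))
    return np.concatenate(out)


class _Cache:
    __slots__ = ("cols", "in_len", "z", "pool_arg", "drop_mask", "gmp_in",
                 "gmp_arg", "dense_in", "p")

    def __init__(self):
        self.cols, self.in_len, self.z = [], [], []
        self.pool_arg, self.drop_mask, self.dense_in = [], [], []


def forward_train(
    config: HPConfig,
    params: ModelParams,
    xb: np.ndarray,
    rng: np.random.Generator | None,
    ws: dict | None = None,
) -> tuple[np.ndarray, _Cache]:
    """Training-mode forward pass with dropout; returns probs and cache.

    Dropout is the inverted convention (surviving units scaled by
    1/(1-alpha) during training, identity at inference); pass ``rng=None``
    to disable it, which makes the pass identical to :func:`forward`.
    """
    cache = _Cache()
    a = xb[:, :, None]
    mp = config.pool_size
    for bi, (w, b) in enumerate(zip(params.conv_w, params.conv_b)):
        cache.in_len.append(a.shape[1])
        z, cols = _conv_forward(a, w, b, ws=ws, block=bi)
        cache.cols.append(cols)
        cache.z.append(z)
        r = np.maximum(z, 0.0)
        bsz, lc, f = r.shape
        n_out = -(-lc // mp)
        if n_out * mp != lc:  # pad remainder window with -inf (never the argmax)
            pad = np.full((bsz, n_out * mp - lc, f), -np.inf, dtype=r.dtype)
            r = np.concatenate([r, pad], axis=1)
        rt = r.reshape(bsz, n_out, mp, f)
        arg = rt.argmax(axis=2)                   # (B, n_out, F)
        pooled = np.take_along_axis(rt, arg[:, :, None, :], axis=2)[:, :, 0, :]
        cache.pool_arg.append(arg)
        if rng is not None and config.dropout > 0.0:
            keep = rng.uniform(size=pooled.shape) >= config.dropout
            mask = keep.astype(pooled.dtype) / pooled.dtype.type(1.0 - config.dropout)
        else:
            mask = None
        cache.drop_mask.append(mask)
        a = pooled * mask if mask is not None else pooled
    cache.gmp_in = a
    cache.gmp_arg = a.argmax(axis=1)              # (B, F_N)
    g = np.take_along_axis(a, cache.gmp_arg[:, None, :], axis=1)[:, 0, :]
    for wd, bd in zip(params.dense_w[:-1], params.dense_b[:-1]):
        cache.dense_in.append(g)
        g = np.maximum(g @ wd.T + bd, 0.0)
    cache.dense_in.append(g)
    z = g @ params.dense_w[-1].T + params.dense_b[-1]
    cache.p = _sigmoid(z[:, 0])
    return cache.p, cache


def backward(
    config: HPConfig,
    params: ModelParams,
    cache: _Cache,
    yb: np.ndarray,
    ws: dict | None = None,
) -> ModelParams:
    """Gradients of mean binary cross-entropy w.r.t. all parameters.

    Exploits dBCE/dz = p - y at the sigmoid pre-activation; max-pool and
    global-max-pool route gradients to their argmax positions.
    """
    nb = len(yb)
    grad = (cache.p - yb)[:, None] / nb  # (B, 1)
    g_dense_w, g_dense_b = [], []
    # dense chain, last to first
    g_dense_w.append(grad.T @ cache.dense_in[-1])
    g_dense_b.append(grad.sum(axis=0))
    dg = grad @ params.dense_w[-1]
    for li in range(len(params.dense_w) - 2, -1, -1):
        act = np.maximum(cache.dense_in[li] @ params.dense_w[li].T + params.dense_b[li], 0.0)
        dz = dg * (act > 0)
        g_dense_w.append(dz.T @ cache.dense_in[li])
        g_dense_b.append(dz.sum(axis=0))
        dg = dz @ params.dense_w[li]
    g_dense_w.reverse()
    g_dense_b.reverse()

    # through global max pooling: scatter to argmax positions
    da = np.zeros_like(cache.gmp_in)
    np.put_along_axis(da, cache.gmp_arg[:, None, :], dg[:, None, :], axis=1)

    g_conv_w = [None] * config.n_blocks
    g_conv_b = [None] * config.n_blocks
    mp = config.pool_size
    for i in range(config.n_blocks - 1, -1, -1):
        mask = cache.drop_mask[i]
        if mask is not None:
            da = da * mask
        # through max pool: route to argmax within each window
        z = cache.z[i]
        bsz, lc, f = z.shape
        n_out = -(-lc // mp)
        dz4 = _ws_buffer(ws, ("dz4", i, bsz), (bsz, n_out, mp, f), z.dtype, zero=True)
        np.put_along_axis(dz4, cache.pool_arg[i][:, :, None, :], da[:, :, None, :], axis=2)
        dz = dz4.reshape(bsz, n_out * mp, f)[:, :lc, :]
        dz *= z > 0  # through ReLU
        w = params.conv_w[i]
        gw, gb, da = _conv_backward(cache.cols[i], w, dz, need_dx=i > 0,
                                    in_len=cache.in_len[i], ws=ws, block=i)
        g_conv_w[i] = gw
        g_conv_b[i] = gb
    return ModelParams(g_conv_w, g_conv_b, g_dense_w, g_dense_b)


# ---------------------------------------------------------------------------
# HDF5 model store
# ---------------------------------------------------------------------------

def save_model(path: str | Path, config: HPConfig, params: ModelParams,
               meta: dict | None = None) -> None:
    """Store config (JSON attribute) and weights in an HDF5 container.

    Layout: groups ``conv/<i>/{w,b}`` (block-major) and ``dense/<j>/{w,b}``;
    round trips are bit-exact.
    """
    with h5py.File(path, "w") as f:
        f.attrs["config"] = config.to_json()
        if meta:
            f.attrs["meta"] = json.dumps(meta)
        for i, (w, b) in enumerate(zip(params.conv_w, params.conv_b)):
            g = f.create_group(f"conv/{i}")
            g.create_dataset("w", data=w)
            g.create_dataset("b", data=b)
        for j, (w, b) in enumerate(zip(params.dense_w, params.dense_b)):
            g = f.create_group(f"dense/{j}")
            g.create_dataset("w", data=w)
            g.create_dataset("b", data=b)


def load_model(path: str | Path) -> tuple[HPConfig, ModelParams, dict]:
    with h5py.File(path, "r") as f:
        config = HPConfig.from_json(f.attrs["config"])
        meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else {}
        conv_w, conv_b = [], []
        for i in range(config.n_blocks):
            conv_w.append(f[f"conv/{i}/w"][()])
            conv_b.append(f[f"conv/{i}/b"][()])
        dense_w, dense_b = [], []
        n_dense = len(config.dense_hidden) + 1
        for j in range(n_dense):
            dense_w.append(f[f"dense/{j}/w"][()])
            dense_b.append(f[f"dense/{j}/b"][()])
    return config, ModelParams(conv_w, conv_b, dense_w, dense_b), meta
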
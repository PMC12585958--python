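"""Directed graph convolutional network for dense weighted transition graphs.

Each layer processes node features through three parallel message-passing
paths — incoming, outgoing and undirected — built on the propagation
matrices of :mod:`protgram.propagation`.  A path combines a propagated
component with a shared feature transformation::

    H_path = A_path (H W_main_path) + b_main_path + H W_shared + b_shared_path

The three path outputs are blended by a learnable gating mechanism (one
score per node in ``vector`` mode, one per path in ``scalar`` mode, disabled
in ``none`` mode), a learnable per-node positional bias B_const is added to
give every n-gram a positional identity, and a residual connection precedes
a LeakyReLU activation (dropout after activation during training).

The network is small and dense, so forward and reverse passes are written
directly in numpy; gradients are analytic and validated against finite
differences in the test suite.  A linear decoder with LogSoftmax produces
class log-probabilities for the self-supervised node classification tasks;
the pre-decoder hidden output is the embedding matrix, L2-normalized on
extraction.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

GATING_MODES = ("vector", "scalar", "none")

DEFAULT_LEAKY_SLOPE = 0.01
DEFAULT_DROPOUT = 0.2


class ConfigurationError(ValueError):
    """Raised for inconsistent layer dimensions or gating configuration."""


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def log_softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise log-softmax; rows of exp(result) sum to 1."""
    shifted = logits - logits.max(axis=1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))


@dataclass
class DirectGCNParams:
    """All learnable tensors of one layer.

    Gates have shape (N, 1) in ``vector`` mode (one score per node,
    broadcast across features) and (1, 1) in ``scalar`` mode (one score per
    path).  In ``none`` mode they are fixed at 1 and excluded from training.
    ``w_res`` is None when input and output dimensions agree — the residual
    is then the identity and carries no parameters.
    """

    w_main_in: np.ndarray
    w_main_out: np.ndarray
    w_main_undir: np.ndarray
    w_shared: np.ndarray
    b_main_in: np.ndarray
    b_main_out: np.ndarray
    b_main_undir: np.ndarray
    b_shared_in: np.ndarray
    b_shared_out: np.ndarray
    b_shared_undir: np.ndarray
    gate_in: np.ndarray
    gate_out: np.ndarray
    gate_undir: np.ndarray
    b_const: np.ndarray
    gating_mode: str = "vector"
    w_res: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.gating_mode not in GATING_MODES:
            raise ConfigurationError(f"unknown gating mode {self.gating_mode!r}")
        n = self.b_const.shape[0]
        expected = {"vector": (n, 1), "scalar": (1, 1), "none": (1, 1)}[self.gating_mode]
        for g in (self.gate_in, self.gate_out, self.gate_undir):
            if g.shape != expected:
                raise ConfigurationError(
                    f"gate shape {g.shape} incompatible with {self.gating_mode!r} mode "
                    f"(expected {expected})"
                )
        if self.gating_mode == "none" and not (
            np.all(self.gate_in == 1) and np.all(self.gate_out == 1) and np.all(self.gate_undir == 1)
        ):
            raise ConfigurationError("gates must be exactly 1 in 'none' mode")

    @property
    def f_in(self) -> int:
        return self.w_main_in.shape[0]

    @property
    def f_out(self) -> int:
        return self.w_main_in.shape[1]

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        n_nodes: int,
        f_in: int,
        f_out: int,
        gating_mode: str = "vector",
    ) -> "DirectGCNParams":
        """Glorot-uniform weights, zero biases and B_const, gates at 1.

        With gates at one and B_const at zero the fresh layer is an ungated
        sum of the three paths — a plain multi-path graph convolution.
        """
        if gating_mode not in GATING_MODES:
            raise ConfigurationError(f"unknown gating mode {gating_mode!r}")
        gate_shape = (n_nodes, 1) if gating_mode == "vector" else (1, 1)
        return cls(
            w_main_in=_glorot(rng, f_in, f_out),
            w_main_out=_glorot(rng, f_in, f_out),
            w_main_undir=_glorot(rng, f_in, f_out),
            w_shared=_glorot(rng, f_in, f_out),
            b_main_in=np.zeros(f_out),
            b_main_out=np.zeros(f_out),
            b_main_undir=np.zeros(f_out),
            b_shared_in=np.zeros(f_out),
            b_shared_out=np.zeros(f_out),
            b_shared_undir=np.zeros(f_out),
            gate_in=np.ones(gate_shape),
            gate_out=np.ones(gate_shape),
            gate_undir=np.ones(gate_shape),
            b_const=np.zeros((n_nodes, f_out)),
            gating_mode=gating_mode,
            w_res=None if f_in == f_out else _glorot(rng, f_in, f_out),
        )

    def trainable(self) -> dict[str, np.ndarray]:
        out = {
            "w_main_in": self.w_main_in,
            "w_main_out": self.w_main_out,
            "w_main_undir": self.w_main_undir,
            "w_shared": self.w_shared,
            "b_main_in": self.b_main_in,
            "b_main_out": self.b_main_out,
            "b_main_undir": self.b_main_undir,
            "b_shared_in": self.b_shared_in,
            "b_shared_out": self.b_shared_out,
            "b_shared_undir": self.b_shared_undir,
            "b_const": self.b_const,
        }
        if self.gating_mode != "none":
            out.update(gate_in=self.gate_in, gate_out=self.gate_out, gate_undir=self.gate_undir)
        if self.w_res is not None:
            out["w_res"] = self.w_res
        return out


def path_message(
    h: np.ndarray,
    a_path: np.ndarray,
    w_main: np.ndarray,
    b_main: np.ndarray,
    w_shared: np.ndarray,
    b_shared: np.ndarray,
) -> np.ndarray:
    """One path's message: A (H W_main) + b_main + H W_shared + b_shared."""
    if h.shape[1] != w_main.shape[0] or h.shape[0] != a_path.shape[1]:
        raise ConfigurationError(
            f"shape mismatch: H {h.shape}, A {a_path.shape}, W {w_main.shape}"
        )
    return a_path @ (h @ w_main) + b_main + h @ w_shared + b_shared


def _gate_rows(gate: np.ndarray, node_idx: np.ndarray | None) -> np.ndarray:
    if gate.shape[0] == 1 or node_idx is None:
        return gate
    return gate[node_idx]


def layer_forward(
    h: np.ndarray,
    propset,
    params: DirectGCNParams,
    leaky_slope: float = DEFAULT_LEAKY_SLOPE,
    dropout: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
    node_idx: np.ndarray | None = None,
    cache: dict | None = None,
) -> np.ndarray:
    """Full layer: gated path sum + positional bias + residual + LeakyReLU.

    ``node_idx`` restricts per-node parameters (gates, B_const) to a
    subgraph whose propagation matrices are already induced on those nodes.
    Pass a dict as ``cache`` to collect intermediates for backpropagation.
    """
    n = h.shape[0]
    if propset.a_in.shape[0] != n:
        raise ConfigurationError("node count of H does not match propagation set")
    b_const = params.b_const if node_idx is None else params.b_const[node_idx]
    if b_const.shape[0] != n:
        raise ConfigurationError("node count of H does not match B_const")

    h_in = path_message(h, propset.a_in, params.w_main_in, params.b_main_in,
                        params.w_shared, params.b_shared_in)
    h_out = path_message(h, propset.a_out, params.w_main_out, params.b_main_out,
                         params.w_shared, params.b_shared_out)
    h_undir = path_message(h, propset.a_undir, params.w_main_undir, params.b_main_undir,
                           params.w_shared, params.b_shared_undir)

    g_in = _gate_rows(params.gate_in, node_idx)
    g_out = _gate_rows(params.gate_out, node_idx)
    g_undir = _gate_rows(params.gate_undir, node_idx)
    pre = g_undir * h_undir + g_in * h_in + g_out * h_out + b_const

    residual = h if params.w_res is None else h @ params.w_res
    z = pre + residual
    act = leaky_relu(z, leaky_slope)

    mask = None
    if training and dropout > 0.0:
        if rng is None:
            raise ConfigurationError("dropout during training requires an rng")
        mask = (rng.random(act.shape) >= dropout) / (1.0 - dropout)
        out = act * mask
    else:
        out = act

    if cache is not None:
        cache.update(
            h=h, h_in=h_in, h_out=h_out, h_undir=h_undir,
            g_in=g_in, g_out=g_out, g_undir=g_undir,
            z=z, mask=mask, node_idx=node_idx, params=params,
            propset=propset, leaky_slope=leaky_slope,
        )
    return out


def layer_backward(cache: dict, d_out: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Analytic reverse pass of :func:`layer_forward`.

    Returns (gradients keyed like ``DirectGCNParams.trainable``, dL/dH).
    Gradients of per-node parameters are returned at full size with zeros
    outside ``node_idx``.
    """
    p: DirectGCNParams = cache["params"]
    propset = cache["propset"]
    h = cache["h"]
    node_idx = cache["node_idx"]

    if cache["mask"] is not None:
        d_out = d_out * cache["mask"]
    dz = d_out * np.where(cache["z"] >= 0, 1.0, cache["leaky_slope"])

    grads: dict[str, np.ndarray] = {}
    # residual
    if p.w_res is None:
        dh = dz.copy()
    else:
        grads["w_res"] = h.T @ dz
        dh = dz @ p.w_res.T

    # positional bias
    if node_idx is None:
        grads["b_const"] = dz
    else:
        g = np.zeros_like(p.b_const)
        g[node_idx] = dz
        grads["b_const"] = g

    def scatter_gate(local: np.ndarray, full_shape: tuple[int, int]) -> np.ndarray:
        if full_shape == (1, 1):
            return np.array([[local.sum()]])
        full = np.zeros(full_shape)
        if node_idx is None:
            full[:] = local
        else:
            full[node_idx] = local
        return full

    d_w_shared = np.zeros_like(p.w_shared)
    for path, a_path, w_main in (
        ("in", propset.a_in, p.w_main_in),
        ("out", propset.a_out, p.w_main_out),
        ("undir", propset.a_undir, p.w_main_undir),
    ):
        g = cache[f"g_{path}"]
        h_path = cache[f"h_{path}"]
        d_path = g * dz
        if p.gating_mode != "none":
            local = (dz * h_path).sum(axis=1, keepdims=True)  # per-node score grad
            grads[f"gate_{path}"] = scatter_gate(local, p.__dict__[f"gate_{path}"].shape)
        # propagated component A (H W_main)
        at_d = a_path.T @ d_path
        grads[f"w_main_{path}"] = h.T @ at_d
        dh += at_d @ w_main.T
        grads[f"b_main_{path}"] = d_path.sum(axis=0)
        # shared component H W_shared
        d_w_shared += h.T @ d_path
        dh += d_path @ p.w_shared.T
        grads[f"b_shared_{path}"] = d_path.sum(axis=0)
    grads["w_shared"] = d_w_shared
    return grads, dh


# ---------------------------------------------------------------------------
# Stacked model with linear decoder
# ---------------------------------------------------------------------------

@dataclass
class DirectGCNModel:
    """Stack of layers plus a linear LogSoftmax decoder.

    ``hidden_dims`` fixes the width of every hidden layer; the input width
    is the feature dimension of H0 (identity at the base n-gram level,
    pooled parent embeddings above it).
    """

    layers: list[DirectGCNParams]
    w_dec: np.ndarray
    b_dec: np.ndarray
    leaky_slope: float = DEFAULT_LEAKY_SLOPE
    dropout: float = DEFAULT_DROPOUT
    gating_mode: str = "vector"
    config: dict = field(default_factory=dict)

    @classmethod
    def init(
        cls,
        n_nodes: int,
        f_in: int,
        hidden_dims: Sequence[int],
        n_classes: int,
        gating_mode: str = "vector",
        dropout: float = DEFAULT_DROPOUT,
        leaky_slope: float = DEFAULT_LEAKY_SLOPE,
        seed: int = 0,
    ) -> "DirectGCNModel":
        if not hidden_dims:
            raise ConfigurationError("at least one hidden layer is required")
        if n_classes < 2:
            raise ConfigurationError("decoder needs at least 2 classes")
        rng = np.random.default_rng(seed)
        dims = [f_in, *hidden_dims]
        layers = [
            DirectGCNParams.init(rng, n_nodes, dims[i], dims[i + 1], gating_mode)
            for i in range(len(hidden_dims))
        ]
        return cls(
            layers=layers,
            w_dec=_glorot(rng, dims[-1], n_classes),
            b_dec=np.zeros(n_classes),
            leaky_slope=leaky_slope,
            dropout=dropout,
            gating_mode=gating_mode,
            config={
                "n_nodes": n_nodes, "f_in": f_in, "hidden_dims": list(hidden_dims),
                "n_classes": n_classes, "gating_mode": gating_mode,
                "dropout": dropout, "leaky_slope": leaky_slope, "seed": seed,
            },
        )

    def forward(
        self,
        h0: np.ndarray,
        propset,
        training: bool = False,
        rng: np.random.Generator | None = None,
        node_idx: np.ndarray | None = None,
        caches: list | None = None,
    ) -> np.ndarray:
        """Hidden output Z (pre-decoder embeddings) after all layers."""
        h = h0
        for params in self.layers:
            cache: dict | None = {} if caches is not None else None
            h = layer_forward(
                h, propset, params,
                leaky_slope=self.leaky_slope,
                dropout=self.dropout, training=training, rng=rng,
                node_idx=node_idx, cache=cache,
            )
            if caches is not None:
                caches.append(cache)
        return h

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Per-node class log-probabilities."""
        return log_softmax(z @ self.w_dec + self.b_dec)

    def loss_and_grads(
        self,
        h0: np.ndarray,
        propset,
        labels: np.ndarray,
        mask: np.ndarray,
        training: bool = True,
        rng: np.random.Generator | None = None,
        node_idx: np.ndarray | None = None,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Masked mean NLL and gradients for every trainable tensor.

        ``labels``/``mask`` are aligned with the rows of ``h0`` (i.e. already
        restricted to the subgraph when ``node_idx`` is given).
        """
        caches: list[dict] = []
        z = self.forward(h0, propset, training=training, rng=rng, node_idx=node_idx, caches=caches)
        logits = z @ self.w_dec + self.b_dec
        logp = log_softmax(logits)
        m = np.flatnonzero(mask)
        if m.size == 0:
            raise ValueError("no labeled nodes in mask")
        loss = -logp[m, labels[m]].mean()
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite loss")

        probs = np.exp(logp)
        dlogits = np.zeros_like(logits)
        dlogits[m] = probs[m]
        dlogits[m, labels[m]] -= 1.0
        dlogits /= m.size

        grads: dict[str, np.ndarray] = {
            "decoder/w": z.T @ dlogits,
            "decoder/b": dlogits.sum(axis=0),
        }
        dh = dlogits @ self.w_dec.T
        for i in reversed(range(len(self.layers))):
            layer_grads, dh = layer_backward(caches[i], dh)
            for k, g in layer_grads.items():
                grads[f"layer{i}/{k}"] = g
        return float(loss), grads

    def trainable(self) -> dict[str, np.ndarray]:
        out = {"decoder/w": self.w_dec, "decoder/b": self.b_dec}
        for i, layer in enumerate(self.layers):
            for k, v in layer.trainable().items():
                out[f"layer{i}/{k}"] = v
        return out

    def embeddings(self, h0: np.ndarray, propset) -> np.ndarray:
        """Final hidden output with each row L2-normalized to unit norm."""
        z = self.forward(h0, propset, training=False)
        return l2_normalize_rows(z)

    # -- checkpointing -------------------------------------------------------

    def save(self, path: str | os.PathLike) -> None:
        """Single-file archive of named tensors plus the JSON config."""
        tensors = dict(self.trainable())
        for i, layer in enumerate(self.layers):
            if layer.gating_mode == "none":
                tensors[f"layer{i}/gate_in"] = layer.gate_in
                tensors[f"layer{i}/gate_out"] = layer.gate_out
                tensors[f"layer{i}/gate_undir"] = layer.gate_undir
        np.savez(path, __config__=np.frombuffer(json.dumps(self.config).encode(), dtype=np.uint8),
                 **tensors)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "DirectGCNModel":
        with np.load(path) as data:
            config = json.loads(bytes(data["__config__"]).decode())
            model = cls.init(**{k: config[k] for k in (
                "n_nodes", "f_in", "hidden_dims", "n_classes",
                "gating_mode", "dropout", "leaky_slope", "seed")})
            for name, arr in model.trainable().items():
                arr[...] = data[name]
        return model


def l2_normalize_rows(z: np.ndarray) -> np.ndarray:
    """Unit Euclidean norm per row; an all-zero row maps to the first basis vector."""
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    out = np.divide(z, norms, out=np.zeros_like(z), where=norms > 0)
    zero = np.flatnonzero(norms.ravel() == 0)
    out[zero, 0] = 1.0
    return out


class Adam:
    """Adam optimizer over a named-parameter dict (in-place updates)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads.get(k)
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
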
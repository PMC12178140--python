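"""L2-regularized graph convolutional encoder.

Each layer linearly transforms node features (H = XW), rescales every row to
a common norm c (the L2 "regularization" that equalizes node magnitudes
regardless of degree), and propagates with the symmetric-normalized
self-looped operator D_hat^{-1/2} A_hat D_hat^{-1/2}.  Node-wise this reads

    z_i = n_i / (d_i + 1) + sum_{j in N(i)} n_j / sqrt((d_i + 1)(d_j + 1)),

which equals the matrix form to numerical precision.  An ELU sits between
layers (not after the last one), and the encoder returns *all* per-layer
embeddings so the decoder can fuse multiple scales.  A "plain GCN" mode
skips the row rescaling for ablations.

Functions accept either numpy arrays (returning arrays) or autodiff
Tensors (returning Tensors), so the same code path serves contract tests
and training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graph import AdjacencyView

__all__ = [
    "EncoderConfig",
    "LayerEmbeddings",
    "init_encoder_params",
    "linear_transform",
    "l2_scale",
    "propagate",
    "grcn_forward",
]


@dataclass
class EncoderConfig:
    """Encoder hyperparameters: K layers of width hidden_dim, row norm c."""

    K: int = 2
    hidden_dim: int = 64
    c: float = 1.0
    learn_c: bool = True
    activation: str = "ELU"
    norm_eps: float = 1e-12
    l2_normalize: bool = True  # False = plain-GCN ablation

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.activation not in ("ELU", "ReLU"):
            raise ValueError("activation must be 'ELU' or 'ReLU'")


@dataclass
class LayerEmbeddings:
    """Per-layer node embedding matrices z^(1..K), row order = graph order."""

    Z_list: list[np.ndarray] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.Z_list)


def init_encoder_params(
    cfg: EncoderConfig, input_dim: int, rng: np.random.Generator
) -> dict[str, Tensor]:
    """Glorot-style weight init per layer, plus the scalar c if learnable."""
    params: dict[str, Tensor] = {}
    fan_in = input_dim
    for k in range(cfg.K):
        fan_out = cfg.hidden_dim
        scale = np.sqrt(2.0 / (fan_in + fan_out))
        params[f"W{k}"] = Tensor(
            rng.normal(0.0, scale, size=(fan_in, fan_out)), requires_grad=True
        )
        fan_in = fan_out
    params["c"] = Tensor(float(cfg.c), requires_grad=cfg.learn_c)
    return params


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def linear_transform(X, W):
    """H = XW with explicit shape checking."""
    Xd = X.data if isinstance(X, Tensor) else np.asarray(X, float)
    Wd = W.data if isinstance(W, Tensor) else np.asarray(W, float)
    if Xd.shape[1] != Wd.shape[0]:
        raise ValueError(
            f"shape mismatch: X has width {Xd.shape[1]}, W expects {Wd.shape[0]}"
        )
    if _is_tensor(X, W):
        return ad.matmul(X, W)
    return Xd @ Wd


def l2_scale(H, c, eps: float = 1e-12):
    """Rescale each row to norm c: n_i = c * h_i / (||h_i|| + eps).

    Zero rows map to zero (no NaN); nonzero rows end up with norm in
    [c - 1e-6, c] for the default eps.
    """
    cv = c.data if isinstance(c, Tensor) else float(c)
    if np.any(np.asarray(cv) <= 0):
        raise ValueError("c must be > 0")
    if _is_tensor(H, c):
        Ht = H if isinstance(H, Tensor) else Tensor(H)
        norm = ad.sqrt(ad.tsum(Ht * Ht, axis=1, keepdims=True))
        return Ht * c * (1.0 / (norm + eps)) if isinstance(c, Tensor) else Ht * (
            cv / (norm + eps)
        )
    H = np.asarray(H, float)
    norm = np.linalg.norm(H, axis=1, keepdims=True)
    return cv * H / (norm + eps)


def propagate(N, adj: AdjacencyView):
    """Z = D_hat^{-1/2} A_hat D_hat^{-1/2} N (self-looped symmetric propagation)."""
    S = adj.propagation_matrix
    Nd = N.data if isinstance(N, Tensor) else np.asarray(N, float)
    if Nd.shape[0] != S.shape[0]:
        raise ValueError(
            f"N has {Nd.shape[0]} rows but the graph has {S.shape[0]} nodes"
        )
    if isinstance(N, Tensor):
        return ad.matmul(Tensor(S), N)
    return S @ Nd


def _activate(Z, name: str):
    if isinstance(Z, Tensor):
        if name == "ELU":
            return ad.elu(Z)
        return ad.clip(Z, 0.0, np.inf)
    if name == "ELU":
        return np.where(Z > 0, Z, np.exp(np.minimum(Z, 0.0)) - 1.0)
    return np.maximum(Z, 0.0)


def grcn_forward(X, adj: AdjacencyView, params: dict, cfg: EncoderConfig):
    """Run the K-layer encoder; returns LayerEmbeddings (or Tensor list).

    Layer k computes propagate(l2_scale(act(prev) @ W_k, c)) where the
    activation applies between layers only; with cfg.l2_normalize False
    the rescaling step is skipped (plain-GCN ablation).
    """
    tensor_mode = isinstance(X, Tensor)
    prev = X
    Z_list = []
    c_raw = params.get("c", cfg.c)
    if tensor_mode and cfg.learn_c and isinstance(c_raw, Tensor):
        c = c_raw
    else:
        c = float(c_raw.data.item() if isinstance(c_raw, Tensor) else c_raw)
    for k in range(cfg.K):
        inp = prev if k == 0 else _activate(prev, cfg.activation)
        H = linear_transform(inp, params[f"W{k}"] if tensor_mode else _as_array(params[f"W{k}"]))
        N = l2_scale(H, c, cfg.norm_eps) if cfg.l2_normalize else H
        Z = propagate(N, adj)
        Zd = Z.data if isinstance(Z, Tensor) else Z
        if not np.all(np.isfinite(Zd)):
            raise FloatingPointError(f"non-finite embedding at encoder layer {k}")
        Z_list.append(Z)
        prev = Z
    if tensor_mode:
        return Z_list
    return LayerEmbeddings(Z_list=[np.asarray(Z) for Z in Z_list])


def _as_array(W):
    return W.data if isinstance(W, Tensor) else np.asarray(W, float)
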
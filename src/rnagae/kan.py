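"""KAN spline machinery, the degree-aware decoder and the multi-scale
Hadamard fusion edge scorer.

A Kolmogorov-Arnold network (KAN) layer learns one univariate function per
input-output connection, parameterized as
scale_base * SiLU(x) + scale_spline * sum_i coeff_i * B_i(x) with B-spline
bases on a fixed uniform grid; inputs outside the grid range are clamped.
The degree-aware decoder maps a node's final-layer embedding through a KAN
(or, for ablation, an MLP) to predict how many of its incident edges were
masked — an auxiliary reconstruction signal.

Edge scoring fuses per-layer embeddings of a node pair over all ordered
layer pairs via Hadamard products (width K^2 * f) and maps the fused vector
through a small ELU/sigmoid head to a probability; symmetrization averages
the two orientations so score(i, j) == score(j, i) exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "KANLayerParams",
    "FusionConfig",
    "init_kan_params",
    "init_mlp_decoder",
    "init_score_head",
    "bspline_basis",
    "kan_forward",
    "mlp_decoder_forward",
    "degree_decode",
    "multiscale_fuse",
    "fuse_pairs",
    "edge_score",
    "score_pairs",
    "spline_curves",
]


@dataclass
class KANLayerParams:
    """Parameters of one KAN layer.

    grid: the base knot vector (grid_size + 1 strictly increasing points
    spanning [-grid_range, grid_range]); order: spline degree; coeff has
    shape (in, out, grid_size + order); scale_base / scale_spline shape
    (in, out).
    """

    grid: np.ndarray
    order: int
    coeff: Tensor
    scale_base: Tensor
    scale_spline: Tensor

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid knots must be strictly increasing")
        if self.order < 1:
            raise ValueError("spline order must be >= 1")
        n_basis = len(self.grid) - 1 + self.order
        if self.coeff.shape[-1] != n_basis:
            raise ValueError(
                f"coeff last dim must be grid_size + order = {n_basis}, "
                f"got {self.coeff.shape[-1]}"
            )

    @property
    def in_dim(self) -> int:
        return self.coeff.shape[0]

    @property
    def out_dim(self) -> int:
        return self.coeff.shape[1]

    def named_params(self, prefix: str = "kan") -> dict[str, Tensor]:
        return {
            f"{prefix}.coeff": self.coeff,
            f"{prefix}.scale_base": self.scale_base,
            f"{prefix}.scale_spline": self.scale_spline,
        }


@dataclass
class FusionConfig:
    """Multi-scale fusion and scoring-head configuration.

    mode "cd" (collaborative decoder) scores the K^2-block fused vector;
    mode "rd" scores only the last-layer Hadamard product.
    """

    K: int = 2
    f: int = 64
    score_hidden: int = 64
    symmetrize: bool = True
    mode: str = "cd"

    def __post_init__(self) -> None:
        if self.mode not in ("cd", "rd"):
            raise ValueError("fusion mode must be 'cd' or 'rd'")

    @property
    def fused_width(self) -> int:
        return self.K * self.K * self.f if self.mode == "cd" else self.f


def init_kan_params(
    in_dim: int,
    out_dim: int,
    rng: np.random.Generator,
    grid_size: int = 5,
    order: int = 3,
    grid_range: float = 1.0,
) -> KANLayerParams:
    grid = np.linspace(-grid_range, grid_range, grid_size + 1)
    n_basis = grid_size + order
    coeff = rng.normal(0.0, 0.1, size=(in_dim, out_dim, n_basis))
    scale_base = rng.normal(0.0, 1.0 / np.sqrt(in_dim), size=(in_dim, out_dim))
    scale_spline = np.full((in_dim, out_dim), 1.0 / np.sqrt(in_dim))
    return KANLayerParams(
        grid=grid,
        order=order,
        coeff=Tensor(coeff, requires_grad=True),
        scale_base=Tensor(scale_base, requires_grad=True),
        scale_spline=Tensor(scale_spline, requires_grad=True),
    )


# ----------------------------------------------------------------------
def _extended_knots(grid: np.ndarray, order: int) -> np.ndarray:
    h = (grid[-1] - grid[0]) / (len(grid) - 1)
    left = grid[0] - h * np.arange(order, 0, -1)
    right = grid[-1] + h * np.arange(1, order + 1)
    return np.concatenate([left, grid, right])


def _cox_de_boor(
    xv: np.ndarray, t: np.ndarray, order: int, with_deriv: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Degree-``order`` basis values at ``xv`` over knot vector ``t`` (numpy).

    With ``with_deriv`` also returns dB/dx, derived from the degree-(order-1)
    bases of the same recursion.
    """
    x_col = xv.reshape(xv.shape + (1,))
    B = ((x_col >= t[:-1]) & (x_col < t[1:])).astype(float)
    for k in range(1, order + 1):
        if with_deriv and k == order:
            dB = k * (
                B[..., :-1] / (t[k:-1] - t[: -(k + 1)])
                - B[..., 1:] / (t[k + 1 :] - t[1:-k])
            )
        lo = t[: -(k + 1)]
        hi_l = t[k:-1]
        lo_r = t[1:-k]
        hi_r = t[k + 1 :]
        left = (x_col - lo) / (hi_l - lo)
        right = (hi_r - x_col) / (hi_r - lo_r)
        B = left * B[..., :-1] + right * B[..., 1:]
    if with_deriv:
        return B, dB
    return B


def bspline_basis(x, grid: np.ndarray, order: int):
    """Cox-de Boor B-spline basis values of degree ``order`` at ``x``.

    ``grid`` holds the base knots; it is extended by ``order`` uniformly
    spaced knots on each side for boundary support.  Output shape is
    x.shape + (len(grid) - 1 + order,).  Inside [grid[0], grid[-1]] the
    basis values sum to 1 (partition of unity).  Accepts numpy arrays or
    autodiff Tensors; in Tensor mode the whole recursion is a single
    autodiff primitive whose pullback uses the analytic derivative
    dB_k/dx = k (B_{i,k-1}/(t_{i+k}-t_i) - B_{i+1,k-1}/(t_{i+k+1}-t_{i+1})).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D knot vector")
    if order < 1:
        raise ValueError("order must be >= 1")
    t = _extended_knots(grid, order)
    tensor_mode = isinstance(x, Tensor)
    xv = x.data if tensor_mode else np.asarray(x, dtype=float)
    if not tensor_mode:
        return _cox_de_boor(xv, t, order)
    B, dB = _cox_de_boor(xv, t, order, with_deriv=True)

    def pull(g, dB=dB):
        return (g * dB).sum(axis=-1)

    return ad._op(B, [(x, pull)])


def kan_forward(x, params: KANLayerParams, clamp: bool = True):
    """Apply the KAN layer: per-connection spline + scaled base function.

    Inputs outside the grid range are clamped before spline evaluation
    (the unclamped value still feeds the SiLU base term); clamping is
    logged at debug level.  Accepts (N, in_dim) arrays or Tensors.
    """
    tensor_mode = isinstance(x, Tensor)
    xv = x.data if tensor_mode else np.asarray(x, dtype=float)
    if xv.ndim != 2 or xv.shape[1] != params.in_dim:
        raise ValueError(
            f"input width {xv.shape[-1] if xv.ndim else 0} does not match "
            f"KAN in_dim {params.in_dim}"
        )
    lo, hi = params.grid[0], params.grid[-1]
    if clamp:
        n_out = int(np.sum((xv < lo) | (xv > hi)))
        if n_out:
            logger.debug("kan_forward: clamped %d of %d inputs to grid range", n_out, xv.size)
    xt = x if tensor_mode else Tensor(xv)
    xc = ad.clip(xt, lo, hi) if clamp else xt
    B = bspline_basis(xc, params.grid, params.order)  # (N, in, nb)
    spline = ad.einsum("nib,iob->nio", B, params.coeff)
    out = ad.einsum("ni,io->no", ad.silu(xt), params.scale_base) + ad.einsum(
        "nio,io->no", spline, params.scale_spline
    )
    return out if tensor_mode else out.data


def spline_curves(params: KANLayerParams, n_points: int = 101) -> tuple[np.ndarray, np.ndarray]:
    """Sample each learned univariate function on the grid range.

    Returns (x, phi) with phi of shape (n_points, in_dim, out_dim) — handy
    for exporting the learned splines as TSV tables.
    """
    x = np.linspace(params.grid[0], params.grid[-1], n_points)
    B = bspline_basis(x, params.grid, params.order)  # (n_points, nb)
    spline = np.einsum("pb,iob->pio", B, params.coeff.data)
    s = 1.0 / (1.0 + np.exp(-x))
    base = (x * s)[:, None, None] * params.scale_base.data[None, :, :]
    return x, base + spline * params.scale_spline.data[None, :, :]


# ----------------------------------------------------------------------
def init_mlp_decoder(
    in_dim: int, rng: np.random.Generator, hidden: int = 64
) -> dict[str, Tensor]:
    """Two-layer perceptron replacing the KAN head in the MLP ablation."""
    return {
        "mlp.W1": Tensor(rng.normal(0, 1 / np.sqrt(in_dim), (in_dim, hidden)), requires_grad=True),
        "mlp.b1": Tensor(np.zeros(hidden), requires_grad=True),
        "mlp.W2": Tensor(rng.normal(0, 1 / np.sqrt(hidden), (hidden, 1)), requires_grad=True),
        "mlp.b2": Tensor(np.zeros(1), requires_grad=True),
    }


def mlp_decoder_forward(x, params: dict):
    tensor_mode = isinstance(x, Tensor)
    xt = x if tensor_mode else Tensor(np.asarray(x, float))
    h = ad.elu(ad.matmul(xt, params["mlp.W1"]) + params["mlp.b1"])
    out = ad.matmul(h, params["mlp.W2"]) + params["mlp.b2"]
    return out if tensor_mode else out.data


def degree_decode(
    z,
    params,
    dropout_p: float = 0.3,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
):
    """Predict per-node masked degree: ELU(Dropout(KAN(z_i))).

    ``params`` is either KANLayerParams or an MLP parameter dict (ablation).
    Eval mode disables dropout and is deterministic; outputs are scalars
    >= -1 (the ELU lower bound).
    """
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    tensor_mode = isinstance(z, Tensor)
    if isinstance(params, KANLayerParams):
        y = kan_forward(z if tensor_mode else np.asarray(z, float), params)
    else:
        y = mlp_decoder_forward(z, params)
    yt = y if isinstance(y, Tensor) else Tensor(y)
    if mode == "train" and dropout_p > 0:
        if rng is None:
            raise ValueError("train-mode dropout requires an rng")
        yt = ad.dropout(yt, dropout_p, rng)
    out = ad.reshape(ad.elu(yt), (yt.shape[0],))
    return out if tensor_mode else out.data


# ----------------------------------------------------------------------
def multiscale_fuse(Zi: list, Zj: list):
    """Fused pair vector: concat over ordered layer pairs (u, v) of
    z_i^(u) ⊙ z_j^(v); width K^2 * f."""
    if len(Zi) != len(Zj):
        raise ValueError("Zi and Zj must have the same number of layers")
    widths = {np.asarray(z).shape[-1] for z in list(Zi) + list(Zj)}
    if len(widths) != 1:
        raise ValueError(f"layer widths differ: {sorted(widths)}")
    K = len(Zi)
    parts = [np.asarray(Zi[u]) * np.asarray(Zj[v]) for u in range(K) for v in range(K)]
    return np.concatenate(parts, axis=-1)


def fuse_pairs(Z_list: list, ii: np.ndarray, jj: np.ndarray, mode: str = "cd"):
    """Batched fusion for index arrays ii, jj over (possibly Tensor) layers."""
    tensor_mode = isinstance(Z_list[0], Tensor)
    K = len(Z_list)
    if mode == "rd":
        Zi = Z_list[-1][ii] if tensor_mode else np.asarray(Z_list[-1])[ii]
        Zj = Z_list[-1][jj] if tensor_mode else np.asarray(Z_list[-1])[jj]
        return Zi * Zj
    parts = []
    for u in range(K):
        Zu = Z_list[u][ii] if tensor_mode else np.asarray(Z_list[u])[ii]
        for v in range(K):
            Zv = Z_list[v][jj] if tensor_mode else np.asarray(Z_list[v])[jj]
            parts.append(Zu * Zv)
    if tensor_mode:
        return ad.concat(parts, axis=1)
    return np.concatenate(parts, axis=1)


def init_score_head(
    fused_width: int, rng: np.random.Generator, hidden: int = 64
) -> dict[str, Tensor]:
    return {
        "head.W1": Tensor(rng.normal(0, 1 / np.sqrt(fused_width), (fused_width, hidden)), requires_grad=True),
        "head.b1": Tensor(np.zeros(hidden), requires_grad=True),
        "head.W2": Tensor(rng.normal(0, 1 / np.sqrt(hidden), (hidden, 1)), requires_grad=True),
        "head.b2": Tensor(np.zeros(1), requires_grad=True),
    }


def edge_score(fused, head: dict):
    """Scalar interaction probability in (0, 1) for each fused pair vector."""
    tensor_mode = isinstance(fused, Tensor)
    ft = fused if tensor_mode else Tensor(np.atleast_2d(np.asarray(fused, float)))
    if ft.shape[-1] != head["head.W1"].shape[0]:
        raise ValueError(
            f"fused width {ft.shape[-1]} does not match head input "
            f"{head['head.W1'].shape[0]}"
        )
    h = ad.elu(ad.matmul(ft, head["head.W1"]) + head["head.b1"])
    s = ad.sigmoid(ad.matmul(h, head["head.W2"]) + head["head.b2"])
    out = ad.reshape(s, (s.shape[0],))
    if tensor_mode:
        return out
    return out.data if np.asarray(fused).ndim > 1 else float(out.data[0])


def score_pairs(
    Z_list: list,
    ii: np.ndarray,
    jj: np.ndarray,
    head: dict,
    cfg: FusionConfig,
):
    """Score node-index pairs; with cfg.symmetrize the two orientations are
    averaged so the score is exactly symmetric."""
    s_ij = edge_score(fuse_pairs(Z_list, ii, jj, cfg.mode), head)
    if not cfg.symmetrize:
        return s_ij
    s_ji = edge_score(fuse_pairs(Z_list, jj, ii, cfg.mode), head)
    return (s_ij + s_ji) * 0.5
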
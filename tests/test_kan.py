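"""B-spline bases, KAN layer, degree decoder, fusion and edge scoring."""

import numpy as np
import pytest

from rnagae import autodiff as ad
from rnagae.autodiff import Adam, Tensor
from rnagae.kan import (
    FusionConfig,
    KANLayerParams,
    _extended_knots,
    bspline_basis,
    degree_decode,
    edge_score,
    fuse_pairs,
    init_kan_params,
    init_mlp_decoder,
    init_score_head,
    kan_forward,
    multiscale_fuse,
    score_pairs,
)

GRID = np.linspace(-1.0, 1.0, 6)  # grid_size 5


def _deboor_oracle(x: float, i: int, k: int, t: np.ndarray) -> float:
    """Independent scalar Cox-de Boor recursion (textbook form)."""
    if k == 0:
        return 1.0 if t[i] <= x < t[i + 1] else 0.0
    left = 0.0
    if t[i + k] != t[i]:
        left = (x - t[i]) / (t[i + k] - t[i]) * _deboor_oracle(x, i, k - 1, t)
    right = 0.0
    if t[i + k + 1] != t[i + 1]:
        right = (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * _deboor_oracle(
            x, i + 1, k - 1, t
        )
    return left + right


def test_bspline_order1_indicator_mix():
    """Degree-1 bases are the familiar hat functions: at a knot midpoint the
    two straddling hats are 1/2 each."""
    B = bspline_basis(np.array([-0.8]), GRID, 1)
    assert B.shape == (1, 6)
    assert np.allclose(B.sum(), 1.0)
    mid = (GRID[0] + GRID[1]) / 2
    B = bspline_basis(np.array([mid]), GRID, 1)
    assert np.isclose(B.max(), 0.5)


def test_bspline_partition_of_unity(rng):
    x = rng.uniform(-1.0, 1.0, size=500)
    for order in (1, 2, 3):
        B = bspline_basis(x, GRID, order)
        assert B.shape == (500, 5 + order)
        assert np.abs(B.sum(axis=-1) - 1.0).max() < 1e-9
        assert np.all(B >= -1e-12)


def test_bspline_matches_deboor_oracle(rng):
    """Vectorized bases equal the independent scalar recursion at 100 points."""
    order = 3
    t = _extended_knots(GRID, order)
    x = rng.uniform(-1.0, 1.0, size=100)
    B = bspline_basis(x, GRID, order)
    for col in range(B.shape[1]):
        expected = np.array([_deboor_oracle(xi, col, order, t) for xi in x])
        assert np.abs(B[:, col] - expected).max() < 1e-9


def test_bspline_rejects_bad_grid():
    with pytest.raises(ValueError):
        bspline_basis(np.zeros(3), np.array([0.0, 0.0, 1.0]), 3)


# ----------------------------------------------------------------------
def _kan(rng, in_dim=1, out_dim=1):
    return init_kan_params(in_dim, out_dim, rng)


def test_kan_null_map(rng):
    p = _kan(rng)
    p.scale_base = Tensor(np.zeros_like(p.scale_base.data))
    p.coeff = Tensor(np.zeros_like(p.coeff.data))
    x = rng.normal(size=(20, 1))
    assert np.allclose(kan_forward(x, p), 0.0)


def test_kan_pure_base_is_monotone_where_silu_is(rng):
    p = _kan(rng)
    p.scale_spline = Tensor(np.zeros_like(p.scale_spline.data))
    p.scale_base = Tensor(np.ones_like(p.scale_base.data))
    x = np.linspace(0.5, 3.0, 50).reshape(-1, 1)  # SiLU is increasing here
    y = kan_forward(x, p).ravel()
    assert np.all(np.diff(y) > 0)


def test_kan_width_mismatch(rng):
    p = _kan(rng, in_dim=4)
    with pytest.raises(ValueError, match="width"):
        kan_forward(np.zeros((3, 5)), p)


def test_kan_fits_sine_as_well_as_lsq_oracle(rng):
    """A single-connection KAN with least-squares spline coefficients matches
    an independent spline regression of sin(x) to the same residual."""
    order = 3
    x = np.linspace(-1, 1, 201)
    y = np.sin(np.pi * x)
    design = bspline_basis(x, GRID, order)  # (201, 8)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    oracle_resid = np.abs(design @ coef - y).max()
    p = _kan(rng)
    p.scale_base = Tensor(np.zeros((1, 1)))
    p.scale_spline = Tensor(np.ones((1, 1)))
    p.coeff = Tensor(coef.reshape(1, 1, -1))
    got = kan_forward(x.reshape(-1, 1), p).ravel()
    assert np.abs(got - y).max() <= oracle_resid + 1e-12


def test_kan_c1_smoothness(rng):
    """Finite-difference derivative matches the autodiff (analytic spline)
    derivative in the grid interior."""
    p = _kan(rng, in_dim=1)
    xs = rng.uniform(-0.9, 0.9, size=40)
    xt = Tensor(xs.reshape(-1, 1), requires_grad=True)
    ad.tsum(kan_forward(xt, p)).backward()
    h = 1e-5
    fd = (
        kan_forward((xs + h).reshape(-1, 1), p) - kan_forward((xs - h).reshape(-1, 1), p)
    ).ravel() / (2 * h)
    assert np.abs(fd - xt.grad.ravel()).max() < 1e-4


def test_kan_clamps_out_of_range(rng):
    p = _kan(rng)
    inside = kan_forward(np.array([[1.0]]), p)
    way_out = kan_forward(np.array([[50.0]]), p)
    # spline part frozen at the boundary; only the SiLU base term changes
    base = p.scale_base.data[0, 0]
    silu = lambda v: v / (1 + np.exp(-v))
    assert np.isclose(
        (way_out - inside).item(), base * (silu(50.0) - silu(1.0)), atol=1e-9
    )


# ----------------------------------------------------------------------
def test_degree_decode_contract(rng):
    p = _kan(rng, in_dim=6)
    z = rng.normal(size=(15, 6))
    out1 = degree_decode(z, p, mode="eval")
    out2 = degree_decode(z, p, mode="eval")
    assert np.array_equal(out1, out2)  # eval is deterministic
    assert out1.shape == (15,)
    assert np.all(out1 >= -1.0)  # ELU lower bound
    with pytest.raises(ValueError, match="rng"):
        degree_decode(z, p, dropout_p=0.5, mode="train")


@pytest.mark.parametrize("head", ["kan", "mlp"])
def test_degree_decoder_fits_constant_target(head, rng):
    """20 nodes with constant target 2.0: 500 Adam steps reach MSE < 0.05.
    Both decoder heads satisfy the same interface contract."""
    z = rng.normal(size=(20, 8)) * 0.5
    target = np.full(20, 2.0)
    if head == "kan":
        params = init_kan_params(8, 1, np.random.default_rng(1))
        tensors = params.named_params()
    else:
        tensors = init_mlp_decoder(8, np.random.default_rng(1))
        params = tensors
    opt = Adam(tensors, lr=0.05)
    zt = Tensor(z)
    for _ in range(500):
        opt.zero_grad()
        pred = degree_decode(zt, params, dropout_p=0.0, mode="train", rng=rng)
        diff = pred - target
        loss = ad.tmean(diff * diff)
        loss.backward()
        opt.step()
    final = degree_decode(z, params, mode="eval")
    assert np.mean((final - target) ** 2) < 0.05


# ----------------------------------------------------------------------
def test_multiscale_fuse_width_and_identity(rng):
    K, f = 2, 3
    Zi = [rng.normal(size=f) for _ in range(K)]
    Zj = [rng.normal(size=f) for _ in range(K)]
    fused = multiscale_fuse(Zi, Zj)
    assert fused.shape == (K * K * f,)
    ones = [np.ones(f)] * K
    assert np.allclose(multiscale_fuse(ones, ones), 1.0)
    with pytest.raises(ValueError, match="width"):
        multiscale_fuse([np.ones(3), np.ones(4)], [np.ones(3), np.ones(3)])


def test_multiscale_fuse_block_swap(rng):
    """fused(j, i) equals fused(i, j) with each (u, v) block moved to (v, u)."""
    K, f = 3, 4
    Zi = [rng.normal(size=f) for _ in range(K)]
    Zj = [rng.normal(size=f) for _ in range(K)]
    fij = multiscale_fuse(Zi, Zj).reshape(K, K, f)
    fji = multiscale_fuse(Zj, Zi).reshape(K, K, f)
    assert np.allclose(fji, fij.transpose(1, 0, 2))


def test_edge_score_contracts(rng):
    head = init_score_head(12, rng)
    fused = rng.normal(size=(100, 12))
    s = edge_score(fused, head)
    assert np.all((s > 0) & (s < 1))
    zero_head = {k: Tensor(np.zeros_like(v.data)) for k, v in head.items()}
    assert np.allclose(edge_score(fused, zero_head), 0.5)
    with pytest.raises(ValueError, match="width"):
        edge_score(rng.normal(size=(5, 9)), head)


def test_score_pairs_symmetrization(rng):
    K, f = 2, 5
    Z_list = [rng.normal(size=(10, f)) for _ in range(K)]
    cfg = FusionConfig(K=K, f=f, symmetrize=True)
    head = init_score_head(cfg.fused_width, rng)
    ii = np.array([0, 3, 7])
    jj = np.array([4, 1, 2])
    s1 = score_pairs(Z_list, ii, jj, head, cfg)
    s2 = score_pairs(Z_list, jj, ii, head, cfg)
    assert np.array_equal(s1, s2)  # bit-exact by averaging
    asym = FusionConfig(K=K, f=f, symmetrize=False)
    assert not np.array_equal(
        score_pairs(Z_list, ii, jj, head, asym),
        score_pairs(Z_list, jj, ii, head, asym),
    )


def test_rd_mode_uses_last_layer_only(rng):
    K, f = 2, 4
    Z_list = [rng.normal(size=(6, f)) for _ in range(K)]
    ii, jj = np.array([0, 1]), np.array([2, 3])
    fused = fuse_pairs(Z_list, ii, jj, mode="rd")
    assert fused.shape == (2, f)
    assert np.allclose(fused, Z_list[-1][ii] * Z_list[-1][jj])
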
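"""Kolmogorov-Arnold layers: learnable univariate splines on every edge.

Each layer maps ``in_dim -> out_dim`` through a sum over inputs of a
per-edge B-spline function plus a base transform (a linear map and a
SiLU-gated residual). With all spline coefficients and the SiLU weight at
zero the layer is exactly its linear base map, so a KAN degrades gracefully
to an ordinary dense layer. Layers stack by composition into a deep KAN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autodiff import Tensor, as_tensor, silu
from .splines import bspline_basis, bspline_basis_derivative, n_basis

__all__ = ["KanLayerParams", "bspline_basis", "kan_layer", "kan_stack",
           "init_kan_layer"]


@dataclass
class KanLayerParams:
    """Parameters of one Kolmogorov-Arnold layer.

    Attributes
    ----------
    grid : knots of the spline interval (strictly increasing).
    order : spline degree; coefficient count per edge is
        ``len(grid) - 1 + order``.
    coef : spline coefficients, shape (in_dim, out_dim, n_basis).
    base_weight : linear base map, shape (in_dim, out_dim).
    silu_weight : SiLU-gated residual map, shape (in_dim, out_dim).
    """

    grid: np.ndarray
    order: int
    coef: Tensor
    base_weight: Tensor
    silu_weight: Tensor
    in_dim: int = field(default=0)
    out_dim: int = field(default=0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid knots must be strictly increasing")
        if self.order < 1:
            raise ValueError("spline order must be >= 1")
        self.coef = as_tensor(self.coef)
        self.base_weight = as_tensor(self.base_weight)
        self.silu_weight = as_tensor(self.silu_weight)
        self.in_dim, self.out_dim = self.base_weight.shape
        expected = (self.in_dim, self.out_dim, n_basis(self.grid, self.order))
        if self.coef.shape != expected:
            raise ValueError(
                f"coef shape {self.coef.shape} != expected {expected}")
        for t in (self.coef, self.base_weight, self.silu_weight):
            if not np.all(np.isfinite(t.data)):
                raise ValueError("KAN parameters must be finite")

    @property
    def trainable(self) -> tuple[Tensor, ...]:
        return (self.coef, self.base_weight, self.silu_weight)


def init_kan_layer(in_dim: int, out_dim: int, rng: np.random.Generator,
                   grid: np.ndarray | None = None, order: int = 3,
                   coef_scale: float = 0.1,
                   identity: bool = False) -> KanLayerParams:
    """Create a layer with near-zero splines so early training follows the
    base map; ``identity=True`` builds an exact identity layer (square only).
    """
    if grid is None:
        grid = np.linspace(-1.0, 1.0, 6)  # 5 intervals on [-1, 1]
    nb = n_basis(np.asarray(grid), order)
    if identity:
        if in_dim != out_dim:
            raise ValueError("identity init requires in_dim == out_dim")
        base = np.eye(in_dim)
        coef = np.zeros((in_dim, out_dim, nb))
        siluw = np.zeros((in_dim, out_dim))
    else:
        base = rng.normal(0.0, 1.0 / np.sqrt(in_dim), size=(in_dim, out_dim))
        siluw = rng.normal(0.0, 1.0 / np.sqrt(in_dim), size=(in_dim, out_dim))
        coef = rng.normal(0.0, coef_scale, size=(in_dim, out_dim, nb))
    return KanLayerParams(grid=np.asarray(grid), order=order,
                          coef=Tensor(coef, requires_grad=True),
                          base_weight=Tensor(base, requires_grad=True),
                          silu_weight=Tensor(siluw, requires_grad=True))


def _spline_term(h: Tensor, params: KanLayerParams) -> Tensor:
    """sum_u spline_{v,u}(h_u) for a batch, as a custom autodiff primitive.

    Inputs are clamped to the grid range; the clamp gates the input gradient
    (zero outside the grid, where the evaluation is flat).
    """
    x = h.data
    lo, hi = params.grid[0], params.grid[-1]
    xc = np.clip(x, lo, hi)
    basis = bspline_basis(xc, params.grid, params.order)     # (n, u, K)
    coef = params.coef
    out_data = np.einsum("nuk,uvk->nv", basis, coef.data)

    def bwd(g):  # g: (n, v)
        coef._accumulate(np.einsum("nuk,nv->uvk", basis, g))
        if h.requires_grad:
            dbasis = bspline_basis_derivative(xc, params.grid, params.order)
            inside = ((x > lo) & (x < hi)).astype(np.float64)
            dx = np.einsum("nuk,uvk,nv->nu", dbasis, coef.data, g)
            h._accumulate(dx * inside)

    return Tensor.from_op(out_data, (h, coef), bwd)


def kan_layer(h: Tensor | np.ndarray, params: KanLayerParams) -> Tensor:
    """Apply one KAN layer to a batch of row vectors.

    out = h @ base_weight + silu(h) @ silu_weight + spline(h).
    """
    h = as_tensor(h)
    squeeze = h.ndim == 1
    if squeeze:
        h = h.reshape(1, -1)
    if h.shape[1] != params.in_dim:
        raise ValueError(
            f"input dim {h.shape[1]} != layer in_dim {params.in_dim}")
    out = h @ params.base_weight + silu(h) @ params.silu_weight \
        + _spline_term(h, params)
    return out.reshape(-1) if squeeze else out


def kan_stack(h: Tensor | np.ndarray,
              layers: Sequence[KanLayerParams]) -> Tensor:
    """Compose KAN layers; consecutive dimensions must chain."""
    if not layers:
        raise ValueError("need at least one layer")
    for a, b in zip(layers, layers[1:]):
        if a.out_dim != b.in_dim:
            raise ValueError(
                f"dimension chain broken: {a.out_dim} -> {b.in_dim}")
    out = as_tensor(h)
    for layer in layers:
        out = kan_layer(out, layer)
    return out


def fit_spline_1d(f, params: KanLayerParams, n_points: int = 200) -> None:
    """Least-squares fit of a 1 -> 1 layer's spline to a target function.

    Utility for inspection/tests: zeroes the base maps and solves for the
    spline coefficients that best reproduce ``f`` on the grid interval.
    """
    if params.in_dim != 1 or params.out_dim != 1:
        raise ValueError("fit_spline_1d requires a 1 -> 1 layer")
    xs = np.linspace(params.grid[0], params.grid[-1], n_points)
    basis = bspline_basis(xs, params.grid, params.order)
    target = np.asarray([f(x) for x in xs], dtype=np.float64)
    coefs, *_ = np.linalg.lstsq(basis, target, rcond=None)
    params.coef.data[0, 0, :] = coefs
    params.base_weight.data[:] = 0.0
    params.silu_weight.data[:] = 0.0
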
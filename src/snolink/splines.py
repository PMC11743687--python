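"""B-spline basis evaluation via the Cox-de Boor recursion.

The Kolmogorov-Arnold layers parameterize every edge function as a B-spline
curve; this module supplies the basis values and their first derivatives on
a uniform extended knot vector. On the interior of the grid the basis is a
partition of unity and each function has local support spanning ``order + 1``
knot intervals.
"""

from __future__ import annotations

import numpy as np

__all__ = ["extend_grid", "bspline_basis", "bspline_basis_derivative", "n_basis"]


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be a 1-D array with at least two knots")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid knots must be strictly increasing")
    return grid


def extend_grid(grid: np.ndarray, order: int) -> np.ndarray:
    """Pad the grid with ``order`` uniformly spaced knots on each side.

    The padding gives every basis function full support inside the original
    interval, so the partition of unity holds on ``[grid[0], grid[-1]]``.
    """
    grid = _check_grid(grid)
    if order < 1:
        raise ValueError("spline order must be >= 1")
    h_lo = grid[1] - grid[0]
    h_hi = grid[-1] - grid[-2]
    left = grid[0] - h_lo * np.arange(order, 0, -1)
    right = grid[-1] + h_hi * np.arange(1, order + 1)
    return np.concatenate([left, grid, right])


def n_basis(grid: np.ndarray, order: int) -> int:
    """Number of basis functions: grid intervals + order."""
    grid = _check_grid(grid)
    return (grid.size - 1) + order


def bspline_basis(x, grid: np.ndarray, order: int) -> np.ndarray:
    """All degree-``order`` B-spline basis values at ``x``.

    Parameters
    ----------
    x : scalar or array
        Evaluation points; values are clamped to ``[grid[0], grid[-1]]``.
    grid : array
        Strictly increasing knots of the base interval.
    order : int
        Spline degree (cubic by default elsewhere).

    Returns
    -------
    ndarray of shape ``x.shape + (n_basis,)``.
    """
    grid = _check_grid(grid)
    if order < 1:
        raise ValueError("spline order must be >= 1")
    knots = extend_grid(grid, order)
    x = np.asarray(x, dtype=np.float64)
    scalar = x.ndim == 0
    xf = np.clip(x.reshape(-1), grid[0], grid[-1])

    # degree 0: indicator of [knots[i], knots[i+1]); right-closed at the top
    # of the base interval so x == grid[-1] lands in the last interval.
    b = ((xf[:, None] >= knots[None, :-1]) & (xf[:, None] < knots[None, 1:])
         ).astype(np.float64)
    top = np.isclose(xf, grid[-1])
    if np.any(top):
        last = np.searchsorted(knots, grid[-1]) - 1
        b[top, :] = 0.0
        b[top, last] = 1.0

    for k in range(1, order + 1):
        left_den = knots[k:-1] - knots[:-k - 1]
        right_den = knots[k + 1:] - knots[1:-k]
        left = (xf[:, None] - knots[None, :-k - 1]) / left_den[None, :]
        right = (knots[None, k + 1:] - xf[:, None]) / right_den[None, :]
        b = left * b[:, :-1] + right * b[:, 1:]

    out = b if not scalar else b[0]
    return out if scalar else out.reshape(*x.shape, b.shape[-1])


def bspline_basis_derivative(x, grid: np.ndarray, order: int) -> np.ndarray:
    """First derivative of each basis function at ``x``.

    Uses d/dx B_{i,k} = k/(t_{i+k}-t_i) B_{i,k-1} - k/(t_{i+k+1}-t_{i+1}) B_{i+1,k-1}.
    Points outside the grid are clamped, so the derivative there reflects the
    clamped evaluation (zero slope contribution is handled by the caller).
    """
    grid = _check_grid(grid)
    if order < 2:
        raise ValueError("derivative formula requires order >= 2")
    knots = extend_grid(grid, order)
    x = np.asarray(x, dtype=np.float64)
    scalar = x.ndim == 0
    xf = np.clip(x.reshape(-1), grid[0], grid[-1])

    # degree-(order-1) basis on the same extended knots has n_basis + 1
    # functions; consecutive pairs combine into each derivative
    lower = _basis_on_knots(xf, knots, order - 1, grid)
    den_l = knots[order:-1] - knots[:-order - 1]
    den_r = knots[order + 1:] - knots[1:-order]
    deriv = order * (lower[:, :-1] / den_l[None, :]
                     - lower[:, 1:] / den_r[None, :])
    out = deriv if not scalar else deriv[0]
    return out if scalar else out.reshape(*x.shape, deriv.shape[-1])


def _basis_on_knots(xf: np.ndarray, knots: np.ndarray, degree: int,
                    grid: np.ndarray) -> np.ndarray:
    """Cox-de Boor on an explicit extended knot vector (flat x only)."""
    b = ((xf[:, None] >= knots[None, :-1]) & (xf[:, None] < knots[None, 1:])
         ).astype(np.float64)
    top = np.isclose(xf, grid[-1])
    if np.any(top):
        last = np.searchsorted(knots, grid[-1]) - 1
        b[top, :] = 0.0
        b[top, last] = 1.0
    for k in range(1, degree + 1):
        left_den = knots[k:-1] - knots[:-k - 1]
        right_den = knots[k + 1:] - knots[1:-k]
        b = ((xf[:, None] - knots[None, :-k - 1]) / left_den[None, :] * b[:, :-1]
             + (knots[None, k + 1:] - xf[:, None]) / right_den[None, :] * b[:, 1:])
    return b
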
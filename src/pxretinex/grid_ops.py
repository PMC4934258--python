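"""Discrete differential operators on regular pixel grids.

All solver stages share a single discretization: forward differences for the
gradient, the exact negative adjoint (backward differences) for the
divergence, so that ``div_backward(grad_forward(u))`` is the 5-point
Laplacian with replicate (homogeneous Neumann) boundary values.  The grid
spacing is 1 and the ``x`` component runs along columns (axis 1), ``y``
along rows (axis 0).

A periodic-boundary operator set is provided for the optional FFT solve of
the elliptic subproblem; it is not used by the Gauss-Seidel path.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np


class Gradient(NamedTuple):
    """Pair of scalar fields holding the x (column) and y (row) components."""

    x: np.ndarray
    y: np.ndarray

    @property
    def shape(self):
        return self.x.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.x, self.y)


def as_field(u, min_size: int = 2) -> np.ndarray:
    """Validate a 2-D scalar field: finite, at least ``min_size`` per axis."""
    u = np.asarray(u, dtype=float)
    if u.ndim != 2:
        raise ValueError(f"expected a 2-D field, got shape {u.shape}")
    if u.shape[0] < min_size or u.shape[1] < min_size:
        raise ValueError(f"field too small for differential operators: {u.shape}")
    if not np.all(np.isfinite(u)):
        raise ValueError("field contains non-finite values")
    return u


def _check_gradient(g: Gradient) -> Gradient:
    gx = np.asarray(g.x, dtype=float)
    gy = np.asarray(g.y, dtype=float)
    if gx.shape != gy.shape:
        raise ValueError(f"gradient components disagree: {gx.shape} vs {gy.shape}")
    if not (np.all(np.isfinite(gx)) and np.all(np.isfinite(gy))):
        raise ValueError("gradient contains non-finite values")
    return Gradient(gx, gy)


def grad_forward(u) -> Gradient:
    """Forward-difference gradient; last row/column of each component is 0."""
    u = as_field(u)
    gx = np.zeros_like(u)
    gy = np.zeros_like(u)
    gx[:, :-1] = u[:, 1:] - u[:, :-1]
    gy[:-1, :] = u[1:, :] - u[:-1, :]
    return Gradient(gx, gy)


def div_backward(g: Gradient) -> np.ndarray:
    """Backward-difference divergence, the exact negative adjoint of
    :func:`grad_forward`: ``<grad u, g> = -<u, div g>`` for all u, g.

    The last column of ``g.x`` / last row of ``g.y`` is ignored (it lies
    outside the range of the forward gradient).
    """
    g = _check_gradient(g)
    d = np.zeros_like(g.x)
    # x component
    d[:, 0] += g.x[:, 0]
    d[:, 1:-1] += g.x[:, 1:-1] - g.x[:, :-2]
    d[:, -1] += -g.x[:, -2]
    # y component
    d[0, :] += g.y[0, :]
    d[1:-1, :] += g.y[1:-1, :] - g.y[:-2, :]
    d[-1, :] += -g.y[-2, :]
    return d


def laplacian(u) -> np.ndarray:
    """5-point Laplacian with replicate (Neumann) boundary handling.

    Identical to ``div_backward(grad_forward(u))``: at the boundary the
    missing neighbour contributes nothing (replicated value cancels).
    """
    u = as_field(u)
    lap = np.zeros_like(u)
    lap[:-1, :] += u[1:, :] - u[:-1, :]
    lap[1:, :] += u[:-1, :] - u[1:, :]
    lap[:, :-1] += u[:, 1:] - u[:, :-1]
    lap[:, 1:] += u[:, :-1] - u[:, 1:]
    return lap


# ---------------------------------------------------------------------------
# periodic-boundary variants (FFT path only)
# ---------------------------------------------------------------------------


def grad_periodic(u) -> Gradient:
    u = as_field(u)
    return Gradient(np.roll(u, -1, axis=1) - u, np.roll(u, -1, axis=0) - u)


def div_periodic(g: Gradient) -> np.ndarray:
    g = _check_gradient(g)
    return (g.x - np.roll(g.x, 1, axis=1)) + (g.y - np.roll(g.y, 1, axis=0))


def laplacian_periodic(u) -> np.ndarray:
    u = as_field(u)
    return (
        np.roll(u, 1, axis=0)
        + np.roll(u, -1, axis=0)
        + np.roll(u, 1, axis=1)
        + np.roll(u, -1, axis=1)
        - 4.0 * u
    )
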
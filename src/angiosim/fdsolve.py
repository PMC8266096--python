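"""Finite-difference reference solver for reaction-diffusion fields.

Second-order central differences for ``D lap(c) - K c = -S`` on a
regular box grid, with Dirichlet or in-plane periodic boundaries.
This is the independent numerical oracle against which the kernel
superposition solvers are validated; it never participates in a
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["OracleGrid", "finite_difference_reference"]


@dataclass
class OracleGrid:
    """Regular box grid: ``shape`` interior points at ``spacing`` (um)."""
    shape: tuple[int, int, int]
    spacing: float
    d_coef: float          # diffusion coefficient, um^2/s (times solubility)
    k_coef: float = 0.0    # linear sink rate, 1/s
    periodic_xy: bool = False
    dirichlet_value: float = 0.0

    def points(self) -> np.ndarray:
        nx, ny, nz = self.shape
        ax = (np.arange(nx) - (nx - 1) / 2.0) * self.spacing
        ay = (np.arange(ny) - (ny - 1) / 2.0) * self.spacing
        az = (np.arange(nz) - (nz - 1) / 2.0) * self.spacing
        xx, yy, zz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)


def finite_difference_reference(grid: OracleGrid, sources: np.ndarray,
                                dirichlet_fn=None) -> np.ndarray:
    """Solve D lap(c) - K c = -S; returns c with the grid's shape.

    ``sources`` is the volumetric release rate S at each grid point (per
    second, same concentration units as c). Boundary planes are either
    held at ``dirichlet_value`` (ghost-node convention), given by
    ``dirichlet_fn(ghost_points) -> values`` evaluated at the ghost-node
    coordinates (in the grid's own frame, origin at its center), or
    wrapped periodically in x and y with Dirichlet top/bottom.
    """
    nx, ny, nz = grid.shape
    n = nx * ny * nz
    s = np.asarray(sources, dtype=float).reshape(n)
    h = grid.spacing
    h2 = h ** 2
    d = grid.d_coef

    def idx(i, j, k):
        return (i * ny + j) * nz + k

    def coord(i, j, k):
        return np.array([(i - (nx - 1) / 2.0) * h,
                         (j - (ny - 1) / 2.0) * h,
                         (k - (nz - 1) / 2.0) * h])

    rows, cols, vals = [], [], []
    rhs = (-s).copy()  # solve A c = b with A = D lap - K, b = -S
    diag = np.full(n, -grid.k_coef - 6.0 * d / h2)
    ghost_rows, ghost_pts = [], []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                me = idx(i, j, k)
                for axis, (di, dj, dk) in enumerate(
                        ((1, 0, 0), (0, 1, 0), (0, 0, 1))):
                    for sign in (-1, 1):
                        ii, jj, kk = i + sign * di, j + sign * dj, \
                            k + sign * dk
                        wrapped = False
                        if grid.periodic_xy and axis == 0:
                            ii %= nx
                            wrapped = True
                        if grid.periodic_xy and axis == 1:
                            jj %= ny
                            wrapped = True
                        if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz:
                            rows.append(me)
                            cols.append(idx(ii, jj, kk))
                            vals.append(d / h2)
                        elif not wrapped or not (0 <= kk < nz):
                            if dirichlet_fn is None:
                                rhs[me] -= d / h2 * grid.dirichlet_value
                            else:
                                ghost_rows.append(me)
                                ghost_pts.append(coord(ii, jj, kk))
    if ghost_rows:
        values = np.asarray(dirichlet_fn(np.array(ghost_pts)), dtype=float)
        for me, v in zip(ghost_rows, values):
            rhs[me] -= d / h2 * v
    a = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr() \
        + sp.diags(diag)
    c = spla.spsolve(a, rhs)
    resid = np.linalg.norm(a @ c - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if resid > 1e-8:
        raise RuntimeError(f"finite-difference solve residual {resid:.2e}")
    return c.reshape(grid.shape)
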
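"""Shared axisymmetric P1 finite-element machinery.

Continuous piecewise-linear elements on triangles in the r-z half-plane,
with one-point (centroid) quadrature and the revolved measure r dr dz (the
constant 2*pi factor is dropped consistently on both sides of every
system).  Assembly is vectorized over elements; linear systems are solved
by sparse LU after symmetric diagonal equilibration, which keeps the
monolithic electromechanical blocks (stiffness ~1e4, permittivity ~1e-18
in SI at this length scale) well conditioned.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


def assemble_scalar_laplace(mesh, kappa: np.ndarray) -> sp.csr_matrix:
    """Assemble sum_e kappa_e * int grad(N_i).grad(N_j) r dA."""
    area, b, rc, _ = mesh.element_geometry()
    w = (kappa * area * rc)[:, None, None]
    ke = w * np.einsum("eik,ejk->eij", b, b)       # (ne, 3, 3)
    tri = mesh.tris
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    n = len(mesh.points)
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def scalar_rhs_from_mz(mesh, Mz: np.ndarray) -> np.ndarray:
    """RHS int Mz * dN/dz r dA for the reduced-scalar-potential solve."""
    area, b, rc, _ = mesh.element_geometry()
    w = Mz * area * rc
    f = np.zeros(len(mesh.points))
    np.add.at(f, mesh.tris.ravel(), (w[:, None] * b[:, :, 1]).ravel())
    return f


class DirichletSystem:
    """A sparse SPD/symmetric system with Dirichlet constraints pre-factorized.

    Supports repeated solves with different right-hand sides and different
    boundary values (lifting is recomputed per solve).
    """

    def __init__(self, K: sp.csr_matrix, fixed_idx: np.ndarray):
        self.n = K.shape[0]
        self.fixed = np.asarray(fixed_idx, dtype=np.int64)
        mask = np.ones(self.n, dtype=bool)
        mask[self.fixed] = False
        self.free = np.where(mask)[0]
        self.K = K
        Kff = K[self.free][:, self.free].tocsc()
        self.Kfc = K[self.free][:, self.fixed].tocsr()
        # symmetric diagonal equilibration
        d = np.abs(Kff.diagonal())
        d[d == 0] = 1.0
        self.scale = 1.0 / np.sqrt(d)
        D = sp.diags(self.scale)
        self.lu = spla.splu((D @ Kff @ D).tocsc())

    def solve(self, f: np.ndarray, fixed_vals: np.ndarray | float = 0.0) -> np.ndarray:
        x = np.zeros(self.n)
        if np.isscalar(fixed_vals):
            xc = np.full(len(self.fixed), float(fixed_vals))
        else:
            xc = np.asarray(fixed_vals, dtype=float)
        x[self.fixed] = xc
        rhs = f[self.free] - self.Kfc @ xc
        y = self.lu.solve(self.scale * rhs)
        x[self.free] = self.scale * y
        return x


def elasticity_B(mesh):
    """Strain-displacement matrices for axisymmetric P1 elements.

    Strain ordering (e_rr, e_zz, e_theta, gamma_rz); the hoop strain u_r/r
    is evaluated at the element centroid (mean-radius rule).
    Returns B of shape (ne, 4, 6) with local dof order
    (u_r1, u_z1, u_r2, u_z2, u_r3, u_z3).
    """
    area, b, rc, _ = mesh.element_geometry()
    ne = len(area)
    B = np.zeros((ne, 4, 6))
    for i in range(3):
        B[:, 0, 2 * i] = b[:, i, 0]
        B[:, 1, 2 * i + 1] = b[:, i, 1]
        B[:, 2, 2 * i] = 1.0 / (3.0 * rc)
        B[:, 3, 2 * i] = b[:, i, 1]
        B[:, 3, 2 * i + 1] = b[:, i, 0]
    return B, area, rc


def isotropic_D(E: float, nu: float) -> np.ndarray:
    """4x4 axisymmetric isotropic stiffness, Voigt order (rr, zz, theta, rz)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.array([
        [lam + 2 * mu, lam, lam, 0.0],
        [lam, lam + 2 * mu, lam, 0.0],
        [lam, lam, lam + 2 * mu, 0.0],
        [0.0, 0.0, 0.0, mu],
    ])
    return D


def coo_accumulate(blocks: np.ndarray, row_dofs: np.ndarray, col_dofs: np.ndarray,
                   shape: tuple[int, int]) -> sp.csr_matrix:
    """Assemble per-element dense blocks into a global sparse matrix.

    ``blocks``: (ne, a, b); ``row_dofs``: (ne, a); ``col_dofs``: (ne, b).
    """
    a, b = blocks.shape[1], blocks.shape[2]
    rows = np.repeat(row_dofs, b, axis=1).ravel()
    cols = np.tile(col_dofs, (1, a)).ravel()
    return sp.coo_matrix((blocks.ravel(), (rows, cols)), shape=shape).tocsr()
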
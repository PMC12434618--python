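"""Magnetization constitutive models and the magnetostatic field solve.

Stationary studies use an anhysteretic Langevin law parameterized so that
the small-field slope is exactly the initial susceptibility chi0 and the
large-field limit is the saturation magnetization Ms.  The magnetostatic
problem is solved in the reduced-scalar-potential formulation
H = H_a z_hat - grad(psi), with the nonlinear M(H) law iterated to
self-consistency (damped Picard); for a sphere this reproduces the
textbook uniform interior field with demagnetizing factor 1/3.

Time-dependent studies use a lumped (volume-averaged) scalar
Jiles-Atherton model along the easy axis z with a spherical
demagnetization correction; see docs/methods.md for the effective-field
convention adopted for the published parameter table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import JAParameters
from .fem import DirichletSystem, assemble_scalar_laplace, scalar_rhs_from_mz
from .mesh import AxisymMesh, REGION_CORE
from .units import MU0

__all__ = [
    "AnhystereticCurve", "anhysteretic_magnetization",
    "MagnetostaticSolution", "solve_magnetostatics", "MagnetostaticsModel",
    "JAState", "ja_update", "hysteresis_loop",
]


# --------------------------------------------------------------------------
# anhysteretic constitutive law
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnhystereticCurve:
    """Odd, saturating M(H) law along the easy axis (+z).

    ``form='langevin'`` (default): M = Ms * L(3*chi0*H/Ms) with
    L(x) = coth(x) - 1/x, so dM/dH|_0 = chi0 and M(inf) = Ms.
    ``form='tanh'``: M = Ms * tanh(chi0*H/Ms) (sharper plateau).
    """

    Ms: float
    chi0: float
    form: str = "langevin"


def _langevin(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[small]
    out[small] = xs / 3.0 - xs ** 3 / 45.0       # series, avoids 0/0
    xl = x[~small]
    out[~small] = 1.0 / np.tanh(xl) - 1.0 / xl
    return out


def anhysteretic_magnetization(H_int, curve: AnhystereticCurve):
    """Magnetization (A/m) at internal field H_int (A/m, along z).

    Total function: odd in H, slope chi0 at the origin, limit +/-Ms.
    """
    H = np.asarray(H_int, dtype=float)
    if curve.form == "langevin":
        M = curve.Ms * _langevin(3.0 * curve.chi0 * H / curve.Ms)
    elif curve.form == "tanh":
        M = curve.Ms * np.tanh(curve.chi0 * H / curve.Ms)
    else:
        raise ValueError(f"unknown anhysteretic form {curve.form!r}")
    return M if M.shape else float(M)


# --------------------------------------------------------------------------
# magnetostatic FEM solve
# --------------------------------------------------------------------------

@dataclass
class MagnetostaticSolution:
    """Self-consistent magnetostatic state for one applied field."""

    psi: np.ndarray             # nodal reduced scalar potential, A
    H_z: np.ndarray             # element axial field H, A/m
    H_r: np.ndarray             # element radial field H, A/m
    M: np.ndarray               # element magnetization (0 outside core), A/m
    H_ext: float                # applied flux density, T
    iterations: int
    residual_history: list

    def core_mean_M(self, mesh: AxisymMesh) -> float:
        """Revolved-volume-averaged core magnetization."""
        area, _, rc, _ = mesh.element_geometry()
        m = mesh.region == REGION_CORE
        w = area[m] * rc[m]
        return float((self.M[m] * w).sum() / w.sum())

    def core_cov_M(self, mesh: AxisymMesh) -> float:
        """Coefficient of variation of M over core elements."""
        area, _, rc, _ = mesh.element_geometry()
        m = mesh.region == REGION_CORE
        w = area[m] * rc[m]
        mean = (self.M[m] * w).sum() / w.sum()
        var = ((self.M[m] - mean) ** 2 * w).sum() / w.sum()
        return float(np.sqrt(var) / abs(mean)) if mean != 0 else 0.0


class ConvergenceError(RuntimeError):
    """Nonlinear iteration failed; carries the residual history."""

    def __init__(self, msg, history):
        super().__init__(f"{msg}; residual history: {history[-5:]}")
        self.history = history


class MagnetostaticsModel:
    """Pre-factorized magnetostatic operator for repeated solves.

    The Laplace matrix does not depend on the applied field or on M, so a
    single LU factorization serves an entire DC sweep.
    """

    def __init__(self, mesh: AxisymMesh, curve: AnhystereticCurve):
        self.mesh = mesh
        self.curve = curve
        K = assemble_scalar_laplace(mesh, np.ones(len(mesh.tris)))
        self.system = DirichletSystem(K, mesh.node_sets["outer_box"])
        _, self.b, _, _ = mesh.element_geometry()
        self.core_mask = mesh.region == REGION_CORE

    def solve(self, H_ext_T: float, tol: float = 1e-9, max_iter: int = 300,
              M_init: np.ndarray | None = None) -> MagnetostaticSolution:
        """Damped Picard iteration on the nonlinear M(H) law.

        ``tol`` is on the relative magnetization update (per Ms).
        """
        mesh, curve = self.mesh, self.curve
        H_a = H_ext_T / MU0
        ne = len(mesh.tris)
        M = np.zeros(ne)
        if M_init is not None:
            M[:] = M_init
        M[~self.core_mask] = 0.0
        # relaxation: Picard eigenvalues are -chi'*N_mode with per-mode
        # demagnetizing factors N_mode in (0, 1); omega = 0.35 damps the
        # whole range, and stalls trigger a further reduction
        omega = 0.35
        history = []
        psi = np.zeros(len(mesh.points))
        for it in range(max_iter):
            f = scalar_rhs_from_mz(mesh, M)
            psi = self.system.solve(f)
            grad_z = np.einsum("ei,ei->e", self.b[:, :, 1], psi[mesh.tris])
            H_z = H_a - grad_z
            target = np.where(
                self.core_mask,
                anhysteretic_magnetization(H_z, curve),
                0.0,
            )
            dM = target - M
            res = float(np.abs(dM[self.core_mask]).max() / curve.Ms) \
                if self.core_mask.any() else 0.0
            history.append(res)
            M = M + omega * dM
            if res < tol:
                break
            if it >= 20 and res > 0.9 * history[-10]:
                omega = max(0.1, omega * 0.7)
        else:
            raise ConvergenceError("magnetostatics did not converge", history)
        grad_r = np.einsum("ei,ei->e", self.b[:, :, 0], psi[mesh.tris])
        grad_z = np.einsum("ei,ei->e", self.b[:, :, 1], psi[mesh.tris])
        return MagnetostaticSolution(
            psi=psi, H_z=H_a - grad_z, H_r=-grad_r, M=M, H_ext=H_ext_T,
            iterations=len(history), residual_history=history,
        )


def solve_magnetostatics(mesh: AxisymMesh, curve: AnhystereticCurve,
                         H_ext_T: float, **kw) -> MagnetostaticSolution:
    """One-shot self-consistent magnetostatic solve (see MagnetostaticsModel)."""
    return MagnetostaticsModel(mesh, curve).solve(H_ext_T, **kw)


# --------------------------------------------------------------------------
# Jiles-Atherton hysteresis
# --------------------------------------------------------------------------

@dataclass
class JAState:
    """Lumped scalar Jiles-Atherton state along the easy axis.

    The effective field is He = H - N*M + alpha*M with the spherical
    demagnetizing factor N and inter-domain coupling alpha taken from the
    parameter set's *effective* convention fields.
    """

    params: JAParameters
    M_irr: float = 0.0
    M: float = 0.0
    H: float = 0.0              # applied field, A/m
    delta: int = 1              # sign of dH/dt

    @property
    def _alpha_net(self) -> float:
        p = self.params
        return p.alpha_effective - p.demag_n_effective

    def anhysteretic(self, M: float, H: float) -> float:
        p = self.params
        He = H + self._alpha_net * M
        return p.Ms * float(_langevin(He / p.a_domain))

    def _total(self, M_guess: float, H: float) -> float:
        """Self-consistent M = c*M_an(He(M)) + (1-c)*M_irr (damped fp)."""
        p = self.params
        M = M_guess
        for _ in range(100):
            M_new = p.c_reversibility * self.anhysteretic(M, H) \
                + (1.0 - p.c_reversibility) * self.M_irr
            if abs(M_new - M) < 1e-10 * p.Ms:
                return M_new
            M = M + 0.7 * (M_new - M)
        return M


def ja_update(state: JAState, H_new: float,
              max_dM_frac: float = 0.02) -> JAState:
    """Advance the Jiles-Atherton state to a new applied field (A/m).

    Explicit sub-stepped Euler on the field increment with step rejection:
    a substep is subdivided until |dM| <= ``max_dM_frac``*Ms.  The
    irreversible component follows
    dM_irr/dH = (M_an - M_irr) / (k*delta - alpha_net*(M_an - M_irr)),
    with the standard physicality clamp (no negative susceptibility after
    reversal) and delta recomputed per substep.
    """
    p = state.params
    st = replace(state)
    dH_total = H_new - st.H
    if dH_total == 0.0:
        return st
    n_sub = 1
    H0, M0, Mirr0 = st.H, st.M, st.M_irr
    while True:
        H, M, M_irr = H0, M0, Mirr0
        ok = True
        dH = dH_total / n_sub
        delta = 1 if dH > 0 else -1
        for _ in range(n_sub):
            M_an = p.Ms * float(_langevin(
                (H + (p.alpha_effective - p.demag_n_effective) * M)
                / p.a_domain))
            gap = M_an - M_irr
            denom = p.k_pinning * delta \
                - (p.alpha_effective - p.demag_n_effective) * gap
            if delta * (M_an - M) < 0:
                dMirr_dH = 0.0            # clamp: no reversal overshoot
            elif delta * denom <= 1e-12 * p.k_pinning:
                dMirr_dH = gap / (1e-3 * p.k_pinning * delta)  # avalanche guard
            else:
                dMirr_dH = gap / denom
            M_irr_new = M_irr + dMirr_dH * dH
            st_tmp = replace(st, M_irr=M_irr_new)
            M_new = st_tmp._total(M, H + dH)
            if abs(M_new - M) > max_dM_frac * p.Ms and n_sub < 2 ** 14:
                ok = False
                break
            H, M, M_irr = H + dH, M_new, M_irr_new
        if ok:
            break
        n_sub *= 2
    st.H, st.M, st.M_irr, st.delta = H_new, M, M_irr, delta
    # hard physical bound
    st.M = float(np.clip(st.M, -p.Ms, p.Ms))
    return st


def hysteresis_loop(params: JAParameters, H_max_T: float,
                    n_steps: int = 200):
    """Major hysteresis loop (H in T applied; returns branches in A/m).

    Ramps 0 -> +Hmax -> -Hmax -> +Hmax; returns (H, M) arrays covering the
    descending and ascending branches after the initial magnetization.
    """
    if n_steps < 100:
        raise ValueError("n_steps must be >= 100 per branch")
    H_max = H_max_T / MU0
    st = JAState(params=params)
    up0 = np.linspace(0.0, H_max, n_steps)
    down = np.linspace(H_max, -H_max, 2 * n_steps)
    up = np.linspace(-H_max, H_max, 2 * n_steps)
    for h in up0[1:]:
        st = ja_update(st, h)
    H_path, M_path = [], []
    for h in np.concatenate([down, up[1:]]):
        st = ja_update(st, h)
        H_path.append(h)
        M_path.append(st.M)
    return np.asarray(H_path), np.asarray(M_path)
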
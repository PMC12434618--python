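"""Stationary coupled solve: magnetostriction -> elasticity -> piezoelectricity
-> electrostatics.

The magnetization of the core imposes a traceless quadratic eigenstrain
(contraction along the field for negative saturation magnetostriction,
expansion transverse to it).  Elasticity transfers that deformation to the
piezoelectric shell, whose stress-charge coupling (poled along +z) sources
the electrostatic potential; the surroundings are treated as pure
dielectrics with their stated relative permittivities (no DC conduction
screening; see docs/methods.md).  Displacements and potential are solved
monolithically: the assembled block system

    [ K_uu   K_uV ] [u]   [f_eigenstrain]
    [ K_uV'  -K_VV] [V] = [0            ]

is symmetric indefinite and is solved by sparse LU after diagonal
equilibration.

Mechanical boundary conditions follow the host environment: the liquid
culture medium (CM) carries no static shear, so mechanics is solved on the
particle only with a traction-free outer shell surface; the solid
blood-vessel wall (BV) is meshed mechanically throughout with the outer
box fixed.  The potential is grounded on the outer box boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .config import CoreMaterial, ScenarioConfig
from .fem import DirichletSystem, coo_accumulate, elasticity_B, isotropic_D
from .magnetics import (AnhystereticCurve, MagnetostaticSolution,
                        MagnetostaticsModel)
from .mesh import (AxisymMesh, REGION_CORE, REGION_SHELL,
                   REGION_SURROUNDINGS, build_mesh)
from .units import EPS0

__all__ = [
    "FieldSolution", "magnetostrictive_strain", "CoupledModel", "Model",
    "solve_coupled_mech_electro", "stationary_solve",
    "solve_dielectric_sphere", "calibrate_piezo_scale",
]


def magnetostrictive_strain(M: np.ndarray, core: CoreMaterial,
                            core_mask: np.ndarray) -> np.ndarray:
    """Magnetostrictive eigenstrain field, Voigt order (rr, zz, theta, rz).

    Isotropic quadratic deviatoric model
    eps* = (3/2)*(lambda_s/Ms^2)*(M (x) M - |M|^2/3 I); with M along z this
    gives eps*_zz = lambda_s*(M/Ms)^2 and
    eps*_rr = eps*_theta = -lambda_s/2*(M/Ms)^2.  Traceless by
    construction; zero outside the core.
    """
    ne = len(M)
    eig = np.zeros((ne, 4))
    m2 = (M / core.Ms) ** 2
    eig[:, 1] = core.lambda_s * m2
    eig[:, 0] = -0.5 * core.lambda_s * m2
    eig[:, 2] = -0.5 * core.lambda_s * m2
    eig[~core_mask] = 0.0
    return eig


@dataclass
class FieldSolution:
    """Nodal displacement/potential and element fields for one solve."""

    mesh: AxisymMesh
    u: np.ndarray               # (n_nodes, 2) displacement, m (0 off-domain)
    V: np.ndarray               # (n_nodes,) potential, volt
    strain: np.ndarray          # (ne, 4) Voigt (rr, zz, theta, rz)
    stress: np.ndarray          # (ne, 4) Pa
    E: np.ndarray               # (ne, 2) electric field (E_r, E_z), V/m
    eigenstrain: np.ndarray     # (ne, 4) imposed eigenstrain
    magnetostatics: MagnetostaticSolution | None = None

    @property
    def E_mag(self) -> np.ndarray:
        return np.hypot(self.E[:, 0], self.E[:, 1])


class CoupledModel:
    """Pre-assembled, pre-factorized electromechanical operator.

    The system matrix depends only on mesh and materials, so a single LU
    factorization serves an entire DC sweep / time series; each applied
    field only changes the eigenstrain right-hand side.
    """

    def __init__(self, mesh: AxisymMesh, config: ScenarioConfig):
        self.mesh = mesh
        self.config = config
        env = config.environment
        if config.shell.sigma:
            warnings.warn(
                "shell electrical conductivity is stored but ignored by the "
                "dielectric potential solve (see docs/methods.md)",
                stacklevel=2,
            )

        mech_regions = [REGION_CORE, REGION_SHELL]
        if env.is_solid:
            mech_regions.append(REGION_SURROUNDINGS)
        self.mech_regions = mech_regions

        region = mesh.region
        self.mech_elems = np.isin(region, mech_regions)
        self.core_mask = region == REGION_CORE

        n_nodes = len(mesh.points)
        mech_nodes = np.unique(mesh.tris[self.mech_elems])
        self.mech_nodes = mech_nodes
        u_index = np.full(n_nodes, -1, dtype=np.int64)
        u_index[mech_nodes] = np.arange(len(mech_nodes))
        self.u_index = u_index
        self.n_u = 2 * len(mech_nodes)
        self.n_dof = self.n_u + n_nodes
        self.v_offset = self.n_u

        # material tables per region
        D_by_region = {
            REGION_CORE: isotropic_D(config.core.E, config.core.nu),
            REGION_SHELL: isotropic_D(config.shell.E, config.shell.nu),
        }
        if env.is_solid:
            D_by_region[REGION_SURROUNDINGS] = isotropic_D(env.E, env.nu)
        eps_by_region = {
            REGION_CORE: EPS0 * config.core.eps_r,
            REGION_SHELL: EPS0 * config.shell.eps_r,
            REGION_SURROUNDINGS: EPS0 * env.eps_r,
        }
        s = config.shell.piezo_scale
        e_mat = s * np.array([
            [0.0, 0.0, 0.0, config.shell.e15],
            [config.shell.e31, config.shell.e33, config.shell.e31, 0.0],
        ])

        B, area, rc = elasticity_B(mesh)
        _, grads, _, _ = mesh.element_geometry()
        G = grads.transpose(0, 2, 1)            # (ne, 2, 3)
        w = area * rc
        self._B, self._G, self._w = B, G, w
        self._D_by_region = D_by_region
        tris = mesh.tris

        # mechanical stiffness
        blocks_uu = []
        dofs_u = np.empty((len(tris), 6), dtype=np.int64)
        dofs_u[:, 0::2] = 2 * u_index[tris]
        dofs_u[:, 1::2] = 2 * u_index[tris] + 1
        Dmat = np.zeros((len(tris), 4, 4))
        for lab, D in D_by_region.items():
            Dmat[region == lab] = D
        self._Dmat = Dmat
        me = self.mech_elems
        kuu = np.einsum("eki,ekl,elj->eij", B[me], Dmat[me], B[me]) \
            * w[me, None, None]
        K = coo_accumulate(kuu, dofs_u[me], dofs_u[me],
                           (self.n_dof, self.n_dof))

        # dielectric matrix (all elements), negated in the monolithic block
        eps_e = np.empty(len(tris))
        for lab, eps in eps_by_region.items():
            eps_e[region == lab] = eps
        kvv = np.einsum("eki,ekj->eij", G, G) * (eps_e * w)[:, None, None]
        dofs_v = self.v_offset + tris
        K = K - coo_accumulate(kvv, dofs_v, dofs_v,
                               (self.n_dof, self.n_dof))

        # piezoelectric coupling (shell only)
        sh = region == REGION_SHELL
        self._e_mat = e_mat
        self._shell_mask = sh
        cup = np.einsum("eki,kl,elj->eij", B[sh], e_mat.transpose(),
                        G[sh]) * w[sh, None, None]
        C = coo_accumulate(cup, dofs_u[sh], dofs_v[sh],
                           (self.n_dof, self.n_dof))
        K = K + C + C.T
        self.K = K.tocsr()
        self._dofs_u = dofs_u
        self._dofs_v = dofs_v

        # Dirichlet constraints
        fixed = [self.v_offset + mesh.node_sets["outer_box"]]
        axis_mech = mesh.node_sets["axis"][
            u_index[mesh.node_sets["axis"]] >= 0]
        fixed.append(2 * u_index[axis_mech])            # u_r = 0 on axis
        if env.is_solid:
            ob = mesh.node_sets["outer_box"]
            fixed.append(2 * u_index[ob])
            fixed.append(2 * u_index[ob] + 1)
        else:
            fixed.append(np.array([2 * u_index[0] + 1]))  # pin u_z at center
        self.fixed = np.unique(np.concatenate(fixed))
        self.system = DirichletSystem(self.K, self.fixed)

    # ------------------------------------------------------------------

    def eigenstrain_rhs(self, eigenstrain: np.ndarray) -> np.ndarray:
        """Load vector int B' D eps* r dA over the core."""
        f = np.zeros(self.n_dof)
        cm = self.core_mask
        load = np.einsum("eki,ekl,el->ei", self._B[cm], self._Dmat[cm],
                         eigenstrain[cm]) * self._w[cm, None]
        np.add.at(f, self._dofs_u[cm].ravel(), load.ravel())
        return f

    def solve(self, eigenstrain: np.ndarray,
              magnetostatics: MagnetostaticSolution | None = None
              ) -> FieldSolution:
        f = self.eigenstrain_rhs(eigenstrain)
        x = self.system.solve(f)
        return self._fields(x, eigenstrain, magnetostatics)

    def _fields(self, x, eigenstrain, magnetostatics) -> FieldSolution:
        mesh = self.mesh
        n_nodes = len(mesh.points)
        u = np.zeros((n_nodes, 2))
        u[self.mech_nodes, 0] = x[0:self.n_u:2]
        u[self.mech_nodes, 1] = x[1:self.n_u:2]
        V = x[self.v_offset:]
        # element fields
        tris = mesh.tris
        u_loc = np.empty((len(tris), 6))
        u_loc[:, 0::2] = u[tris, 0]
        u_loc[:, 1::2] = u[tris, 1]
        strain = np.einsum("eij,ej->ei", self._B, u_loc)
        strain[~self.mech_elems] = 0.0
        gradV = np.einsum("eij,ej->ei", self._G, V[tris])
        E = -gradV
        stress = np.einsum("eij,ej->ei", self._Dmat,
                           strain - eigenstrain)
        stress[~self.mech_elems] = 0.0
        sh = self._shell_mask
        stress[sh] += np.einsum("ij,ej->ei", self._e_mat.transpose(),
                                gradV[sh])
        return FieldSolution(
            mesh=mesh, u=u, V=V, strain=strain, stress=stress, E=E,
            eigenstrain=eigenstrain, magnetostatics=magnetostatics,
        )

    def outer_boundary_charge(self, sol: FieldSolution) -> tuple[float, float]:
        """Reaction charge on the grounded outer boundary.

        Returns (net, gross): the signed sum and the sum of magnitudes of
        the nodal reaction charges (up to the dropped 2*pi factor).  For a
        dipolar source the net charge vanishes within solver tolerance.
        """
        x = np.zeros(self.n_dof)
        x[0:self.n_u:2] = sol.u[self.mech_nodes, 0]
        x[1:self.n_u:2] = sol.u[self.mech_nodes, 1]
        x[self.v_offset:] = sol.V
        resid = self.K @ x - self.eigenstrain_rhs(sol.eigenstrain)
        vb = self.v_offset + self.mesh.node_sets["outer_box"]
        q = resid[vb]
        return float(q.sum()), float(np.abs(q).sum())


def solve_coupled_mech_electro(mesh: AxisymMesh, eigenstrain: np.ndarray,
                               config: ScenarioConfig,
                               magnetostatics=None) -> FieldSolution:
    """One-shot coupled solve (see CoupledModel for the cached variant)."""
    return CoupledModel(mesh, config).solve(eigenstrain, magnetostatics)


# --------------------------------------------------------------------------
# high-level model: chained stationary solve with cached factorizations
# --------------------------------------------------------------------------

class Model:
    """Mesh + magnetostatics + electromechanics for one scenario."""

    def __init__(self, config: ScenarioConfig, mesh: AxisymMesh | None = None):
        config.validate()
        self.config = config
        self.mesh = mesh if mesh is not None else build_mesh(
            config.geometry, config.mesh_resolution)
        self.curve = AnhystereticCurve(Ms=config.core.Ms,
                                       chi0=config.core.chi0)
        self.mag = MagnetostaticsModel(self.mesh, self.curve)
        self.coupled = CoupledModel(self.mesh, config)
        self._delta_v_sat = None

    def stationary(self, H_ext_T: float,
                   M_init: np.ndarray | None = None) -> FieldSolution:
        """Chain magnetostatics -> eigenstrain -> coupled solve."""
        ms = self.mag.solve(H_ext_T, M_init=M_init)
        eig = magnetostrictive_strain(ms.M, self.config.core,
                                      self.coupled.core_mask)
        return self.coupled.solve(eig, magnetostatics=ms)

    def delta_v(self, sol: FieldSolution) -> float:
        """Surface potential difference max(V)-min(V) on the shell outer
        border, in mV."""
        surf = self.mesh.node_sets["shell_outer_surface"]
        if len(surf) == 0:
            raise ValueError("empty shell_outer_surface node set")
        Vs = sol.V[surf]
        return float((Vs.max() - Vs.min()) * 1e3)

    def delta_v_sat(self) -> float:
        """Surface potential difference (mV) for a uniformly saturated core
        (M = Ms everywhere in the core); the quasi-static mapping scale."""
        if self._delta_v_sat is None:
            M = np.where(self.coupled.core_mask, self.config.core.Ms, 0.0)
            eig = magnetostrictive_strain(M, self.config.core,
                                          self.coupled.core_mask)
            self._delta_v_sat = self.delta_v(self.coupled.solve(eig))
        return self._delta_v_sat


def stationary_solve(config: ScenarioConfig, H_ext_T: float) -> FieldSolution:
    """Full stationary chain for a single applied field (T, along z)."""
    return Model(config).stationary(H_ext_T)


# --------------------------------------------------------------------------
# verification-mode solves
# --------------------------------------------------------------------------

def solve_dielectric_sphere(mesh: AxisymMesh, eps_in: float, eps_out: float,
                            E0: float):
    """Dielectric sphere (the core region) in an imposed uniform field E0.

    Electrostatics only: V = -E0*z on the outer box.  Returns (V, E_mean)
    where E_mean is the volume-averaged interior field magnitude, to be
    compared with the closed form 3*eps_out*E0/(eps_in + 2*eps_out).
    """
    from .fem import assemble_scalar_laplace

    eps_e = np.where(mesh.region == REGION_CORE, EPS0 * eps_in,
                     EPS0 * eps_out)
    K = assemble_scalar_laplace(mesh, eps_e)
    ob = mesh.node_sets["outer_box"]
    sys_ = DirichletSystem(K, ob)
    V = sys_.solve(np.zeros(len(mesh.points)),
                   fixed_vals=-E0 * mesh.points[ob, 1])
    area, grads, rc, _ = mesh.element_geometry()
    gradV = np.einsum("eik,ei->ek", grads, V[mesh.tris])
    Emag = np.hypot(gradV[:, 0], gradV[:, 1])
    cm = mesh.region == REGION_CORE
    w = area[cm] * rc[cm]
    return V, float((Emag[cm] * w).sum() / w.sum())


def calibrate_piezo_scale(config: ScenarioConfig, target_mV: float = 6.07,
                          H_T: float = 2.0, bracket=(1e-4, 1.0),
                          rtol: float = 1e-6) -> float:
    """One-time calibration of the piezo stress-charge scale factor.

    Finds the multiplier of the BaTiO3 coefficient matrix such that the
    stationary baseline at ``H_T`` reproduces ``target_mV`` on the shell
    outer border.  Used once to fix the shipped default; see
    docs/methods.md.
    """
    from scipy.optimize import brentq
    import copy

    mesh = build_mesh(config.geometry, config.mesh_resolution)
    mag = MagnetostaticsModel(
        mesh, AnhystereticCurve(Ms=config.core.Ms, chi0=config.core.chi0))
    ms = mag.solve(H_T)

    def dv_of(scale: float) -> float:
        cfg = copy.deepcopy(config)
        cfg.shell.piezo_scale = scale
        cm = CoupledModel(mesh, cfg)
        eig = magnetostrictive_strain(ms.M, cfg.core, cm.core_mask)
        sol = cm.solve(eig, magnetostatics=ms)
        surf = mesh.node_sets["shell_outer_surface"]
        return float((sol.V[surf].max() - sol.V[surf].min()) * 1e3)

    return float(brentq(lambda s: dv_of(s) - target_mV, *bracket,
                        rtol=rtol))
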
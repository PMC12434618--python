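import copy

import numpy as np
import pytest

from menpsim.analysis import delta_v
from menpsim.config import default_scenario
from menpsim.coupled import (CoupledModel, magnetostrictive_strain,
                             solve_dielectric_sphere)
from menpsim.mesh import REGION_SURROUNDINGS, build_mesh


class TestMagnetostrictiveStrain:
    def test_saturation_values(self, bv_config):
        core = bv_config.core
        M = np.array([core.Ms])
        eig = magnetostrictive_strain(M, core, np.array([True]))
        assert eig[0, 1] == pytest.approx(-200e-6)      # along the field
        assert eig[0, 0] == pytest.approx(+100e-6)      # transverse
        assert eig[0, 2] == pytest.approx(+100e-6)

    def test_zero_magnetization_and_outside_core(self, bv_config):
        M = np.array([0.0, 2e5])
        eig = magnetostrictive_strain(M, bv_config.core,
                                      np.array([True, False]))
        assert np.all(eig == 0.0)

    def test_traceless(self, bv_config):
        M = np.linspace(0, bv_config.core.Ms, 11)
        eig = magnetostrictive_strain(M, bv_config.core,
                                      np.ones(11, dtype=bool))
        trace = eig[:, 0] + eig[:, 1] + eig[:, 2]
        assert np.abs(trace).max() < 1e-20


class TestCoupledSolve:
    def test_zero_eigenstrain_gives_trivial_solution(self, bv_model):
        eig = np.zeros((len(bv_model.mesh.tris), 4))
        sol = bv_model.coupled.solve(eig)
        assert np.abs(sol.V).max() == 0.0
        assert np.abs(sol.u).max() == 0.0

    def test_zero_field_gives_zero_potential(self, bv_model):
        sol = bv_model.stationary(0.0)
        assert delta_v(sol) == 0.0

    def test_potential_antisymmetric_in_z(self, sol_2t, bv_model):
        perm = bv_model.mesh.mirror_map()
        resid = np.abs(sol_2t.V + sol_2t.V[perm]).max()
        assert resid < 1e-9 * np.abs(sol_2t.V).max()

    def test_delta_v_linear_in_magnetostriction(self, bv_model, sol_2t):
        dv0 = delta_v(sol_2t)
        for gamma in (0.5, 2.0):
            cfg = copy.deepcopy(bv_model.config)
            cfg.core.lambda_s *= gamma
            cm = CoupledModel(bv_model.mesh, cfg)
            eig = magnetostrictive_strain(sol_2t.magnetostatics.M, cfg.core,
                                          cm.core_mask)
            dv = delta_v(cm.solve(eig))
            assert dv == pytest.approx(gamma * dv0, rel=1e-9)

    def test_axis_displacement_vanishes(self, sol_2t, bv_model):
        ax = bv_model.mesh.node_sets["axis"]
        assert np.abs(sol_2t.u[ax, 0]).max() < 1e-20

    def test_dipole_far_field_decay(self, sol_2t, bv_model):
        mesh = bv_model.mesh
        rp = mesh.geometry.outer_radius
        r, z = mesh.points[:, 0], mesh.points[:, 1]
        ax = np.where((r < 1e-16) & (z > 0))[0]
        ax = ax[np.argsort(z[ax])]
        zz, VV = z[ax], sol_2t.V[ax]
        Ez = -(VV[2:] - VV[:-2]) / (zz[2:] - zz[:-2])
        zm = zz[1:-1]
        m = (zm >= 3 * rp) & (zm <= 6 * rp)
        slope = np.polyfit(np.log(zm[m]), np.log(np.abs(Ez[m])), 1)[0]
        assert slope == pytest.approx(-3.0, rel=0.05)

    def test_outer_boundary_reaction_charge_vanishes(self, sol_2t, bv_model):
        net, gross = bv_model.coupled.outer_boundary_charge(sol_2t)
        assert abs(net) < 1e-6 * gross

    def test_cm_and_bv_potentials_overlap(self, bv_model, cm_model):
        dv_bv = delta_v(bv_model.stationary(2.0))
        dv_cm = delta_v(cm_model.stationary(2.0))
        assert dv_cm == pytest.approx(dv_bv, rel=0.02)

    def test_cm_has_no_mechanical_surroundings(self, cm_model):
        surr = cm_model.mesh.region == REGION_SURROUNDINGS
        assert not cm_model.coupled.mech_elems[surr].any()
        assert np.abs(cm_model.stationary(2.0).strain[surr]).max() == 0.0

    def test_core_strain_order_hundred_ppm_at_2T(self, sol_2t, bv_model):
        cm = bv_model.coupled.core_mask
        ezz = sol_2t.strain[cm, 1].mean() * 1e6
        assert 50 < abs(ezz) < 500                  # order of 1e2 ppm
        assert ezz < 0                              # contraction along z


class TestDielectricSphereOracle:
    def test_interior_field_matches_closed_form(self, bv_model):
        V, Em = solve_dielectric_sphere(bv_model.mesh, 10.0, 1.0, 1e4)
        assert Em == pytest.approx(3 * 1.0 * 1e4 / (10 + 2), rel=0.01)

    def test_homogeneous_limit(self, bv_model):
        _, Em = solve_dielectric_sphere(bv_model.mesh, 1.0, 1.0, 1e4)
        assert Em == pytest.approx(1e4, rel=1e-3)

    def test_high_contrast_suppresses_interior(self, bv_model):
        _, Em = solve_dielectric_sphere(bv_model.mesh, 1e4, 1.0, 1e4)
        assert Em < 0.01 * 1e4


@pytest.fixture(scope="module")
def inclusion():
    """Homogeneous elasticity, no piezo coupling, uniform core eigenstrain."""
    cfg = default_scenario("BV")
    cfg.shell.E = cfg.core.E
    cfg.shell.nu = cfg.core.nu
    cfg.environment.E = cfg.core.E
    cfg.environment.nu = cfg.core.nu
    cfg.shell.e31 = cfg.shell.e33 = cfg.shell.e15 = 0.0
    mesh = build_mesh(cfg.geometry, "default")
    cm = CoupledModel(mesh, cfg)
    M = np.where(cm.core_mask, cfg.core.Ms, 0.0)
    eig = magnetostrictive_strain(M, cfg.core, cm.core_mask)
    return mesh, cm, cm.solve(eig), eig


class TestEigenstrainInclusion:
    """Uniform eigenstrain in a homogeneous medium: uniform interior stress."""

    def _interior(self, mesh, cm):
        area, _, rc, zc = mesh.element_geometry()
        s = np.hypot(rc, zc)
        inside = cm.core_mask & (s < 0.8 * mesh.geometry.core_radius)
        return inside, (area * rc)[inside]

    def test_interior_stress_uniform(self, inclusion):
        mesh, cm, sol, _ = inclusion
        inside, w = self._interior(mesh, cm)
        for comp in (0, 1):
            st = sol.stress[inside, comp]
            mean = (st * w).sum() / w.sum()
            cov = np.sqrt(((st - mean) ** 2 * w).sum() / w.sum()) / abs(mean)
            assert cov < 0.03

    def test_stress_scales_linearly_with_eigenstrain(self, inclusion):
        mesh, cm, sol, eig = inclusion
        sol2 = cm.solve(2.0 * eig)
        inside, _ = self._interior(mesh, cm)
        ratio = sol2.stress[inside, 1] / sol.stress[inside, 1]
        assert np.allclose(ratio, 2.0, rtol=1e-3)

    def test_no_piezo_coupling_no_potential(self, inclusion):
        _, _, sol, _ = inclusion
        assert np.abs(sol.V).max() == 0.0


def test_mesh_convergence_of_delta_v(bv_model, fine_model):
    dv_default = delta_v(bv_model.stationary(2.0))
    dv_fine = delta_v(fine_model.stationary(2.0))
    assert dv_fine == pytest.approx(dv_default, rel=0.01)
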
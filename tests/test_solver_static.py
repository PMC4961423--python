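"""Static solver: rigid-body modes, energy oracle, bar, patch test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condylefe.densitymap import MaterialField
from condylefe.meshing import build_voxel_mesh
from condylefe.solver_static import (StaticLoadCase, assemble_system,
                                     element_stresses, isotropic_D,
                                     pressure_forces, solve_dirichlet,
                                     solve_static, von_mises)
from condylefe.volume import VoxelVolume


def box_mesh(dims, spacing=1.0):
    mask = VoxelVolume(np.ones(dims, bool), (spacing,) * 3,
                       np.zeros(3), "mask")
    return build_voxel_mesh(mask, 1)


def uniform_materials(mesh, E=10000.0, nu=0.3, rho=1.0):
    n = mesh.n_elements
    return MaterialField(np.full(n, E), np.full(n, nu), np.full(n, rho))


def energy_oracle(mesh, materials, u):
    """Independent strain-energy quadrature: trilinear interpolation with
    central-difference gradients (exact for multilinear fields) at 2x2x2
    Gauss points per element."""
    gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    en = mesh.nodes[mesh.elements]
    h = (en.max(axis=1) - en.min(axis=1))[0]
    uu = u.reshape(-1, 3)
    total = 0.0
    eps = 1e-5

    def interp(e, xi):
        # trilinear interpolation at natural coords xi in [-1,1]^3
        lo = en[e].min(axis=0)
        t = (xi + 1) / 2
        val = np.zeros(3)
        for a, off in enumerate([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
                                 (0, 0, 1), (1, 0, 1), (1, 1, 1),
                                 (0, 1, 1)]):
            w = 1.0
            for d in range(3):
                w *= t[d] if off[d] else (1 - t[d])
            val += w * uu[mesh.elements[e, a]]
        return val

    for e in range(mesh.n_elements):
        D = isotropic_D(materials.E[e], materials.nu[e])
        for x in gp:
            for y in gp:
                for z in gp:
                    xi = np.array([x, y, z])
                    grad = np.zeros((3, 3))
                    for d in range(3):
                        dxi = np.zeros(3)
                        dxi[d] = eps
                        grad[:, d] = (interp(e, xi + dxi)
                                      - interp(e, xi - dxi)) \
                            / (2 * eps) * (2.0 / h[d])
                    strain = np.array([
                        grad[0, 0], grad[1, 1], grad[2, 2],
                        grad[0, 1] + grad[1, 0], grad[1, 2] + grad[2, 1],
                        grad[0, 2] + grad[2, 0]])
                    total += 0.5 * strain @ D @ strain * np.prod(h) / 8.0
    return total


class TestAssembly:
    def test_single_hex_symmetric_with_six_rigid_modes(self):
        mesh = box_mesh((1, 1, 1))
        K = assemble_system(mesh, uniform_materials(mesh)).toarray()
        assert np.abs(K - K.T).max() < 1e-10 * np.abs(K).max()
        w = np.linalg.eigvalsh(K)
        scale = np.abs(w).max()
        assert np.sum(np.abs(w) < 1e-9 * scale) == 6

    def test_rigid_translation_gives_zero_force(self):
        mesh = box_mesh((2, 2, 3))
        K = assemble_system(mesh, uniform_materials(mesh))
        u = np.tile([1.0, -2.0, 0.5], mesh.n_nodes)
        f = K @ u
        norm = np.abs(K.data).max()
        assert np.abs(f).max() < 1e-8 * norm

    @pytest.mark.parametrize("seed", [0, 1])
    def test_strain_energy_matches_quadrature_oracle(self, seed):
        mesh = box_mesh((2, 2, 2), spacing=0.8)
        mats = uniform_materials(mesh, E=5000.0, nu=0.25)
        K = assemble_system(mesh, mats)
        rng = np.random.default_rng(seed)
        u = rng.normal(0, 1e-3, 3 * mesh.n_nodes)
        e_K = 0.5 * u @ (K @ u)
        e_ref = energy_oracle(mesh, mats, u)
        assert e_K == pytest.approx(e_ref, rel=1e-8)

    def test_misaligned_materials_rejected(self):
        mesh = box_mesh((2, 2, 2))
        mats = MaterialField(np.ones(3), np.full(3, 0.3), np.ones(3))
        with pytest.raises(ValueError):
            assemble_system(mesh, mats)


class TestStaticSolve:
    def _bar(self, E=10000.0, p=5.0, dims=(4, 4, 20)):
        mesh = box_mesh(dims)
        mats = uniform_materials(mesh, E=E, nu=0.0)
        z = mesh.nodes[:, 2]
        mesh.node_sets["bot"] = np.flatnonzero(z < z.min() + 0.1)
        top = np.flatnonzero(mesh.facet_normals[:, 2] > 0.5)
        top = top[mesh.facet_centroids()[top][:, 2] > z.max() - 0.1]
        mesh.facet_sets["top"] = top
        return mesh, mats, StaticLoadCase({"top": p}, "bot")

    def test_uniaxial_bar_closed_form(self):
        E, p, L = 10000.0, 5.0, 20.0
        mesh, mats, case = self._bar(E, p)
        sol = solve_static(mesh, mats, case)
        z = mesh.nodes[:, 2]
        tip = sol.displacements[z > z.max() - 0.1, 2].mean()
        assert tip == pytest.approx(-p * L / E, rel=0.01)
        assert np.all(np.abs(sol.von_mises - p) < 0.01 * p)

    def test_zero_pressure_zero_solution(self):
        mesh, mats, _ = self._bar(dims=(2, 2, 4))
        case = StaticLoadCase({"top": 0.0}, "bot")
        sol = solve_static(mesh, mats, case)
        assert np.all(sol.displacements == 0)
        assert np.all(sol.von_mises == 0)

    def test_linearity_in_load(self):
        mesh, mats, case1 = self._bar(dims=(2, 2, 6))
        sol1 = solve_static(mesh, mats, case1)
        case2 = StaticLoadCase({"top": 2 * case1.pressure_patches["top"]},
                               "bot")
        sol2 = solve_static(mesh, mats, case2)
        assert np.allclose(sol2.displacements, 2 * sol1.displacements,
                           rtol=1e-10, atol=1e-15)
        assert np.allclose(sol2.stress, 2 * sol1.stress, rtol=1e-10,
                           atol=1e-15)

    def test_patch_test_constant_stress(self):
        mesh = box_mesh((3, 3, 3), spacing=0.9)
        mats = uniform_materials(mesh, E=7000.0, nu=0.3)
        K = assemble_system(mesh, mats)
        A = np.array([[1e-3, 2e-4, 0.0], [0.0, -5e-4, 3e-4],
                      [1e-4, 0.0, 8e-4]])
        uref = mesh.nodes @ A.T
        bn = np.unique(mesh.boundary_facets)
        fd = (3 * bn[:, None] + np.arange(3)).ravel()
        u, _ = solve_dirichlet(K, np.zeros(K.shape[0]), fd,
                               uref[bn].ravel())
        stress = element_stresses(mesh, mats, u)
        spread = np.abs(stress - stress[0]).max()
        assert spread <= 1e-8 * np.abs(stress).max()

    def test_rigid_body_dirichlet_motion_is_stress_free(self):
        mesh = box_mesh((2, 2, 3))
        mats = uniform_materials(mesh)
        K = assemble_system(mesh, mats)
        shift = np.array([0.3, -0.7, 1.1])
        bn = np.unique(mesh.boundary_facets)
        fd = (3 * bn[:, None] + np.arange(3)).ravel()
        u, _ = solve_dirichlet(K, np.zeros(K.shape[0]), fd,
                               np.tile(shift, bn.size))
        stress = element_stresses(mesh, mats, u)
        assert np.abs(stress).max() < 1e-8 * mats.E[0]

    def test_global_equilibrium(self):
        mesh, mats, case = self._bar(dims=(3, 3, 8))
        sol = solve_static(mesh, mats, case)
        f = pressure_forces(mesh, case.pressure_patches)
        gap = np.abs(sol.meta["equilibrium_gap_N"]).max()
        assert gap < 1e-6 * np.abs(f).sum()

    def test_underconstrained_rejected(self):
        mesh = box_mesh((2, 2, 2))
        K = assemble_system(mesh, uniform_materials(mesh))
        with pytest.raises(ValueError):
            solve_dirichlet(K, np.zeros(K.shape[0]), np.array([], int))


class TestVonMises:
    def test_uniaxial(self):
        assert von_mises(np.array([7.0, 0, 0, 0, 0, 0])) == pytest.approx(
            7.0)

    def test_hydrostatic_vanishes(self):
        assert von_mises(np.array([3.0, 3.0, 3.0, 0, 0, 0])) == \
            pytest.approx(0.0)

    def test_pure_shear(self):
        tau = 2.5
        assert von_mises(np.array([0, 0, 0, tau, 0, 0])) == pytest.approx(
            np.sqrt(3) * tau)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(s=st.lists(st.floats(-50, 50), min_size=6, max_size=6),
           angles=st.lists(st.floats(0, 2 * np.pi), min_size=3,
                           max_size=3))
    def test_frame_invariance(self, s, angles):
        s = np.asarray(s)
        T = np.array([[s[0], s[3], s[5]],
                      [s[3], s[1], s[4]],
                      [s[5], s[4], s[2]]])
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("xyz", angles).as_matrix()
        Tr = R @ T @ R.T
        rot = np.array([Tr[0, 0], Tr[1, 1], Tr[2, 2],
                        Tr[0, 1], Tr[1, 2], Tr[0, 2]])
        a, b = von_mises(s), von_mises(rot)
        assert np.isclose(a, b, rtol=1e-10, atol=1e-8)
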
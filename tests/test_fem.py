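import numpy as np
import pytest

import swellanchor as sa
from swellanchor import fem
from swellanchor.materials import MaterialState


def _uniform_material(n, E=1000.0, nu=0.3, rho=1.0):
    return MaterialState(np.full(n, rho), np.full(n, E), nu)


class TestSingleElement:
    def test_free_swelling_is_stress_free(self, single_element_mesh_2d):
        mesh = single_element_mesh_2d
        mat = _uniform_material(1)
        bc = fem.BoundaryConditions.free_swelling(mesh)
        st = fem.solve_hygroelastic(mesh, mat, {"all": 0.01}, bc)
        np.testing.assert_allclose(st.strain[0, :2], 0.01, atol=1e-14)
        assert np.abs(st.stress).max() < 1e-11
        assert st.sed[0] < 1e-25

    def test_clamped_element_matches_closed_form(self, single_element_mesh_2d):
        # all nodes fixed -> u = 0 -> sigma = -C eps0; plane strain isotropic:
        # sxx = syy = -E e / ((1+nu)(1-2nu))
        mesh = single_element_mesh_2d
        E, nu, e = 1000.0, 0.3, 0.01
        mat = _uniform_material(1, E=E, nu=nu)
        bc = fem.BoundaryConditions.fix_nodes(mesh, range(mesh.n_nodes))
        st = fem.solve_hygroelastic(mesh, mat, {"all": e}, bc)
        expected = -E * e / ((1 + nu) * (1 - 2 * nu))
        assert st.stress[0, 0] == pytest.approx(expected, rel=1e-12)
        assert st.stress[0, 1] == pytest.approx(expected, rel=1e-12)
        assert st.stress[0, 2] == pytest.approx(0.0, abs=1e-12)
        # SED from the independent closed form 1/2 sigma : eps_el
        assert st.sed[0] == pytest.approx(-expected * e, rel=1e-12)

    def test_rigid_translation_stores_no_energy(self):
        labels = fem.make_block_labels((3, 3))
        mesh = fem.VoxelMesh.from_labels(labels, 1.0, mode="plane_strain")
        mat = _uniform_material(mesh.n_elements)
        boundary = mesh.boundary_nodes()
        fixed = np.zeros((mesh.n_nodes, 2), dtype=bool)
        fixed[boundary] = True
        values = np.zeros((mesh.n_nodes, 2))
        values[boundary] = [0.3, -0.2]
        bc = fem.BoundaryConditions(fixed, values, tag="rigid")
        st = fem.solve_hygroelastic(mesh, mat, None, bc)
        assert st.total_strain_energy(mesh) < 1e-20
        expected = np.broadcast_to([0.3, -0.2], st.displacement.shape)
        np.testing.assert_allclose(st.displacement, expected, atol=1e-12)


class TestPatchTest:
    @pytest.mark.parametrize("shape, mode", [
        ((6, 5), "plane_stress"),
        ((4, 4, 3), "3d"),
    ])
    def test_uniform_eigenstrain_free_body(self, shape, mode):
        labels = fem.make_block_labels(shape)
        mesh = fem.VoxelMesh.from_labels(labels, 0.5, mode=mode)
        mat = _uniform_material(mesh.n_elements, E=2500.0)
        bc = fem.BoundaryConditions.free_swelling(mesh)
        e = 0.02
        st = fem.solve_hygroelastic(mesh, mat, {"all": e}, bc)
        dim = mesh.dim
        np.testing.assert_allclose(st.strain[:, :dim], e, rtol=1e-10)
        assert np.abs(st.stress).max() / (2500.0 * e) < 1e-10


class TestAssembly:
    def test_stiffness_symmetric_and_psd(self):
        labels = fem.make_block_labels((3, 2))
        mesh = fem.VoxelMesh.from_labels(labels, 1.0, mode="plane_strain")
        mat = _uniform_material(mesh.n_elements)
        K, f, _ = fem.assemble_system(mesh, mat, None)
        asym = abs(K - K.T).max()
        assert asym < 1e-10
        rng = np.random.default_rng(0)
        for _ in range(5):
            v = rng.standard_normal(K.shape[0])
            assert v @ (K @ v) >= -1e-9

    def test_insufficient_constraints_rejected(self, single_element_mesh_2d):
        mesh = single_element_mesh_2d
        mat = _uniform_material(1)
        bc = fem.BoundaryConditions.fix_nodes(mesh, [0], components=[0])
        with pytest.raises(ValueError, match="rigid-body"):
            fem.solve_hygroelastic(mesh, mat, None, bc)

    def test_nonpositive_modulus_rejected(self, single_element_mesh_2d):
        mesh = single_element_mesh_2d
        with pytest.raises(ValueError):
            MaterialState(np.array([1.0]), np.array([-5.0]), 0.3)

    def test_per_element_eigenstrain_array(self):
        labels = fem.make_block_labels((2, 1))
        mesh = fem.VoxelMesh.from_labels(labels, 1.0, mode="plane_strain")
        mat = _uniform_material(2)
        bc = fem.BoundaryConditions.free_swelling(mesh)
        st = fem.solve_hygroelastic(mesh, mat, np.array([0.01, 0.01]), bc)
        np.testing.assert_allclose(st.eigenstrain, [0.01, 0.01])
        with pytest.raises(ValueError):
            fem.solve_hygroelastic(mesh, mat, np.array([0.01]), bc)


class TestElementSed:
    def test_zero(self):
        assert fem.element_sed(np.zeros(3), np.zeros(3)) == 0.0

    def test_uniaxial(self):
        # sigma_xx = 2 MPa, eps_xx = 0.001 -> 0.001 J/cm^3
        u = fem.element_sed(np.array([2.0, 0, 0]), np.array([0.001, 0, 0]))
        assert u == pytest.approx(0.001)

    def test_pure_shear_engineering_convention(self):
        # tensor shear eps_xy = 0.0005 -> engineering gamma = 0.001;
        # U = 1/2 * 2 * sigma_xy * eps_xy = 0.0005 J/cm^3
        u = fem.element_sed(np.array([0, 0, 1.0]), np.array([0, 0, 0.001]))
        assert u == pytest.approx(0.0005)


class TestStimulusField:
    def _state_with_sed(self, mesh, sed):
        nv = 3 if mesh.dim == 2 else 6
        z = np.zeros((mesh.n_elements, nv))
        return fem.FieldState(np.zeros((mesh.n_nodes, mesh.dim)), z, z, z,
                              np.asarray(sed, dtype=float),
                              np.zeros(mesh.n_elements))

    def test_division_examples(self):
        labels = fem.make_block_labels((3, 1))
        mesh = fem.VoxelMesh.from_labels(labels, 1.0, mode="plane_strain")
        mat = MaterialState(np.array([1.1, 1.0, 0.01]),
                            np.full(3, 100.0), 0.3)
        st = self._state_with_sed(mesh, [0.0044, 0.0, 0.02])
        S = fem.stimulus_field(st, mat, mesh)
        np.testing.assert_allclose(S, [0.004, 0.0, 2.0])

    def test_anchor_elements_carry_zero(self):
        from swellanchor import microct
        labels = np.array([[microct.REGION_BONE, microct.REGION_ANCHOR]], dtype=np.int8).T
        mesh = fem.VoxelMesh.from_labels(labels, 1.0, mode="plane_strain")
        mat = MaterialState(np.array([1.0, 1.0]), np.full(2, 100.0), 0.3)
        st = self._state_with_sed(mesh, [0.01, 0.5])
        S = fem.stimulus_field(st, mat, mesh)
        assert S[mesh.region == fem.REGION_ANCHOR][0] == 0.0

    def test_corrupted_density_rejected(self):
        labels = fem.make_block_labels((1, 1))
        mesh = fem.VoxelMesh.from_labels(labels, 1.0, mode="plane_strain")
        mat = MaterialState(np.array([0.02]), np.array([100.0]), 0.3)
        mat.density[0] = 0.001  # corrupt after validation
        st = self._state_with_sed(mesh, [0.01])
        with pytest.raises(ValueError, match="rho_min"):
            fem.stimulus_field(st, mat, mesh)


class TestLameShrinkfitOracle:
    def test_zero_interference_zero_pressure(self):
        assert fem.lame_shrinkfit_oracle(4, 8, 6000, 0.3, 6000, 0.3, 0.0) == 0.0

    def test_pressure_grows_with_wall_thickness(self):
        # a thicker annulus is a stiffer constraint, so the interface
        # pressure increases monotonically with b and saturates as b -> inf
        a = 4.0
        ps = [fem.lame_shrinkfit_oracle(a, b, 2500, 0.3, 6000, 0.3, 0.05)
              for b in (10 * a, 100 * a)]
        assert ps[0] < ps[1]
        limit = 0.05 / (1.0 / 6000 + 0.3 / 6000 + 0.7 / 2500)
        assert ps[1] == pytest.approx(limit, rel=1e-3)

    def test_invalid_radii(self):
        with pytest.raises(ValueError):
            fem.lame_shrinkfit_oracle(8, 4, 2500, 0.3, 6000, 0.3, 0.05)


def test_mesh_convergence_runner_stops_on_small_change():
    seen = []

    def run(h):
        seen.append(h)
        return 10.0 + h  # 5% rule satisfied between the first two levels

    table = fem.mesh_convergence(run, h0=0.4, rtol=0.05, max_levels=5)
    assert len(table) == 2
    assert table["rel_change"].iloc[-1] < 0.05
    assert seen == [0.4, 0.2]


def test_von_mises_uniaxial():
    assert fem.von_mises(np.array([3.0, 0.0, 0.0]), "plane_stress") == pytest.approx(3.0)
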
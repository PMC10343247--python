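"""Embedded bar fibers: path segmentation, strain transformation, fiber
stiffness and superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from braidfe.embedded import (
    ElementLocator,
    FiberPath,
    direction_row,
    fiber_stiffness,
    fiber_strain_row,
    segment_fibers,
    superpose,
)
from braidfe.hexfem import box_mesh, elastic_matrix, element_stiffness, strain_matrix
from braidfe.materials import IsotropicMaterial


def _single_segment(mesh, p0, p1, area=1.0, Ef=1.0):
    path = FiberPath(points=[p0, p1], area=area, Ef=Ef)
    segs = segment_fibers(mesh, path)
    return path, segs


class TestFiberPath:
    def test_validation(self):
        with pytest.raises(ValueError, match="at least 2"):
            FiberPath(points=[[0, 0, 0]], area=1.0, Ef=1.0)
        with pytest.raises(ValueError, match="distinct"):
            FiberPath(points=[[0, 0, 0], [0, 0, 0]], area=1.0, Ef=1.0)
        with pytest.raises(ValueError, match="area"):
            FiberPath(points=[[0, 0, 0], [1, 0, 0]], area=0.0, Ef=1.0)

    def test_length(self):
        f = FiberPath(points=[[0, 0, 0], [1, 0, 0], [1, 1, 0]], area=1.0, Ef=1.0)
        assert f.length == pytest.approx(2.0)


class TestSegmentation:
    def test_face_crossing_splits_in_two(self):
        mesh = box_mesh((2, 1, 1), (2, 1, 1))
        _, segs = _single_segment(mesh, [0.1, 0.5, 0.5], [1.9, 0.5, 0.5])
        assert [s.element for s in segs] == [0, 1]
        assert sum(s.length for s in segs) == pytest.approx(1.8, rel=1e-12)
        # split exactly at the shared face x=1
        assert segs[0].p1[0] == pytest.approx(1.0, abs=1e-8)

    def test_contained_fiber_natural_coords(self, unit_cube):
        """Newton inversion matches the closed-form affine mapping."""
        _, segs = _single_segment(unit_cube, [0.2, 0.3, 0.4], [0.8, 0.6, 0.5])
        (s,) = segs
        assert np.allclose(s.xi0, [2 * 0.2 - 1, 2 * 0.3 - 1, 2 * 0.4 - 1], atol=1e-8)
        assert np.allclose(s.xi1, [2 * 0.8 - 1, 2 * 0.6 - 1, 2 * 0.5 - 1], atol=1e-8)
        d = s.direction
        assert d @ d == pytest.approx(1.0, abs=1e-12)

    def test_length_conservation_through_many_elements(self):
        mesh = box_mesh((4, 2, 1), (8, 4, 2))
        path = FiberPath(
            points=[[0.05, 0.1, 0.3], [3.9, 1.9, 0.7], [0.2, 1.8, 0.2]],
            area=0.5, Ef=10.0,
        )
        segs = segment_fibers(mesh, path)
        assert sum(s.length for s in segs) == pytest.approx(path.length, rel=1e-9)
        assert len({s.element for s in segs}) > 4

    def test_thin_element_not_skipped(self):
        """Elements much thinner than the scan step still get their piece."""
        xs = [0.0, 0.45, 0.5, 1.0]
        nodes, elements = [], []
        for k, x in enumerate(xs):
            for y in (0.0, 1.0):
                for z in (0.0, 1.0):
                    nodes.append([x, y, z])
        for k in range(3):
            b = 4 * k
            elements.append([b, b + 4, b + 6, b + 2, b + 1, b + 5, b + 7, b + 3])
        from braidfe.hexfem import HexMesh

        mesh = HexMesh(np.array(nodes), np.array(elements))
        _, segs = _single_segment(mesh, [0.01, 0.5, 0.5], [0.99, 0.5, 0.5])
        assert [s.element for s in segs] == [0, 1, 2]
        assert segs[1].length == pytest.approx(0.05, abs=1e-6)

    def test_outside_point_raises_or_drops(self, unit_cube):
        path = FiberPath(points=[[0.5, 0.5, 0.5], [2.5, 0.5, 0.5]], area=1.0, Ef=1.0)
        with pytest.raises(ValueError, match="outside"):
            segment_fibers(unit_cube, path)
        segs = segment_fibers(unit_cube, path, drop_outside=True)
        assert sum(s.length for s in segs) == pytest.approx(0.5, abs=1e-6)


class TestFiberStrainRow:
    def test_axis_aligned_equals_eps_x_row(self, unit_cube):
        _, (seg,) = _single_segment(unit_cube, [0.01, 0.5, 0.5], [0.99, 0.5, 0.5])
        X = unit_cube.element_coords(0)
        B, _ = strain_matrix(X, [0, 0, 0])
        assert np.allclose(fiber_strain_row(seg, X, 0.0), B[0], atol=1e-9)

    def test_45_degree_fiber_under_simple_shear(self):
        """A fiber at 45 deg in the xy-plane sees gamma_xy / 2."""
        row = direction_row(np.array([1, 1, 0]) / np.sqrt(2))
        eps = np.array([0, 0, 0, 0, 0, 1.0])  # pure gamma_xy
        assert row @ eps == pytest.approx(0.5)

    def test_volumetric_strain_any_direction(self, rng):
        eps = np.array([1.0, 1, 1, 0, 0, 0])
        for _ in range(5):
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            assert direction_row(d) @ eps == pytest.approx(1.0)

    def test_rigid_motion_gives_zero_fiber_strain(self, unit_cube):
        _, (seg,) = _single_segment(unit_cube, [0.2, 0.3, 0.2], [0.7, 0.8, 0.9])
        X = unit_cube.element_coords(0)
        u = np.tile([0.4, -0.1, 2.0], 8)
        assert fiber_strain_row(seg, X, 0.3) @ u == pytest.approx(0.0, abs=1e-12)


class TestFiberStiffness:
    def test_axial_bar_matches_truss_EA_over_L(self, unit_cube):
        """Full-span axial fiber adds exactly EA/L between the end faces."""
        _, (seg,) = _single_segment(unit_cube, [1e-9, 0.5, 0.5], [1 - 1e-9, 0.5, 0.5])
        X = unit_cube.element_coords(0)
        kf = fiber_stiffness(seg, X, Ef=1.0, area=1.0)
        u = np.zeros(24)
        u[0::3] = X[:, 0]  # unit relative axial displacement of the faces
        assert u @ kf @ u == pytest.approx(1.0, rel=1e-6)  # EA/L = 1
        assert np.allclose(kf, kf.T)
        assert np.linalg.matrix_rank(kf, tol=1e-12) <= 2

    def test_zero_modulus_gives_zero(self, unit_cube):
        _, (seg,) = _single_segment(unit_cube, [0.1, 0.2, 0.3], [0.9, 0.7, 0.6])
        kf = fiber_stiffness(seg, unit_cube.element_coords(0), Ef=0.0, area=2.0)
        assert np.abs(kf).max() == 0.0

    def test_collinear_halves_sum_to_whole(self, unit_cube):
        X = unit_cube.element_coords(0)
        _, (whole,) = _single_segment(unit_cube, [0.1, 0.5, 0.5], [0.9, 0.5, 0.5])
        _, (h1,) = _single_segment(unit_cube, [0.1, 0.5, 0.5], [0.5, 0.5, 0.5])
        _, (h2,) = _single_segment(unit_cube, [0.5, 0.5, 0.5], [0.9, 0.5, 0.5])
        k_whole = fiber_stiffness(whole, X, 3.0, 0.7)
        k_sum = fiber_stiffness(h1, X, 3.0, 0.7) + fiber_stiffness(h2, X, 3.0, 0.7)
        assert np.abs(k_whole - k_sum).max() < 1e-10 * np.abs(k_whole).max()


class TestSuperpose:
    def test_no_fibers_is_identity(self, unit_cube, pcu):
        km = element_stiffness(unit_cube.element_coords(0), elastic_matrix(pcu))
        assert np.array_equal(superpose(km, []).k, km.k)

    def test_mismatched_element_rejected(self, unit_cube, pcu):
        km = element_stiffness(unit_cube.element_coords(0), elastic_matrix(pcu), 3)
        with pytest.raises(ValueError, match="element"):
            superpose(km, [(5, np.zeros((24, 24)))])

    def test_contribution_scales_linearly(self, unit_cube, pcu):
        X = unit_cube.element_coords(0)
        km = element_stiffness(X, elastic_matrix(pcu))
        _, (seg,) = _single_segment(unit_cube, [0.1, 0.5, 0.5], [0.9, 0.5, 0.5])
        kf = fiber_stiffness(seg, X, 100.0, 0.1)
        one = superpose(km, [(0, kf)]).k
        three = superpose(km, [(0, kf)] * 3).k
        assert np.allclose(three - km.k, 3 * (one - km.k))

    def test_voxel_rule_of_mixtures(self, unit_cube):
        """Uniaxial modulus of a fiber-reinforced element is Em + (A/Acell) Ef."""
        mat = IsotropicMaterial(E=57.0, v=0.0)  # v=0 isolates the axial response
        X = unit_cube.element_coords(0)
        km = element_stiffness(X, elastic_matrix(mat))
        Ef, A = 90000.0, 0.02
        _, (seg,) = _single_segment(unit_cube, [1e-9, 0.5, 0.5], [1 - 1e-9, 0.5, 0.5])
        ke = superpose(km, [(0, fiber_stiffness(seg, X, Ef, A))]).k
        u = np.zeros(24)
        u[0::3] = X[:, 0]  # unit axial strain
        E_eff = u @ ke @ u  # energy = E_eff * V * eps^2 with V = eps = 1
        assert E_eff == pytest.approx(57.0 + A * Ef, rel=1e-2)


class TestInvariants:
    def test_volume_conservation_per_path(self):
        mesh = box_mesh((3, 1, 1), (6, 2, 2))
        path = FiberPath(
            points=[[0.1, 0.2, 0.5], [2.9, 0.8, 0.5], [2.9, 0.2, 0.9]],
            area=0.25, Ef=1.0,
        )
        segs = segment_fibers(mesh, path)
        vol = sum(path.area * s.length for s in segs)
        assert vol == pytest.approx(path.area * path.length, rel=1e-5)

    def test_orientation_invariance_of_energy(self, rng):
        """Rotating mesh, fiber and loads together leaves the energy fixed."""
        mesh = box_mesh((1, 1, 1), (2, 2, 2))
        path = FiberPath(points=[[0.1, 0.4, 0.6], [0.9, 0.6, 0.4]], area=0.3, Ef=500.0)
        u = rng.standard_normal(3 * mesh.n_nodes)

        def energy(mesh, path, u):
            total = 0.0
            for seg in segment_fibers(mesh, path):
                X = mesh.element_coords(seg.element)
                kf = fiber_stiffness(seg, X, path.Ef, path.area)
                dofs = (3 * mesh.elements[seg.element][:, None] + np.arange(3)).ravel()
                total += u[dofs] @ kf @ u[dofs]
            return total

        e0 = energy(mesh, path, u)
        R = Rotation.from_rotvec([0.4, 0.2, -0.6]).as_matrix()
        from braidfe.hexfem import HexMesh

        mesh_r = HexMesh(mesh.nodes @ R.T, mesh.elements)
        path_r = FiberPath(points=np.asarray(path.points) @ R.T, area=0.3, Ef=500.0)
        u_r = (u.reshape(-1, 3) @ R.T).ravel()
        assert energy(mesh_r, path_r, u_r) == pytest.approx(e0, rel=1e-8)
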
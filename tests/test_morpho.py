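"""Morphometry: tallies, contact areas, min distances and sections
against analytic values and brute-force scans."""

import numpy as np
import pytest

from ngvkit.glam_morphometrics import (
    GranuleSet,
    MeshValidationError,
    SurfaceMesh,
    contact_area,
    cross_section_area,
    min_distance,
    nearest_element_tally,
)
from ngvkit.glam_morphometrics.geometry import closest_point_on_triangles
from ngvkit.synthetic_data import box_mesh, capped_tube, flat_patch, icosphere


def _sphere(r=1.0, c=(0, 0, 0), sub=2, cls="bouton", oid=0):
    v, f = icosphere(r, c, subdivisions=sub)
    return SurfaceMesh(v, f, mesh_class=cls, object_id=oid)


class TestTally:
    def test_nearest_wins(self):
        bouton = _sphere(0.5, (0, 0, 0), cls="bouton", oid=0)
        axon = _sphere(0.5, (5, 0, 0), cls="axon", oid=1)
        g = GranuleSet(np.array([[0.0, 0.0, 0.6]]), np.array([0.02]))
        result = nearest_element_tally(g, [bouton, axon])
        assert result.per_class["bouton"] == 1
        assert "axon" not in result.per_class

    def test_counts_sum_to_granules(self):
        meshes = [_sphere(0.5, (i * 3, 0, 0), cls=c, oid=i)
                  for i, c in enumerate(["bouton", "axon", "spine"])]
        rng = np.random.default_rng(0)
        g = GranuleSet(rng.uniform(-1, 8, size=(40, 3)), np.full(40, 0.02))
        result = nearest_element_tally(g, meshes)
        assert result.per_class.sum() == 40
        assert result.per_object.sum() == 40
        assert len(result.assignment) == 40

    def test_tie_breaks_to_lower_object_id(self):
        a = _sphere(0.5, (-1.0, 0, 0), cls="axon", oid=7)
        b = _sphere(0.5, (1.0, 0, 0), cls="bouton", oid=2)
        g = GranuleSet(np.array([[0.0, 0.0, 0.0]]), np.array([0.02]))
        result = nearest_element_tally(g, [a, b])
        assert result.assignment.loc[0, "object_id"] == 2

    def test_empty_mesh_list_rejected(self):
        g = GranuleSet(np.array([[0.0, 0, 0]]), np.array([0.02]))
        with pytest.raises(ValueError):
            nearest_element_tally(g, [])


class TestContactArea:
    def test_parallel_patches_within_epsilon(self):
        va, fa = flat_patch(10.0, 5)
        vb, fb = flat_patch(10.0, 5, center=(0, 0, 0.5))
        a = SurfaceMesh(va, fa, object_id=0)
        b = SurfaceMesh(vb, fb, object_id=1)
        assert contact_area(a, b, epsilon=1.0) == pytest.approx(100.0)
        assert contact_area(a, b, epsilon=0.1) == 0.0

    def test_sphere_above_plane_vs_brute(self):
        sph = _sphere(1.0, (0, 0, 1.2), sub=3)
        vp, fp = flat_patch(8.0, 8)
        plane = SurfaceMesh(vp, fp, object_id=1)
        fast = contact_area(sph, plane, epsilon=0.5)
        brute = contact_area(sph, plane, epsilon=0.5, brute=True)
        assert fast == pytest.approx(brute, abs=1e-12)
        assert 0 < fast < sph.area

    def test_monotone_in_epsilon(self):
        sph = _sphere(1.0, (0, 0, 1.2), sub=2)
        vp, fp = flat_patch(8.0, 8)
        plane = SurfaceMesh(vp, fp, object_id=1)
        areas = [contact_area(sph, plane, e) for e in (0.25, 0.5, 1.0, 2.0)]
        assert all(x <= y for x, y in zip(areas, areas[1:]))

    def test_not_symmetric_by_convention(self):
        sph = _sphere(1.0, (0, 0, 1.2), sub=2)
        vp, fp = flat_patch(8.0, 8)
        plane = SurfaceMesh(vp, fp, object_id=1)
        assert contact_area(sph, plane, 0.5) != contact_area(plane, sph, 0.5)

    def test_epsilon_positive_required(self):
        sph = _sphere()
        with pytest.raises(ValueError):
            contact_area(sph, sph, epsilon=0.0)


class TestMinDistance:
    def test_two_unit_spheres(self):
        a = _sphere(1.0, (0, 0, 0), sub=3, oid=0)
        b = _sphere(1.0, (4, 0, 0), sub=3, oid=1)
        d, pa, pb = min_distance(a, b)
        assert d == pytest.approx(2.0, rel=0.01)
        np.testing.assert_allclose(pa, [1, 0, 0], atol=0.05)
        np.testing.assert_allclose(pb, [3, 0, 0], atol=0.05)

    def test_overlapping_zero(self):
        a = _sphere(1.0, (0, 0, 0), sub=2, oid=0)
        b = _sphere(1.0, (1.0, 0, 0), sub=2, oid=1)
        d, _, _ = min_distance(a, b)
        assert d == 0.0

    def test_symmetric(self):
        a = _sphere(0.7, (0, 0, 0), sub=2, oid=0)
        v, f = capped_tube((3, -2, 0.4), (3, 2, 0.4), 0.5)
        b = SurfaceMesh(v, f, object_id=1)
        d_ab, _, _ = min_distance(a, b)
        d_ba, _, _ = min_distance(b, a)
        assert d_ab == pytest.approx(d_ba, abs=1e-12)

    def test_matches_exhaustive_pair_scan(self):
        from ngvkit.glam_morphometrics.geometry import triangle_triangle_distance

        a = _sphere(0.6, (0, 0, 0), sub=1, oid=0)
        v, f = box_mesh((1.5, -1, -1), (3.0, 1, 1))
        b = SurfaceMesh(v, f, object_id=1)
        d, _, _ = min_distance(a, b)
        brute = min(
            triangle_triangle_distance(a.tri_pts[i], b.tri_pts[j])
            for i in range(len(a.triangles)) for j in range(len(b.triangles))
        )
        assert d == pytest.approx(brute, abs=1e-12)

    def test_empty_rejected(self):
        a = _sphere()
        empty = SurfaceMesh(np.empty((0, 3)), np.empty((0, 3), dtype=int))
        with pytest.raises(ValueError):
            min_distance(a, empty)


class TestCrossSection:
    def test_cube_mid_height_exact(self):
        v, f = box_mesh((0, 0, 0), (2, 2, 2))
        cube = SurfaceMesh(v, f)
        area, perim = cross_section_area(cube, (1, 1, 1), (0, 0, 1))
        assert area == pytest.approx(4.0, abs=1e-12)
        assert perim == pytest.approx(8.0, abs=1e-12)

    def test_sphere_through_center(self):
        sph = _sphere(1.0, sub=3)
        area, perim = cross_section_area(sph, (0, 0, 0), (0, 0, 1))
        assert area == pytest.approx(np.pi, rel=0.01)
        assert perim == pytest.approx(2 * np.pi, rel=0.01)

    def test_sphere_offset_section(self):
        sph = _sphere(1.0, sub=3)
        area, _ = cross_section_area(sph, (0, 0, 0.5), (0, 0, 1))
        assert area == pytest.approx(np.pi * 0.75, rel=0.02)

    def test_plane_missing_mesh(self):
        sph = _sphere(1.0, sub=2)
        assert cross_section_area(sph, (0, 0, 5.0), (0, 0, 1)) == (0.0, 0.0)

    def test_oblique_plane_on_cube(self):
        v, f = box_mesh((-1, -1, -1), (1, 1, 1))
        cube = SurfaceMesh(v, f)
        n = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        area, _ = cross_section_area(cube, (0, 0, 0), n)
        assert area == pytest.approx(2 * np.sqrt(2) * 2, rel=1e-9)

    def test_non_watertight_rejected(self):
        v, f = flat_patch(2.0, 2)
        open_mesh = SurfaceMesh(v, f)
        with pytest.raises(MeshValidationError, match="watertight"):
            cross_section_area(open_mesh, (0, 0, 0), (0, 0, 1))

    def test_tube_section_matches_circle(self):
        v, f = capped_tube((0, 0, -2), (0, 0, 2), 0.8, n_seg=64)
        tube = SurfaceMesh(v, f)
        area, perim = cross_section_area(tube, (0, 0, 0), (0, 0, 1))
        # inscribed regular 64-gon
        expected = 0.5 * 64 * 0.8 ** 2 * np.sin(2 * np.pi / 64)
        assert area == pytest.approx(expected, rel=1e-9)


class TestMeshValidation:
    def test_zero_area_triangle_named(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [2, 0, 0]], dtype=float)
        f = np.array([[0, 1, 2], [0, 1, 3]])      # second is collinear
        with pytest.raises(MeshValidationError, match="1"):
            SurfaceMesh(v, f).validate()

    def test_out_of_range_index(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        f = np.array([[0, 1, 5]])
        with pytest.raises(MeshValidationError, match="out of range"):
            SurfaceMesh(v, f).validate()

    def test_watertight_flags(self):
        v, f = icosphere(1.0, subdivisions=1)
        assert SurfaceMesh(v, f).watertight
        v, f = flat_patch(1.0, 2)
        m = SurfaceMesh(v, f)
        assert m.consistent_winding and not m.watertight

    def test_outward_orientation_positive_volume(self):
        v, f = box_mesh((0, 0, 0), (1, 1, 1))
        m = SurfaceMesh(v, f)
        assert m.signed_volume == pytest.approx(1.0)
        assert m.flipped().signed_volume == pytest.approx(-1.0)
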
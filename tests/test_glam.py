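"""Absorption-map tests: closed-form irradiance, superposition,
occlusion, Monte-Carlo convergence and aggregation."""

import numpy as np
import pytest

from ngvkit.glam_morphometrics import (
    GranuleSet,
    SurfaceMesh,
    absorption_map,
    aggregate_absorption,
    granule_power,
)
from ngvkit.synthetic_data import flat_patch, icosphere

#: radius for which the volume power law yields exactly P = 1
R_UNIT = (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


@pytest.fixture(scope="module")
def patch():
    v, f = flat_patch(4.0, 20)
    mesh = SurfaceMesh(v, f, mesh_class="bouton", object_id=0, name="patch")
    mesh.validate()
    return mesh


def _granule(x=0.0, y=0.0, z=1.0, r=R_UNIT):
    return GranuleSet(np.array([[x, y, z]]), np.array([r]))


class TestGranulePower:
    def test_zero_radius(self):
        assert granule_power(0.0) == 0.0

    def test_cubic_scaling(self):
        assert granule_power(2.0) == pytest.approx(8 * granule_power(1.0))

    def test_coefficient_normalization(self):
        assert granule_power(1.0, k=3.0 / (4.0 * np.pi)) == pytest.approx(1.0)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            granule_power(-0.1)


class TestAnalytic:
    def test_closed_form_directly_beneath(self, patch):
        maps = absorption_map([patch], _granule(z=1.0))
        foot = int(np.argmin(np.linalg.norm(patch.vertices, axis=1)))
        assert maps[0].values[foot] == pytest.approx(1.0 / (4 * np.pi), rel=1e-9)

    def test_superposition_exact(self, patch):
        one = absorption_map([patch], _granule())[0].values
        g2 = GranuleSet(np.array([[0, 0, 1.0], [0, 0, 1.0]]),
                        np.array([R_UNIT, R_UNIT]))
        two = absorption_map([patch], g2)[0].values
        np.testing.assert_array_equal(two, 2 * one)

    def test_linearity_in_power(self, patch):
        base = absorption_map([patch], _granule())[0].values
        scaled = absorption_map([patch], _granule(), power_coeff=3.0)[0].values
        np.testing.assert_allclose(scaled, 3 * base, rtol=1e-12)

    def test_inverse_square_slope(self, patch):
        foot = int(np.argmin(np.linalg.norm(patch.vertices, axis=1)))
        hs = np.geomspace(0.5, 8.0, 12)
        es = [absorption_map([patch], _granule(z=h))[0].values[foot] for h in hs]
        slope = np.polyfit(np.log(hs), np.log(es), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.02)

    def test_below_surface_contributes_nothing(self, patch):
        maps = absorption_map([patch], _granule(z=-1.0))
        assert np.all(maps[0].values == 0.0)

    def test_granule_on_surface_rejected(self, patch):
        with pytest.raises(ValueError, match="on target surface"):
            absorption_map([patch], _granule(z=0.0))


class TestOcclusion:
    def test_occluder_blocks(self, patch):
        ov, of = flat_patch(4.0, 4, center=(0, 0, 0.5))
        occ = SurfaceMesh(ov, of, mesh_class="astrocyte", object_id=9)
        open_map = absorption_map([patch], _granule())[0].values
        shut = absorption_map([patch], _granule(), occlusion=True,
                              extra_occluders=[occ])[0].values
        assert np.all(shut == 0.0)
        assert open_map.max() > 0

    def test_partial_shadow(self, patch):
        ov, of = flat_patch(1.0, 2, center=(0, 0, 0.5))
        occ = SurfaceMesh(ov, of, mesh_class="astrocyte", object_id=9)
        open_map = absorption_map([patch], _granule())[0].values
        shut = absorption_map([patch], _granule(), occlusion=True,
                              extra_occluders=[occ])[0].values
        assert np.all(shut <= open_map + 1e-15)
        assert shut.max() > 0          # penumbra region still lit
        assert (shut < open_map - 1e-12).any()

    def test_host_mesh_not_occluding_by_default(self, patch):
        # granule inside its host: host surfaces must not shadow
        hv, hf = icosphere(0.5, center=(0, 0, 1.0), subdivisions=2)
        host = SurfaceMesh(hv, hf, mesh_class="astrocyte", object_id=3)
        g = GranuleSet(np.array([[0, 0, 1.0]]), np.array([R_UNIT]),
                       np.array([3]))
        open_map = absorption_map([patch], g)[0].values
        hosted = absorption_map([patch], g, occlusion=True,
                                extra_occluders=[host])[0].values
        np.testing.assert_array_equal(hosted, open_map)
        # flag restores the shadowing
        blocked = absorption_map([patch], g, occlusion=True,
                                 extra_occluders=[host],
                                 include_host_occluder=True)[0].values
        assert np.all(blocked == 0.0)


class TestMonteCarlo:
    def test_requires_photons_and_seed(self, patch):
        with pytest.raises(ValueError, match="n_photons"):
            absorption_map([patch], _granule(), mode="montecarlo")
        with pytest.raises(ValueError, match="seed"):
            absorption_map([patch], _granule(), mode="montecarlo", n_photons=10)

    def test_deterministic_given_seed(self, patch):
        a = absorption_map([patch], _granule(), mode="montecarlo",
                           n_photons=2000, seed=5)[0].values
        b = absorption_map([patch], _granule(), mode="montecarlo",
                           n_photons=2000, seed=5)[0].values
        np.testing.assert_array_equal(a, b)

    def test_within_three_se_of_analytic(self, patch):
        exact = absorption_map([patch], _granule())[0].values
        mc = absorption_map([patch], _granule(), mode="montecarlo",
                            n_photons=30000, seed=8)[0]
        inner = np.flatnonzero(
            np.all(np.abs(patch.vertices[:, :2]) < 1.5, axis=1))
        z = (mc.values[inner] - exact[inner]) / np.maximum(mc.stderr[inner], 1e-12)
        assert np.abs(z).max() < 3.0

    def test_occluded_leq_unoccluded_same_seed(self, patch):
        ov, of = flat_patch(1.0, 2, center=(0, 0, 0.5))
        occ = SurfaceMesh(ov, of, mesh_class="astrocyte", object_id=9)
        free = absorption_map([patch], _granule(), mode="montecarlo",
                              n_photons=5000, seed=3)[0].values
        shut = absorption_map([patch], _granule(), mode="montecarlo",
                              n_photons=5000, seed=3, occlusion=True,
                              extra_occluders=[occ])[0].values
        assert np.all(shut <= free + 1e-15)


class TestAggregate:
    def test_empty_granules_zero_total(self, patch):
        g = GranuleSet(np.empty((0, 3)), np.empty(0), np.empty(0, dtype=int))
        amap = absorption_map([patch], g)[0]
        summary = aggregate_absorption(amap)
        assert summary.total == 0.0

    def test_totals_additive_over_partition(self, patch):
        v, f = flat_patch(4.0, 10, center=(10, 0, 0))
        other = SurfaceMesh(v, f, mesh_class="spine", object_id=1)
        g = _granule(z=1.0)
        maps = absorption_map([patch, other], g)
        totals = [aggregate_absorption(m).total for m in maps]
        both = GranuleSet(np.array([[0, 0, 1.0]]), np.array([R_UNIT]))
        # union total = sum of part totals (maps are independent per target)
        assert sum(totals) == pytest.approx(totals[0] + totals[1])
        assert totals[0] > totals[1] > 0

    def test_top1_is_vertex_nearest_foot_point(self, patch):
        amap = absorption_map([patch], _granule(x=0.31, y=-0.52))[0]
        summary = aggregate_absorption(amap, top_k=1)
        brute = int(np.argmax(amap.values))
        assert summary.top_vertices[0] == brute
        foot = np.array([0.31, -0.52, 0.0])
        d = np.linalg.norm(patch.vertices - foot, axis=1)
        assert brute == int(np.argmin(d))

    def test_top_k_patches_connected(self, patch):
        amap = absorption_map([patch], _granule())[0]
        summary = aggregate_absorption(amap, top_k=6)
        # vertices around the foot point form one connected patch
        assert len(summary.patches) == 1
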
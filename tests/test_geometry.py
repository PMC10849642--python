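"""Vessel geometry: distance fields, centerlines, arc length, diameter."""

import numpy as np
import pytest

from conftest import brute_force_distance, make_arc_tube_mask, make_cylinder_mask
from vesseltau.geometry import (
    VesselRecord,
    assign_arclength,
    compute_distance_field,
    estimate_diameter,
    extract_centerline,
)

VOXEL_DIAG = np.sqrt(3.0)


class TestDistanceField:
    def test_single_voxel_neighbors(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        f = compute_distance_field(mask, (1, 1, 1))
        assert f.values[1, 1, 1] == 0.0
        assert f.values[1, 1, 2] == 1.0
        assert f.values[0, 0, 0] == pytest.approx(np.sqrt(3))

    def test_anisotropic_spacing(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        f = compute_distance_field(mask, (2.0, 1.0, 1.0))
        assert f.values[0, 1, 1] == 2.0
        assert f.values[1, 0, 1] == 1.0

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(10):
            shape = tuple(rng.integers(3, 13, 3))
            mask = rng.random(shape) < 0.1
            if not mask.any():
                mask.flat[0] = True
            vs = tuple(rng.uniform(0.5, 3.0, 3))
            f = compute_distance_field(mask, vs)
            oracle = brute_force_distance(mask, vs)
            np.testing.assert_allclose(f.values, oracle, rtol=0, atol=1e-10)

    def test_lipschitz_in_um(self, rng):
        mask = rng.random((10, 10, 10)) < 0.05
        mask[5, 5, 5] = True
        vs = (2.0, 1.0, 0.8)
        f = compute_distance_field(mask, vs)
        for ax, step in enumerate(vs):
            d = np.abs(np.diff(f.values, axis=ax))
            assert d.max() <= step + 1e-9

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_distance_field(np.zeros((4, 4, 4), bool), (1, 1, 1))


class TestCenterline:
    def test_one_voxel_wide_line(self):
        mask = np.zeros((5, 5, 50), bool)
        mask[2, 2, :] = True
        with pytest.warns(UserWarning, match="no interior"):
            cl = extract_centerline(mask, (1, 1, 1))
        assert cl.total_length_um == pytest.approx(49.0, abs=1.0)
        assert np.allclose(cl.nodes[:, 0], 2.5, atol=0.6)
        assert np.allclose(cl.nodes[:, 1], 2.5, atol=0.6)

    def test_straight_cylinder_axis_recovery(self):
        mask = make_cylinder_mask(radius_vox=3, length_vox=60)
        cl = extract_centerline(mask, (1, 1, 1))
        assert cl.total_length_um == pytest.approx(60.0, rel=0.05)
        c = mask.shape[0] / 2
        dev = np.linalg.norm(cl.nodes[:, :2] - c, axis=1)
        assert dev.max() <= VOXEL_DIAG

    def test_quarter_circle_arc_length(self):
        mask, _, true_len = make_arc_tube_mask(bend_radius_um=40, tube_radius_um=3)
        cl = extract_centerline(mask, (1, 1, 1))
        assert cl.total_length_um == pytest.approx(true_len, rel=0.05)

    def test_disconnected_mask_reports_count(self):
        mask = np.zeros((6, 6, 20), bool)
        mask[2, 2, 2:6] = True
        mask[2, 2, 12:16] = True
        with pytest.raises(ValueError, match="2"):
            extract_centerline(mask, (1, 1, 1))

    def test_arclength_nondecreasing_and_spacing(self):
        mask = make_cylinder_mask(radius_vox=3, length_vox=40)
        cl = extract_centerline(mask, (1, 1, 1))
        assert np.all(np.diff(cl.cumulative_arclength) >= 0)
        assert np.all(np.diff(cl.cumulative_arclength) <= VOXEL_DIAG)


class TestAssignArclength:
    def _line_centerline(self):
        mask = np.zeros((5, 5, 30), bool)
        mask[2, 2, :] = True
        with pytest.warns(UserWarning):
            return extract_centerline(mask, (1, 1, 1))

    def test_node_coincident_point(self):
        cl = self._line_centerline()
        k = 7
        arc = assign_arclength(cl.nodes[k], cl)
        assert arc[0] == pytest.approx(cl.cumulative_arclength[k])

    def test_equidistant_tie_breaks_to_lower_node(self):
        cl = self._line_centerline()
        mid = (cl.nodes[4] + cl.nodes[5]) / 2
        arc = assign_arclength(mid, cl)
        assert arc[0] == pytest.approx(cl.cumulative_arclength[4])

    def test_matches_exhaustive_search(self, rng):
        mask, _, _ = make_arc_tube_mask(bend_radius_um=30, tube_radius_um=3)
        cl = extract_centerline(mask, (1, 1, 1))
        pts = rng.uniform(0, 50, size=(500, 3))
        arc = assign_arclength(pts, cl)
        # oracle: exhaustive nearest node, lower index on ties
        d = np.linalg.norm(pts[:, None, :] - cl.nodes[None], axis=2)
        oracle = cl.cumulative_arclength[np.argmin(d, axis=1)]
        np.testing.assert_allclose(arc, oracle)

    def test_empty_points(self):
        cl = self._line_centerline()
        assert assign_arclength(np.empty((0, 3)), cl).size == 0

    def test_translation_invariance(self, rng):
        cl = self._line_centerline()
        pts = rng.uniform(0, 20, size=(50, 3))
        shift = np.array([5.0, -3.0, 11.0])
        from vesseltau.geometry import Centerline

        cl2 = Centerline(cl.nodes + shift, cl.cumulative_arclength)
        np.testing.assert_allclose(
            assign_arclength(pts, cl), assign_arclength(pts + shift, cl2)
        )

    def test_reversal_maps_arc_to_total_minus_arc(self, rng):
        mask = make_cylinder_mask(radius_vox=3, length_vox=50)
        cl = extract_centerline(mask, (1, 1, 1))
        pts = rng.uniform(0, 30, size=(100, 3))
        fwd = assign_arclength(pts, cl)
        rev = assign_arclength(pts, cl.reversed())
        np.testing.assert_allclose(fwd + rev, cl.total_length_um, atol=1e-6)


class TestDiameter:
    def test_cylinder_diameter(self):
        mask = make_cylinder_mask(radius_vox=8, length_vox=50)
        cl = extract_centerline(mask, (1, 1, 1))
        d = estimate_diameter(mask, cl, (1, 1, 1))
        assert d == pytest.approx(16.0, abs=VOXEL_DIAG)

    def test_degenerate_line_warns_one_voxel(self):
        mask = np.zeros((5, 5, 30), bool)
        mask[2, 2, :] = True
        with pytest.warns(UserWarning):
            cl = extract_centerline(mask, (1, 1, 1))
        with pytest.warns(UserWarning, match="degenerate"):
            d = estimate_diameter(mask, cl, (1, 1, 1))
        assert d == pytest.approx(1.0)

    def test_cone_mean_of_local_diameters(self):
        # radius grows linearly 5 → 10 μm over 60 μm of axis
        length, pad = 60, 12
        side = 2 * (10 + pad)
        z, y, x = np.mgrid[0:side, 0:side, 0 : length + 4]
        c = side / 2
        ax = np.clip((x + 0.5 - 2) / length, 0, 1)
        r_local = 5 + 5 * ax
        mask = (
            ((z + 0.5 - c) ** 2 + (y + 0.5 - c) ** 2 <= r_local**2)
            & (x >= 2) & (x < 2 + length)
        )
        cl = extract_centerline(mask, (1, 1, 1))
        d = estimate_diameter(mask, cl, (1, 1, 1), n_sites=3)
        # sites at 1/4, 1/2, 3/4 → diameters 12.5, 15, 17.5, mean 15
        assert d == pytest.approx(15.0, abs=VOXEL_DIAG)

    def test_vessel_record_from_mask(self):
        mask = make_cylinder_mask(radius_vox=5, length_vox=40)
        rec = VesselRecord.from_mask(mask, (1, 1, 1), vessel_id=3, donor_id="d1")
        assert rec.total_length_um == pytest.approx(40, rel=0.06)
        assert rec.diameter_um == pytest.approx(10, abs=VOXEL_DIAG)
        assert rec.distance_field.values[mask].max() == 0.0
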
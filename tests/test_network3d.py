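"""3D network metrics: tracing, pitch, interaction, depth profiles, shape."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

import tuftmorph as tm

ISO = (100.0, 100.0, 100.0)


def column_volume(n_z=100, shape=(100, 9, 9), at=(4, 4)):
    vox = np.zeros(shape, bool)
    vox[:n_z, at[0], at[1]] = True
    return tm.VolumeMask(vox, ISO, "actin")


class TestPitchOf:
    @pytest.mark.parametrize("vec,expected", [
        ((1, 0, 1), 45.0),    # (z, y, x): equal rise and run
        ((1, 0, 0), 90.0),    # vertical
        ((0, 1, 1), 0.0),     # horizontal
        ((np.sqrt(3), 0, 1), 60.0),
    ])
    def test_analytic_directions(self, vec, expected):
        path = np.array([[0.0, 0.0, 0.0], list(vec)])
        assert tm.pitch_of(path, (1.0, 1.0, 1.0)) == pytest.approx(
            expected, abs=1e-9)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            tm.pitch_of(np.array([[1, 1, 1], [1, 1, 1]]), (1, 1, 1))

    def test_anisotropic_calibration(self):
        # one z step of 200 nm vs one x step of 100 nm -> atan(2) pitch
        path = np.array([[0, 0, 0], [1, 0, 1]])
        got = tm.pitch_of(path, (100.0, 100.0, 200.0))
        assert got == pytest.approx(np.degrees(np.arctan2(200, 100)),
                                    abs=1e-9)


class TestTracePolymers:
    def test_vertical_column(self):
        traces = tm.trace_polymers(column_volume())
        assert len(traces) == 1
        t = traces[0]
        assert t.pitch_deg == pytest.approx(90.0)
        assert t.length_um == pytest.approx(9.9)  # 100 voxels, 99 steps

    def test_two_disjoint_columns(self):
        vox = np.zeros((50, 9, 19), bool)
        vox[:, 4, 4] = True
        vox[:, 4, 14] = True
        traces = tm.trace_polymers(tm.VolumeMask(vox, ISO, "actin"))
        assert len(traces) == 2

    def test_short_components_discarded(self):
        vox = np.zeros((20, 9, 9), bool)
        vox[:3, 4, 4] = True  # 0.2 um < 0.5 um default minimum
        assert tm.trace_polymers(tm.VolumeMask(vox, ISO, "actin")) == []

    def test_empty_mask(self):
        vox = np.zeros((10, 10, 10), bool)
        assert tm.trace_polymers(tm.VolumeMask(vox, ISO, "actin")) == []

    def test_recovers_generated_pitches(self):
        spec = tm.Network3DSpec(volume_shape_vox=(130, 200, 200),
                                n_actin=50, n_mt=0, pitch_mean_deg=81.1,
                                pitch_sd_deg=5.0, seed=17)
        actin, _, truth = tm.gen_network_volume(spec)
        traces = tm.trace_polymers(actin)
        assert len(traces) == 50
        mids = 0.5 * (truth[["x0_nm", "y0_nm", "z0_nm"]].to_numpy()
                      + truth[["x1_nm", "y1_nm", "z1_nm"]].to_numpy())
        tree = cKDTree(mids)
        for t in traces:
            p = t.path_vox[:, ::-1] * 100.0 + 50.0  # voxel centres, nm
            _, i = tree.query(0.5 * (p[0] + p[-1]))
            assert abs(t.pitch_deg - truth.pitch_deg.iloc[i]) < 3.0

    def test_rotation_about_z_preserves_pitch(self):
        spec = tm.Network3DSpec(volume_shape_vox=(130, 160, 160),
                                n_actin=5, n_mt=0, seed=3)
        actin, _, _ = tm.gen_network_volume(spec)
        rotated = tm.VolumeMask(np.rot90(actin.voxels, axes=(1, 2)).copy(),
                                ISO, "actin")
        p0 = sorted(t.pitch_deg for t in tm.trace_polymers(actin))
        p1 = sorted(t.pitch_deg for t in tm.trace_polymers(rotated))
        assert np.allclose(p0, p1, atol=1.5)


class TestInteractionMap:
    def test_parallel_polymers_within_reach(self):
        # two straight lines 2 voxels apart: full-length interaction
        vox_a = np.zeros((60, 9, 9), bool)
        vox_m = np.zeros((60, 9, 9), bool)
        vox_a[:, 4, 3] = True
        vox_m[:, 4, 5] = True
        res = tm.interaction_map(tm.VolumeMask(vox_a, ISO, "actin"),
                                 tm.VolumeMask(vox_m, ISO, "microtubule"),
                                 dilation_radius_vox=4)
        assert len(res.segment_lengths_um) == 1
        assert res.percent_interacting == pytest.approx(100.0)
        assert res.segment_lengths_um[0] == pytest.approx(
            res.total_actin_um)

    def test_far_apart_polymers_do_not_interact(self):
        vox_a = np.zeros((60, 9, 40), bool)
        vox_m = np.zeros((60, 9, 40), bool)
        vox_a[:, 4, 2] = True
        vox_m[:, 4, 30] = True  # 28 voxels away >> reach of 4
        res = tm.interaction_map(tm.VolumeMask(vox_a, ISO, "actin"),
                                 tm.VolumeMask(vox_m, ISO, "microtubule"),
                                 dilation_radius_vox=4)
        assert res.percent_interacting == 0.0
        assert res.segment_lengths_um == []

    def test_perpendicular_crossing_bounded_segment(self):
        vox_a = np.zeros((9, 9, 60), bool)
        vox_m = np.zeros((9, 9, 60), bool)
        vox_a[4, 4, :] = True          # along x
        vox_m[:, 4, 30] = True         # along z, crossing at x=30
        r = 4
        res = tm.interaction_map(tm.VolumeMask(vox_a, ISO, "actin"),
                                 tm.VolumeMask(vox_m, ISO, "microtubule"),
                                 dilation_radius_vox=r, min_length_um=0.1)
        assert len(res.segment_lengths_um) == 1
        # brute-force reach along the actin line: |dx| <= r voxels
        assert res.segment_lengths_um[0] <= (2 * r + 1) * 0.1 + 1e-9

    def test_total_interaction_monotone_in_dilation(self):
        spec = tm.Network3DSpec(n_actin=15, n_mt=15, paired_fraction=0.5,
                                pair_offset_nm=300.0, seed=5)
        a, m, _ = tm.gen_network_volume(spec)
        totals = [tm.interaction_map(a, m, r).total_interacting_actin_um
                  for r in range(1, 7)]
        assert all(x <= y + 1e-12 for x, y in zip(totals, totals[1:]))

    def test_full_cover_reaches_100_percent(self):
        vox_a = np.zeros((40, 9, 9), bool)
        vox_a[:, 4, 4] = True
        actin = tm.VolumeMask(vox_a, ISO, "actin")
        covered = ndimage.binary_dilation(
            vox_a, ndimage.generate_binary_structure(3, 1), iterations=2)
        mt = tm.VolumeMask(covered, ISO, "microtubule")
        res = tm.interaction_map(actin, mt, 4)
        assert res.percent_interacting == pytest.approx(100.0)

    def test_length_conservation(self):
        spec = tm.Network3DSpec(n_actin=10, n_mt=10, paired_fraction=0.5,
                                seed=7)
        a, m, _ = tm.gen_network_volume(spec)
        res = tm.interaction_map(a, m, 4)
        traces = tm.trace_polymers(a)
        assert res.total_actin_um == pytest.approx(
            sum(t.length_um for t in traces))
        assert 0.0 <= res.percent_interacting <= 100.0

    def test_paired_fraction_recovery(self):
        for p in (0.0, 0.5, 1.0):
            spec = tm.Network3DSpec(volume_shape_vox=(130, 200, 200),
                                    n_actin=50, n_mt=50, paired_fraction=p,
                                    pair_offset_nm=200.0, seed=21)
            a, m, _ = tm.gen_network_volume(spec)
            res = tm.interaction_map(a, m, 4)
            assert abs(res.percent_interacting - 100.0 * p) <= 10.0

    def test_geometry_mismatch_rejected(self):
        a = column_volume(shape=(50, 9, 9))
        b = tm.VolumeMask(np.zeros((50, 9, 10), bool), ISO, "microtubule")
        with pytest.raises(ValueError):
            tm.interaction_map(a, b)

    def test_volume_fraction_variant(self):
        vox_a = np.zeros((40, 9, 9), bool)
        vox_a[:, 4, 4] = True
        a = tm.VolumeMask(vox_a, ISO, "actin")
        m = tm.VolumeMask(vox_a.copy(), ISO, "microtubule")
        assert tm.interaction_volume_fraction(a, m, 1) == 1.0
        empty = tm.VolumeMask(np.zeros_like(vox_a), ISO, "microtubule")
        assert tm.interaction_volume_fraction(a, empty, 4) == 0.0


class TestAreaVsDepth:
    def test_linear_area_stack_recovers_slope(self):
        # squares sized so cell area = 20 + 5.412 z um^2
        nz = 60
        cell = np.zeros((nz, 120, 120), bool)
        for zi in range(nz):
            side = int(round(np.sqrt(20.0 + 5.412 * zi * 0.1) / 0.1))
            cell[zi, 10:10 + side, 10:10 + side] = True
        bundle = np.zeros_like(cell)
        bundle[:, 40, 40] = True
        res = tm.area_vs_depth(tm.VolumeMask(cell, ISO, "cell"),
                               tm.VolumeMask(bundle, ISO, "bundle_region"))
        assert res.slope_cell == pytest.approx(5.412, rel=0.02)
        assert res.slope_bundle == pytest.approx(0.0, abs=1e-9)

    def test_cylinder_has_zero_slope(self):
        yy, xx = np.mgrid[:60, :60]
        disc = (yy - 30) ** 2 + (xx - 30) ** 2 <= 20 ** 2
        cyl = np.broadcast_to(disc, (50, 60, 60)).copy()
        res = tm.area_vs_depth(tm.VolumeMask(cyl, ISO, "cell"),
                               tm.VolumeMask(np.zeros_like(cyl), ISO,
                                             "bundle_region"),
                               depths_um=[0.0, 1.5, 3.0, 4.5])
        assert res.slope_cell == pytest.approx(0.0, abs=1e-12)

    def test_bundle_area_uses_convex_hull(self):
        # 4 corner columns: hull area = full square, not 4 voxels
        cell = np.ones((50, 60, 60), bool)
        bundle = np.zeros_like(cell)
        for y, x in ((10, 10), (10, 50), (50, 10), (50, 50)):
            bundle[:, y, x] = True
        res = tm.area_vs_depth(tm.VolumeMask(cell, ISO, "cell"),
                               tm.VolumeMask(bundle, ISO, "bundle_region"))
        assert res.bundle_area_um2[0] == pytest.approx(16.0, rel=0.01)

    def test_depth_outside_volume_rejected(self):
        res_mask = column_volume(shape=(10, 9, 9))
        with pytest.raises(ValueError):
            tm.area_vs_depth(res_mask, res_mask, depths_um=[0.0, 5.0])


class TestApicalShape:
    def test_disc_circularity_near_one(self):
        yy, xx = np.mgrid[:120, :120]
        disc = (yy - 60) ** 2 + (xx - 60) ** 2 <= 50 ** 2
        shape = tm.apical_shape(disc, 1000.0)
        assert shape.circularity >= 0.95
        assert shape.area_um2 == pytest.approx(np.pi * 50 ** 2, rel=0.05)

    def test_square_circularity_closed_form(self):
        sq = np.zeros((120, 120), bool)
        sq[10:110, 10:110] = True
        shape = tm.apical_shape(sq, 1000.0)
        assert shape.circularity == pytest.approx(np.pi / 4, rel=0.03)

    def test_thin_bar_low_circularity(self):
        bar = np.zeros((10, 120), bool)
        bar[5, 10:110] = True
        assert tm.apical_shape(bar, 1000.0).circularity < 0.1

    def test_multi_component_rejected_with_count(self):
        mask = np.zeros((30, 30), bool)
        mask[5:10, 5:10] = True
        mask[20:25, 20:25] = True
        with pytest.raises(ValueError, match="2"):
            tm.apical_shape(mask, 1000.0)
        with pytest.raises(ValueError):
            tm.apical_shape(np.zeros((10, 10), bool), 1000.0)
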
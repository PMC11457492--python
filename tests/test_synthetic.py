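"""Generators: geometry, determinism, and closed-form rendering checks."""

import numpy as np
import pandas as pd
import pytest

import tuftmorph as tm
from conftest import enumerate_hex_disc


class TestLatticePoints:
    def test_rosette_is_center_plus_ring(self):
        pts, truth = tm.gen_lattice_points(
            tm.LatticeSpec("hex", spacing_nm=9.0, bundle_radius_nm=10.0))
        assert len(pts) == 7
        # all nearest-neighbour distances exactly 9 by brute force
        c = pts.coords_nm
        dists = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        nn = np.where(dists == 0, np.inf, dists).min(axis=1)
        assert np.allclose(nn, 9.0, atol=1e-9)
        assert len(truth) == 7

    def test_matches_independent_enumeration_at_bundle_scale(self):
        # a 53-nm bundle radius (106-nm diameter) at 9-nm spacing
        pts, _ = tm.gen_lattice_points(
            tm.LatticeSpec("hex", spacing_nm=9.0, bundle_radius_nm=53.0))
        ref = enumerate_hex_disc(9.0, 53.0)
        assert len(pts) == len(ref)
        # ~100 filaments per bundle, as in real cross-sections
        assert 80 <= len(pts) <= 160
        got = set(map(tuple, np.round(pts.coords_nm, 6)))
        want = set(map(tuple, np.round(ref, 6)))
        assert got == want

    @pytest.mark.parametrize("kind", ["hex", "square", "csr"])
    def test_deterministic(self, kind):
        spec = tm.LatticeSpec(kind, spacing_nm=9.0, jitter_sd_nm=0.5,
                              vacancy_fraction=0.1, bundle_radius_nm=40.0,
                              n_points=50 if kind == "csr" else None, seed=3)
        a, _ = tm.gen_lattice_points(spec)
        b, _ = tm.gen_lattice_points(spec)
        assert np.array_equal(a.coords_nm, b.coords_nm)

    def test_points_stay_inside_bundle(self):
        spec = tm.LatticeSpec("csr", bundle_radius_nm=30.0, n_points=500,
                              seed=1)
        pts, _ = tm.gen_lattice_points(spec)
        assert np.all(np.linalg.norm(pts.coords_nm, axis=1) <= 30.0 + 1e-9)

    def test_vacancies_remove_expected_fraction(self):
        full, _ = tm.gen_lattice_points(
            tm.LatticeSpec("hex", spacing_nm=5.0, bundle_radius_nm=100.0))
        vac, _ = tm.gen_lattice_points(
            tm.LatticeSpec("hex", spacing_nm=5.0, bundle_radius_nm=100.0,
                           vacancy_fraction=0.2, seed=4))
        frac = 1.0 - len(vac) / len(full)
        assert abs(frac - 0.2) < 0.04

    def test_interior_hex_points_have_six_neighbors_at_d(self):
        pts, _ = tm.gen_lattice_points(
            tm.LatticeSpec("hex", spacing_nm=9.0, bundle_radius_nm=45.0))
        c = pts.coords_nm
        dists = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        interior = np.linalg.norm(c, axis=1) <= 45.0 - 9.0
        for i in np.flatnonzero(interior):
            at_d = np.sum(np.abs(dists[i] - 9.0) < 1e-6)
            assert at_d == 6

    def test_csr_nn_distance_matches_poisson_form(self):
        # mean NN distance for CSR at intensity lambda is 0.5 / sqrt(lambda)
        n, radius = 2000, 1000.0
        pts, _ = tm.gen_lattice_points(
            tm.LatticeSpec("csr", bundle_radius_nm=radius, n_points=n,
                           seed=11))
        from scipy.spatial import cKDTree
        d, _ = cKDTree(pts.coords_nm).query(pts.coords_nm, k=2)
        lam = n / (np.pi * radius ** 2)
        assert abs(d[:, 1].mean() - 0.5 / np.sqrt(lam)) \
            < 0.05 * (0.5 / np.sqrt(lam))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            tm.LatticeSpec("hex", spacing_nm=-1.0)
        with pytest.raises(ValueError):
            tm.LatticeSpec("hex", vacancy_fraction=1.0)
        with pytest.raises(ValueError):
            tm.LatticeSpec("csr")  # missing n_points
        with pytest.raises(ValueError):
            tm.LatticeSpec("penrose")


class TestRenderCrossSection:
    def test_single_dark_blob_is_global_minimum(self):
        pts = tm.PointSet([0], [[20.0, 24.0]])
        img = tm.render_cross_section(
            pts, tm.RenderSpec(pixel_size_nm=1.0, psf_sigma_nm=2.0,
                               image_shape_px=(48, 48)))
        r, c = np.unravel_index(np.argmin(img.pixels), img.shape)
        assert (abs((c + 0.5) - 20.0) <= 1.0
                and abs((r + 0.5) - 24.0) <= 1.0)

    def test_empty_pointset_gives_constant_background(self):
        img = tm.render_cross_section(
            tm.PointSet([], np.zeros((0, 2))),
            tm.RenderSpec(image_shape_px=(32, 32), background_level=0.6))
        assert np.all(img.pixels == 0.6)

    def test_rosette_blob_sum_matches_closed_form(self, rosette):
        render = tm.RenderSpec(pixel_size_nm=1.0, psf_sigma_nm=2.0,
                               image_shape_px=(64, 64))
        shifted = rosette.translated(32.0, 32.0)
        img = tm.render_cross_section(shifted, render)

        def blob_sum(x, y):
            d2 = np.sum((shifted.coords_nm - [x, y]) ** 2, axis=1)
            return render.background_level - render.blob_amplitude * np.sum(
                np.exp(-d2 / (2 * render.psf_sigma_nm ** 2)))

        # value at the bundle centre sample vs direct formula
        val_center = img.pixels[32, 32]
        assert val_center == pytest.approx(blob_sum(32.5, 32.5), abs=1e-12)
        # centre is darker than the midpoint between two ring points
        ring = shifted.coords_nm[
            np.argsort(np.linalg.norm(shifted.coords_nm - 32.5, axis=1))][-2:]
        mx, my = ring.mean(axis=0)
        assert blob_sum(32.5, 32.5) < blob_sum(mx, my)

    def test_mean_intensity_decreases_with_point_count(self):
        means = []
        for n in (10, 40, 90):
            pts, _ = tm.gen_lattice_points(
                tm.LatticeSpec("csr", bundle_radius_nm=50.0, n_points=n,
                               center_nm=(64.0, 64.0), seed=2))
            img = tm.render_cross_section(
                pts, tm.RenderSpec(image_shape_px=(128, 128), noise_sd=0.01,
                                   seed=7))
            means.append(img.pixels.mean())
        assert means[0] > means[1] > means[2]

    def test_point_outside_fov_is_an_error_naming_ids(self):
        pts = tm.PointSet([0, 1], [[10.0, 10.0], [500.0, 10.0]])
        with pytest.raises(ValueError, match=r"\[1\]"):
            tm.render_cross_section(pts, tm.RenderSpec(
                image_shape_px=(32, 32)))


class TestNetworkVolume:
    def test_vertical_polymer_is_single_voxel_column(self):
        spec = tm.Network3DSpec(volume_shape_vox=(130, 40, 40),
                                n_actin=1, n_mt=0, pitch_mean_deg=90.0,
                                pitch_sd_deg=0.0, length_um_range=(8.0, 8.0),
                                seed=0)
        actin, mt, truth = tm.gen_network_volume(spec)
        assert truth.pitch_deg.iloc[0] == 90.0
        zs, ys, xs = np.nonzero(actin.voxels)
        assert len(set(ys)) == 1 and len(set(xs)) == 1
        assert not mt.voxels.any()

    def test_paired_microtubules_copy_partner_direction(self):
        spec = tm.Network3DSpec(n_actin=10, n_mt=10, paired_fraction=1.0,
                                pair_offset_nm=300.0, seed=8)
        _, _, truth = tm.gen_network_volume(spec)
        actin = truth[truth.channel == "actin"].set_index("id")
        for _, row in truth[truth.channel == "microtubule"].iterrows():
            assert row.paired_with >= 0
            p = actin.loc[row.paired_with]
            v_mt = np.array([row.x1_nm - row.x0_nm, row.y1_nm - row.y0_nm,
                             row.z1_nm - row.z0_nm])
            v_ac = np.array([p.x1_nm - p.x0_nm, p.y1_nm - p.y0_nm,
                             p.z1_nm - p.z0_nm])
            dot = v_mt @ v_ac / (np.linalg.norm(v_mt) * np.linalg.norm(v_ac))
            assert dot == pytest.approx(1.0, abs=1e-12)

    def test_truth_pitch_median_recomputable_from_endpoints(self):
        spec = tm.Network3DSpec(volume_shape_vox=(130, 220, 220),
                                n_actin=200, n_mt=0, pitch_mean_deg=81.1,
                                pitch_sd_deg=5.0, seed=11)
        _, _, truth = tm.gen_network_volume(spec)
        v = truth[["x1_nm", "y1_nm", "z1_nm"]].to_numpy() \
            - truth[["x0_nm", "y0_nm", "z0_nm"]].to_numpy()
        recomputed = np.degrees(np.arcsin(np.abs(v[:, 2])
                                          / np.linalg.norm(v, axis=1)))
        assert np.allclose(recomputed, truth.pitch_deg, atol=1e-9)
        assert abs(np.median(recomputed) - 81.1) < 1.0

    def test_truth_rows_cover_all_polymers(self):
        spec = tm.Network3DSpec(n_actin=5, n_mt=3, seed=2)
        _, _, truth = tm.gen_network_volume(spec)
        assert len(truth) == 8
        assert truth.id.tolist() == list(range(8))

    def test_oversized_polymer_raises(self):
        with pytest.raises(ValueError):
            tm.Network3DSpec(volume_shape_vox=(20, 20, 20),
                             length_um_range=(10.0, 12.0))


class TestProfiles:
    def test_constant_noiseless(self):
        prof, _ = tm.gen_profile(tm.ProfileSpec("constant", (0.4,),
                                                5.0, 20, 0.0))
        assert np.all(prof.intensity == 0.4)

    def test_four_pl_bottom_plateau_at_origin(self):
        # EPS8-style sigmoid: bottom plateau 0.15, top 0.66
        prof, _ = tm.gen_profile(tm.ProfileSpec(
            "four_pl", (0.15, 0.66, 3.0, 5.0), 7.0, 100, 0.0))
        assert prof.intensity[0] == pytest.approx(0.15, abs=1e-6)
        assert prof.intensity[-1] == pytest.approx(0.66, abs=1e-6)

    def test_lognormal_argmax_at_mode(self):
        spec = tm.ProfileSpec("lognormal", (1.0, 2.0, 0.4), 7.0, 141, 0.0)
        prof, _ = tm.gen_profile(spec)
        xmax = prof.arclength_um[np.argmax(prof.intensity)]
        grid_step = 7.0 / 140
        assert abs(xmax - 2.0) <= grid_step / 2 + 1e-12

    def test_deterministic_and_truth_passthrough(self):
        spec = tm.ProfileSpec("exp_decay", (1.0, 2.0, 0.1), 7.0, 50, 0.2,
                              seed=5)
        a, ta = tm.gen_profile(spec)
        b, _ = tm.gen_profile(spec)
        assert np.array_equal(a.intensity, b.intensity)
        assert ta["params"] == [1.0, 2.0, 0.1]

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            tm.ProfileSpec("spline", (1.0,), 5.0, 20, 0.0)
        with pytest.raises(ValueError):
            tm.ProfileSpec("lognormal", (1.0,), 5.0, 20, 0.0)  # arity
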
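import numpy as np
import pytest

from iqspect.core import (Geometry, ImageVolume, MuMap, ProjectionSet,
                          ScatterParams)
from iqspect.phantoms import make_cylinder_phantom, simulate_static_scan
from iqspect.profiles import INSTITUTION_A
from iqspect.projector import forward_project, project_slices
from iqspect.recon import (calibrate_bcf, calibrate_ccf, estimate_mu_map,
                           mlem_reconstruct, osem_reconstruct,
                           reconstruct_uncorrected, tdcs_scatter_correct)


def _proj_set(sino, geo, duration=1.0):
    return ProjectionSet(sino[None], geo, np.array([0.0]), np.array([duration]))


def _true_mu(phantom):
    m = phantom.mask("source")
    return MuMap(values=m * 0.160, mask=m, spacing_mm=phantom.spacing_mm)


class TestFBPOutline:
    def test_disc_support_recovered(self, disc_64):
        img, geo, r = disc_64
        proj = forward_project(img, geo)
        rec = reconstruct_uncorrected(proj, geo)
        mask = rec.data[0] > 0.5 * np.percentile(rec.data, 99)
        truth = img.data[0] > 0
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice > 0.9

    def test_zero_projections_give_zero_image(self):
        geo = Geometry(30, 32, 2.0)
        rec = reconstruct_uncorrected(_proj_set(np.zeros((1, 30, 32)), geo), geo)
        assert not rec.data.any()

    def test_point_source_peaks_at_true_location(self):
        n = 64
        geo = Geometry(60, n, 2.0)
        img = np.zeros((n, n))
        img[40, 25] = 1.0
        proj = forward_project(ImageVolume(img, (1, 2, 2)), geo)
        rec = reconstruct_uncorrected(proj, geo).data[0]
        peak = np.unravel_index(np.argmax(rec), rec.shape)
        assert abs(peak[0] - 40) <= 1 and abs(peak[1] - 25) <= 1


class TestMuMap:
    def test_noiseless_disc_area_within_5_percent(self, disc_64):
        img, geo, _ = disc_64
        rec = reconstruct_uncorrected(forward_project(img, geo), geo)
        mu = estimate_mu_map(rec, 0.5)
        assert mu.mask.sum() == pytest.approx(img.data.sum(), rel=0.05)
        assert np.allclose(np.unique(mu.values), [0.0, 0.160])

    def test_all_zero_image_rejected(self):
        img = ImageVolume(np.zeros((32, 32)), (1, 2, 2))
        with pytest.raises(ValueError):
            estimate_mu_map(img)

    def test_bad_threshold_rejected(self, disc_64):
        img, _, _ = disc_64
        with pytest.raises(ValueError):
            estimate_mu_map(img, 1.5)


class TestTDCS:
    def test_no_scatter_no_offset_is_identity(self, disc_64):
        img, geo, _ = disc_64
        proj = forward_project(img, geo)
        mu = estimate_mu_map(reconstruct_uncorrected(proj, geo), 0.5)
        params = ScatterParams(a=1.0, b=0.0, penetration_offset_fraction=0.0)
        out = tdcs_scatter_correct(proj, mu, geo, params)
        assert np.allclose(out.data, proj.data, atol=1e-9)

    def test_offset_only_subtracts_uniform_background(self, disc_64):
        img, geo, _ = disc_64
        proj = forward_project(img, geo)
        mu = estimate_mu_map(reconstruct_uncorrected(proj, geo), 0.5)
        frac = 0.05
        shifted = ProjectionSet(proj.data + frac * proj.data.mean(),
                                geo, proj.frame_starts_min,
                                proj.frame_durations_min)
        params = ScatterParams(a=1.0, b=0.0, penetration_offset_fraction=frac)
        out = tdcs_scatter_correct(shifted, mu, geo, params)
        assert np.allclose(out.data, np.clip(proj.data, 0, None),
                           atol=1e-6 * proj.data.max())

    def test_invalid_scatter_fraction_rejected(self):
        with pytest.raises(ValueError):
            ScatterParams(a=1.5, b=1.0, beta=1.0).validate()

    def test_simulated_scatter_removed_within_3_percent(self):
        phantom = make_cylinder_phantom(160.0, 50_000.0, "disc")
        clean = simulate_static_scan(phantom, INSTITUTION_A, 20.0, noise=False,
                                     scatter=False, offset=False)
        dirty = simulate_static_scan(phantom, INSTITUTION_A, 20.0, noise=False,
                                     scatter=True, offset=True)
        geo = dirty.geometry
        mu = estimate_mu_map(reconstruct_uncorrected(dirty, geo), 0.5)
        corrected = tdcs_scatter_correct(dirty, mu, geo, INSTITUTION_A.scatter)
        assert corrected.data.sum() == pytest.approx(clean.data.sum(), rel=0.03)

    def test_scatter_correction_improves_cold_spot_contrast(self):
        # disc with a cold insert
        n, sp = 96, 2.5
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2
        r = np.hypot((xx - c) * sp, (yy - c) * sp)
        r_cold = np.hypot((xx - c - 12) * sp, (yy - c) * sp)
        labels = np.zeros((1, n, n), np.int16)
        labels[0, r < 80] = 1
        labels[0, r_cold < 20] = 2
        from iqspect.core import PhantomSpec
        phantom = PhantomSpec(
            labels=labels, structures={"background": 0, "source": 1, "cold": 2},
            compartment_of={"background": "background", "source": "gray",
                            "cold": "white"},
            spacing_mm=(sp, sp, sp),
            mu_cm={"source": 0.160, "cold": 0.160},
            activity_bqml={"source": 50_000.0, "cold": 0.0})
        proj = simulate_static_scan(phantom, INSTITUTION_A, 20.0, noise=False)
        geo = proj.geometry
        mu = estimate_mu_map(reconstruct_uncorrected(proj, geo), 0.5)

        def contrast(p):
            img = osem_reconstruct(p, mu, geo)
            hot = img.data[0][(r < 70) & (r_cold > 30)].mean()
            cold = img.data[0][r_cold < 10].mean()
            return 1.0 - cold / hot

        assert contrast(tdcs_scatter_correct(proj, mu, geo,
                                             INSTITUTION_A.scatter)) \
            >= contrast(proj)


class TestOSEM:
    def test_uniform_disc_recovered_within_3_percent(self):
        phantom = make_cylinder_phantom(120.0, 1000.0, "disc")
        proj = simulate_static_scan(phantom, INSTITUTION_A, 20.0, noise=False,
                                    scatter=False, offset=False)
        geo = proj.geometry
        img = osem_reconstruct(proj, _true_mu(phantom), geo)
        from iqspect.phantoms import COUNT_SENSITIVITY
        rate = img.data / 20.0 / (COUNT_SENSITIVITY / INSTITUTION_A.bcf)
        n, sp = 96, 2.5
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2
        r = np.hypot((xx - c) * sp, (yy - c) * sp)
        assert rate[0][r < 45].mean() == pytest.approx(1000.0, rel=0.03)

    def test_zero_projections_reconstruct_to_zero(self):
        geo = Geometry(30, 32, 2.0)
        mask = np.ones((1, 32, 32), bool)
        mu = MuMap(values=mask * 0.0, mask=mask, spacing_mm=(2, 2, 2))
        img = osem_reconstruct(_proj_set(np.zeros((1, 30, 32)), geo), mu, geo)
        assert img.data.max() < 1e-12

    def test_em_fixed_point_preserves_total_counts(self):
        # attenuation-free disc: the fitted geometric-mean data equal the
        # measured sinogram, so reprojecting the reconstruction must
        # reproduce the measured counts
        img0, geo, r = None, Geometry(60, 64, 2.0), None
        n, sp = 64, 2.0
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2
        r = np.hypot((xx - c) * sp, (yy - c) * sp)
        act = (r < 40).astype(float) * 1000.0
        proj = forward_project(ImageVolume(act, (1, sp, sp)), geo)
        mask = (r < 60)[None]
        mu = MuMap(values=mask * 0.0, mask=mask, spacing_mm=(sp, sp, sp))
        rec = osem_reconstruct(proj, mu, geo, post_filter_fwhm_mm=0.0)
        half_geo = Geometry(30, n, sp, full_circle=False)
        reproj = project_slices(rec, half_geo)
        measured_half = proj.data[0][:, :30]
        assert reproj.sum() == pytest.approx(measured_half.sum(), rel=0.02)

    def test_single_subset_matches_classical_mlem_oracle(self):
        # direct dense-matrix MLEM implementation as the oracle
        rng = np.random.default_rng(4)
        n = 32
        geo = Geometry(20, n, 2.0)
        act = np.zeros((n, n))
        act[10:22, 8:20] = rng.random((12, 12)) + 0.5
        mask = np.zeros((1, n, n), bool)
        mask[0, 4:28, 4:28] = True
        mu = MuMap(values=mask * 0.0, mask=mask, spacing_mm=(2, 2, 2))
        proj = forward_project(ImageVolume(act, (1, 2, 2)), geo)
        ours = osem_reconstruct(proj, mu, geo, n_iter=3, n_subsets=1,
                                post_filter_fwhm_mm=0.0).data[0]

        from iqspect.projector import system_matrix
        half = geo.n_views // 2
        sino = proj.data[0, 0]
        gm = np.sqrt(np.clip(sino[:half] * sino[half:, ::-1], 0, None))
        geo_half = Geometry(half, n, 2.0, full_circle=False)
        A = system_matrix(n, geo_half).toarray()
        x = mask[0].ravel().astype(float)
        sens = A.sum(axis=0)
        y = gm.ravel()
        for _ in range(3):
            est = A @ x
            ratio = np.where(est > 0, y / np.maximum(est, 1e-30), 1.0)
            corr = A.T @ ratio
            x = x * np.where(sens > 0, corr / np.maximum(sens, 1e-30), 1.0)
        oracle = x.reshape(n, n)
        assert np.abs(ours - oracle).max() < 1e-6 * max(oracle.max(), 1.0)

    def test_odd_view_count_rejected(self):
        geo = Geometry(30, 32, 2.0, full_circle=False)
        mask = np.ones((1, 32, 32), bool)
        mu = MuMap(values=mask * 0.0, mask=mask, spacing_mm=(2, 2, 2))
        # 15 views over 180 degrees cannot be paired
        bad_geo = Geometry(15, 32, 2.0, full_circle=False)
        with pytest.raises(ValueError):
            osem_reconstruct(_proj_set(np.zeros((1, 15, 32)), bad_geo), mu,
                             bad_geo)


class TestCalibration:
    def test_image_already_calibrated_gives_unit_bcf(self):
        mask = np.zeros((1, 32, 32), bool)
        mask[0, 10:20, 10:20] = True
        img = ImageVolume(mask * 500.0, (1, 2, 2))
        assert calibrate_bcf(img, 500.0, mask) == pytest.approx(1.0)

    def test_halved_sensitivity_doubles_bcf(self):
        mask = np.zeros((1, 32, 32), bool)
        mask[0, 10:20, 10:20] = True
        img = ImageVolume(mask * 500.0, (1, 2, 2))
        half = ImageVolume(mask * 250.0, (1, 2, 2))
        assert calibrate_bcf(half, 500.0, mask) == \
            pytest.approx(2 * calibrate_bcf(img, 500.0, mask))

    def test_zero_intensity_rejected(self):
        mask = np.ones((1, 8, 8), bool)
        img = ImageVolume(np.zeros((1, 8, 8)), (1, 2, 2))
        with pytest.raises(ValueError):
            calibrate_bcf(img, 100.0, mask)
        with pytest.raises(ValueError):
            calibrate_ccf(img, 100.0, mask)

    def test_ccf_is_well_over_spect_ratio(self):
        mask = np.ones((1, 8, 8), bool)
        img = ImageVolume(np.full((1, 8, 8), 50_000.0), (1, 2, 2))
        assert calibrate_ccf(img, 50_000.0, mask) == pytest.approx(1.0)
        assert calibrate_ccf(img, 100_000.0, mask) == pytest.approx(2.0)
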
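"""Phantom generators: embryos, bleach series, cohorts, morphology, gels."""

import numpy as np
import pytest

import fretbench as fb
from fretbench.phantom import PhantomConfigError


class TestEmbryoPhantom:
    def test_domain_means_equal_requested_values(self, gastrula):
        assert gastrula.domain_mean_activity("margin") == pytest.approx(0.6, abs=1e-9)
        assert gastrula.domain_mean_activity("bulk") == pytest.approx(0.2, abs=1e-9)

    def test_zero_activity_gives_inactive_efficiency_everywhere(self):
        ph = fb.make_embryo_phantom(
            "gastrula_5hpf", (32, 32), {"margin": 0.0, "bulk": 0.0}, seed=3
        )
        inside = ph.embryo_mask
        np.testing.assert_allclose(ph.truth_efficiency[inside], ph.e_inactive)

    def test_activity_zero_outside_mask(self, gastrula):
        assert not gastrula.activity_map[~gastrula.embryo_mask].any()

    def test_same_seed_is_bit_identical(self):
        a = fb.make_embryo_phantom("pharyngula_24hpf", (48, 48), {"tailbud": 0.5}, seed=7)
        b = fb.make_embryo_phantom("pharyngula_24hpf", (48, 48), {"tailbud": 0.5}, seed=7)
        np.testing.assert_array_equal(a.density_map, b.density_map)
        np.testing.assert_array_equal(a.activity_map, b.activity_map)

    def test_unknown_stage_rejected(self):
        with pytest.raises(PhantomConfigError, match="stage"):
            fb.make_embryo_phantom("blastula_3hpf", (32, 32), {}, seed=0)

    def test_domains_are_connected_regions_inside_mask(self):
        from skimage.measure import label as cc_label

        for stage in ("gastrula_5hpf", "segmentation_11hpf", "pharyngula_24hpf"):
            ph = fb.make_embryo_phantom(stage, (64, 64), {}, seed=0)
            for code, name in ph.domain_names.items():
                if name == "background":
                    continue
                m2d = ph.domain_mask(name)[0]
                assert m2d.any(), f"{stage}/{name} empty"
                assert not m2d[~ph.embryo_mask[0]].any()
                # margin ring is connected when diagonal adjacency counts
                _, n = cc_label(m2d, connectivity=2, return_num=True)
                assert n == 1, f"{stage}/{name} has {n} components"


class TestRenderLambdaStack:
    def test_per_pixel_band_sum_matches_conservation_formula(self, gastrula):
        """Over an acquisition covering the full emission support of both
        unit-area spectra, the band sum equals density * budget *
        [(1-E) Q_D + E Q_A] per pixel."""
        grid = np.arange(360.0, 620.5, 0.5)
        wide = fb.Acquisition(lambda_min=360.0, lambda_max=620.0, step=5.0)
        stack = fb.render_lambda_stack(
            gastrula,
            donor_spectrum=fb.EmissionSpectrum.gaussian("CFP", 476, 18, grid),
            acceptor_spectrum=fb.EmissionSpectrum.gaussian("YPet", 530, 14, grid),
            acquisition=wide,
            noise=fb.NOISE_OFF,
        )
        e = gastrula.truth_efficiency
        expected_total = gastrula.density_map * 1000.0 * ((1 - e) * 1.0 + e * 1.0)
        np.testing.assert_allclose(stack.data.sum(-1), expected_total, rtol=1e-6)

    def test_noise_is_reproducible_and_nonnegative(self, gastrula):
        a = fb.render_lambda_stack(gastrula, seed=5)
        b = fb.render_lambda_stack(gastrula, seed=5)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.data.min() >= 0

    def test_spectrum_not_covering_range_rejected(self, gastrula):
        narrow = fb.EmissionSpectrum.gaussian("narrow", 476, 3.0)
        with pytest.raises(PhantomConfigError, match="cover"):
            fb.render_lambda_stack(gastrula, donor_spectrum=narrow, noise=fb.NOISE_OFF)


class TestRenderBleachSeries:
    def test_complete_bleach_dequenches_donor_by_expected_factor(self):
        """With uniform E=0.3 and total bleach, the donor rises by 1/(1-0.3)."""
        ph = fb.make_embryo_phantom(
            "gastrula_5hpf", (32, 32), {"margin": 1.0, "bulk": 1.0},
            seed=0, e_inactive=0.0, e_active=0.3, density_texture=0.0,
        )
        roi = ph.domain_mask("margin")[0]
        bs = fb.render_bleach_series(ph, roi, 50, 0.0, noise=fb.NOISE_OFF)
        pre = bs.pre_donor.mean(0)[roi]
        post = bs.post_donor[roi]
        np.testing.assert_allclose(post / pre, 1.0 / 0.7, rtol=1e-12)

    def test_survival_one_leaves_frames_unchanged(self, gastrula):
        roi = gastrula.domain_mask("margin")[0]
        bs = fb.render_bleach_series(gastrula, roi, 50, 1.0, noise=fb.NOISE_OFF)
        np.testing.assert_array_equal(bs.pre_donor[0], bs.post_donor)
        np.testing.assert_array_equal(bs.pre_acceptor[0], bs.post_acceptor)

    def test_donor_and_acceptor_untouched_outside_roi(self, gastrula):
        roi = gastrula.domain_mask("margin")[0]
        bs = fb.render_bleach_series(gastrula, roi, 50, 0.0, noise=fb.NOISE_OFF)
        np.testing.assert_array_equal(bs.pre_donor[0][~roi], bs.post_donor[~roi])
        np.testing.assert_array_equal(bs.pre_acceptor[0][~roi], bs.post_acceptor[~roi])

    def test_partial_survival_bias_matches_closed_form(self):
        """Noise-free estimator output follows the forward model exactly:
        E_est = E (1 - s') / (1 - E s') with s' = survival**iterations —
        approximately (1 - s') E, the first-order de-quenching deficit."""
        e_truth, survival, iters = 0.3, 0.9, 50
        ph = fb.make_embryo_phantom(
            "gastrula_5hpf", (32, 32), {"margin": 1.0, "bulk": 1.0},
            seed=0, e_inactive=0.0, e_active=e_truth, density_texture=0.0,
        )
        roi2d = ph.domain_mask("margin")[0]
        bs = fb.render_bleach_series(ph, roi2d, iters, survival, noise=fb.NOISE_OFF)
        roi = fb.ROI("margin", roi2d)
        _, e_est = fb.efficiency(bs.pre_donor, bs.post_donor, roi)
        s = survival**iters
        assert s == pytest.approx(0.00515, abs=5e-5)
        exact = e_truth * (1 - s) / (1 - e_truth * s)
        assert e_est == pytest.approx(exact, abs=1e-9)
        # first-order form holds to its analytic second-order remainder
        assert abs(e_est - (1 - s) * e_truth) <= e_truth**2 * s * (1 - s) / (1 - e_truth * s) + 1e-12

    def test_roi_shape_mismatch_rejected(self, gastrula):
        with pytest.raises(PhantomConfigError, match="ROI"):
            fb.render_bleach_series(gastrula, np.ones((8, 8), bool), 50, 0.0)


class TestCohort:
    def test_genotype_effect_recovered_from_truth_maps(self):
        groups = (
            fb.GroupSpec("WT", 4, {"margin": 1.0}),
            fb.GroupSpec("D61G", 4, {"margin": 1.3}),
        )
        cfg = fb.CohortConfig(
            groups=groups, shape=(64, 64), seed=21, noise=fb.NOISE_OFF, n_z=1
        )
        members = fb.make_cohort(cfg)
        from fretbench.phantom import cohort_truth_table

        truth = cohort_truth_table(members)
        means = truth.groupby("group")["activity_margin"].mean()
        # lognormal between-embryo factor has CV 10%; n=4 -> SE ~ 5% per group
        assert means["D61G"] / means["WT"] == pytest.approx(1.3, rel=0.15)

    def test_dose_suppression_written_into_truth(self):
        cfg = fb.default_cohort_config(seed=2, n_embryos=2, shape=(64, 64),
                                       noise=fb.NOISE_OFF, embryo_cv=0.0)
        members = fb.make_cohort(cfg)
        act = {m.group: m.phantom.domain_mean_activity("margin") for m in members}
        assert act["Shp2D61G+1uMPD"] == pytest.approx(0.4 * act["Shp2D61G"], rel=1e-9)
        assert act["Shp2D61G+0.25uMPD"] == pytest.approx(0.7 * act["Shp2D61G"], rel=1e-9)

    def test_single_embryo_groups_still_run(self):
        cfg = fb.default_cohort_config(seed=3, n_embryos=1, shape=(64, 64))
        members = fb.make_cohort(cfg)
        assert len(members) == 4
        from fretbench.report import Design, StatsDesignError, compare_groups

        vals = {m.group: [m.phantom.domain_mean_activity("margin")] for m in members[:2]}
        with pytest.raises(StatsDesignError, match="n >= 2"):
            compare_groups(vals, Design("t_unpaired", alternative="greater"))

    def test_cohort_reproducible_from_seed(self):
        cfg = fb.default_cohort_config(seed=5, n_embryos=2, shape=(64, 64))
        a, b = fb.make_cohort(cfg), fb.make_cohort(cfg)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.lambda_stack.data, mb.lambda_stack.data)
            np.testing.assert_array_equal(ma.bleach_series.post_donor, mb.bleach_series.post_donor)

    def test_suppression_must_decrease_with_dose(self):
        with pytest.raises(PhantomConfigError, match="decrease"):
            fb.CohortConfig(
                groups=(fb.GroupSpec("g", 1),),
                dose_response=((0.25, 0.4), (1.0, 0.7)),
            )


class TestMorphologyPhantom:
    def test_circle_and_truth_ratio(self):
        circle = fb.make_morphology_phantom(100, 100, shape=(160, 160))
        major, minor, ratio = fb.axis_lengths(circle)
        assert ratio == pytest.approx(1.0, abs=0.02)
        ell = fb.make_morphology_phantom(200, 100, shape=(256, 256))
        assert fb.axis_lengths(ell)[2] == pytest.approx(2.0, rel=0.02)

    def test_rotation_preserves_pixel_count_within_1pct(self):
        a = fb.make_morphology_phantom(180, 90, 0, shape=(256, 256))
        b = fb.make_morphology_phantom(180, 90, 37, shape=(256, 256))
        assert abs(a.sum() - b.sum()) / a.sum() < 0.01

    def test_axes_exceeding_image_rejected(self):
        with pytest.raises(PhantomConfigError, match="bounds"):
            fb.make_morphology_phantom(300, 100, shape=(128, 128))
        with pytest.raises(PhantomConfigError, match="major"):
            fb.make_morphology_phantom(50, 100, shape=(128, 128))


class TestGelPhantom:
    def test_noise_free_truth_recovery(self):
        lanes = [{"pERK": 200.0, "tERK": 100.0, "GAPDH": 50.0}]
        img, truth = fb.make_gel_phantom(lanes)
        from fretbench.densitometry import RectROI, band_density

        for row in truth.itertuples():
            d = band_density(img, RectROI(row.y0, row.y1, row.x0, row.x1))
            assert d == pytest.approx(row.truth_density, abs=1e-9)

    def test_uniform_background_subtracted_within_1pct(self):
        lanes = [{"pERK": 200.0, "tERK": 100.0, "GAPDH": 50.0}]
        img, truth = fb.make_gel_phantom(lanes, background_level=10.0)
        from fretbench.densitometry import RectROI, band_density

        for row in truth.itertuples():
            d = band_density(img, RectROI(row.y0, row.y1, row.x0, row.x1))
            assert d == pytest.approx(row.truth_density, rel=0.01)

    def test_all_zero_bands_give_zero_density(self):
        img, truth = fb.make_gel_phantom([{"pERK": 0.0, "tERK": 0.0, "GAPDH": 0.0}])
        from fretbench.densitometry import RectROI, band_density

        for row in truth.itertuples():
            assert band_density(img, RectROI(row.y0, row.y1, row.x0, row.x1)) == 0.0

    def test_overlapping_bands_rejected(self):
        with pytest.raises(PhantomConfigError, match="overlap"):
            fb.make_gel_phantom([{}], band_shape=(50, 60), lane_pitch=50, row_pitch=40)
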
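"""Acceptor-photobleaching efficiency, Förster inversion and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fretbench as fb
from fretbench.fretindex import MeasurementError


def efficiency_from_distance(r_nm: float, r0: float = 4.7) -> float:
    """Independent oracle: the Förster law E(R) = R0^6 / (R0^6 + R^6)."""
    return r0**6 / (r0**6 + r_nm**6)


class TestEfficiency:
    def test_printed_formula_arithmetic(self):
        pre = np.full((1, 4, 4), 100.0)
        post = np.full((4, 4), 125.0)
        roi = fb.ROI("r", np.ones((4, 4), bool))
        dp, e = fb.efficiency(pre, post, roi)
        assert (dp.DA, dp.DOmega) == (100.0, 125.0)
        assert e == pytest.approx(0.20)

    def test_equal_pre_post_gives_zero(self):
        frames = np.full((2, 4, 4), 50.0)
        roi = fb.ROI("r", np.ones((4, 4), bool))
        _, e = fb.efficiency(frames, frames[0], roi)
        assert e == 0.0

    def test_two_pre_scans_are_averaged(self):
        pre = np.stack([np.full((4, 4), 90.0), np.full((4, 4), 110.0)])
        post = np.full((4, 4), 125.0)
        roi = fb.ROI("r", np.ones((4, 4), bool))
        dp, e = fb.efficiency(pre, post, roi)
        assert dp.DA == pytest.approx(100.0) and e == pytest.approx(0.2)

    def test_negative_e_retained_not_clamped(self):
        pre = np.full((1, 4, 4), 100.0)
        post = np.full((4, 4), 80.0)
        roi = fb.ROI("r", np.ones((4, 4), bool))
        _, e = fb.efficiency(pre, post, roi)
        assert e == pytest.approx(-0.25)

    def test_zero_post_donor_rejected(self):
        roi = fb.ROI("r", np.ones((2, 2), bool))
        with pytest.raises(MeasurementError, match="undefined"):
            fb.efficiency(np.ones((1, 2, 2)), np.zeros((2, 2)), roi)

    def test_noise_free_complete_bleach_recovers_truth(self, gastrula, margin_roi):
        bs = fb.render_bleach_series(
            gastrula, margin_roi.mask, 50, 0.0, noise=fb.NOISE_OFF
        )
        _, e = fb.efficiency(bs.pre_donor, bs.post_donor, margin_roi)
        assert e == pytest.approx(bs.truth["roi_mean_efficiency"], abs=1e-6)


class TestDistance:
    def test_half_transfer_returns_forster_distance(self):
        assert fb.distance_from_efficiency(0.5) == pytest.approx(4.7, abs=1e-12)

    def test_sixth_root_worked_value(self):
        # E = 1/65 -> (1/E - 1) = 64, 64^(1/6) = 2 -> R = 2 R0
        assert fb.distance_from_efficiency(1 / 65) == pytest.approx(9.4, abs=1e-9)

    def test_limits_and_exclusion(self):
        assert fb.distance_from_efficiency(0.0) is None
        assert fb.distance_from_efficiency(-0.1) is None
        with pytest.warns(UserWarning):
            assert fb.distance_from_efficiency(1.0) == 0.0
        assert fb.distance_from_efficiency(0.999999) < 0.5

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(deadline=None, max_examples=200)
    def test_round_trip_with_forster_law_oracle(self, e):
        r = fb.distance_from_efficiency(e)
        assert efficiency_from_distance(r) == pytest.approx(e, abs=1e-12)

    def test_strictly_decreasing_in_e(self):
        es = np.linspace(0.05, 0.95, 19)
        rs = [fb.distance_from_efficiency(e) for e in es]
        assert np.all(np.diff(rs) < 0)


class TestPreABMetrics:
    def test_equal_channels_ratio_one(self):
        f = np.full((4, 4), 7.0)
        roi = fb.ROI("r", np.ones((4, 4), bool))
        ratio, donor = fb.pre_ab_metrics(f, f, roi)
        assert ratio == pytest.approx(1.0) and donor == pytest.approx(7.0)

    def test_suppressed_phantom_shows_dequenched_donor(self):
        """Lower sensor activity (MEK-inhibited) means less donor quenching:
        acceptor/donor FRET proxy falls while donor intensity rises."""
        ratios, donors = {}, {}
        for label, act in (("untreated", 0.6), ("high_dose", 0.24)):
            ph = fb.make_embryo_phantom(
                "gastrula_5hpf", (48, 48), {"margin": act, "bulk": 0.1},
                seed=4, density_texture=0.0,
            )
            roi2d = ph.domain_mask("margin")[0]
            bs = fb.render_bleach_series(ph, roi2d, 50, 0.0, noise=fb.NOISE_OFF)
            roi = fb.ROI("margin", roi2d)
            ratios[label], donors[label] = fb.pre_ab_metrics(
                bs.pre_donor, bs.pre_acceptor, roi
            )
        # acceptor channel tracks sensor abundance; donor emission is
        # quenched by E, so lower activity means higher donor, lower A/D
        assert donors["high_dose"] > donors["untreated"]
        assert ratios["high_dose"] < ratios["untreated"]

    def test_empty_roi_rejected_at_construction(self):
        with pytest.raises(MeasurementError, match="non-empty"):
            fb.ROI("empty", np.zeros((4, 4), bool))


class TestRunAbfret:
    def test_mutant_margin_e_exceeds_wildtype(self):
        cfg = fb.default_cohort_config(seed=23, n_embryos=4, shape=(64, 64))
        members = fb.make_cohort(cfg)
        es = {}
        for m in members:
            roi = fb.ROI("margin", m.margin_roi)
            (rec,) = fb.run_abfret(m.bleach_series, [roi], embryo_id=m.embryo_id, group=m.group)
            es.setdefault(m.group, []).append(rec.E)
        assert np.mean(es["Shp2D61G"]) > np.mean(es["Shp2WT"])

    def test_no_bleach_gives_near_zero_e(self, gastrula, margin_roi):
        bs = fb.render_bleach_series(
            gastrula, margin_roi.mask, 50, 1.0,
            noise=fb.NoiseModel(photon_budget=1000, read_noise_sd=3), seed=6,
        )
        (rec,) = fb.run_abfret(bs, [margin_roi])
        # |E| bounded by 3x the noise-propagated SD of the ROI-mean ratio
        n = margin_roi.n_pixels
        mean_count = bs.pre_donor.mean()
        sd_e = np.sqrt((mean_count + 9) / n) / mean_count * np.sqrt(1.5)
        assert abs(rec.E) < 3 * sd_e

    def test_exclusion_rule_drops_nonpositive_e_from_distances(self):
        roi = fb.ROI("r", np.ones((4, 4), bool))
        bleach = np.ones((4, 4), bool)
        records = []
        for da, dom in ((100.0, 125.0), (100.0, 100.0), (100.0, 110.0)):
            bs = fb.BleachSeries(
                pre_donor=np.full((2, 4, 4), da),
                pre_acceptor=np.full((2, 4, 4), 50.0),
                post_donor=np.full((4, 4), dom),
                post_acceptor=np.full((4, 4), 5.0),
                bleach_roi=bleach, iterations=50, per_iteration_survival=0.0,
            )
            records += fb.run_abfret(bs, [roi])
        r_das = [r.R_DA_nm for r in records if r.R_DA_nm is not None]
        assert len(r_das) == 2
        assert [r.excluded_reason for r in records] == [
            "none", "E_zero_or_negative", "none"
        ]

    def test_roi_outside_bleach_region_flagged(self, gastrula):
        bleach = gastrula.domain_mask("margin")[0]
        outside = fb.ROI("bulk", gastrula.domain_mask("bulk")[0])
        bs = fb.render_bleach_series(gastrula, bleach, 50, 0.0, noise=fb.NOISE_OFF)
        (rec,) = fb.run_abfret(bs, [outside])
        assert rec.excluded_reason == "roi_not_bleached" and np.isnan(rec.E)


class TestClassification:
    def test_counts_above_and_below_threshold(self):
        out = fb.classify_by_threshold([5, 8, 9], threshold=7.53)
        assert out["n_high"] == 2 and out["prop_high"] == pytest.approx(2 / 3)

    def test_all_below_threshold(self):
        assert fb.classify_by_threshold([1, 2, 3], 7.53)["n_high"] == 0

    def test_tie_goes_to_low(self):
        out = fb.classify_by_threshold([7.53, 7.54], 7.53)
        assert out["n_high"] == 1 and out["n_low"] == 1

    def test_dose_reduces_high_proportion(self):
        cfg = fb.default_cohort_config(seed=31, n_embryos=6, shape=(64, 64))
        members = fb.make_cohort(cfg)
        es = {}
        for m in members:
            roi = fb.ROI("margin", m.margin_roi)
            (rec,) = fb.run_abfret(m.bleach_series, [roi])
            es.setdefault(m.group, []).append(rec.E_percent)
        high = {g: fb.classify_by_threshold(v)["prop_high"] for g, v in es.items()}
        assert high["Shp2D61G+1uMPD"] <= high["Shp2D61G"]

    def test_empty_group_rejected(self):
        with pytest.raises(MeasurementError):
            fb.classify_by_threshold([])
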
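"""ROI time courses, onset/saturation timing and COM trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from svoct import phantom, segmentation as seg
from svoct.diffusion import (
    ROISet,
    Square,
    compare_formulations,
    onset_time,
    place_rois,
    roi_timecourse,
    saturation_time,
    sv_center_of_mass,
    sv_center_of_mass_frame,
)
from svoct.pipeline import run_pipeline
from svoct.speckle_variance import SVImage


def make_mask(nz=150, nx=264, surface=20, bed=106):
    plate = np.zeros((nz, nx), bool)
    plate[surface:bed, :] = True
    prof = seg.SurfaceProfile(np.full(nx, surface), np.ones(nx, bool))
    return seg.NailMask(plate=plate, maz_interior=np.zeros((nz, nx), bool),
                        policy="exclude_maz"), prof


def sv_image(arr, t):
    return SVImage(sv=arr, stage="thresholded", timestamp_s=t,
                   reference_timestamp_s=0.0, threshold=0.05)


class TestPlaceROIs:
    apices = [(60, 73), (132, 73), (204, 73)]

    def test_three_squares_per_region_with_three_mazs(self):
        mask, prof = make_mask()
        rois = place_rois(mask, prof, self.apices)
        assert set(rois.regions) == {"I", "II", "III"}
        assert all(len(v) == 3 for v in rois.regions.values())

    def test_single_maz_omits_region_three(self):
        mask, prof = make_mask()
        rois = place_rois(mask, prof, self.apices[:1])
        assert "III" not in rois.regions
        assert set(rois.regions) == {"I", "II"}

    def test_all_squares_intersect_plate_mask(self):
        mask, prof = make_mask()
        rois = place_rois(mask, prof, self.apices)
        for squares in rois.regions.values():
            for s in squares:
                assert mask.plate[s.z0 : s.z1, s.x0 : s.x1].any()


class TestTimecourse:
    def make_rois(self):
        mask, prof = make_mask()
        return place_rois(mask, prof, TestPlaceROIs.apices), mask, prof

    def test_zero_sv_gives_zero_curves(self):
        rois, mask, prof = self.make_rois()
        series = [sv_image(np.zeros((150, 264)), 0.5 * (i + 1)) for i in range(4)]
        tc = roi_timecourse(series, rois)
        for label in tc.region_labels:
            assert np.all(tc.region_mean[label] == 0)
            assert np.all(tc.region_sd[label] == 0)

    def test_constant_sv_gives_area_scaled_sum_and_zero_sd(self):
        rois, mask, prof = self.make_rois()
        c = 0.2
        series = [sv_image(np.full((150, 264), c), 0.5)]
        tc = roi_timecourse(series, rois)
        area = rois.square_size_px**2
        for label in tc.region_labels:
            assert np.allclose(tc.region_mean[label], c * area)
            assert np.allclose(tc.region_sd[label], 0.0)

    def test_roi_outside_image_rejected(self):
        rois = ROISet(regions={"I": [Square(0, 10, 300, 310)]}, square_size_px=10)
        series = [sv_image(np.zeros((150, 264)), 0.5)]
        with pytest.raises(ValueError, match="outside"):
            roi_timecourse(series, rois)


class TestOnset:
    def test_flat_curve_has_no_onset(self):
        t = np.arange(10) * 0.5
        assert onset_time(t, np.zeros(10)) is None

    def test_step_curve_onset_at_jump(self):
        t = np.arange(10) * 0.5
        curve = np.where(np.arange(10) >= 4, 5.0, 0.0)
        assert onset_time(t, curve) == t[4]

    def test_single_spike_not_an_onset(self):
        t = np.arange(10) * 0.5
        curve = np.zeros(10)
        curve[4] = 5.0
        assert onset_time(t, curve) is None

    def test_baseline_shifts_threshold(self):
        t = np.arange(10) * 0.5
        curve = np.full(10, 2.0)
        assert onset_time(t, curve, baseline_mean=1.0, baseline_sd=1.0) is None
        assert onset_time(t, curve, baseline_mean=1.0, baseline_sd=0.1) == t[0]

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            onset_time(np.array([0.0]), np.array([1.0]))


class TestSaturation:
    def test_exponential_rise_crosses_at_analytic_time(self):
        # 1 - exp(-t/3) reaches 95% of its (asymptotic) plateau at
        # t = -3*ln(0.05) ~ 8.99 s; the finite-tail plateau pulls the
        # crossing slightly earlier, so allow one sample either side
        t = np.arange(0, 15, 0.2)
        curve = 1 - np.exp(-t / 3.0)
        sat = saturation_time(t, curve)
        plateau = curve[-int(np.ceil(0.1 * curve.size)) :].mean()
        analytic = 3.0 * np.log(1 / (1 - 0.95 * plateau))
        assert abs(sat - analytic) <= 0.2 + 1e-9

    def test_flat_zero_curve_undefined(self):
        t = np.arange(0, 5, 0.2)
        assert saturation_time(t, np.zeros(t.size)) is None

    def test_step_saturates_at_step_time(self):
        t = np.arange(0, 10, 0.5)
        curve = np.where(t >= 2.0, 4.0, 0.0)
        assert saturation_time(t, curve) == 2.0

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError, match="10 samples"):
            saturation_time(np.arange(5.0), np.arange(5.0))


class TestCenterOfMass:
    def test_single_pixel_com_at_its_depth(self):
        mask, prof = make_mask()
        arr = np.zeros((150, 264))
        arr[30, 100] = 0.3  # 10 px below the surface at row 20
        com = sv_center_of_mass_frame(sv_image(arr, 0.5), mask, prof, 7.0)
        assert com == pytest.approx(10 * 7.0)

    def test_two_equal_pixels_average_depths(self):
        mask, prof = make_mask()
        arr = np.zeros((150, 264))
        arr[30, 100] = 0.3
        arr[40, 100] = 0.3
        com = sv_center_of_mass_frame(sv_image(arr, 0.5), mask, prof, 7.0)
        assert com == pytest.approx(15 * 7.0)

    def test_scaling_sv_leaves_com_unchanged(self):
        mask, prof = make_mask()
        rng = np.random.default_rng(0)
        arr = np.zeros((150, 264))
        arr[25:90, :] = rng.random((65, 264))
        c1 = sv_center_of_mass_frame(sv_image(arr, 0.5), mask, prof, 7.0)
        c2 = sv_center_of_mass_frame(sv_image(3 * arr, 0.5), mask, prof, 7.0)
        assert c1 == pytest.approx(c2)

    def test_zero_sv_frame_undefined(self):
        mask, prof = make_mask()
        com = sv_center_of_mass([sv_image(np.zeros((150, 264)), 0.5)], mask, prof, 7.0)
        assert np.isnan(com[0])


class TestCompare:
    def make_tc(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(0.5, 12.5, 0.5)
        curve = np.clip((t - 1.0 - shift) * 2, 0, 10)
        tc_curves = {r: curve.copy() for r in ("I", "II", "III")}
        from svoct.diffusion import TimeCourse

        tc = TimeCourse(
            times_s=t,
            region_mean=tc_curves,
            region_sd={r: np.zeros(t.size) for r in tc_curves},
            com_depth_um=np.clip((t - shift) * 20, 0, 250),
            total_sv=np.clip((t - shift) * 50, 1, None),
        )
        for r in tc_curves:
            tc.onset_s[r] = onset_time(t, tc.region_mean[r])
            tc.saturation_s[r] = saturation_time(t, tc.region_mean[r])
        return tc

    def test_identical_courses_give_zero_diffs_unit_ratio(self):
        tc = self.make_tc()
        c = compare_formulations(tc, tc)
        assert all(v == 0.0 for v in c.onset_diff_s.values())
        assert c.com_rate_ratio == pytest.approx(1.0)

    def test_time_shifted_copy_gives_onset_difference(self):
        a, b = self.make_tc(), self.make_tc(shift=1.0)
        c = compare_formulations(a, b)
        assert all(v == pytest.approx(-1.0) for v in c.onset_diff_s.values())

    def test_no_time_overlap_rejected(self):
        from dataclasses import replace

        a = self.make_tc()
        b = self.make_tc()
        b.times_s = b.times_s + 100.0
        with pytest.raises(ValueError, match="overlap"):
            compare_formulations(a, b)


class TestSimulationOrdering:
    def test_liquid_before_cream_and_faster_descent(self, preset_cache):
        cfgL, truthL, concL = preset_cache("liquid_like")
        cfgC, truthC, concC = preset_cache("cream_like")
        orderings, ratios = [], []
        for s in (7, 8, 9):
            a = run_pipeline(
                phantom.render_series(truthL, concL, cfgL, seed=s)
            ).timecourse
            b = run_pipeline(
                phantom.render_series(truthC, concC, cfgC, seed=s)
            ).timecourse
            orderings.append(
                all(
                    a.onset_s[r] is not None
                    and b.onset_s[r] is not None
                    and a.onset_s[r] <= b.onset_s[r]
                    for r in ("II", "III")
                )
            )
            ratios.append(compare_formulations(a, b).com_rate_ratio)
        assert all(orderings)
        assert all(r > 1 for r in ratios)

    def test_region_one_first_for_wall_only_sources(self):
        # with the surface source off, the MAZ tips (Region I) must light
        # up before the upper-nail and mid-plate regions
        from dataclasses import replace

        cfg = replace(
            phantom.preset_config("liquid_like"),
            surface_source_relative=0.0,
            crater_fill_um_per_s=float("inf"),
        )
        truth, conc = phantom.preset_concentration(cfg)
        res = run_pipeline(phantom.render_series(truth, conc, cfg, seed=3))
        tc = res.timecourse
        assert tc.onset_s["I"] is not None
        for r in ("II", "III"):
            if tc.onset_s[r] is not None:
                assert tc.onset_s["I"] <= tc.onset_s[r]

    def test_com_nondecreasing_after_onset_liquid(self, liquid_run):
        res, _ = liquid_run
        tc = res.timecourse
        onset = min(v for v in tc.onset_s.values() if v is not None)
        post = tc.com_depth_um[tc.times_s >= onset + 1.0]
        post = post[np.isfinite(post)]
        # nondecreasing within simulation noise (small dips allowed)
        assert np.min(np.diff(post)) > -20.0
        assert post[-1] > post[0]
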
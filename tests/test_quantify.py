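"""ROI extraction, background subtraction, bleach correction, conversion."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ionoptode as ion
from ionoptode.quantify import (
    FLAG_NEGATIVE_INTENSITY,
    FLAG_OUT_OF_RANGE,
    plateau_concentrations,
)

FIT = ion.HillFit(r_min=0.4, r_max=2.0, ec50=1.05e-7, slope=-1.5)


def make_stack(sense, ref, dt=1.0):
    return ion.TwoChannelStack(sense=np.asarray(sense, float), ref=np.asarray(ref, float), frame_interval=dt)


def uniform_stack(n_frames=20, shape=(16, 16), value_s=100.0, value_r=50.0):
    return make_stack(
        np.full((n_frames,) + shape, value_s), np.full((n_frames,) + shape, value_r)
    )


def simple_rois(shape=(16, 16)):
    roi = np.zeros(shape, bool)
    roi[2:6, 2:6] = True
    bg = np.zeros(shape, bool)
    bg[10:14, 10:14] = True
    return ion.RoiSet(rois={"cell": roi}, background=bg)


class TestRoiExtraction:
    def test_uniform_image_gives_constant_trace(self):
        traces, bg = ion.extract_roi_traces(uniform_stack(), simple_rois())
        np.testing.assert_allclose(traces["cell"].sense_raw, 100.0)
        np.testing.assert_allclose(bg.ref_raw, 50.0)

    def test_single_pixel_mask_returns_pixel_series(self):
        rng = np.random.default_rng(0)
        sense = rng.uniform(10, 200, size=(12, 8, 8))
        stack = make_stack(sense, sense + 1)
        roi = np.zeros((8, 8), bool)
        roi[3, 4] = True
        bg = np.zeros((8, 8), bool)
        bg[0, 0] = True
        traces, _ = ion.extract_roi_traces(stack, ion.RoiSet(rois={"px": roi}, background=bg))
        np.testing.assert_allclose(traces["px"].sense_raw, sense[:, 3, 4])

    def test_ground_truth_means_match_generator_field(self, comp, eq, gains):
        # noise-free render: ROI means equal analytic density-field means
        t = np.arange(5.0)
        ca = np.full(5, 1.0e-7)
        stack, truth = ion.render_stack(
            (t, ca), comp, eq, gains=gains,
            noise=ion.NoiseSpec.noiseless(4), shape=(64, 64), n_cells=1,
        )
        rois = truth.roi_set()
        traces, _ = ion.extract_roi_traces(stack, rois)
        mask = list(rois.rois.values())[0]
        alpha = truth.alpha[0]
        f_s, _ = ion.channel_intensities_from_alpha(alpha, gains)
        expected = float(truth.density[mask].mean()) * f_s
        got = traces[list(rois.rois)[0]].sense_raw[0]
        assert got == pytest.approx(expected, rel=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ion.RoiError):
            ion.extract_roi_traces(uniform_stack(shape=(16, 16)), simple_rois((8, 8)))

    def test_overlapping_background_rejected(self):
        roi = np.zeros((8, 8), bool)
        roi[0:4, 0:4] = True
        with pytest.raises(ion.RoiError, match="overlaps"):
            ion.RoiSet(rois={"a": roi}, background=roi)


class TestBackgroundSubtract:
    def _trace(self, s, r):
        n = len(s)
        return ion.RatioTrace(name="t", time=np.arange(n, dtype=float),
                              sense_raw=np.asarray(s, float), ref_raw=np.asarray(r, float))

    def test_zero_background_is_identity(self):
        tr = self._trace([10, 20], [5, 5])
        bg = self._trace([0, 0], [0, 0])
        out = ion.background_subtract(tr, bg)
        np.testing.assert_allclose(out.sense_corr, tr.sense_raw)

    def test_constant_background_subtracts(self):
        tr = self._trace([10.0, 10.0], [8.0, 8.0])
        bg = self._trace([3.0, 3.0], [2.0, 2.0])
        out = ion.background_subtract(tr, bg)
        np.testing.assert_allclose(out.sense_corr, 7.0)
        np.testing.assert_allclose(out.ref_corr, 6.0)

    def test_negative_results_floored_and_flagged(self):
        tr = self._trace([1.0, 10.0], [5.0, 5.0])
        bg = self._trace([2.0, 2.0], [1.0, 1.0])
        out = ion.background_subtract(tr, bg)
        assert out.sense_corr[0] == 0.0
        assert out.flags[0] & FLAG_NEGATIVE_INTENSITY
        assert out.flags[1] == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ion.QuantifyError):
            ion.background_subtract(self._trace([1], [1]), self._trace([1, 2], [1, 2]))

    def test_generator_background_recovered(self, comp, eq, gains):
        # additive background field removed within the shot-noise budget
        t = np.arange(30.0)
        ca = np.full(30, 1.0e-7)
        noise = dataclasses.replace(
            ion.NoiseSpec.paper_like(9), bleach_rate_sense=0.0, bleach_rate_ref=0.0
        )
        stack, truth = ion.render_stack((t, ca), comp, eq, gains=gains, noise=noise,
                                        shape=(96, 96), n_cells=1)
        rois = truth.roi_set()
        traces, bg = ion.extract_roi_traces(stack, rois)
        name, mask = next(iter(rois.rois.items()))
        corr = ion.background_subtract(traces[name], bg)
        f_s, _ = ion.channel_intensities_from_alpha(truth.alpha[0], gains)
        expected = float(truth.density[mask].mean()) * f_s
        got = corr.sense_corr.mean()
        assert got == pytest.approx(expected, rel=0.03)


class TestPhotobleachCorrect:
    def _decay_trace(self, k_s, k_r, n=100, dt=1.0, i0=1000.0):
        t = np.arange(n) * dt
        return ion.RatioTrace(
            name="t", time=t,
            sense_raw=i0 * np.exp(-k_s * t), ref_raw=i0 * np.exp(-k_r * t),
        )

    def test_constant_trace_unchanged(self):
        tr = self._decay_trace(0.0, 0.0)
        out = ion.photobleach_correct(tr, (0, 50))
        np.testing.assert_allclose(out.sense_corr, tr.sense_raw)
        assert abs(out.bleach_rate_sense) < 1e-12

    def test_noiseless_decay_recovered_and_flattened(self):
        tr = self._decay_trace(0.01, 0.004)
        out = ion.photobleach_correct(tr, (0, 40), significance=None)
        assert out.bleach_rate_sense == pytest.approx(0.01, rel=1e-6)
        assert out.bleach_rate_ref == pytest.approx(0.004, rel=1e-6)
        np.testing.assert_allclose(out.sense_corr, out.sense_corr[0], rtol=1e-9)

    def test_equal_rates_leave_ratio_unchanged(self):
        tr = self._decay_trace(0.005, 0.005)
        raw_ratio = tr.sense_raw / tr.ref_raw
        out = ion.compute_trace_ratio(ion.photobleach_correct(tr, (0, 40), significance=None))
        np.testing.assert_allclose(out.ratio, raw_ratio, rtol=1e-9)

    def test_idempotent_on_corrected_trace(self):
        tr = self._decay_trace(0.008, 0.002)
        once = ion.photobleach_correct(tr, (0, 50), significance=None)
        twice = ion.photobleach_correct(once, (0, 50))
        np.testing.assert_allclose(twice.sense_corr, once.sense_corr, rtol=1e-9)

    def test_linear_model_flattens_linear_drift(self):
        t = np.arange(60.0)
        tr = ion.RatioTrace(name="t", time=t,
                            sense_raw=1000.0 * (1 - 0.002 * t), ref_raw=np.full(60, 500.0))
        out = ion.photobleach_correct(tr, (0, 60), model="linear", significance=None)
        np.testing.assert_allclose(out.sense_corr, 1000.0, rtol=1e-9)

    def test_insignificant_rate_not_extrapolated(self):
        rng = np.random.default_rng(2)
        t = np.arange(100.0)
        tr = ion.RatioTrace(
            name="t", time=t,
            sense_raw=1000.0 + rng.normal(0, 20, 100),
            ref_raw=500.0 + rng.normal(0, 10, 100),
        )
        out = ion.photobleach_correct(tr, (0, 20), significance=2.0)
        np.testing.assert_allclose(out.sense_corr, tr.sense_raw)

    def test_short_window_rejected(self):
        tr = self._decay_trace(0.01, 0.01)
        with pytest.raises(ion.QuantifyError, match=">= 10"):
            ion.photobleach_correct(tr, (0, 5))

    def test_quiescent_windows_extend_fit(self):
        tr = self._decay_trace(0.003, 0.001, n=300)
        out = ion.photobleach_correct(
            tr, (0, 20), significance=None, quiescent_windows=[(250, 300)]
        )
        assert out.bleach_rate_sense == pytest.approx(0.003, rel=1e-6)


class TestRatioToConcentration:
    def test_midpoint_ratio_maps_to_ec50(self):
        for slope in (-1.5, -0.7, 1.2):
            fit = ion.HillFit(r_min=0.4, r_max=2.0, ec50=1.05e-7, slope=slope)
            assert ion.ratio_to_concentration(1.2, fit) == pytest.approx(
                1.05e-7, rel=1e-12
            )

    def test_round_trip_through_forward_model(self):
        c = 2.5e-7
        assert ion.ratio_to_concentration(FIT.ratio_at(c), FIT) == pytest.approx(
            c, rel=1e-9
        )

    def test_matches_numerical_inversion_oracle(self):
        # brute-force bisection of the forward dose-response curve
        fit = ion.HillFit(r_min=0.4, r_max=2.0, ec50=1.05e-7, slope=-1.2)
        ratios = np.linspace(0.45, 1.95, 40)

        def oracle(r):
            lo, hi = -12.0, -2.0  # log10 concentration bracket
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if fit.ratio_at(10**mid) > r:
                    lo = mid  # ratio decreases with concentration
                else:
                    hi = mid
            return 10 ** (0.5 * (lo + hi))

        expected = np.array([oracle(r) for r in ratios])
        got = ion.ratio_to_concentration(ratios, fit)
        np.testing.assert_allclose(got, expected, rtol=1e-8)

    def test_out_of_range_is_nan_never_extrapolated(self):
        assert np.isnan(ion.ratio_to_concentration(2.0, FIT))  # at plateau
        assert np.isnan(ion.ratio_to_concentration(2.4, FIT))  # beyond plateau
        assert np.isnan(ion.ratio_to_concentration(0.1, FIT))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(ratio=st.floats(-5.0, 5.0))
    def test_adversarial_ratios_property(self, ratio):
        conc = ion.ratio_to_concentration(ratio, FIT)
        lo, hi = FIT.plateau_interval
        if lo < ratio < hi:
            assert np.isfinite(conc) and conc > 0
        else:
            assert np.isnan(conc)

    def test_convert_trace_flags_out_of_range_frames(self):
        tr = ion.RatioTrace(
            name="t", time=np.arange(3.0),
            sense_raw=np.ones(3), ref_raw=np.ones(3),
            ratio=np.array([1.2, 2.5, 0.9]),
        )
        out = ion.convert_trace(tr, FIT)
        assert out.flags[1] & FLAG_OUT_OF_RANGE
        assert out.flags[0] == 0 and out.flags[2] == 0


class TestQuantifyTimelapse:
    def test_common_gain_leaves_concentrations_unchanged(self, comp, eq, gains):
        spec = ion.TransientSpec(duration=240.0, onset=30.0, decay_tau=60.0)
        t, ca = ion.make_transient_trace(spec, 1.0)
        stack, truth = ion.render_stack(
            (t, ca), comp, eq, gains=gains,
            noise=ion.NoiseSpec.noiseless(6), shape=(64, 64), n_cells=1,
        )
        rois = truth.roi_set()
        series, _ = ion.make_calibration_series(comp, eq, gains=gains, noise=ion.NoiseSpec.noiseless(1))
        fit = ion.fit_hill(series)
        _, s1 = ion.quantify_timelapse(stack, rois, fit, 30)
        boosted = ion.TwoChannelStack(
            sense=stack.sense * 3.7, ref=stack.ref * 3.7, frame_interval=1.0
        )
        _, s2 = ion.quantify_timelapse(boosted, rois, fit, 30)
        for name in s1:
            assert s2[name]["peak_molar"] == pytest.approx(
                s1[name]["peak_molar"], rel=1e-6
            )

    def test_noise_free_pipeline_inverts_generator(self, comp, eq, gains):
        spec = ion.TransientSpec(duration=240.0, onset=30.0, decay_tau=60.0)
        t, ca = ion.make_transient_trace(spec, 1.0)
        stack, truth = ion.render_stack(
            (t, ca), comp, eq, gains=gains,
            noise=ion.NoiseSpec.noiseless(6), shape=(64, 64), n_cells=1,
        )
        rois = truth.roi_set()
        series, _ = ion.make_calibration_series(comp, eq, gains=gains, noise=ion.NoiseSpec.noiseless(1))
        fit = ion.fit_hill(series)
        traces, _ = ion.quantify_timelapse(stack, rois, fit, 30)
        trace = next(iter(traces.values()))
        # per-frame concentrations track the generator's Ca(t) closely
        np.testing.assert_allclose(trace.concentration, ca, rtol=0.02)

    def test_zero_amplitude_transient_stays_flat(self, comp, eq, gains):
        spec = ion.TransientSpec(peak=1.0e-7, duration=240.0, onset=30.0, decay_tau=60.0)
        t, ca = ion.make_transient_trace(spec, 1.0)
        stack, truth = ion.render_stack(
            (t, ca), comp, eq, gains=gains,
            noise=ion.NoiseSpec.paper_like(8), shape=(128, 128), n_cells=2,
        )
        series, _ = ion.make_calibration_series(comp, eq, gains=gains, noise=ion.NoiseSpec.plate_reader(2))
        fit = ion.fit_hill(series)
        # long extrapolation from a short baseline is fragile, so declare the
        # recovered tail quiescent and the reference channel static — the
        # recommended configuration for slow recordings
        _, summaries = ion.quantify_timelapse(
            stack, truth.roi_set(), fit, 30,
            static_reference=True, quiescent_windows=[(180, 240)],
        )
        # per-cell ROIs here are small (~500 px), so single-frame noise in
        # concentration is large; "flat within noise" means the summary
        # statistics sit at baseline well inside that noise scale
        for s in summaries.values():
            assert s["peak_molar"] == pytest.approx(1.0e-7, rel=0.30)
            assert s["baseline_molar"] == pytest.approx(1.0e-7, rel=0.15)

    def test_stimulus_frame_out_of_range_rejected(self, comp, eq):
        stack = uniform_stack()
        with pytest.raises(ion.QuantifyError):
            ion.quantify_timelapse(stack, simple_rois(), FIT, 999)


class TestPlateauAnalysis:
    def test_noiseless_square_wave_recovered_exactly(self, comp, eq, gains):
        t, ca, plateaus = ion.make_square_wave_trace(n_cycles=2)
        stack, truth = ion.render_stack(
            (t, ca), comp, eq, gains=gains,
            noise=ion.NoiseSpec.noiseless(5), shape=(64, 64), n_cells=1,
        )
        series, _ = ion.make_calibration_series(comp, eq, gains=gains, noise=ion.NoiseSpec.noiseless(1))
        fit = ion.fit_hill(series)
        conc = plateau_concentrations(stack, truth.roi_set(), fit, plateaus)
        for c, (_, _, level) in zip(conc, plateaus):
            assert c == pytest.approx(level, rel=0.02)


class TestInSituCalibration:
    CONCS = np.logspace(-8, -5.5, 7)

    def _endpoints(self, comp, eq, gains):
        series, _ = ion.make_calibration_series(
            comp, eq, gains=gains, noise=ion.NoiseSpec.noiseless(1)
        )
        return series.endpoint_ratios

    def test_recovers_generator_midpoint(self, comp, eq, gains):
        steps, truth = ion.make_in_situ_series(
            comp, eq, self.CONCS, gains=gains, noise=ion.NoiseSpec.paper_like(3)
        )
        fit = ion.in_situ_calibrate(steps, truth.roi_set(), self._endpoints(comp, eq, gains))
        assert fit.tag == "in_situ"
        # Monte-Carlo tolerance frozen from a seeded oracle study of this
        # estimator (shallow response + short series => ~35% band)
        assert fit.ec50 == pytest.approx(1.05e-7, rel=0.35)

    def test_discriminates_cytosol_shifted_sensitivity(self, comp, eq, gains):
        shifted = ion.default_equilibrium(comp, midpoint=2.0e-7)
        steps, truth = ion.make_in_situ_series(
            comp, shifted, self.CONCS, gains=gains, noise=ion.NoiseSpec.paper_like(3)
        )
        fit = ion.in_situ_calibrate(steps, truth.roi_set(), self._endpoints(comp, eq, gains))
        # recovered value sits with the shifted truth, not the in-solution one
        assert abs(np.log(fit.ec50 / 2.0e-7)) < abs(np.log(fit.ec50 / 1.05e-7))

    def test_single_step_rejected(self, comp, eq, gains):
        steps, truth = ion.make_in_situ_series(
            comp, eq, self.CONCS, gains=gains, noise=ion.NoiseSpec.paper_like(3)
        )
        with pytest.raises(ion.QuantifyError, match=">= 5"):
            ion.in_situ_calibrate(steps[:1], truth.roi_set())

    def test_unsorted_steps_rejected(self, comp, eq, gains):
        steps, truth = ion.make_in_situ_series(
            comp, eq, self.CONCS, gains=gains, noise=ion.NoiseSpec.paper_like(3)
        )
        with pytest.raises(ion.QuantifyError, match="increasing"):
            ion.in_situ_calibrate(steps[::-1], truth.roi_set())


class TestStackIO:
    def test_tiff_round_trip_interleaved_pages(self, tmp_path):
        rng = np.random.default_rng(1)
        stack = make_stack(
            rng.integers(0, 4000, (6, 16, 16)).astype(float),
            rng.integers(0, 4000, (6, 16, 16)).astype(float),
        )
        path = tmp_path / "stack.tif"
        stack.to_tiff(path)
        back = ion.TwoChannelStack.from_tiff(path, frame_interval=1.0)
        np.testing.assert_allclose(back.sense, stack.sense)
        np.testing.assert_allclose(back.ref, stack.ref)

    def test_roi_label_tiff_round_trip(self, tmp_path):
        rois = simple_rois()
        path = tmp_path / "rois.tif"
        rois.to_label_tiff(path)
        back = ion.RoiSet.from_label_tiff(path)
        np.testing.assert_array_equal(back.background, rois.background)
        np.testing.assert_array_equal(list(back.rois.values())[0], rois.rois["cell"])

    def test_roi_csv_round_trip(self, tmp_path):
        rois = simple_rois()
        path = tmp_path / "rois.csv"
        rois.to_csv(path)
        back = ion.RoiSet.from_csv(path, (16, 16))
        np.testing.assert_array_equal(back.rois["cell"], rois.rois["cell"])
        np.testing.assert_array_equal(back.background, rois.background)
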
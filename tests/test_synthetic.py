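"""Simulator: schedules, kinetics, indicator model, kernels, noise model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lumipipe as lp
from lumipipe.synthetic import kernel_traces, substrate_trace


class TestStimulusSchedule:
    @pytest.mark.parametrize("args, expected_onsets", [
        ((57, 1.0, 19.0, 60.0), 60.0 + 20.0 * np.arange(57)),
        ((1, 1.0, 19.0, 0.0), [0.0]),
        ((3, 2.0, 8.0, 5.0), [5.0, 15.0, 25.0]),
    ])
    def test_onset_arithmetic(self, args, expected_onsets):
        sched = lp.make_stimulus_schedule(*args)
        assert np.allclose(sched.onsets, expected_onsets)
        assert sched.n_cycles == len(sched.onsets)
        assert sched.cycle_length == args[1] + args[2]

    @pytest.mark.parametrize("args", [
        (0, 1.0, 19.0, 0.0), (3, 0.0, 19.0, 0.0), (3, 1.0, -1.0, 0.0),
    ])
    def test_invalid_parameters(self, args):
        with pytest.raises(ValueError):
            lp.make_stimulus_schedule(*args)

    def test_irregular_onsets_rejected(self):
        with pytest.raises(ValueError):
            lp.StimulusSchedule((0.0, 20.0, 50.0), 1.0, 20.0, 3)


class TestSubstrateKinetics:
    def test_zero_at_injection_instant(self):
        kin = lp.SubstrateKinetics(t_offset=0.0)
        assert substrate_trace(kin, np.array([0.0]))[0] == 0.0

    def test_positive_after_injection(self, kinetics):
        t = np.linspace(0, 1200, 500)
        assert np.all(substrate_trace(kinetics, t) > 0)

    def test_equal_rate_analytic_limit(self):
        k = 0.3
        kin = lp.SubstrateKinetics(amplitude=2.0, k_abs=k, k_elim=k,
                                   t_offset=0.0)
        t = np.array([30.0, 120.0, 600.0])
        expected = 2.0 * k * (t / 60.0) * np.exp(-k * t / 60.0)
        assert np.allclose(substrate_trace(kin, t), expected, rtol=1e-9)

    def test_peak_time_matches_grid_argmax(self, kinetics):
        """Closed-form peak time against a brute-force dense grid search."""
        t = np.arange(0.0, 1800.0, 0.05)
        kin = lp.SubstrateKinetics(t_offset=0.0, k_abs=kinetics.k_abs,
                                   k_elim=kinetics.k_elim)
        trace = substrate_trace(kin, t)
        assert kin.peak_time() == pytest.approx(t[np.argmax(trace)], abs=0.1)

    def test_single_interior_maximum(self, kinetics):
        t = np.arange(0.0, 1800.0, 0.2)
        trace = substrate_trace(lp.SubstrateKinetics(t_offset=0.0), t)
        d = np.diff(trace)
        sign_changes = np.sum(np.diff(np.sign(d[d != 0])) != 0)
        assert sign_changes == 1


class TestCalciumIndicator:
    def test_binding_curve_anchor_points(self):
        model = lp.CalciumIndicatorModel()  # Kd 110 nM, eightfold, n = 1
        assert lp.calcium_to_brightness(0.0, model) == 1.0
        assert lp.calcium_to_brightness(110.0, model) == pytest.approx(4.5)
        assert lp.calcium_to_brightness(np.inf, model) == 8.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            lp.calcium_to_brightness(-1.0, lp.CalciumIndicatorModel())

    @settings(derandomize=True, max_examples=50)
    @given(kd=st.floats(1.0, 1e4), rng_=st.floats(1.0, 50.0),
           n=st.floats(0.5, 3.0))
    def test_monotone_and_bounded(self, kd, rng_, n):
        model = lp.CalciumIndicatorModel(kd=kd, dynamic_range=rng_, hill_n=n)
        ca = np.logspace(-2, 7, 200)
        mult = lp.calcium_to_brightness(ca, model)
        assert np.all(np.diff(mult) >= 0)
        assert np.all((mult >= 1.0) & (mult <= rng_))


class TestResponseKernels:
    @pytest.mark.parametrize("kernel", [
        lp.ResponseKernel.hemodynamic(), lp.ResponseKernel.calcium(),
    ], ids=["hemodynamic", "calcium"])
    def test_causal_nonnegative_finite_support(self, kernel):
        t = np.arange(-5.0, 30.0, 0.01)
        y = kernel.evaluate(t)
        assert np.all(y >= 0)
        assert np.all(y[t < kernel.onset_delay] == 0)
        assert np.all(y[t > kernel.onset_delay + kernel.duration] == 0)
        assert t[np.argmax(y)] == pytest.approx(kernel.latency_to_peak,
                                                abs=0.02)
        assert y.max() == pytest.approx(kernel.amplitude, rel=1e-6)

    def test_hemodynamic_silent_before_two_seconds(self):
        """The late blood-flow response occupies 2-6 s post-stimulus."""
        k = lp.ResponseKernel.hemodynamic()
        t = np.arange(0.0, 2.0, 0.01)
        assert np.all(k.evaluate(t) == 0)

    def test_trace_superposition_over_onsets(self):
        sched = lp.make_stimulus_schedule(3, 1.0, 19.0, 0.0)
        t = np.arange(0, 60.0, 0.2)
        kern = lp.ResponseKernel.calcium()
        hemo, ca = kernel_traces([kern], sched, t)
        assert np.all(hemo == 0)
        single = sum(kern.evaluate(t - onset) for onset in sched.onsets)
        assert np.allclose(ca, single)


class TestSimulateVideo:
    def test_null_movie_is_deterministic_expectation(self, kinetics, camera,
                                                     tiny_geom):
        sched = lp.make_stimulus_schedule(2, 1.0, 19.0, 10.0)
        video, truth = lp.simulate_video(kinetics, camera, sched,
                                         geometry=tiny_geom, seed=0,
                                         noise=False)
        profile = tiny_geom.profile()
        expected = camera.dark_offset + camera.em_gain * camera.exposure * \
            truth.substrate_trace[:, None, None] * profile
        assert np.allclose(video.data, expected, rtol=1e-12)

    def test_same_seed_bit_identical(self, kinetics, camera, tiny_geom):
        sched = lp.make_stimulus_schedule(2, 1.0, 19.0, 10.0)
        a, _ = lp.simulate_video(kinetics, camera, sched, geometry=tiny_geom,
                                 seed=11)
        b, _ = lp.simulate_video(kinetics, camera, sched, geometry=tiny_geom,
                                 seed=11)
        c, _ = lp.simulate_video(kinetics, camera, sched, geometry=tiny_geom,
                                 seed=12)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_schedule_past_video_end_names_last_valid_onset(
            self, kinetics, camera, tiny_geom):
        sched = lp.make_stimulus_schedule(5, 1.0, 19.0, 10.0)
        with pytest.raises(ValueError, match="last onset that fits: 30"):
            lp.simulate_video(kinetics, camera, sched, geometry=tiny_geom,
                              duration=40.0)

    def test_noise_model_unbiased(self, kinetics, camera, tiny_geom):
        """Monte-Carlo: mean over 500 realizations of one pixel sits within
        3 standard errors of its noiseless expectation."""
        sched = lp.make_stimulus_schedule(1, 1.0, 3.0, 0.0)
        ref, _ = lp.simulate_video(kinetics, camera, sched,
                                   geometry=tiny_geom, noise=False)
        frame, px = 10, (8, 8)
        vals = np.array([
            lp.simulate_video(kinetics, camera, sched, geometry=tiny_geom,
                              seed=1000 + i)[0].data[frame][px]
            for i in range(500)])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - ref.data[frame][px]) < 3 * se

    def test_variance_grows_linearly_with_photon_count(self, kinetics,
                                                       camera, tiny_geom):
        """Regression of per-pixel residual variance on expected photons:
        slope within 10% of gain^2 * excess_noise_factor^2."""
        sched = lp.make_stimulus_schedule(1, 1.0, 19.0, 30.0)
        video, truth = lp.simulate_video(kinetics, camera, sched,
                                         geometry=tiny_geom, seed=21,
                                         duration=200.0)
        profile = tiny_geom.profile()
        lam = (camera.exposure * truth.substrate_trace[:, None, None]
               * profile)
        resid2 = (video.data - (camera.dark_offset
                                + camera.em_gain * lam)) ** 2
        lam_f, r2_f = lam.ravel(), resid2.ravel()
        # bin by expected photon count, regress bin-mean variance on lam
        bins = np.quantile(lam_f[lam_f > 1], np.linspace(0, 1, 20))
        idx = np.digitize(lam_f, bins)
        xs, ys = [], []
        for k in range(1, len(bins)):
            sel = idx == k
            if sel.sum() > 500:
                xs.append(lam_f[sel].mean())
                ys.append(r2_f[sel].mean())
        slope = np.polyfit(xs, ys, 1)[0]
        predicted = (camera.em_gain * camera.excess_noise_factor) ** 2
        assert slope == pytest.approx(predicted, rel=0.10)

    def test_truth_consistency(self, noiseless_sim, small_geom):
        """Masked-mean of a noiseless movie, divided by the substrate trace
        and the mean head profile, recovers 1 + hemo + calcium to 1e-9."""
        video, truth = noiseless_sim
        profile = small_geom.profile()
        mask = truth.head_mask_true
        fg = (video.data[:, mask] - lp.CameraModel().dark_offset)
        trace = fg.mean(axis=1)
        denom = (truth.substrate_trace * lp.CameraModel().em_gain
                 * lp.CameraModel().exposure * profile[mask].mean())
        recovered = trace / denom
        assert np.max(np.abs(recovered - truth.modulation)) < 1e-9
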
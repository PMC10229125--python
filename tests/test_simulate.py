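"""Ground-truth and statistical-law tests for the synthetic-data generators."""

import numpy as np
import pytest

from alquant.errors import ParameterError
from alquant.simulate import (
    ExposureProtocol,
    GlomerulusSpec,
    LabelVolumeParams,
    MovieParams,
    SsrTrialParams,
    UepscSessionParams,
    VmTrialParams,
    exposure_spike_budget,
    gas_concentration_ppb,
    gen_calcium_movie,
    gen_label_volume,
    gen_ssr_trial,
    gen_uepsc_session,
    gen_vm_trial,
)


class TestExposureDosimetry:
    def test_default_protocol_spike_budget(self):
        # 1 s pulse / 20 s cycle / 48 h / 150 spikes per pulse
        budget = exposure_spike_budget(ExposureProtocol())
        assert budget.pulses == 8640
        assert budget.total_spikes == 1_296_000
        assert budget.total_spikes_2sf == 1.3e6
        assert budget.extra_rate_per_min == pytest.approx(450.0)

    def test_zero_duration(self):
        assert exposure_spike_budget(ExposureProtocol(duration_h=0)).total_spikes == 0

    def test_21s_cycle(self):
        # floor(172800 / 21) * 150 = 1,234,200
        assert exposure_spike_budget(ExposureProtocol(cycle_s=21)).total_spikes == 1_234_200

    def test_invalid_protocol(self):
        with pytest.raises(ParameterError):
            ExposureProtocol(pulse_s=30, cycle_s=20)


class TestGasConcentration:
    @pytest.mark.parametrize(
        "vp,dil,air,expected",
        [
            (760.0, 1.0, 1.0, 1e9),       # pure saturated vapor
            (76.0, 1e-4, 11.0, 909.0909090909),
            (7.6, 1e-7, 11.0, 9.0909090909e-2),
        ],
    )
    def test_ideal_formula(self, vp, dil, air, expected):
        assert gas_concentration_ppb(vp, dil, air) == pytest.approx(expected, rel=1e-9)

    def test_preconditions(self):
        with pytest.raises(ParameterError):
            gas_concentration_ppb(-1, 1e-4, 11)
        with pytest.raises(ParameterError):
            gas_concentration_ppb(76, 2.0, 11)


class TestVmTrials:
    def test_silent_noiseless_trace_is_flat(self):
        params = VmTrialParams(
            spont_rate_hz=0, evoked_rate_hz=0, noise_sd_mV=0,
            depol_mV=0, ahp_mV=0, seed=0,
        )
        trial, truth = gen_vm_trial(params)
        assert truth.n_spikes == 0
        np.testing.assert_allclose(trial.samples, -60.0, atol=1e-12)

    def test_evoked_count_calibrated_to_150(self):
        counts = []
        for seed in range(50):
            _, truth = gen_vm_trial(VmTrialParams(seed=seed))
            counts.append(truth.count_in(5.0, 6.0))
        assert np.mean(counts) == pytest.approx(150.0, abs=10.0)

    def test_spontaneous_counts_follow_poisson_mean(self):
        # 5 Hz for 5 s pre-stimulus: mean 25 within 3 standard errors
        counts = [
            gen_vm_trial(VmTrialParams(seed=s))[1].count_in(0.0, 5.0)
            for s in range(200)
        ]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 25.0) <= 3 * se + 1e-9

    def test_refractory_gap_in_ground_truth(self):
        for seed in range(5):
            _, truth = gen_vm_trial(VmTrialParams(seed=seed))
            assert np.all(np.diff(truth.spike_times_s) >= 0.002 - 1e-9)

    def test_seed_reproducibility(self):
        a, _ = gen_vm_trial(VmTrialParams(seed=42))
        b, _ = gen_vm_trial(VmTrialParams(seed=42))
        c, _ = gen_vm_trial(VmTrialParams(seed=43))
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_rate_above_refractory_limit_rejected(self):
        with pytest.raises(ParameterError, match="500"):
            gen_vm_trial(VmTrialParams(evoked_rate_hz=600, seed=0))

    def test_test_pulse_deflection(self):
        params = VmTrialParams(
            spont_rate_hz=0, evoked_rate_hz=0, noise_sd_mV=0, depol_mV=0,
            ahp_mV=0, seed=0,
            test_pulse={"amplitude_pA": -5.0, "window": (1.0, 2.0), "rin_mohm": 500.0},
        )
        trial, _ = gen_vm_trial(params)
        sl = trial.index_window(1.1, 1.9)
        assert trial.samples[sl].mean() == pytest.approx(-60.0 - 2.5)


class TestSsrTrials:
    def test_silent_trace_is_noise_only(self):
        trial, ta, tb = gen_ssr_trial(SsrTrialParams(rate_a_hz=0, rate_b_hz=0, seed=0))
        assert ta.n_spikes == 0 and tb.n_spikes == 0
        assert np.abs(trial.samples).max() < 1.0  # no spike reaches unit amplitude

    def test_noiseless_two_amplitude_support_points(self):
        from alquant.spikes import detect_events_extracellular

        trial, ta, tb = gen_ssr_trial(
            SsrTrialParams(rate_a_hz=3, rate_b_hz=1, noise_sd=0, seed=0)
        )
        _, amps = detect_events_extracellular(trial, thresh_k=0.1)
        assert amps.size == ta.n_spikes + tb.n_spikes
        near_a = np.abs(amps - 2.0) < 0.02
        near_b = np.abs(amps - 1.0) < 0.02
        assert np.all(near_a | near_b)
        assert near_a.sum() == ta.n_spikes and near_b.sum() == tb.n_spikes

    def test_counts_follow_rates(self):
        na, nb = [], []
        for seed in range(100):
            _, ta, tb = gen_ssr_trial(SsrTrialParams(seed=seed))
            na.append(ta.n_spikes)
            nb.append(tb.n_spikes)
        assert np.mean(na) == pytest.approx(100, abs=3 * np.std(na) / 10 + 1)
        assert np.mean(nb) == pytest.approx(30, abs=3 * np.std(nb) / 10 + 1)

    def test_amplitude_ratio_contract(self):
        with pytest.raises(ParameterError, match="1.2"):
            SsrTrialParams(amp_a=1.1, amp_b=1.0)


class TestUepscSessions:
    def test_no_axons_all_failures(self):
        from alquant.uepsc import detect_epsc

        params = UepscSessionParams(
            n_axons=0, axon_thresholds_mW_mm2=(), trials_per_intensity=2, seed=0
        )
        session = gen_uepsc_session(params)
        assert all(not r for r in session.ground_truth["recruited"])
        assert not any(detect_epsc(s).present for s in session.sweeps)

    def test_single_axon_noiseless_unitary_amplitude(self):
        params = UepscSessionParams(
            n_axons=1, axon_thresholds_mW_mm2=(0.17,), noise_sd_pA=0,
            intensities=(0.30, 0.31, 0.32), trials_per_intensity=3, seed=1,
        )
        session = gen_uepsc_session(params)
        for sweep in session.sweeps:
            peak = -sweep.trial.samples.min()
            assert peak == pytest.approx(40.0, abs=0.05)

    def test_staircase_amplitude_doubles(self):
        # median success amplitude well above theta_2 is ~2x the plateau
        session = gen_uepsc_session(UepscSessionParams(seed=0))
        lows, highs = [], []
        for sweep, rec in zip(session.sweeps, session.ground_truth["recruited"]):
            if not rec:
                continue
            peak = -sweep.trial.samples.min()
            if sweep.light_intensity_mW_mm2 <= 0.19:
                lows.append(peak)
            elif sweep.light_intensity_mW_mm2 >= 0.25:
                highs.append(peak)
        assert np.median(highs) == pytest.approx(2 * np.median(lows), rel=0.15)

    def test_overlapping_thresholds_warn(self):
        with pytest.warns(UserWarning, match="unresolvable"):
            UepscSessionParams(axon_thresholds_mW_mm2=(0.170, 0.172), seed=0)


class TestCalciumMovies:
    def test_zero_response_is_stationary(self):
        movie, true_peak = gen_calcium_movie(
            MovieParams(dff_true=0.0, shot_noise=False, seed=0)
        )
        assert true_peak == 0.0
        assert np.ptp(movie.frames) == 0.0

    def test_noiseless_peak_pixel_value(self):
        params = MovieParams(dff_true=0.5, shot_noise=False, rise_tau_s=1e-4, seed=0)
        movie, _ = gen_calcium_movie(params)
        inside_max = movie.frames.max()
        assert inside_max == pytest.approx(1.5 * 100.0 + 10.0, rel=1e-3)

    def test_default_geometry(self):
        movie, _ = gen_calcium_movie(MovieParams(seed=0))
        assert movie.shape == (165, 96, 256)
        assert movie.frame_rate_hz == 11.0

    def test_short_baseline_rejected(self):
        with pytest.raises(ParameterError, match="70"):
            MovieParams(stim_on_frame=50)


class TestLabelVolumes:
    def test_no_glomeruli_background_only(self):
        vol, truth = gen_label_volume(
            LabelVolumeParams(glomeruli=(), noise_sd=0, seed=0)
        )
        assert truth == {}
        assert np.all(vol.cd8 == 100)

    def test_ellipsoid_volume_within_5pct_of_analytic(self):
        # min semi-axis >= 8 voxels in every direction
        glom = GlomerulusSpec(
            name="G", center_um=(20.0, 12.8, 25.6), semi_axes_um=(8.0, 1.8, 1.8)
        )
        _, truth = gen_label_volume(
            LabelVolumeParams(glomeruli=(glom,), noise_sd=0, seed=0)
        )
        info = truth["G"]
        assert info["voxel_volume_um3"] == pytest.approx(
            info["analytic_volume_um3"], rel=0.05
        )

    def test_default_dl5_scale_is_200_um3(self):
        _, truth = gen_label_volume(LabelVolumeParams(seed=0))
        assert truth["DL5"]["voxel_volume_um3"] == pytest.approx(200.0, rel=0.1)

    def test_overlapping_glomeruli_rejected(self):
        a = GlomerulusSpec(name="A", center_um=(20.0, 12.8, 25.6))
        b = GlomerulusSpec(name="B", center_um=(20.0, 12.8, 27.0))
        with pytest.raises(ParameterError, match="overlap"):
            gen_label_volume(LabelVolumeParams(glomeruli=(a, b), seed=0))

    def test_out_of_bounds_rejected(self):
        g = GlomerulusSpec(center_um=(1.0, 12.8, 25.6))
        with pytest.raises(ParameterError, match="fit"):
            gen_label_volume(LabelVolumeParams(glomeruli=(g,), seed=0))
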
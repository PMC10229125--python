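"""Windowed response metrics: arithmetic oracles, spike stripping,
normalization, Rin QC and f-I protocols."""

import numpy as np
import pytest

from alquant.errors import DataError, ParameterError
from alquant.io import MeasurementTable, TimeSeriesTrial
from alquant.metrics import (
    FiCurve,
    ResponseWindows,
    current_at_time,
    evoked_rate,
    fi_from_ramp,
    fi_from_steps,
    input_resistance_from_test_pulse,
    input_resistance_qc,
    mean_depolarization,
    normalize_to_control,
    post_stim_hyperpolarization,
    strip_spikes,
    vm_cv,
)
from alquant.simulate import VmTrialParams, gen_vm_trial
from alquant.spikes import SpikeTrain

FS = 10000.0


def vm_trial(samples, stim_on=5.0, stim_off=6.0, trial_id="t", meta=None):
    return TimeSeriesTrial(
        trial_id=trial_id, signal_kind="voltage_mV", fs=FS, samples=samples,
        stim_on=stim_on, stim_off=stim_off, meta=meta or {},
    )


def flat_trial(level=-60.0, duration=10.0, **kw):
    return vm_trial(np.full(int(duration * FS), level), **kw)


class TestEvokedRate:
    def test_equal_rates_cancel(self):
        train = SpikeTrain("t", np.concatenate([4.6 + np.arange(4) * 0.1,
                                                5.05 + np.arange(4) * 0.1]))
        assert evoked_rate(train, flat_trial()) == pytest.approx(0.0)

    def test_arithmetic(self):
        # 75 spikes in the 0.5 s onset window, 2 in the 0.5 s baseline -> 146 Hz
        onset = np.linspace(5.0, 5.499, 75)
        base = np.array([4.6, 4.8])
        train = SpikeTrain("t", np.sort(np.concatenate([base, onset])))
        assert evoked_rate(train, flat_trial()) == pytest.approx(146.0)

    def test_recovery_from_generator(self):
        # expected windowed difference from the generator's rate profile
        params = VmTrialParams(seed=0)
        peak, tau = params.evoked_peak_hz(), params.adapt_tau_s
        w = 0.5
        expected = peak * tau * (1 - np.exp(-w / tau)) / w  # spont cancels
        vals = []
        for seed in range(100):
            trial, truth = gen_vm_trial(VmTrialParams(seed=seed))
            vals.append(evoked_rate(truth, trial))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) <= 3 * se + 1e-9

    def test_window_outside_record_rejected(self):
        with pytest.raises(ParameterError):
            evoked_rate(SpikeTrain("t", []), flat_trial(stim_on=0.1, stim_off=0.9, duration=1.0))


class TestMeanDepolarization:
    def test_flat_trace_zero(self):
        val, qc = mean_depolarization(flat_trial(), None)
        assert val == 0.0 and qc == {}

    def test_square_depolarization_recovered(self):
        v = np.full(int(10 * FS), -60.0)
        v[int(5.0 * FS):int(6.0 * FS)] += 8.0
        val, _ = mean_depolarization(vm_trial(v), None)
        assert val == pytest.approx(8.0)

    def test_spike_stripping_removes_spike_bias(self):
        v = np.full(int(10 * FS), -60.0)
        v[int(5.0 * FS):int(6.0 * FS)] += 8.0
        clean, _ = mean_depolarization(vm_trial(v), None)
        spike_times = 5.05 + np.arange(8) * 0.05
        vs = v.copy()
        for t in spike_times:
            c = int(t * FS)
            vs[c - 5:c + 5] += 40.0
        spiky, _ = mean_depolarization(
            vm_trial(vs), SpikeTrain("t", spike_times)
        )
        assert abs(spiky - clean) < 0.5

    def test_mostly_stripped_window_flagged(self):
        v = np.full(int(10 * FS), -60.0)
        times = 5.0 + np.arange(0.002, 0.498, 0.003)
        _, qc = mean_depolarization(vm_trial(v), SpikeTrain("t", times))
        assert "onset_mostly_stripped" in qc

    def test_translation_invariance(self):
        trial, truth = gen_vm_trial(VmTrialParams(seed=2))
        v1, _ = mean_depolarization(trial, truth)
        shifted = vm_trial(trial.samples + 11.0)
        v2, _ = mean_depolarization(shifted, truth)
        assert v1 == pytest.approx(v2, abs=1e-9)


class TestPostStimHyperpolarization:
    def test_flat_trace_zero(self):
        assert post_stim_hyperpolarization(flat_trial()) == pytest.approx(0.0)

    def test_square_undershoot(self):
        v = np.full(int(10 * FS), -60.0)
        v[int(6.0 * FS):int(8.5 * FS)] -= 3.0
        assert post_stim_hyperpolarization(vm_trial(v)) == pytest.approx(3.0)

    def test_persistent_depolarization_is_negative(self):
        # delayed-excitation phenotype: depolarization outlasting the stimulus
        v = np.full(int(10 * FS), -60.0)
        v[int(5.0 * FS):int(8.5 * FS)] += 5.0
        assert post_stim_hyperpolarization(vm_trial(v)) == pytest.approx(-5.0)

    def test_short_record_rejected(self):
        with pytest.raises(ParameterError, match="offset"):
            post_stim_hyperpolarization(flat_trial(duration=7.0))


class TestVmCv:
    def test_constant_trace_zero(self):
        cv, qc = vm_cv(flat_trial())
        assert cv == 0.0 and qc == {}

    def test_sine_cv(self):
        # SD-2 mV sine around -60 mV: CV = 2/60
        t = np.arange(int(10 * FS)) / FS
        v = -60.0 + 2.0 * np.sqrt(2) * np.sin(2 * np.pi * 10 * t)
        cv, _ = vm_cv(vm_trial(v))
        assert cv == pytest.approx(2.0 / 60.0, rel=1e-3)

    def test_mean_near_zero_flagged(self):
        cv, qc = vm_cv(flat_trial(level=0.5))
        assert np.isnan(cv) and "undefined_mean_near_zero" in qc

    def test_decreases_with_noise(self):
        cvs = []
        for sd in (0.8, 0.4, 0.1):
            trial, truth = gen_vm_trial(
                VmTrialParams(noise_sd_mV=sd, spont_rate_hz=0, seed=9)
            )
            cvs.append(vm_cv(trial, truth)[0])
        assert cvs[0] > cvs[1] > cvs[2] >= 0


class TestNormalizeToControl:
    @staticmethod
    def table(rows):
        return MeasurementTable.from_records(
            [
                dict(
                    fly_id=f"f{i}", cell_id=f"c{i}", glomerulus="DL5",
                    exposure_group=g, stimulus_id=s, metric_name="depol", value=v,
                )
                for i, (g, s, v) in enumerate(rows)
            ]
        )

    def test_solvent_only_normalizes_to_one(self):
        t = self.table([("solvent", "s1", 3.0), ("solvent", "s1", 5.0),
                        ("solvent", "s2", 2.0), ("solvent", "s2", 6.0)])
        out = normalize_to_control(t, "depol")
        df = out.df
        for stim in ("s1", "s2"):
            sub = df[(df.stimulus_id == stim) & (df.metric_name == "depol_norm")]
            assert sub.value.mean() == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        t = self.table([("odor", "s1", 6.0), ("solvent", "s1", 4.0),
                        ("solvent", "s1", 4.0)])
        out = normalize_to_control(t, "depol")
        odor = out.df[(out.df.exposure_group == "odor")
                      & (out.df.stimulus_id == "s1")]
        assert odor.value.iloc[0] == pytest.approx(1.5)

    def test_pooled_mean_recovers_group_ratio(self):
        rows = []
        for stim in ("s1", "s2", "s3", "s4", "s5"):
            rows += [("solvent", stim, 4.0), ("solvent", stim, 4.0),
                     ("odor", stim, 5.0), ("odor", stim, 5.0)]
        out = normalize_to_control(self.table(rows), "depol")
        pooled = out.df[(out.df.stimulus_id == "pooled")
                        & (out.df.exposure_group == "odor")]
        assert pooled.value.mean() == pytest.approx(1.25)

    def test_small_solvent_mean_excluded(self):
        t = self.table([("odor", "s1", 6.0), ("solvent", "s1", 0.1),
                        ("solvent", "s1", -0.1),
                        ("odor", "s2", 6.0), ("solvent", "s2", 4.0),
                        ("solvent", "s2", 4.0)])
        out = normalize_to_control(t, "depol", eps=0.5)
        assert out.df.attrs["excluded_stimuli"] == ["s1"]
        assert set(out.df.stimulus_id) == {"s2", "pooled"}


class TestInputResistanceQc:
    def test_constant_passes(self):
        qc = input_resistance_qc([500.0, 500.0, 500.0])
        assert qc.passed and qc.max_drift_fraction == 0.0

    def test_20_percent_boundary(self):
        assert input_resistance_qc([500.0, 590.0]).passed          # 18%
        assert not input_resistance_qc([500.0, 605.0]).passed      # 21%

    def test_zero_first_value_unavailable(self):
        qc = input_resistance_qc([0.0, 500.0])
        assert not qc.available

    def test_single_measurement_rejected(self):
        with pytest.raises(ParameterError):
            input_resistance_qc([500.0])

    def test_rin_from_synthetic_test_pulse(self):
        params = VmTrialParams(
            spont_rate_hz=0, evoked_rate_hz=0, noise_sd_mV=0, depol_mV=0,
            ahp_mV=0, seed=0,
            test_pulse={"amplitude_pA": -5.0, "window": (1.0, 2.0), "rin_mohm": 480.0},
        )
        trial, _ = gen_vm_trial(params)
        rin = input_resistance_from_test_pulse(trial, -5.0, (1.0, 2.0))
        assert rin == pytest.approx(480.0, rel=0.01)


def threshold_linear_spikes(i_pA, rheobase=20.0, gain=2.0, duration=1.0, t0=0.0):
    """Deterministic threshold-linear cell: spikes whenever the integrated
    rate crosses an integer (integrate-and-fire-like oracle)."""
    rate = gain * max(i_pA - rheobase, 0.0)
    n = int(rate * duration)
    if n == 0:
        return np.empty(0)
    return t0 + (np.arange(1, n + 1)) / rate


class TestFiCurves:
    def make_steps(self, currents, rheobase=20.0):
        out = []
        for i, cur in enumerate(currents):
            trial = flat_trial(
                duration=3.0, stim_on=1.0, stim_off=2.0,
                meta={"step_pA": cur}, trial_id=f"s{i}",
            )
            spikes = threshold_linear_spikes(cur, rheobase=rheobase, t0=1.0)
            out.append((trial, SpikeTrain(trial.trial_id, spikes)))
        return out

    def test_subthreshold_curve_is_zero(self):
        curve = fi_from_steps(self.make_steps([0, 5, 10, 15]))
        assert np.all(curve.rate_hz == 0)
        assert curve.rheobase() is None

    def test_rate_arithmetic(self):
        trial = flat_trial(duration=3.0, stim_on=1.0, stim_off=2.0,
                           meta={"step_pA": 40.0})
        train = SpikeTrain("t", 1.0 + np.linspace(0.01, 0.99, 37))
        curve = fi_from_steps([(trial, train)])
        assert curve.rate_hz[0] == pytest.approx(37.0)

    def test_rheobase_recovered_within_one_step(self):
        currents = np.arange(0, 60, 5.0)
        curve = fi_from_steps(self.make_steps(currents, rheobase=22.0))
        assert abs(curve.rheobase() - 22.0) <= 5.0

    def test_unequal_durations_rejected(self):
        trials = self.make_steps([10.0])
        bad = flat_trial(duration=3.0, stim_on=1.0, stim_off=2.5,
                         meta={"step_pA": 15.0}, trial_id="bad")
        with pytest.raises(DataError, match="durations"):
            fi_from_steps(trials + [(bad, SpikeTrain("bad", []))])

    def test_ramp_zero_curve(self):
        trial = flat_trial(duration=22.0, stim_on=1.0, stim_off=21.0)
        curve = fi_from_ramp(trial, SpikeTrain("t", []))
        assert np.all(curve.rate_hz == 0)
        assert curve.protocol == "ramp_4p5pA_per_s"

    def test_current_pairing_on_ascent(self):
        # spike 2 s into the ascent with I0 = 0 sits at 9 pA
        trial = flat_trial(duration=22.0, stim_on=0.0, stim_off=20.0)
        assert current_at_time(2.0, trial) == pytest.approx(9.0)
        curve = fi_from_ramp(trial, SpikeTrain("t", [2.0]))
        hot = np.flatnonzero(curve.rate_hz > 0)
        assert np.all(np.abs(curve.current_pA[hot] - 9.0) <= 4.5 * 0.05 + 1e-9)

    def test_ramp_rheobase_consistent_with_steps(self):
        # same threshold-linear cell on a ramp: ascending-limb rheobase within
        # 2 pA of the step-protocol rheobase
        rheo, gain, slope = 22.0, 2.0, 4.5
        trial = flat_trial(duration=42.0, stim_on=1.0, stim_off=41.0)
        apex = 21.0
        # integrate the ramp-driven rate on the ascent to place spikes
        tt = np.linspace(1.0, apex, 200001)
        rate = gain * np.clip(slope * (tt - 1.0) - rheo, 0, None)
        cum = np.cumsum(rate) * (tt[1] - tt[0])
        spike_t = np.interp(np.arange(1, int(cum[-1]) + 1), cum, tt)
        curve = fi_from_ramp(trial, SpikeTrain("t", spike_t))
        ascent = curve.limb == "ascent"
        first = np.flatnonzero((curve.rate_hz > 0) & ascent)[0]
        step_curve = fi_from_steps(self.make_steps(np.arange(0, 60, 5.0), rheobase=rheo))
        assert abs(curve.current_pA[first] - step_curve.rheobase()) <= 2.0

    def test_slope_mismatch_rejected(self):
        trial = flat_trial(duration=22.0, stim_on=1.0, stim_off=21.0,
                           meta={"ramp_slope_pA_per_s": 9.0})
        with pytest.raises(DataError, match="slope"):
            fi_from_ramp(trial, SpikeTrain("t", []))


class TestStripSpikes:
    def test_no_spikes_identity(self):
        trial = flat_trial()
        v, replaced = strip_spikes(trial, None)
        np.testing.assert_array_equal(v, trial.samples)
        assert not replaced.any()

    def test_interpolation_bridges_spike(self):
        v = np.zeros(1000)
        v[500] = 40.0
        trial = vm_trial(v, stim_on=0.01, stim_off=0.02)
        stripped, replaced = strip_spikes(trial, SpikeTrain("t", [0.05]))
        assert np.all(stripped == 0.0)
        assert replaced.sum() == 41  # +/-2 ms at 10 kHz
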
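"""Synthetic-data generators with exact ground truth.

Every input the pipeline consumes can be generated here: membrane-potential
trials with Poisson spontaneous spiking, stimulus-locked depolarization,
evoked spiking and afterhyperpolarization; two-unit extracellular sensillum
traces; minimal-stimulation staircase sessions with per-axon recruitment
thresholds and a double-exponential unitary EPSC; calcium-imaging movies
with indicator kinetics and shot noise; and two-channel confocal volumes
with ellipsoidal glomeruli.  Each generator returns the exact ground truth
alongside the data, so every downstream stage is testable without recorded
data.  Generators are phenomenological (no conductance-based biophysics).

Spike trains are inhomogeneous Poisson processes with a 2 ms absolute
refractory (dead time), generated by thinning.  Because dead time removes a
fraction ``r * tau_ref`` of candidate events, the hazard is pre-corrected as
``lambda(t) = r(t) / (1 - r(t) * tau_ref)`` so that the *realized* rate
matches the requested rate ``r(t)``; requested rates must therefore stay
below the refractory-limited maximum of 500 Hz.

The module also models the chronic-exposure protocol's dosimetry: the total
extra spikes driven over days of periodic odor pulses, and the ideal-mixing
estimate of the gas-phase odor concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.signal import butter, filtfilt

from .anatomy import LabelVolume
from .errors import ParameterError
from .imaging import Movie
from .io import TimeSeriesTrial
from .spikes import SpikeTrain
from .uepsc import StaircaseSession, Sweep, epsc_template

REFRACTORY_S = 0.002
MAX_RATE_HZ = 1.0 / REFRACTORY_S / 2  # hazard correction safe well below 500


# ---------------------------------------------------------------------------
# Point-process machinery
# ---------------------------------------------------------------------------

def _thinned_poisson(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    duration: float,
    rate_max: float,
    rng: np.random.Generator,
    refractory_s: float = REFRACTORY_S,
) -> np.ndarray:
    """Inhomogeneous Poisson times with dead time, by thinning.

    ``rate_fn`` gives the target *realized* rate (Hz) at each time; the
    hazard is dead-time corrected so the realized rate matches it.
    """
    if rate_max >= 1.0 / refractory_s:
        raise ParameterError(
            f"rate {rate_max:.1f} Hz exceeds the refractory-limited maximum "
            f"({1.0 / refractory_s:.0f} Hz)"
        )
    hazard_max = rate_max / (1.0 - rate_max * refractory_s)
    if hazard_max <= 0:
        return np.empty(0)
    n = rng.poisson(hazard_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n))
    r = rate_fn(cand)
    hazard = r / (1.0 - r * refractory_s)
    keep = rng.uniform(0.0, hazard_max, size=n) < hazard
    cand = cand[keep]
    # greedy dead-time pass
    out = []
    last = -np.inf
    for t in cand:
        if t - last >= refractory_s:
            out.append(t)
            last = t
    return np.asarray(out)


def _filtered_noise(
    n: int, fs: float, sd: float, bandwidth_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian recording noise, low-pass filtered and rescaled to ``sd``."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if bandwidth_hz < fs / 2:
        b, a = butter(4, bandwidth_hz / (fs / 2))
        white = filtfilt(b, a, white)
        white /= white.std()
    return sd * white


def _spike_waveform(fs: float, amp_mV: float, width_ms: float) -> tuple[np.ndarray, int]:
    """Biphasic spike template; returns (waveform, index of the peak)."""
    sigma = width_ms / 1000.0 / 6.0
    half = int(round(5 * sigma * fs)) + int(round(0.003 * fs))
    t = (np.arange(2 * half + 1) - half) / fs
    w = np.exp(-(t**2) / (2 * sigma**2))
    w -= 0.15 * np.exp(-((t - 3 * sigma) ** 2) / (2 * (3 * sigma) ** 2))
    w *= amp_mV / w.max()  # peak equals the requested amplitude exactly
    return w, int(np.argmax(w))


def _add_events(signal: np.ndarray, fs: float, times: np.ndarray, wave: np.ndarray, peak_i: int) -> None:
    n = signal.size
    for t in times:
        c = int(round(t * fs))
        lo, hi = c - peak_i, c - peak_i + wave.size
        wlo, whi = max(0, -lo), wave.size - max(0, hi - n)
        lo, hi = max(lo, 0), min(hi, n)
        if lo < hi:
            signal[lo:hi] += wave[wlo:whi]


# ---------------------------------------------------------------------------
# Membrane-potential trials
# ---------------------------------------------------------------------------

@dataclass
class VmTrialParams:
    """Parameters of one synthetic PN membrane-potential trial.

    The default evoked peak rate is solved so that the expected realized
    spike count during the stimulus equals ``target_spikes_per_pulse``
    (the chronic-exposure calibration: ~150 spikes per 1 s pulse).
    """

    fs: float = 10000.0
    duration: float = 9.0  # 5 s pre-stimulus, 1 s stimulus, 3 s post
    stim_on: float = 5.0
    stim_off: float = 6.0
    rest_mV: float = -60.0
    spont_rate_hz: float = 5.0  # spontaneous PN rates span ~3-7 Hz
    evoked_rate_hz: float | None = None  # peak; None -> calibrated
    target_spikes_per_pulse: float = 150.0
    adapt_tau_s: float = 0.6
    depol_mV: float = 8.0
    depol_tau_s: float = 0.02
    ahp_mV: float = 2.0
    ahp_tau_s: float = 1.0
    noise_sd_mV: float = 0.4
    noise_bandwidth_hz: float = 1000.0
    spike_amp_mV: float = 12.0
    spike_width_ms: float = 2.0
    test_pulse: dict | None = None  # {"amplitude_pA", "window", "rin_mohm"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spont_rate_hz < 0 or (self.evoked_rate_hz or 0) < 0:
            raise ParameterError("rates must be >= 0")
        if self.noise_sd_mV < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.spike_width_ms <= 0:
            raise ParameterError("spike width must be > 0")
        if not self.stim_on < self.stim_off <= self.duration:
            raise ParameterError("stimulus window must fit inside the record")

    @property
    def stim_duration(self) -> float:
        return self.stim_off - self.stim_on

    def evoked_peak_hz(self) -> float:
        """Peak evoked rate; calibrated to the target per-pulse count if unset."""
        if self.evoked_rate_hz is not None:
            return self.evoked_rate_hz
        d = self.stim_duration
        tau = self.adapt_tau_s
        integral = tau * (1.0 - np.exp(-d / tau)) if tau > 0 else d
        target = self.target_spikes_per_pulse - self.spont_rate_hz * d
        return max(target, 0.0) / integral


def _vm_rate_fn(params: VmTrialParams) -> Callable[[np.ndarray], np.ndarray]:
    peak = params.evoked_peak_hz()

    def rate(t: np.ndarray) -> np.ndarray:
        r = np.full_like(t, params.spont_rate_hz, dtype=float)
        in_stim = (t >= params.stim_on) & (t < params.stim_off)
        if params.adapt_tau_s > 0:
            r[in_stim] += peak * np.exp(-(t[in_stim] - params.stim_on) / params.adapt_tau_s)
        else:
            r[in_stim] += peak
        return r

    return rate


def gen_vm_trial(params: VmTrialParams) -> tuple[TimeSeriesTrial, SpikeTrain]:
    """Simulate one PN whole-cell voltage trial; returns (trial, true spikes).

    The trace is resting potential + stimulus-locked depolarization +
    afterhyperpolarization + spike waveforms at dead-time-corrected
    inhomogeneous-Poisson times + band-limited Gaussian noise.  The returned
    spike times (template peaks) are exact ground truth.
    """
    peak_total = params.spont_rate_hz + params.evoked_peak_hz()
    if peak_total >= 1.0 / REFRACTORY_S:
        raise ParameterError(
            f"total rate {peak_total:.0f} Hz exceeds the refractory-limited 500 Hz"
        )
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.fs))
    t = np.arange(n) / params.fs

    v = np.full(n, params.rest_mV)
    # subthreshold stimulus-locked depolarization with exponential edges
    in_stim = (t >= params.stim_on) & (t < params.stim_off)
    post = t >= params.stim_off
    tau_m = params.depol_tau_s
    v[in_stim] += params.depol_mV * (1 - np.exp(-(t[in_stim] - params.stim_on) / tau_m))
    level_off = params.depol_mV * (1 - np.exp(-params.stim_duration / tau_m))
    v[post] += level_off * np.exp(-(t[post] - params.stim_off) / tau_m)
    # afterhyperpolarization
    if params.ahp_mV != 0:
        dt_post = t[post] - params.stim_off
        v[post] -= params.ahp_mV * (1 - np.exp(-dt_post / 0.1)) * np.exp(-dt_post / params.ahp_tau_s)
    # test pulse for input-resistance QC
    if params.test_pulse is not None:
        tp = params.test_pulse
        w0, w1 = tp["window"]
        mask = (t >= w0) & (t < w1)
        v[mask] += tp["amplitude_pA"] * tp.get("rin_mohm", 500.0) * 1e-3

    spike_times = _thinned_poisson(_vm_rate_fn(params), params.duration, peak_total, rng)
    wave, peak_i = _spike_waveform(params.fs, params.spike_amp_mV, params.spike_width_ms)
    _add_events(v, params.fs, spike_times, wave, peak_i)
    v += _filtered_noise(n, params.fs, params.noise_sd_mV, params.noise_bandwidth_hz, rng)

    trial = TimeSeriesTrial(
        trial_id=f"vm-{params.seed}",
        signal_kind="voltage_mV",
        fs=params.fs,
        samples=v,
        stim_on=params.stim_on,
        stim_off=params.stim_off,
        meta={"cell_type": "PN", "seed": params.seed},
    )
    # ground-truth times at the template peak, snapped to the sample grid
    truth = np.round(spike_times * params.fs) / params.fs
    truth = np.unique(truth)
    return trial, SpikeTrain(trial.trial_id, truth)


# ---------------------------------------------------------------------------
# Two-unit extracellular (sensillum) trials
# ---------------------------------------------------------------------------

@dataclass
class SsrTrialParams:
    """Two-unit extracellular trace: the large (A) and small (B) spike."""

    fs: float = 10000.0
    duration: float = 10.0
    rate_a_hz: float = 10.0
    rate_b_hz: float = 3.0
    amp_a: float = 2.0
    amp_b: float = 1.0
    spike_width_ms: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.amp_a > self.amp_b:
            raise ParameterError("unit A must be larger than unit B")
        if self.amp_b <= self.noise_sd:
            raise ParameterError("unit B amplitude must exceed the noise SD")
        if self.amp_a / self.amp_b < 1.2:
            raise ParameterError(
                "amplitude ratio < 1.2: units not separable by design contract"
            )


def gen_ssr_trial(params: SsrTrialParams) -> tuple[TimeSeriesTrial, SpikeTrain, SpikeTrain]:
    """Simulate a sensillum trace holding two spike waveforms of distinct size."""
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.fs))
    v = np.zeros(n)
    trains = []
    for amp, rate in ((params.amp_a, params.rate_a_hz), (params.amp_b, params.rate_b_hz)):
        times = _thinned_poisson(
            lambda t, r=rate: np.full_like(t, float(r)), params.duration, max(rate, 1e-9), rng
        )
        wave, peak_i = _spike_waveform(params.fs, amp, params.spike_width_ms)
        _add_events(v, params.fs, times, wave, peak_i)
        trains.append(np.round(times * params.fs) / params.fs)
    v += _filtered_noise(n, params.fs, params.noise_sd, 2000.0, rng)
    trial = TimeSeriesTrial(
        trial_id=f"ssr-{params.seed}",
        signal_kind="voltage_mV",
        fs=params.fs,
        samples=v,
        stim_on=0.0,
        stim_off=params.duration,
        meta={"recording": "single_sensillum", "seed": params.seed},
    )
    return (
        trial,
        SpikeTrain(trial.trial_id, np.unique(trains[0]), unit_label="A"),
        SpikeTrain(trial.trial_id, np.unique(trains[1]), unit_label="B"),
    )


# ---------------------------------------------------------------------------
# Minimal-stimulation staircase sessions
# ---------------------------------------------------------------------------

@dataclass
class UepscSessionParams:
    """Synthetic minimal-stimulation session.

    Each axon k fires with probability sigmoid((I - theta_k)/slope) on a
    sweep at intensity I; every recruited axon adds one double-exponential
    unitary EPSC at a latency drawn per trial.
    """

    n_axons: int = 2
    unitary_amp_pA: float = 40.0
    rise_ms: float = 2.0
    half_decay_ms: float = 7.0
    latency_mean_ms: float = 23.0
    latency_sd_ms: float = 2.2
    axon_thresholds_mW_mm2: tuple = (0.17, 0.21)
    recruit_slope: float = 0.004
    noise_sd_pA: float = 2.0
    intensities: tuple = tuple(np.round(np.arange(0.10, 0.265, 0.01), 3))
    trials_per_intensity: int = 10
    fs: float = 10000.0
    sweep_duration_s: float = 0.35
    light_onset_s: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_axons < 0:
            raise ParameterError("n_axons must be >= 0")
        if self.unitary_amp_pA <= 0:
            raise ParameterError("unitary amplitude must be > 0")
        th = list(self.axon_thresholds_mW_mm2)[: self.n_axons]
        if len(th) < self.n_axons:
            raise ParameterError("need one threshold per axon")
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ParameterError("axon thresholds must be strictly increasing")
        if any(b - a < self.recruit_slope for a, b in zip(th, th[1:])):
            warnings.warn(
                "axon thresholds overlap within the recruitment slope; "
                "the doubling step may be unresolvable",
                stacklevel=2,
            )


def gen_uepsc_session(params: UepscSessionParams) -> StaircaseSession:
    """Simulate a staircase session; ground-truth recruitment labels are in
    ``session.ground_truth``."""
    rng = np.random.default_rng(params.seed)
    n = int(round(params.sweep_duration_s * params.fs))
    t = np.arange(n) / params.fs
    thresholds = np.asarray(params.axon_thresholds_mW_mm2[: params.n_axons], dtype=float)
    sweeps = []
    recruited_truth = []
    latencies_truth = []
    k = 0
    for intensity in params.intensities:
        for _ in range(params.trials_per_intensity):
            i = np.zeros(n)
            if params.n_axons:
                p = 1.0 / (1.0 + np.exp(-(intensity - thresholds) / params.recruit_slope))
                recruited = np.flatnonzero(rng.uniform(size=params.n_axons) < p)
            else:
                recruited = np.empty(0, dtype=int)
            lats = []
            for _axon in recruited:
                lat_ms = max(rng.normal(params.latency_mean_ms, params.latency_sd_ms), 1.0)
                lats.append(lat_ms)
                i += epsc_template(
                    t,
                    amplitude_pA=params.unitary_amp_pA,
                    rise_ms=params.rise_ms,
                    half_decay_ms=params.half_decay_ms,
                    onset_s=params.light_onset_s + lat_ms / 1000.0,
                )
            if params.noise_sd_pA > 0:
                i += rng.normal(0.0, params.noise_sd_pA, size=n)
            trial = TimeSeriesTrial(
                trial_id=f"uepsc-{params.seed}-{k}",
                signal_kind="current_pA",
                fs=params.fs,
                samples=i,
                stim_on=params.light_onset_s,
                stim_off=params.light_onset_s + 1e-4,
                meta={"light_intensity_mW_mm2": float(intensity)},
            )
            sweeps.append(
                Sweep(trial=trial, light_onset_s=params.light_onset_s,
                      light_intensity_mW_mm2=float(intensity))
            )
            recruited_truth.append(recruited.tolist())
            latencies_truth.append(lats)
            k += 1
    return StaircaseSession(
        sweeps=sweeps,
        pulse_dur_s=1e-4,
        ground_truth={
            "recruited": recruited_truth,
            "latencies_ms": latencies_truth,
            "thresholds": thresholds.tolist(),
            "unitary_amp_pA": params.unitary_amp_pA,
            "rise_ms": params.rise_ms,
            "half_decay_ms": params.half_decay_ms,
            "latency_mean_ms": params.latency_mean_ms,
        },
    )


# ---------------------------------------------------------------------------
# Calcium-imaging movies
# ---------------------------------------------------------------------------

@dataclass
class MovieParams:
    """Synthetic glomerular calcium-imaging movie (15 s trial at 11 Hz)."""

    shape: tuple = (165, 96, 256)  # T, H, W
    frame_rate_hz: float = 11.0
    baseline_F: float = 100.0
    dark_offset: float = 10.0
    roi_center: tuple = (48, 128)
    roi_radius: float = 12.0
    dff_true: float = 0.5
    rise_tau_s: float = 0.05
    decay_tau_s: float = 0.4
    stim_on_frame: int = 88  # 8 s of baseline at 11 Hz
    stim_len_s: float = 0.5
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if np.prod(self.shape) <= 0:
            raise ParameterError("movie shape must be non-empty")
        if not self.baseline_F > self.dark_offset >= 0:
            raise ParameterError("need baseline_F > dark_offset >= 0")
        if self.stim_on_frame < 70:
            raise ParameterError("need >= 70 baseline frames before the stimulus")


def _indicator_kernel(params: MovieParams) -> np.ndarray:
    """Per-frame indicator response, 0 at baseline and peaking near 1."""
    tt, _, _ = params.shape
    t = np.arange(tt) / params.frame_rate_hz
    t_on = params.stim_on_frame / params.frame_rate_hz
    t_off = t_on + params.stim_len_s
    k = np.zeros(tt)
    rising = (t >= t_on) & (t < t_off)
    k[rising] = 1 - np.exp(-(t[rising] - t_on) / params.rise_tau_s)
    peak = 1 - np.exp(-params.stim_len_s / params.rise_tau_s)
    after = t >= t_off
    k[after] = peak * np.exp(-(t[after] - t_off) / params.decay_tau_s)
    return k


def gen_calcium_movie(params: MovieParams) -> tuple[Movie, float]:
    """Simulate a movie with a circular responsive ROI; returns the true
    peak dF/F as ground truth."""
    rng = np.random.default_rng(params.seed)
    tt, h, w = params.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = params.roi_center
    roi = (yy - cy) ** 2 + (xx - cx) ** 2 <= params.roi_radius**2
    k = _indicator_kernel(params)
    f_true = np.full((tt, h, w), params.baseline_F, dtype=float)
    f_true[:, roi] *= 1 + params.dff_true * k[:, None]
    if params.shot_noise:
        frames = rng.poisson(f_true).astype(float) + params.dark_offset
    else:
        frames = f_true + params.dark_offset
    movie = Movie(
        frames=frames,
        frame_rate_hz=params.frame_rate_hz,
        stim_on_frame=params.stim_on_frame,
        stim_len_s=params.stim_len_s,
        dark_offset=params.dark_offset,
    )
    frames_in_stim = k[
        params.stim_on_frame : params.stim_on_frame
        + int(np.ceil(params.stim_len_s * params.frame_rate_hz))
    ]
    true_peak = params.dff_true * float(frames_in_stim.max(initial=0.0))
    return movie, true_peak


# ---------------------------------------------------------------------------
# Confocal label volumes
# ---------------------------------------------------------------------------

@dataclass
class GlomerulusSpec:
    """Ellipsoidal glomerulus in micrometre coordinates."""

    name: str = "DL5"
    center_um: tuple = (20.0, 12.8, 25.6)  # (z, y, x)
    semi_axes_um: tuple = (3.6, 3.6, 3.6)  # ~200 um^3, the DL5 scale
    cd8_level: int = 2000
    nc82_level: int = 4000


@dataclass
class LabelVolumeParams:
    shape: tuple = (40, 128, 256)  # Z, Y, X voxels
    voxel_size: tuple = (1.0, 0.2, 0.2)  # um; 1 um slices, sub-um pixels
    glomeruli: tuple = (GlomerulusSpec(),)
    background_cd8: int = 100
    background_nc82: int = 200
    noise_sd: float = 20.0
    bit_depth: int = 16
    seed: int = 0


def _ellipsoid_mask(shape, voxel_size, center_um, semi_axes_um) -> np.ndarray:
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    dz, dy, dx = voxel_size
    cz, cy, cx = center_um
    az, ay, ax = semi_axes_um
    return (
        ((zz * dz - cz) / az) ** 2
        + ((yy * dy - cy) / ay) ** 2
        + ((xx * dx - cx) / ax) ** 2
    ) <= 1.0


def gen_label_volume(params: LabelVolumeParams) -> tuple[LabelVolume, dict]:
    """Simulate a two-channel stack; ground truth holds per-glomerulus voxel
    counts, analytic volumes, masks and channel levels."""
    rng = np.random.default_rng(params.seed)
    z, y, x = params.shape
    dz, dy, dx = params.voxel_size
    for g in params.glomeruli:
        cz, cy, cx = g.center_um
        az, ay, ax = g.semi_axes_um
        if (
            cz - az < 0 or cz + az > z * dz
            or cy - ay < 0 or cy + ay > y * dy
            or cx - ax < 0 or cx + ax > x * dx
        ):
            raise ParameterError(f"glomerulus {g.name!r} does not fit inside the volume")
    cd8 = np.full(params.shape, float(params.background_cd8))
    nc82 = np.full(params.shape, float(params.background_nc82))
    truth = {}
    occupied = np.zeros(params.shape, dtype=bool)
    for g in params.glomeruli:
        mask = _ellipsoid_mask(params.shape, params.voxel_size, g.center_um, g.semi_axes_um)
        if (mask & occupied).any():
            raise ParameterError(f"glomerulus {g.name!r} overlaps another glomerulus")
        occupied |= mask
        cd8[mask] = g.cd8_level
        nc82[mask] = g.nc82_level
        az, ay, ax = g.semi_axes_um
        truth[g.name] = {
            "n_voxels": int(mask.sum()),
            "voxel_volume_um3": int(mask.sum()) * dz * dy * dx,
            "analytic_volume_um3": 4.0 / 3.0 * np.pi * az * ay * ax,
            "cd8_level": g.cd8_level,
            "nc82_level": g.nc82_level,
            "mask": mask,
        }
    top = 2**params.bit_depth - 1
    if params.noise_sd > 0:
        cd8 += rng.normal(0, params.noise_sd, size=params.shape)
        nc82 += rng.normal(0, params.noise_sd, size=params.shape)
    cd8 = np.clip(np.round(cd8), 1, top - 1).astype(np.int64)
    nc82 = np.clip(np.round(nc82), 1, top - 1).astype(np.int64)
    vol = LabelVolume(cd8=cd8, nc82=nc82, voxel_size=params.voxel_size, bit_depth=params.bit_depth)
    return vol, truth


# ---------------------------------------------------------------------------
# Exposure dosimetry
# ---------------------------------------------------------------------------

@dataclass
class ExposureProtocol:
    """Chronic odor-exposure protocol: a 1 s odor pulse every ``cycle_s``
    seconds, around the clock."""

    pulse_s: float = 1.0
    cycle_s: float = 20.0
    duration_h: float = 48.0
    spikes_per_pulse: float = 150.0

    def __post_init__(self) -> None:
        if not 0 < self.pulse_s < self.cycle_s:
            raise ParameterError("need 0 < pulse < cycle")
        if self.duration_h < 0:
            raise ParameterError("duration must be >= 0")


@dataclass
class SpikeBudget:
    total_spikes: int
    total_spikes_2sf: float
    pulses: int
    extra_rate_per_min: float


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def exposure_spike_budget(protocol: ExposureProtocol) -> SpikeBudget:
    """Total extra spikes driven by the exposure protocol.

    Defaults (1 s pulse / 20 s cycle / 48 h / 150 spikes per pulse) give
    1,296,000 extra spikes, ~1.3 million at two significant figures.
    """
    seconds = protocol.duration_h * 3600.0
    pulses = int(np.floor(seconds / protocol.cycle_s + 1e-9))
    total = int(round(pulses * protocol.spikes_per_pulse))
    per_min = (
        protocol.spikes_per_pulse * 60.0 / protocol.cycle_s if protocol.cycle_s else 0.0
    )
    return SpikeBudget(
        total_spikes=total,
        total_spikes_2sf=_round_sig(total, 2),
        pulses=pulses,
        extra_rate_per_min=per_min,
    )


def gas_concentration_ppb(
    vapor_pressure_torr: float,
    liquid_vv_dilution: float,
    airflow_dilution: float,
) -> float:
    """Ideal-mixing estimate of headspace odor concentration in air (ppb).

    Assumes Raoult's law with the volumetric dilution standing in for the
    mole fraction, and a further ``airflow_dilution``-fold dilution of the
    headspace into the carrier stream:
    ppb = (vp / 760) * dilution / airflow * 1e9.
    Real headspace concentrations deviate from this ideal estimate whenever
    activity coefficients differ from 1.
    """
    if vapor_pressure_torr <= 0 or liquid_vv_dilution <= 0 or airflow_dilution <= 0:
        raise ParameterError("all inputs must be > 0")
    if liquid_vv_dilution > 1:
        raise ParameterError("liquid dilution is a fraction <= 1")
    return vapor_pressure_torr / 760.0 * liquid_vv_dilution / airflow_dilution * 1e9
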
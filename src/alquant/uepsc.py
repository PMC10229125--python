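"""Minimal-stimulation unitary-EPSC analysis.

In a minimal-stimulation session the light driving presynaptic axons is
ramped in small increments across sweeps.  Sweeps at sub-threshold
intensities are failures; at the recruitment threshold of the first axon an
EPSC appears in an all-or-none manner, its amplitude stays constant over a
range of intensities (the unitary regime), and it abruptly doubles when a
second axon is recruited.  The unitary EPSC is characterized by averaging
peak-aligned successes at an intensity about halfway between the initial
threshold and the doubling intensity, and measuring amplitude, 10-90% rise
time, and half-decay time on the mean trace; onset latency statistics are
taken over individual sweeps.

Sign convention: EPSCs are inward (negative) in raw sweeps; all reported
amplitudes are positive magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, fsolve

from .errors import DataError, ParameterError
from .io import TimeSeriesTrial


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class Sweep:
    """One voltage-clamp sweep with its light-pulse timing and intensity."""

    trial: TimeSeriesTrial
    light_onset_s: float
    light_intensity_mW_mm2: float


@dataclass
class StaircaseSession:
    """Ordered ramp of sweeps over non-decreasing light intensities."""

    sweeps: list[Sweep]
    pulse_dur_s: float = 1e-4  # 100 us light pulse
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ints = [s.light_intensity_mW_mm2 for s in self.sweeps]
        if any(b < a - 1e-12 for a, b in zip(ints, ints[1:])):
            raise DataError("light intensities must be non-decreasing across the ramp")
        for s in self.sweeps:
            if s.trial.signal_kind != "current_pA":
                raise DataError("staircase sweeps must be current_pA trials")

    @property
    def intensities(self) -> np.ndarray:
        return np.unique([s.light_intensity_mW_mm2 for s in self.sweeps])


@dataclass
class EpscEvent:
    """Per-sweep EPSC detection result."""

    present: bool
    amplitude_pA: float = 0.0
    onset_s: float = 0.0
    latency_ms: float = 0.0
    peak_time_s: float = 0.0


@dataclass
class StaircaseSegmentation:
    """Failure / unitary / doubled regimes of an intensity staircase."""

    threshold_intensity: float | None
    doubling_intensity: float | None
    unitary_range: tuple[float, float | None] | None
    plateau_amp_pA: float | None
    per_intensity: dict  # intensity -> {"success_rate", "median_amp", "n"}


@dataclass
class UnitaryEpsc:
    """Kinetic summary of the unitary EPSC of one cell."""

    mean_trace: np.ndarray
    fs: float
    amplitude_pA: float
    rise_ms: float
    half_decay_ms: float
    latency_mean_ms: float
    latency_sd_ms: float
    n_trials: int
    chosen_intensity: float
    unitary_intensity_range: tuple[float, float | None]
    doubling_intensity: float | None
    qc: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Double-exponential template
# ---------------------------------------------------------------------------

def _diffexp(t: np.ndarray, tau_r: float, tau_d: float) -> np.ndarray:
    out = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_d) - np.exp(-np.maximum(t, 0) / tau_r), 0.0)
    return out


def _peak_time(tau_r: float, tau_d: float) -> float:
    return tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)


def _kinetics_of(tau_r: float, tau_d: float) -> tuple[float, float]:
    """(10-90% rise time, peak-to-50% half decay) of the normalized template."""
    tp = _peak_time(tau_r, tau_d)
    peak = _diffexp(np.array([tp]), tau_r, tau_d)[0]

    def level(frac):
        return lambda t: _diffexp(np.array([t]), tau_r, tau_d)[0] - frac * peak

    t10 = brentq(level(0.1), 1e-12, tp)
    t90 = brentq(level(0.9), t10, tp)
    t50 = brentq(level(0.5), tp, tp + 20 * tau_d)
    return t90 - t10, t50 - tp


def epsc_template_taus(rise_ms: float, half_decay_ms: float) -> tuple[float, float]:
    """Solve for the (tau_rise, tau_decay) of a difference-of-exponentials
    whose normalized waveform has the requested 10-90% rise and half-decay
    times (both in ms)."""
    if not 0 < rise_ms < half_decay_ms:
        raise ParameterError("need 0 < rise < half-decay")

    def resid(x):
        tr, td = np.exp(x)  # log-parameterized to keep taus positive, td > tr
        if td <= tr * 1.0001:
            td = tr * 1.0001
        r, h = _kinetics_of(tr, td)
        return [r - rise_ms, h - half_decay_ms]

    x0 = np.log([rise_ms / 2.2, half_decay_ms / np.log(2)])
    sol = fsolve(resid, x0, full_output=False, xtol=1e-10)
    tau_r, tau_d = np.exp(sol)
    r, h = _kinetics_of(tau_r, tau_d)
    if abs(r - rise_ms) > 1e-3 * rise_ms or abs(h - half_decay_ms) > 1e-3 * half_decay_ms:
        raise ParameterError("template solver failed to match rise/half-decay")
    return float(tau_r), float(tau_d)


def epsc_template(
    t_s: np.ndarray,
    amplitude_pA: float = 40.0,
    rise_ms: float = 2.0,
    half_decay_ms: float = 7.0,
    onset_s: float = 0.0,
) -> np.ndarray:
    """Inward (negative) unitary-EPSC waveform sampled at times ``t_s``."""
    tau_r, tau_d = epsc_template_taus(rise_ms, half_decay_ms)
    tms = (np.asarray(t_s) - onset_s) * 1000.0
    w = _diffexp(tms, tau_r, tau_d)
    tp = _peak_time(tau_r, tau_d)
    peak = _diffexp(np.array([tp]), tau_r, tau_d)[0]
    return -amplitude_pA * w / peak


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _boxcar(x: np.ndarray, fs: float, width_ms: float = 0.5) -> np.ndarray:
    """Light boxcar smoothing used only for peak localization/measurement;
    keeps the peak estimate from riding single noise samples."""
    n = max(int(round(width_ms / 1000.0 * fs)), 1)
    if n <= 1:
        return x
    return np.convolve(x, np.ones(n) / n, mode="same")


def detect_epsc(
    sweep: Sweep,
    search_window_ms: float = 100.0,
    thresh_k: float = 3.0,
    sustain_ms: float = 1.0,
    baseline_ms: float = 20.0,
) -> EpscEvent:
    """Detect an evoked EPSC in one sweep.

    Baseline mean and noise SD come from the ``baseline_ms`` before light
    onset.  The onset is the first post-light sample whose inward deviation
    exceeds ``thresh_k`` x SD and stays beyond threshold for at least
    ``sustain_ms``; the amplitude is the magnitude of the extremum relative
    to baseline within the search window.
    """
    trial = sweep.trial
    fs = trial.fs
    t_on = sweep.light_onset_s
    if t_on - baseline_ms / 1000.0 < trial.t0 - 1e-12:
        raise ParameterError("baseline window unavailable before light onset")
    base_sl = trial.index_window(t_on - baseline_ms / 1000.0, t_on)
    base = trial.samples[base_sl]
    base_mean = float(base.mean())
    sd = float(base.std())
    inward = -(trial.samples - base_mean)

    i_on = int(np.ceil((t_on - trial.t0) * fs - 1e-9))
    i_end = min(int(np.ceil((t_on + search_window_ms / 1000.0 - trial.t0) * fs)), inward.size)
    n_sustain = max(int(round(sustain_ms / 1000.0 * fs)), 1)
    thresh = max(thresh_k * sd, 1e-12)

    seg = inward[i_on:i_end]
    above = seg > thresh
    onset_idx = None
    # candidate onsets: rising edges of the threshold mask with a sustained run
    edges = np.flatnonzero(above & ~np.r_[False, above[:-1]])
    for e in edges:
        if e + n_sustain <= seg.size and np.all(seg[e : e + n_sustain] > thresh):
            onset_idx = i_on + e
            break
    if onset_idx is None:
        return EpscEvent(present=False)

    smoothed = _boxcar(inward, fs)
    peak_idx = onset_idx + int(np.argmax(smoothed[onset_idx:i_end]))
    onset_s = trial.t0 + onset_idx / fs
    return EpscEvent(
        present=True,
        amplitude_pA=float(smoothed[peak_idx]),
        onset_s=onset_s,
        latency_ms=(onset_s - t_on) * 1000.0,
        peak_time_s=trial.t0 + peak_idx / fs,
    )


# ---------------------------------------------------------------------------
# Staircase segmentation
# ---------------------------------------------------------------------------

def staircase_segment(
    session: StaircaseSession,
    events: list[EpscEvent],
    success_rate_min: float = 0.5,
    doubling_factor: float = 1.5,
) -> StaircaseSegmentation:
    """Segment the intensity staircase into failure/unitary/doubled regimes.

    Per intensity the success rate and the median success amplitude are
    computed.  The recruitment threshold is the lowest intensity whose
    success rate reaches ``success_rate_min``; scanning upward from there,
    the doubling intensity is the first whose median amplitude reaches
    ``doubling_factor`` x the running plateau median.
    """
    if len(events) != len(session.sweeps):
        raise ParameterError("one event per sweep required")
    intensities = session.intensities
    if intensities.size < 3:
        raise ParameterError("need >= 3 distinct intensities")

    per = {}
    for inten in intensities:
        evs = [
            ev
            for ev, sw in zip(events, session.sweeps)
            if sw.light_intensity_mW_mm2 == inten
        ]
        amps = [ev.amplitude_pA for ev in evs if ev.present]
        per[float(inten)] = {
            "success_rate": len(amps) / len(evs),
            "median_amp": float(np.median(amps)) if amps else None,
            "n": len(evs),
        }

    threshold = None
    for inten in intensities:
        if per[float(inten)]["success_rate"] >= success_rate_min:
            threshold = float(inten)
            break
    if threshold is None:
        return StaircaseSegmentation(None, None, None, None, per)

    plateau_pool: list[float] = []
    doubling = None
    for inten in intensities[intensities >= threshold]:
        info = per[float(inten)]
        if info["median_amp"] is None:
            continue
        if plateau_pool:
            running = float(np.median(plateau_pool))
            if info["median_amp"] >= doubling_factor * running:
                doubling = float(inten)
                break
        amps = [
            ev.amplitude_pA
            for ev, sw in zip(events, session.sweeps)
            if sw.light_intensity_mW_mm2 == inten and ev.present
        ]
        plateau_pool.extend(amps)
    plateau_amp = float(np.median(plateau_pool)) if plateau_pool else None
    return StaircaseSegmentation(
        threshold_intensity=threshold,
        doubling_intensity=doubling,
        unitary_range=(threshold, doubling),
        plateau_amp_pA=plateau_amp,
        per_intensity=per,
    )


# ---------------------------------------------------------------------------
# Mean unitary EPSC
# ---------------------------------------------------------------------------

def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float:
    """Linearly interpolated time where y crosses ``level``."""
    if rising:
        idx = np.flatnonzero((y[:-1] < level) & (y[1:] >= level))
    else:
        idx = np.flatnonzero((y[:-1] >= level) & (y[1:] < level))
    if idx.size == 0:
        raise DataError("no crossing found")
    i = idx[0]
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return t[i] + frac * (t[i + 1] - t[i])


def mean_uepsc(
    session: StaircaseSession,
    events: list[EpscEvent],
    segmentation: StaircaseSegmentation,
    min_successes: int = 8,
    pre_peak_ms: float = 10.0,
    post_peak_ms: float = 40.0,
    failure_rate_max: float = 0.10,
    stability_span_mW_mm2: float = 0.005,
    stability_tol: float = 0.30,
    shape_corr_min: float = 0.8,
) -> UnitaryEpsc:
    """Average peak-aligned successes at the mid-range intensity and measure
    unitary-EPSC kinetics on the mean trace.

    The data-collection intensity is the available intensity closest to the
    midpoint of the unitary range.  QC flags (not errors) mark sessions
    with a failure rate above 10% at that intensity, unstable amplitude
    across a span of intensities around it, or unstable EPSC shape.
    """
    if segmentation.unitary_range is None:
        raise ParameterError("no unitary regime in this session")
    lo, hi = segmentation.unitary_range
    intensities = session.intensities
    if hi is None:
        in_range = intensities[intensities >= lo]
        midpoint = float(np.median(in_range))
    else:
        in_range = intensities[(intensities >= lo) & (intensities < hi)]
        midpoint = (lo + hi) / 2.0
    if in_range.size == 0:
        raise ParameterError("no sampled intensity inside the unitary range")
    by_distance = sorted(in_range, key=lambda i: abs(i - midpoint))
    chosen = float(by_distance[0])

    # collect unitary-sized successes near the midpoint, widening to the
    # next-closest in-range intensity only if the chosen one cannot supply
    # enough sweeps (e.g. chance multi-axon contamination)
    gate = (
        1.5 * segmentation.plateau_amp_pA if segmentation.plateau_amp_pA else np.inf
    )
    successes: list = []
    for inten in by_distance:
        pairs = [
            (ev, sw)
            for ev, sw in zip(events, session.sweeps)
            if sw.light_intensity_mW_mm2 == inten
        ]
        successes.extend(
            (ev, sw) for ev, sw in pairs if ev.present and ev.amplitude_pA <= gate
        )
        if len(successes) >= min_successes:
            break
    if len(successes) < min_successes:
        raise ParameterError(
            f"only {len(successes)} unitary-sized successful sweeps near the "
            f"midpoint intensity; need >= {min_successes}"
        )
    successes = successes[:12]  # ~8-12 trials enter the average

    qc: dict = {}
    chosen_pairs = [
        (ev, sw)
        for ev, sw in zip(events, session.sweeps)
        if sw.light_intensity_mW_mm2 == chosen
    ]
    failure_rate = 1 - sum(ev.present for ev, _ in chosen_pairs) / len(chosen_pairs)
    if failure_rate > failure_rate_max:
        qc["high_failure_rate"] = failure_rate

    # amplitude stability across neighboring in-range intensities
    span_amps = []
    for inten in in_range:
        if abs(inten - chosen) <= stability_span_mW_mm2:
            info = segmentation.per_intensity.get(float(inten))
            if info and info["median_amp"] is not None:
                span_amps.append(info["median_amp"])
    if span_amps:
        center = float(np.median(span_amps))
        if center > 0 and (max(span_amps) - min(span_amps)) / center > stability_tol:
            qc["amplitude_unstable"] = True

    # peak-aligned average; extract with margin so a realignment pass can
    # shift snippets by up to +/-2 ms
    fs = successes[0][1].trial.fs
    n_pre = int(round(pre_peak_ms / 1000.0 * fs))
    n_post = int(round(post_peak_ms / 1000.0 * fs))
    margin = int(round(0.002 * fs))
    raw = []
    for ev, sw in successes:
        tr = sw.trial
        p = int(round((ev.peak_time_s - tr.t0) * fs))
        base_sl = tr.index_window(sw.light_onset_s - 0.020, sw.light_onset_s)
        base_mean = tr.samples[base_sl].mean()
        lo_i, hi_i = p - n_pre - margin, p + n_post + margin + 1
        if lo_i < 0 or hi_i > tr.n_samples:
            continue
        raw.append(tr.samples[lo_i:hi_i] - base_mean)
    if len(raw) < min_successes:
        raise ParameterError("too few full-length snippets for averaging")
    raw = np.array(raw)
    core = slice(margin, margin + n_pre + n_post + 1)
    mean_trace = raw[:, core].mean(axis=0)

    # one cross-correlation refinement of the peak alignment: noise jitters
    # single-sweep peak estimates, which would smear the mean-trace rise
    shifts = []
    for row in raw:
        scores = [
            float(np.dot(row[core.start + s : core.stop + s], mean_trace))
            for s in range(-margin, margin + 1)
        ]
        shifts.append(int(np.argmax(scores)) - margin)
    snippets = np.array(
        [row[core.start + s : core.stop + s] for row, s in zip(raw, shifts)]
    )
    mean_trace = snippets.mean(axis=0)

    # shape stability: correlation of each sweep with the mean
    corrs = [
        float(np.corrcoef(s, mean_trace)[0, 1]) for s in snippets
    ]
    if min(corrs) < shape_corr_min:
        qc["shape_unstable"] = min(corrs)

    inward = _boxcar(-mean_trace, fs)
    t_ms = (np.arange(mean_trace.size) - n_pre) / fs * 1000.0
    peak_i = int(np.argmax(inward))
    amp = float(inward[peak_i])
    rise = _interp_crossing(
        t_ms[: peak_i + 1], inward[: peak_i + 1], 0.9 * amp, rising=True
    ) - _interp_crossing(t_ms[: peak_i + 1], inward[: peak_i + 1], 0.1 * amp, rising=True)
    half_decay = _interp_crossing(
        t_ms[peak_i:], inward[peak_i:], 0.5 * amp, rising=False
    ) - t_ms[peak_i]

    latencies = [ev.latency_ms for ev, _ in successes]
    return UnitaryEpsc(
        mean_trace=mean_trace,
        fs=fs,
        amplitude_pA=amp,
        rise_ms=float(rise),
        half_decay_ms=float(half_decay),
        latency_mean_ms=float(np.mean(latencies)),
        latency_sd_ms=float(np.std(latencies, ddof=1)),
        n_trials=len(snippets),
        chosen_intensity=chosen,
        unitary_intensity_range=(lo, hi),
        doubling_intensity=segmentation.doubling_intensity,
        qc=qc,
    )
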
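"""Spike detection, two-unit sorting, and peristimulus time histograms.

Spikes are found on intracellular voltage traces by thresholding the first
and second temporal derivatives of Vm: a candidate requires the first
derivative to exceed ``d1_thresh_k`` robust standard deviations *and* the
second derivative within +/-1 ms to dip below ``-d2_thresh_k`` robust SDs
(the sharp downward curvature at the spike peak).  Robust SD is
1.4826 x MAD of the derivative over the whole trial, so the detector is
invariant to adding a constant to Vm and its thresholds are scale-free.
Spike time is the local Vm maximum within 2 ms after the slope crossing; a
2 ms absolute refractory period is enforced, keeping the larger-slope event.

Firing rates are summarized as overlapping-bin PSTHs: spike counts in 50 ms
bins stepped by 25 ms, converted to Hz, averaged across trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import DataError, ParameterError
from .io import TimeSeriesTrial

REFRACTORY_S = 0.002


@dataclass
class SpikeTrain:
    """Detected (or ground-truth) event times for one trial.

    ``spike_times_s`` is strictly increasing; for a single unit successive
    times are at least one refractory period (2 ms) apart.  ``qc`` carries
    detector quality flags (e.g. ``clipped``) rather than raising.
    """

    trial_id: str
    spike_times_s: np.ndarray
    unit_label: str | None = None
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.spike_times_s.size > 1 and not np.all(np.diff(self.spike_times_s) > 0):
            raise DataError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.spike_times_s.size

    def count_in(self, start: float, end: float) -> int:
        """Spike count in the half-open window [start, end)."""
        t = self.spike_times_s
        return int(np.searchsorted(t, end - 1e-12) - np.searchsorted(t, start - 1e-12))


@dataclass
class PSTH:
    """Overlapping-bin trial-averaged firing-rate estimate."""

    bin_start_s: np.ndarray
    bin_width_s: float
    step_s: float
    rate_hz: np.ndarray
    n_trials: int

    @property
    def bin_center_s(self) -> np.ndarray:
        return self.bin_start_s + self.bin_width_s / 2


def robust_sd(x: np.ndarray) -> float:
    """1.4826 x median absolute deviation; Gaussian-consistent, outlier-proof."""
    x = np.asarray(x, dtype=float)
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _clipped_flag(v: np.ndarray, min_run: int = 5) -> bool:
    """True if the trace sits at its global extremum for >= min_run samples."""
    for extremum in (v.max(), v.min()):
        at = np.flatnonzero(v == extremum)
        if at.size >= min_run:
            # look for a consecutive run
            runs = np.split(at, np.flatnonzero(np.diff(at) > 1) + 1)
            if max(len(r) for r in runs) >= min_run:
                return True
    return False


def detect_spikes(
    trial: TimeSeriesTrial,
    d1_thresh_k: float = 5.0,
    d2_thresh_k: float = 3.0,
    refractory_s: float = REFRACTORY_S,
) -> SpikeTrain:
    """Derivative-threshold spike detection on an intracellular voltage trace.

    Parameters
    ----------
    trial : TimeSeriesTrial
        Must hold a voltage signal sampled at >= 5 kHz.
    d1_thresh_k, d2_thresh_k : float
        Thresholds in robust-SD units of dV/dt and d2V/dt2.
    refractory_s : float
        Minimum inter-spike interval; on violation the event with the larger
        peak slope wins.
    """
    if trial.signal_kind != "voltage_mV":
        raise ParameterError("detect_spikes requires a voltage_mV trial")
    if trial.fs < 5000:
        raise ParameterError(f"sampling rate {trial.fs} Hz too low (need >= 5 kHz)")
    v = trial.samples
    fs = trial.fs
    d1 = np.gradient(v) * fs
    d2 = np.gradient(d1) * fs
    # noiseless traces are flat almost everywhere, giving MAD = 0; fall back
    # to the plain SD (spike-dominated, still a usable scale) in that case
    sd1 = robust_sd(d1) or float(np.std(d1))
    sd2 = robust_sd(d2) or float(np.std(d2))
    if sd1 == 0 or sd2 == 0:
        # truly featureless (constant/linear) trace: no spikes by construction
        return SpikeTrain(trial.trial_id, np.empty(0))

    above = d1 > d1_thresh_k * sd1
    # rising-edge indices of the threshold-crossing mask
    crossings = np.flatnonzero(above & ~np.r_[False, above[:-1]])

    one_ms = max(int(round(0.001 * fs)), 1)
    two_ms = max(int(round(0.002 * fs)), 1)
    n = v.size
    candidates = []  # (time_index, peak_slope)
    for i in crossings:
        lo, hi = max(i - one_ms, 0), min(i + one_ms + 1, n)
        if d2[lo:hi].min() > -d2_thresh_k * sd2:
            continue
        seg = v[i : min(i + two_ms + 1, n)]
        peak = i + int(np.argmax(seg))
        slope = d1[i : min(i + two_ms + 1, n)].max()
        candidates.append((peak, slope))

    # dedupe candidates mapping to the same peak, then enforce refractory
    best: dict[int, float] = {}
    for peak, slope in candidates:
        if peak not in best or slope > best[peak]:
            best[peak] = slope
    kept: list[tuple[int, float]] = []
    ref_n = int(round(refractory_s * fs))
    for peak in sorted(best):
        slope = best[peak]
        if kept and peak - kept[-1][0] < ref_n:
            if slope > kept[-1][1]:
                kept[-1] = (peak, slope)
        else:
            kept.append((peak, slope))

    times = trial.t0 + np.array([p for p, _ in kept], dtype=float) / fs
    qc = {}
    if _clipped_flag(v):
        qc["clipped"] = True
    return SpikeTrain(trial.trial_id, times, qc=qc)


def detect_events_extracellular(
    trial: TimeSeriesTrial,
    thresh_k: float = 4.0,
    min_separation_s: float = 0.001,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold-crossing event detection on an extracellular trace.

    Returns (event times, peak amplitudes) for positive-going events
    exceeding ``thresh_k`` robust SDs.  The minimum peak separation is half
    the single-unit refractory period: events from *different* units may
    fall closer than one unit's refractory.  Amplitudes feed
    :func:`sort_two_units`.
    """
    from scipy.signal import find_peaks

    v = trial.samples
    sd = robust_sd(v) or float(np.std(v))
    if sd == 0:
        return np.empty(0), np.empty(0)
    distance = max(int(round(min_separation_s * trial.fs)), 1)
    idx, props = find_peaks(v, height=thresh_k * sd, distance=distance)
    return trial.t0 + idx / trial.fs, props["peak_heights"]


@dataclass
class TwoUnitSort:
    """Result of the 1-D two-class amplitude split."""

    train_a: SpikeTrain
    train_b: SpikeTrain
    separable: bool
    silhouette: float


def sort_two_units(
    times: np.ndarray,
    amplitudes: np.ndarray,
    trial_id: str = "",
    min_silhouette: float = 0.5,
) -> TwoUnitSort:
    """Split extracellular events into two units by peak amplitude.

    1-D k-means with k=2, deterministically initialized at the amplitude
    minimum and maximum; the larger-amplitude class is unit A.  A silhouette
    below ``min_silhouette`` marks the split as not separable.
    """
    times = np.asarray(times, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if times.size < 2:
        raise ParameterError("need at least 2 events to sort two units")
    x = amplitudes.reshape(-1, 1)
    if np.ptp(amplitudes) == 0:
        labels = np.zeros(times.size, dtype=int)
        sil = 0.0
    else:
        km = KMeans(
            n_clusters=2,
            init=np.array([[amplitudes.min()], [amplitudes.max()]]),
            n_init=1,
        ).fit(x)
        labels = km.labels_
        if len(set(labels)) < 2:
            sil = 0.0
        else:
            sil = float(silhouette_score(x, labels))
    separable = sil >= min_silhouette
    if len(set(labels)) == 2:
        mean0 = amplitudes[labels == 0].mean()
        mean1 = amplitudes[labels == 1].mean()
        a_label = 0 if mean0 > mean1 else 1
    else:
        a_label = labels[0]
    mask_a = labels == a_label
    qc = {} if separable else {"units_not_separable": True}
    return TwoUnitSort(
        train_a=SpikeTrain(trial_id, times[mask_a], unit_label="A", qc=dict(qc)),
        train_b=SpikeTrain(trial_id, times[~mask_a], unit_label="B", qc=dict(qc)),
        separable=separable,
        silhouette=sil,
    )


def compute_psth(
    trains: Sequence[SpikeTrain],
    t_start: float,
    t_end: float,
    bin_width_s: float = 0.050,
    step_s: float = 0.025,
) -> PSTH:
    """Trial-averaged firing rate in overlapping bins.

    Bins start at ``t_start + i * step_s`` for every i with
    ``start + bin_width <= t_end`` (half-open bins).  Per-bin rate is the
    mean over trials of (count in bin) / bin_width.

    Raises
    ------
    DataError
        If any spike falls outside [t_start, t_end).
    """
    if len(trains) == 0:
        raise ParameterError("compute_psth needs at least one spike train")
    n_bins = int(np.floor((t_end - t_start - bin_width_s) / step_s + 1e-9)) + 1
    if n_bins < 1:
        raise ParameterError("record shorter than one bin")
    starts = t_start + step_s * np.arange(n_bins)
    rates = np.zeros(n_bins)
    for train in trains:
        t = train.spike_times_s
        if t.size and (t.min() < t_start - 1e-12 or t.max() >= t_end + 1e-12):
            raise DataError("spike time outside the PSTH record")
        lo = np.searchsorted(t, starts - 1e-12)
        hi = np.searchsorted(t, starts + bin_width_s - 1e-12)
        rates += (hi - lo) / bin_width_s
    rates /= len(trains)
    return PSTH(
        bin_start_s=starts,
        bin_width_s=bin_width_s,
        step_s=step_s,
        rate_hz=rates,
        n_trials=len(trains),
    )


def spontaneous_rate(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Mean firing rate (Hz) in a half-open window, typically the 5 s before
    stimulus onset."""
    start, end = window
    if not end > start:
        raise ParameterError(f"empty window [{start}, {end})")
    return train.count_in(start, end) / (end - start)
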
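"""Per-cell scalar response metrics from trials and spike trains.

The figure-level quantities: baseline-subtracted evoked firing rate and mean
depolarization in the onset window (500 ms after nominal stimulus onset;
1000 ms for VA6-style protracted responders), post-stimulus
hyperpolarization over 2.5 s after offset, the coefficient of variation of
the membrane potential over the 5 s before onset, control-group
normalization, input-resistance quality control, and f-I curves from current
steps or a slow triangular ramp.

Membrane-potential means are computed on spike-stripped traces: each
detected spike is replaced by linear interpolation over +/-2 ms.  All
windowed Vm metrics are invariant to adding a constant to the trace (except
the CV, whose denominator is |mean Vm|).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .io import MeasurementTable, TimeSeriesTrial
from .spikes import PSTH, SpikeTrain, compute_psth


@dataclass
class ResponseWindows:
    """Analysis-window durations in seconds, anchored to the nominal
    stimulus command times."""

    onset_window_s: float = 0.5  # 1.0 for VA6-style protracted responses
    baseline_window_s: float = 0.5
    ahp_window_s: float = 2.5
    cv_window_s: float = 5.0

    def __post_init__(self) -> None:
        for name in ("onset_window_s", "baseline_window_s", "ahp_window_s", "cv_window_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")


@dataclass
class FiCurve:
    """Firing rate versus injected current, from steps or a triangular ramp."""

    current_pA: np.ndarray
    rate_hz: np.ndarray
    protocol: str  # "steps_5pA" | "ramp_4p5pA_per_s"
    limb: np.ndarray | None = None  # "ascent"/"descent" per bin for ramps

    def rheobase(self) -> float | None:
        """Lowest current that elicits any firing (None if silent)."""
        firing = np.flatnonzero(self.rate_hz > 0)
        if firing.size == 0:
            return None
        return float(self.current_pA[firing[0]])


@dataclass
class RinQC:
    """Input-resistance drift check over a recording."""

    passed: bool
    max_drift_fraction: float
    available: bool = True


def strip_spikes(
    trial: TimeSeriesTrial,
    spike_train: SpikeTrain | None,
    half_width_s: float = 0.002,
) -> tuple[np.ndarray, np.ndarray]:
    """Replace +/-2 ms around each spike by linear interpolation.

    Returns (stripped trace, boolean mask of replaced samples).
    """
    v = trial.samples.astype(float).copy()
    replaced = np.zeros(v.size, dtype=bool)
    if spike_train is None or spike_train.n_spikes == 0:
        return v, replaced
    fs = trial.fs
    for t in spike_train.spike_times_s:
        c = int(round((t - trial.t0) * fs))
        lo = max(c - int(round(half_width_s * fs)), 0)
        hi = min(c + int(round(half_width_s * fs)) + 1, v.size)
        if lo < hi:
            replaced[lo:hi] = True
    if replaced.all():
        raise DataError("every sample falls inside a spike window")
    idx = np.arange(v.size)
    v[replaced] = np.interp(idx[replaced], idx[~replaced], v[~replaced])
    return v, replaced


def _window_rate(train: SpikeTrain, start: float, end: float) -> float:
    return train.count_in(start, end) / (end - start)


def evoked_rate(
    train: SpikeTrain,
    trial: TimeSeriesTrial,
    windows: ResponseWindows | None = None,
) -> float:
    """Baseline-subtracted evoked firing rate (Hz) for one trial:
    rate in the onset window minus rate in the preceding baseline window."""
    windows = windows or ResponseWindows()
    on = trial.stim_on
    _check_window(trial, on - windows.baseline_window_s, on + windows.onset_window_s)
    return _window_rate(train, on, on + windows.onset_window_s) - _window_rate(
        train, on - windows.baseline_window_s, on
    )


def _check_window(trial: TimeSeriesTrial, start: float, end: float) -> None:
    if start < trial.t0 - 1e-9 or end > trial.t_end + 1e-9:
        raise ParameterError(
            f"analysis window [{start}, {end}) outside record [{trial.t0}, {trial.t_end})"
        )


def mean_depolarization(
    trial: TimeSeriesTrial,
    spike_train: SpikeTrain | None = None,
    windows: ResponseWindows | None = None,
) -> tuple[float, dict]:
    """Mean odor-evoked depolarization (mV) for one trial.

    Spike-stripped mean Vm in the onset window minus the mean in the
    preceding baseline window.  Returns (value, qc); qc flags windows with
    more than half their samples stripped.
    """
    windows = windows or ResponseWindows()
    on = trial.stim_on
    _check_window(trial, on - windows.baseline_window_s, on + windows.onset_window_s)
    v, replaced = strip_spikes(trial, spike_train)
    sl_on = trial.index_window(on, on + windows.onset_window_s)
    sl_base = trial.index_window(on - windows.baseline_window_s, on)
    qc = {}
    for name, sl in (("onset", sl_on), ("baseline", sl_base)):
        frac = float(replaced[sl].mean())
        if frac > 0.5:
            qc[f"{name}_mostly_stripped"] = frac
    return float(v[sl_on].mean() - v[sl_base].mean()), qc


def post_stim_hyperpolarization(
    trial: TimeSeriesTrial,
    spike_train: SpikeTrain | None = None,
    windows: ResponseWindows | None = None,
) -> float:
    """Post-stimulus hyperpolarization (mV; positive = hyperpolarized):
    baseline mean Vm minus the mean over the 2.5 s after stimulus offset."""
    windows = windows or ResponseWindows()
    off = trial.stim_off
    if off + windows.ahp_window_s > trial.t_end + 1e-9:
        raise ParameterError("record does not extend far enough past stimulus offset")
    _check_window(trial, trial.stim_on - windows.baseline_window_s, off + windows.ahp_window_s)
    v, _ = strip_spikes(trial, spike_train)
    sl_base = trial.index_window(trial.stim_on - windows.baseline_window_s, trial.stim_on)
    sl_post = trial.index_window(off, off + windows.ahp_window_s)
    return float(v[sl_base].mean() - v[sl_post].mean())


def vm_cv(
    trial: TimeSeriesTrial,
    spike_train: SpikeTrain | None = None,
    windows: ResponseWindows | None = None,
    min_abs_mean_mV: float = 1.0,
) -> tuple[float, dict]:
    """Coefficient of variation of the membrane potential over the pre-stimulus
    window: SD(Vm) / |mean(Vm)| on the spike-stripped trace.

    Returns (cv, qc); qc flags an undefined CV when |mean| is below
    ``min_abs_mean_mV``.
    """
    windows = windows or ResponseWindows()
    start = trial.stim_on - windows.cv_window_s
    _check_window(trial, start, trial.stim_on)
    v, _ = strip_spikes(trial, spike_train)
    seg = v[trial.index_window(start, trial.stim_on)]
    mean = float(seg.mean())
    if abs(mean) < min_abs_mean_mV:
        return float("nan"), {"undefined_mean_near_zero": mean}
    return float(seg.std() / abs(mean)), {}


def trial_mean(values: Sequence[float]) -> float:
    """Per-cell aggregate: the mean across a cell's trials."""
    if len(values) == 0:
        raise ParameterError("no trials to average")
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Control normalization
# ---------------------------------------------------------------------------

def normalize_to_control(
    table: MeasurementTable,
    metric_name: str,
    eps: float = 0.5,
    pooled_stimulus_id: str = "pooled",
) -> MeasurementTable:
    """Normalize a metric to the solvent-group mean within each stimulus.

    Every value is divided by the mean of the solvent-exposed cells for the
    same stimulus, making the solvent per-stimulus normalized mean exactly
    one.  A pooled per-cell mean across stimuli is appended under
    ``pooled_stimulus_id``.  Stimuli whose solvent mean has magnitude below
    ``eps`` are excluded from normalization and pooling (recorded in the
    result's ``excluded_stimuli`` DataFrame attribute).
    """
    df = table.df[table.df["metric_name"] == metric_name].copy()
    if len(df) == 0:
        raise ParameterError(f"no rows with metric {metric_name!r}")
    norm_metric = metric_name + "_norm"
    out_rows = []
    excluded = []
    for stim, sub in df.groupby("stimulus_id", sort=False):
        solvent = sub[sub["exposure_group"] == "solvent"]
        if len(solvent) == 0:
            raise ParameterError(f"stimulus {stim!r} has no solvent-group cell")
        denom = solvent["value"].mean()
        if abs(denom) < eps:
            excluded.append(str(stim))
            continue
        sub = sub.copy()
        sub["value"] = sub["value"] / denom
        sub["metric_name"] = norm_metric
        out_rows.append(sub)
    if not out_rows:
        raise DataError("all stimuli excluded: solvent means below epsilon")
    norm = pd.concat(out_rows, ignore_index=True)
    pooled = (
        norm.groupby(["fly_id", "cell_id", "glomerulus", "exposure_group"], sort=False)[
            "value"
        ]
        .mean()
        .reset_index()
    )
    pooled["stimulus_id"] = pooled_stimulus_id
    pooled["metric_name"] = norm_metric
    result = MeasurementTable(pd.concat([norm, pooled], ignore_index=True))
    result.df.attrs["excluded_stimuli"] = excluded
    return result


# ---------------------------------------------------------------------------
# Input-resistance QC
# ---------------------------------------------------------------------------

def input_resistance_from_test_pulse(
    trial: TimeSeriesTrial,
    amplitude_pA: float,
    window: tuple[float, float],
    settle_s: float = 0.05,
) -> float:
    """Rin (MOhm) from the steady-state voltage deflection of a test pulse."""
    w0, w1 = window
    _check_window(trial, w0 - 0.1, w1)
    base = trial.samples[trial.index_window(w0 - 0.1, w0)].mean()
    steady = trial.samples[trial.index_window(w0 + settle_s, w1)].mean()
    return float((steady - base) / amplitude_pA * 1000.0)  # mV/pA -> MOhm


def input_resistance_qc(
    rin_mohm: Sequence[float], max_drift: float = 0.20
) -> RinQC:
    """Fail when any trial's Rin deviates from the first trial's by > 20%."""
    rin = np.asarray(rin_mohm, dtype=float)
    if rin.size < 2:
        raise ParameterError("need >= 2 Rin measurements")
    if rin[0] == 0 or not np.all(np.isfinite(rin)):
        return RinQC(passed=False, max_drift_fraction=float("nan"), available=False)
    drift = np.abs(rin - rin[0]) / abs(rin[0])
    return RinQC(passed=bool(drift.max() <= max_drift), max_drift_fraction=float(drift.max()))


# ---------------------------------------------------------------------------
# f-I curves
# ---------------------------------------------------------------------------

def fi_from_steps(
    step_trials: Sequence[tuple[TimeSeriesTrial, SpikeTrain]],
) -> FiCurve:
    """f-I curve from 1 s current steps (5 pA increments).

    Each trial's stimulus window is the step; its metadata carries
    ``step_pA``.  Rate = spike count in the step / step duration.
    """
    if len(step_trials) == 0:
        raise ParameterError("no step trials")
    durations = {round(tr.stim_off - tr.stim_on, 9) for tr, _ in step_trials}
    if len(durations) > 1:
        raise DataError(f"unequal step durations: {sorted(durations)}")
    rows = []
    for trial, train in step_trials:
        if "step_pA" not in trial.meta:
            raise DataError(f"trial {trial.trial_id!r} lacks step_pA metadata")
        dur = trial.stim_off - trial.stim_on
        rows.append((float(trial.meta["step_pA"]), train.count_in(trial.stim_on, trial.stim_off) / dur))
    rows.sort()
    cur, rate = map(np.asarray, zip(*rows))
    return FiCurve(current_pA=cur, rate_hz=rate, protocol="steps_5pA")


def fi_from_ramp(
    trial: TimeSeriesTrial,
    train: SpikeTrain,
    ramp_slope_pA_per_s: float = 4.5,
    i0_pA: float = 0.0,
    bin_width_s: float = 0.050,
    step_s: float = 0.025,
) -> FiCurve:
    """f-I curve from a slow triangular current ramp.

    The stimulus window is the full triangle (ascent to the apex at its
    midpoint, mirrored descent).  Firing rate comes from the overlapping-bin
    PSTH (50/25 ms); each bin is paired with the injected current at its
    center, I(t) = I0 + slope * (t - on) on the ascent and the mirror on the
    descent.
    """
    if "ramp_slope_pA_per_s" in trial.meta and not np.isclose(
        float(trial.meta["ramp_slope_pA_per_s"]), ramp_slope_pA_per_s
    ):
        raise DataError("ramp slope mismatch with trial metadata")
    psth: PSTH = compute_psth(
        [train], trial.stim_on, trial.stim_off, bin_width_s=bin_width_s, step_s=step_s
    )
    centers = psth.bin_center_s
    apex = (trial.stim_on + trial.stim_off) / 2.0
    ascent = centers <= apex
    current = np.where(
        ascent,
        i0_pA + ramp_slope_pA_per_s * (centers - trial.stim_on),
        i0_pA + ramp_slope_pA_per_s * (apex - trial.stim_on)
        - ramp_slope_pA_per_s * (centers - apex),
    )
    limb = np.where(ascent, "ascent", "descent")
    return FiCurve(
        current_pA=current,
        rate_hz=psth.rate_hz,
        protocol="ramp_4p5pA_per_s",
        limb=limb,
    )


def current_at_time(
    t: float, trial: TimeSeriesTrial, ramp_slope_pA_per_s: float = 4.5, i0_pA: float = 0.0
) -> float:
    """Injected current at time ``t`` of a triangular ramp trial."""
    apex = (trial.stim_on + trial.stim_off) / 2.0
    if t <= apex:
        return i0_pA + ramp_slope_pA_per_s * (t - trial.stim_on)
    return i0_pA + ramp_slope_pA_per_s * (apex - trial.stim_on) - ramp_slope_pA_per_s * (t - apex)
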
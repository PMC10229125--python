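"""Shared data model and file formats.

Time-series trials are the single currency of the electrophysiology stages:
one recorded (or simulated) sweep with its sampling rate, nominal stimulus
command window, and free-form metadata.  All analysis windows downstream are
anchored to the nominal stimulus command times stored here, not to physical
odor arrival.  Per-cell scalar results are collected in a
:class:`MeasurementTable`, which feeds control-normalization and the
permutation statistics.

Two on-disk dialects are supported:

``csv_long``
    One CSV per bundle with columns ``trial_id, t_s, value`` plus a sidecar
    JSON (``<path>.meta.json``) holding ``fs``, ``stim_on``, ``stim_off``,
    ``signal_kind``, ``t0`` and the metadata map for every trial.
``hdf5_bundle``
    A single HDF5 file, one group per trial, dataset ``samples``, all scalar
    fields and metadata stored as group attributes.

Times are seconds internally; sample ``i`` of a trial sits at
``t0 + i / fs`` (0-based).  Windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError

SIGNAL_KINDS = ("voltage_mV", "current_pA", "pid_V")

#: Columns of a MeasurementTable, in stable on-disk order.
TABLE_COLUMNS = (
    "fly_id",
    "cell_id",
    "glomerulus",
    "exposure_group",
    "stimulus_id",
    "metric_name",
    "value",
)

EXPOSURE_GROUPS = ("odor", "solvent")


@dataclass
class TimeSeriesTrial:
    """One sweep of a time-varying signal with stimulus timing and metadata.

    Parameters
    ----------
    trial_id : str
        Unique identifier within a bundle.
    signal_kind : str
        One of ``voltage_mV``, ``current_pA``, ``pid_V``.
    fs : float
        Sampling rate in Hz; must be positive.
    samples : numpy.ndarray
        Ordered, finite signal values.
    t0 : float
        Time of the first sample in seconds (default 0).
    stim_on, stim_off : float
        Nominal stimulus command window in seconds; ``stim_on < stim_off``.
    meta : dict
        Free-form metadata (cell_type, glomerulus, exposure_group, odor_name,
        concentration_log10, fly_id, trial_index, light_intensity_mW_mm2, ...).
    """

    trial_id: str
    signal_kind: str
    fs: float
    samples: np.ndarray
    stim_on: float
    stim_off: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.signal_kind not in SIGNAL_KINDS:
            raise DataError(f"unknown signal_kind {self.signal_kind!r}")
        if not self.fs > 0:
            raise DataError(f"fs must be > 0, got {self.fs}")
        if not self.stim_on < self.stim_off:
            raise DataError(
                f"stim_on ({self.stim_on}) must precede stim_off ({self.stim_off})"
            )
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise DataError("samples must be a 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n / fs)."""
        return self.n_samples / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        """Per-sample time stamps in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def index_window(self, start: float, end: float) -> slice:
        """Sample slice covering the half-open time window [start, end).

        Raises
        ------
        DataError
            If the window is empty or falls outside the record.
        """
        if not start < end:
            raise DataError(f"empty window [{start}, {end})")
        if start < self.t0 - 0.5 / self.fs or end > self.t_end + 0.5 / self.fs:
            raise DataError(
                f"window [{start}, {end}) outside record "
                f"[{self.t0}, {self.t_end})"
            )
        i0 = int(np.ceil((start - self.t0) * self.fs - 1e-9))
        i1 = int(np.ceil((end - self.t0) * self.fs - 1e-9))
        return slice(max(i0, 0), min(i1, self.n_samples))


# ---------------------------------------------------------------------------
# Trial bundles
# ---------------------------------------------------------------------------

def write_trials(trials: Sequence[TimeSeriesTrial], path, dialect: str = "csv_long") -> None:
    """Write a bundle of trials in the requested dialect."""
    path = Path(path)
    if dialect == "csv_long":
        _write_trials_csv(trials, path)
    elif dialect == "hdf5_bundle":
        _write_trials_hdf5(trials, path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


def read_trials(path, dialect: str = "csv_long") -> list[TimeSeriesTrial]:
    """Read a bundle of trials; every trial satisfies the type invariants."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv_long":
        return _read_trials_csv(path)
    if dialect == "hdf5_bundle":
        return _read_trials_hdf5(path)
    raise FormatError(f"unknown dialect {dialect!r}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _write_trials_csv(trials: Sequence[TimeSeriesTrial], path: Path) -> None:
    frames = []
    sidecar = {}
    for tr in trials:
        frames.append(
            pd.DataFrame(
                {"trial_id": tr.trial_id, "t_s": tr.times(), "value": tr.samples}
            )
        )
        sidecar[tr.trial_id] = {
            "signal_kind": tr.signal_kind,
            "fs": tr.fs,
            "t0": tr.t0,
            "stim_on": tr.stim_on,
            "stim_off": tr.stim_off,
            "meta": tr.meta,
        }
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["trial_id", "t_s", "value"])
    )
    df.to_csv(path, index=False)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def _read_trials_csv(path: Path) -> list[TimeSeriesTrial]:
    df = pd.read_csv(path)
    required = {"trial_id", "t_s", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"trial CSV missing column(s): {sorted(missing)}")
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FormatError(f"missing sidecar metadata file {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    trials = []
    for trial_id, sub in df.groupby("trial_id", sort=False):
        t = sub["t_s"].to_numpy()
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise DataError(f"non-monotone time column in trial {trial_id!r}")
        info = sidecar.get(str(trial_id))
        if info is None:
            raise FormatError(f"sidecar lacks entry for trial {trial_id!r}")
        trials.append(
            TimeSeriesTrial(
                trial_id=str(trial_id),
                signal_kind=info["signal_kind"],
                fs=float(info["fs"]),
                samples=sub["value"].to_numpy(),
                t0=float(info.get("t0", 0.0)),
                stim_on=float(info["stim_on"]),
                stim_off=float(info["stim_off"]),
                meta=dict(info.get("meta", {})),
            )
        )
    return trials


def _write_trials_hdf5(trials: Sequence[TimeSeriesTrial], path: Path) -> None:
    with h5py.File(path, "w") as f:
        for tr in trials:
            g = f.create_group(tr.trial_id)
            g.create_dataset("samples", data=tr.samples)
            g.attrs["signal_kind"] = tr.signal_kind
            g.attrs["fs"] = tr.fs
            g.attrs["t0"] = tr.t0
            g.attrs["stim_on"] = tr.stim_on
            g.attrs["stim_off"] = tr.stim_off
            g.attrs["meta_json"] = json.dumps(tr.meta, sort_keys=True)


def _read_trials_hdf5(path: Path) -> list[TimeSeriesTrial]:
    trials = []
    with h5py.File(path, "r") as f:
        for trial_id in f:
            g = f[trial_id]
            if "samples" not in g:
                raise FormatError(f"group {trial_id!r} lacks a 'samples' dataset")
            trials.append(
                TimeSeriesTrial(
                    trial_id=trial_id,
                    signal_kind=str(g.attrs["signal_kind"]),
                    fs=float(g.attrs["fs"]),
                    samples=g["samples"][()],
                    t0=float(g.attrs.get("t0", 0.0)),
                    stim_on=float(g.attrs["stim_on"]),
                    stim_off=float(g.attrs["stim_off"]),
                    meta=json.loads(g.attrs.get("meta_json", "{}")),
                )
            )
    return trials


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

class MeasurementTable:
    """Per-cell scalar responses keyed by (cell, stimulus, metric).

    Thin wrapper over a pandas DataFrame with a fixed schema.  Invariants:
    one row per (cell_id, stimulus_id, metric_name); exposure_group is
    ``odor`` or ``solvent``; each cell maps to exactly one fly (one cell is
    recorded per fly).
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=list(TABLE_COLUMNS))
        missing = set(TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"measurement table missing column(s): {sorted(missing)}")
        df = df.loc[:, list(TABLE_COLUMNS)].reset_index(drop=True)
        self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if len(df) == 0:
            return
        bad_groups = set(df["exposure_group"].unique()) - set(EXPOSURE_GROUPS)
        if bad_groups:
            raise DataError(f"unknown exposure_group values: {sorted(bad_groups)}")
        key = ["cell_id", "stimulus_id", "metric_name"]
        dup = df.duplicated(subset=key)
        if dup.any():
            first = df.loc[dup, key].iloc[0].tolist()
            raise DataError(f"duplicate (cell, stimulus, metric) key: {first}")
        flies_per_cell = df.groupby("cell_id")["fly_id"].nunique()
        if (flies_per_cell > 1).any():
            cell = flies_per_cell[flies_per_cell > 1].index[0]
            raise DataError(f"cell {cell!r} maps to more than one fly")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        return self.df.equals(other.df)

    def rows(self) -> Iterator[Mapping]:
        return (row._asdict() for row in self.df.itertuples(index=False))

    @classmethod
    def from_records(cls, records: Sequence[Mapping]) -> "MeasurementTable":
        return cls(pd.DataFrame.from_records(records, columns=list(TABLE_COLUMNS)))

    def write(self, path) -> None:
        """Write as CSV with stable column order; ``read`` round-trips."""
        self.df.to_csv(path, index=False)

    @classmethod
    def read(cls, path) -> "MeasurementTable":
        df = pd.read_csv(
            path,
            dtype={c: str for c in TABLE_COLUMNS if c != "value"},
        )
        df["value"] = df["value"].astype(float)
        return cls(df)


def write_table(table: MeasurementTable, path) -> None:
    table.write(path)


def read_table(path) -> MeasurementTable:
    return MeasurementTable.read(path)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline-wide knobs; every stochastic operation takes its seed from here.

    Attributes hold the detector thresholds, analysis-window durations,
    permutation settings and file dialects used by the CLI; library functions
    accept the same values as keyword arguments.
    """

    seed: int = 0
    dialect: str = "csv_long"
    # spike detector
    d1_thresh_k: float = 5.0
    d2_thresh_k: float = 3.0
    refractory_s: float = 0.002
    # PSTH
    bin_width_s: float = 0.050
    step_s: float = 0.025
    # response windows (seconds)
    onset_window_s: float = 0.5
    baseline_window_s: float = 0.5
    ahp_window_s: float = 2.5
    cv_window_s: float = 5.0
    # statistics
    n_perm: int = 10000
    alpha: float = 0.05
    m_comparisons: int = 1
    # normalization guard
    norm_eps: float = 0.5
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config field(s): {sorted(unknown)}")
        if "seed" not in data:
            raise FormatError("config must set a seed")
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the configuration for run manifests."""
        canon = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
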
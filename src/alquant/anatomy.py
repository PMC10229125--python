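"""3-D ROI quantification of two-channel confocal stacks.

Glomerular innervation is quantified from dual-label confocal volumes: a
membrane label on the neurites of interest (anti-CD8) and a general neuropil
counterstain (nc82).  ROIs are traced on a subset of slices and interpolated
through the stack; per-glomerulus metrics are the ROI volume, the per-channel
intensity sums and means, and the CD8/nc82 intensity ratio.  Measurements are
pooled across brains by normalizing each glomerulus to the mean of the
solvent-exposed control group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import distance_transform_edt

from .errors import DataError, ParameterError

SATURATION_FRACTION = 1e-4  # 0.01% of neuropil voxels


@dataclass
class LabelVolume:
    """Two-channel confocal stack (Z x Y x X) with voxel size in micrometres."""

    cd8: np.ndarray
    nc82: np.ndarray
    voxel_size: tuple[float, float, float]  # (dz, dy, dx) um
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.cd8 = np.asarray(self.cd8)
        self.nc82 = np.asarray(self.nc82)
        if self.cd8.shape != self.nc82.shape or self.cd8.ndim != 3:
            raise DataError("channels must be two equal-shape Z x Y x X stacks")
        if np.any(self.cd8 < 0) or np.any(self.nc82 < 0):
            raise DataError("intensities must be non-negative")
        if self.bit_depth <= 0:
            raise DataError("bit depth unknown; saturation bounds undefined")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cd8.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def write_tiff(self, path) -> None:
        stack = np.stack([self.cd8, self.nc82], axis=1).astype(np.uint16)
        tifffile.imwrite(
            path,
            stack,
            metadata={"voxel_size": list(self.voxel_size), "bit_depth": self.bit_depth},
        )

    @classmethod
    def read_tiff(cls, path) -> "LabelVolume":
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        return cls(
            cd8=stack[:, 0],
            nc82=stack[:, 1],
            voxel_size=tuple(meta.get("voxel_size", (1.0, 1.0, 1.0))),
            bit_depth=int(meta.get("bit_depth", 16)),
        )


@dataclass
class RoiVolume:
    """Volumetric binary mask of one glomerulus, with tracing provenance."""

    glomerulus: str
    mask: np.ndarray
    traced_slices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise DataError(f"ROI for {self.glomerulus!r} is empty")


@dataclass
class GlomerulusStats:
    """Volume and innervation metrics of one glomerulus in one brain."""

    glomerulus: str
    volume_um3: float
    n_voxels: int
    cd8_sum: float
    nc82_sum: float
    cd8_per_voxel: float
    nc82_per_voxel: float
    ratio_cd8_nc82: float | None  # None when nc82_sum == 0


@dataclass
class SaturationQC:
    passed: bool
    frac_cd8: float
    frac_nc82: float


def saturation_qc(
    volume: LabelVolume,
    neuropil_mask: np.ndarray,
    max_fraction: float = SATURATION_FRACTION,
) -> SaturationQC:
    """Reject brains with more than 0.01% saturated neuropil voxels.

    A voxel is saturated when it sits at 0 or at the bit-depth maximum;
    the fraction is assessed per channel within the neuropil mask.
    """
    neuropil_mask = np.asarray(neuropil_mask, dtype=bool)
    if not neuropil_mask.any():
        raise ParameterError("neuropil mask is empty")
    top = 2**volume.bit_depth - 1
    fracs = []
    for chan in (volume.cd8, volume.nc82):
        vals = chan[neuropil_mask]
        fracs.append(float(np.mean((vals == 0) | (vals == top))))
    return SaturationQC(
        passed=all(f <= max_fraction for f in fracs),
        frac_cd8=fracs[0],
        frac_nc82=fracs[1],
    )


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed distance field of a 2-D mask: negative inside, positive outside."""
    if mask.all():
        return -distance_transform_edt(mask)
    if not mask.any():
        return distance_transform_edt(~mask)
    return distance_transform_edt(~mask) - distance_transform_edt(mask)


def interpolate_roi(
    traced: dict[int, np.ndarray],
    n_slices: int,
    glomerulus: str = "",
) -> RoiVolume:
    """Fill untraced slices between sparsely traced ROI outlines.

    Boundaries traced on every k-th slice are propagated to intermediate
    slices by linear interpolation of their signed distance fields,
    thresholded at zero.  Traced slices are preserved exactly; slices outside
    the traced range stay empty.
    """
    if len(traced) < 2:
        raise ParameterError("need at least 2 traced slices to interpolate")
    zs = sorted(traced)
    shape = np.asarray(traced[zs[0]]).shape
    vol = np.zeros((n_slices, *shape), dtype=bool)
    sdfs = {}
    for z in zs:
        m = np.asarray(traced[z], dtype=bool)
        if m.shape != shape:
            raise DataError("traced slices must share one shape")
        if not m.any():
            raise DataError(f"traced mask on slice {z} is empty")
        if not (0 <= z < n_slices):
            raise DataError(f"traced slice {z} outside stack of {n_slices}")
        vol[z] = m
        sdfs[z] = _signed_distance(m)
    for z0, z1 in zip(zs[:-1], zs[1:]):
        for z in range(z0 + 1, z1):
            w = (z - z0) / (z1 - z0)
            vol[z] = ((1 - w) * sdfs[z0] + w * sdfs[z1]) <= 0
    return RoiVolume(glomerulus=glomerulus, mask=vol, traced_slices=tuple(zs))


def glomerulus_metrics(
    volume: LabelVolume,
    roi: RoiVolume,
) -> GlomerulusStats:
    """Volume, per-channel intensity sums/means, and the CD8/nc82 ratio."""
    if roi.mask.shape != volume.shape:
        raise DataError("ROI shape does not match the stack")
    n = int(roi.mask.sum())
    cd8_sum = float(volume.cd8[roi.mask].sum())
    nc82_sum = float(volume.nc82[roi.mask].sum())
    return GlomerulusStats(
        glomerulus=roi.glomerulus,
        volume_um3=n * volume.voxel_volume_um3,
        n_voxels=n,
        cd8_sum=cd8_sum,
        nc82_sum=nc82_sum,
        cd8_per_voxel=cd8_sum / n,
        nc82_per_voxel=nc82_sum / n,
        ratio_cd8_nc82=(cd8_sum / nc82_sum) if nc82_sum > 0 else None,
    )


def normalize_across_brains(
    stats: pd.DataFrame,
    control_group: str = "solvent",
    group_col: str = "exposure_group",
) -> pd.DataFrame:
    """Normalize each glomerulus/metric to the control-group mean.

    ``stats`` holds one row per (brain, glomerulus) with a ``glomerulus``
    column, the group column, and numeric metric columns.  Each metric value
    is divided by the mean of that metric for the same glomerulus across
    control brains, so the control-group normalized mean is exactly 1.
    Glomeruli without any control brain are dropped (logged via a
    ``dropped_glomeruli`` DataFrame attribute).
    """
    metric_cols = [
        c
        for c in stats.columns
        if c not in ("glomerulus", group_col) and pd.api.types.is_numeric_dtype(stats[c])
    ]
    out_rows = []
    dropped = []
    for glom, sub in stats.groupby("glomerulus", sort=False):
        ctrl = sub[sub[group_col] == control_group]
        if len(ctrl) == 0:
            dropped.append(glom)
            continue
        sub = sub.copy()
        for c in metric_cols:
            denom = ctrl[c].mean()
            sub[c] = sub[c] / denom if denom != 0 else np.nan
        out_rows.append(sub)
    out = (
        pd.concat(out_rows, ignore_index=True)
        if out_rows
        else stats.iloc[0:0].copy()
    )
    out.attrs["dropped_glomeruli"] = dropped
    return out
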
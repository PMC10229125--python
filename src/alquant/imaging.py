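"""Pixelwise dF/F quantification of calcium-imaging movies.

The response measure is the fractional fluorescence change
(F - F0) / F0 computed per pixel per frame on background-subtracted movies,
with F0 the mean over the 70 frames immediately preceding the stimulus.
Heat maps may be smoothed with a 4x4-pixel Gaussian lowpass; responses are
averaged over ROI pixels and over trials, and the peak is taken from the
frame with the maximum mean signal during the stimulus presentation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy.ndimage import convolve
from skimage.draw import polygon as draw_polygon

from .errors import DataError, ParameterError

BASELINE_FRAMES = 70


@dataclass
class Movie:
    """A T x H x W fluorescence movie with stimulus timing.

    ``stim_on_frame`` is the first frame whose acquisition interval overlaps
    the stimulus command; at least 70 baseline frames must precede it.
    ``dark_offset`` is the camera/PMT offset subtracted before any ratio is
    formed.
    """

    frames: np.ndarray
    frame_rate_hz: float
    stim_on_frame: int
    stim_len_s: float = 0.5
    dark_offset: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise DataError("movie must be T x H x W")
        if np.any(self.frames < 0):
            raise DataError("fluorescence values must be non-negative")
        t = self.frames.shape[0]
        if t < self.stim_on_frame + 1:
            raise DataError("stimulus frame beyond end of movie")
        if self.stim_on_frame < BASELINE_FRAMES:
            raise ParameterError(
                f"need >= {BASELINE_FRAMES} baseline frames before the stimulus, "
                f"got {self.stim_on_frame}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def write_tiff(self, path) -> None:
        tifffile.imwrite(
            path,
            np.clip(self.frames, 0, 65535).astype(np.uint16),
            metadata={
                "frame_rate_hz": self.frame_rate_hz,
                "stim_on_frame": self.stim_on_frame,
                "stim_len_s": self.stim_len_s,
                "dark_offset": self.dark_offset,
            },
        )

    @classmethod
    def read_tiff(
        cls,
        path,
        frame_rate_hz: float | None = None,
        stim_on_frame: int | None = None,
        stim_len_s: float | None = None,
        dark_offset: float | None = None,
    ) -> "Movie":
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        return cls(
            frames=frames,
            frame_rate_hz=float(frame_rate_hz if frame_rate_hz is not None else meta["frame_rate_hz"]),
            stim_on_frame=int(stim_on_frame if stim_on_frame is not None else meta["stim_on_frame"]),
            stim_len_s=float(stim_len_s if stim_len_s is not None else meta.get("stim_len_s", 0.5)),
            dark_offset=float(dark_offset if dark_offset is not None else meta.get("dark_offset", 0.0)),
        )


@dataclass
class RoiSet2D:
    """Named binary pixel masks over one imaging field."""

    masks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mask in self.masks.items():
            mask = np.asarray(mask, dtype=bool)
            if not mask.any():
                raise DataError(f"ROI {name!r} is empty")
            self.masks[name] = mask

    @classmethod
    def from_label_image(cls, path_or_array) -> "RoiSet2D":
        labels = (
            tifffile.imread(path_or_array)
            if not isinstance(path_or_array, np.ndarray)
            else path_or_array
        )
        return cls(
            {str(k): labels == k for k in np.unique(labels) if k != 0}
        )

    @classmethod
    def from_polygon_json(cls, path, shape: tuple[int, int]) -> "RoiSet2D":
        """Polygons as {name: [[row, col], ...]} vertex lists."""
        data = json.loads(open(path).read())
        masks = {}
        for name, verts in data.items():
            verts = np.asarray(verts, dtype=float)
            rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape)
            mask = np.zeros(shape, dtype=bool)
            mask[rr, cc] = True
            masks[name] = mask
        return cls(masks)


def compute_dff(movie: Movie, f0_eps: float = 1e-6) -> np.ndarray:
    """Per-pixel dF/F relative to the pre-stimulus baseline.

    F' = F - dark_offset; F0 = mean of F' over the 70 frames preceding
    ``stim_on_frame``; dF/F = (F' - F0) / F0.  Pixels whose F0 does not
    exceed ``f0_eps`` are masked (NaN) and propagate as missing, never as
    zeros.  Invariant to a common gain applied to F' (offset-corrected
    fluorescence).
    """
    f = movie.frames - movie.dark_offset
    b0 = movie.stim_on_frame - BASELINE_FRAMES
    f0 = f[b0 : movie.stim_on_frame].mean(axis=0)
    if np.any(f0 < -f0_eps):
        raise DataError("dark_offset exceeds the baseline fluorescence")
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (f - f0[None]) / f0[None]
    dff[:, f0 <= f0_eps] = np.nan
    return dff


def gaussian_kernel_4x4(sigma: float = 1.0) -> np.ndarray:
    """4x4 Gaussian lowpass kernel, sum 1.

    An even-sized kernel has no central pixel; the grid is offset by half a
    pixel, sampling the Gaussian at {-1.5, -0.5, +0.5, +1.5} in each axis.
    """
    g = np.exp(-np.array([-1.5, -0.5, 0.5, 1.5]) ** 2 / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def smooth_dff(dff: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Per-frame 4x4 Gaussian smoothing with reflective padding.

    NaN (masked) pixels propagate through the kernel footprint.
    """
    k = gaussian_kernel_4x4(sigma)
    if k.shape[0] > dff.shape[1] or k.shape[1] > dff.shape[2]:
        raise ParameterError("kernel larger than frame")
    out = np.empty_like(dff)
    for t in range(dff.shape[0]):
        out[t] = convolve(dff[t], k, mode="reflect")
    return out


def stim_frame_span(stim_on_frame: int, stim_len_s: float, frame_rate_hz: float) -> range:
    """Frames whose acquisition interval intersects the stimulus window.

    With the stimulus starting at the ``stim_on_frame`` boundary, the number
    of intersected frame intervals is ceil(stim_len_s * frame_rate); a
    500 ms stimulus at 11 Hz spans 6 frames.
    """
    n = math.ceil(stim_len_s * frame_rate_hz - 1e-9)
    return range(stim_on_frame, stim_on_frame + max(n, 1))


def roi_response(
    dff_movies: list[np.ndarray],
    roi_mask: np.ndarray,
    stim_on_frame: int,
    stim_len_s: float,
    frame_rate_hz: float,
) -> tuple[np.ndarray, float]:
    """ROI- and trial-averaged dF/F trace, and its in-stimulus peak.

    The trace is the mean over ROI pixels per frame (missing pixels
    excluded), averaged across trials; the peak is the maximum of the trace
    over the frames intersecting the stimulus window.
    """
    if len(dff_movies) == 0:
        raise ParameterError("need at least one trial")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    traces = []
    for dff in dff_movies:
        sub = dff[:, roi_mask]
        if sub.shape[1] == 0 or np.all(np.isnan(sub)):
            raise DataError("ROI does not intersect any valid pixel")
        traces.append(np.nanmean(sub, axis=1))
    trace = np.mean(traces, axis=0)
    span = stim_frame_span(stim_on_frame, stim_len_s, frame_rate_hz)
    stop = min(span.stop, trace.size)
    peak = float(np.max(trace[span.start : stop]))
    return trace, peak
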
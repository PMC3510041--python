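"""Cardiogram extraction from an M-mode.

In the M-mode the two heart walls appear as two bright traces flanking the
lumen.  The *cardiogram* is the per-frame distance between the fluorescence
maxima on either side of the heart's median position -- i.e. the
instantaneous heart diameter.  Extraction proceeds in two steps:

1. :func:`find_midline` -- the median over frames of the per-frame intensity
   centroid along the space axis.  The median makes the estimate robust to
   transient signal loss, and a single static midline matches the fixed
   reference line the method draws on the M-mode.
2. :func:`extract_cardiogram` -- per frame, smooth the spatial profile,
   locate the maximum-intensity position on each side of the midline
   (optionally with sub-pixel parabolic refinement), and take the distance
   between the two.  Frames whose wall peaks do not rise above the signal
   floor, or whose walls merge (separation below 2 px), are flagged
   ``low_signal`` and their walls linearly interpolated from neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .stackio import MMode

__all__ = [
    "Cardiogram",
    "MidlineResult",
    "NoWallSignalError",
    "find_midline",
    "extract_cardiogram",
    "write_cardiogram",
    "read_cardiogram",
]

QUALITY_OK = "ok"
QUALITY_LOW = "low_signal"

#: Frames with wall separation below this are treated as wall-merge artefacts.
MIN_WALL_SEPARATION_PX = 2.0

#: Fraction of the global intensity range a wall peak must rise above the
#: per-frame background to count as signal.
SIGNAL_FLOOR_FRAC = 0.05


class NoWallSignalError(RuntimeError):
    """Raised when more than half of the frames lack a usable wall signal."""


@dataclass
class Cardiogram:
    """Per-frame heart diameter trace with wall positions and midline.

    Wall positions are in M-mode space-axis pixels (0 = top of the span,
    increasing downward); sub-pixel values are allowed.  ``diameter_um`` is
    ``diameter_px * pixel_size_um``, the reporting unit for diameters.
    """

    time_s: np.ndarray
    upper_wall_px: np.ndarray
    lower_wall_px: np.ndarray
    diameter_px: np.ndarray
    diameter_um: np.ndarray
    midline_px: float
    quality: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("upper_wall_px", "lower_wall_px", "diameter_px", "diameter_um", "quality"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != n_frames")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    @property
    def dt_s(self) -> float:
        if self.n_frames < 2:
            raise ValueError("need >= 2 frames for a frame interval")
        return float(self.time_s[1] - self.time_s[0])

    @classmethod
    def from_diameter(
        cls,
        time_s: np.ndarray,
        diameter_um: np.ndarray,
        pixel_size_um: float = 1.0,
    ) -> "Cardiogram":
        """Build a cardiogram from a bare diameter trace (walls symmetric about 0)."""
        time_s = np.asarray(time_s, dtype=float)
        diameter_um = np.asarray(diameter_um, dtype=float)
        d_px = diameter_um / pixel_size_um
        return cls(
            time_s=time_s,
            upper_wall_px=-d_px / 2,
            lower_wall_px=d_px / 2,
            diameter_px=d_px,
            diameter_um=diameter_um,
            midline_px=0.0,
            quality=np.full(len(time_s), QUALITY_OK, dtype="<U10"),
            pixel_size_um=pixel_size_um,
        )


@dataclass
class MidlineResult:
    """Midline estimate plus the per-frame centroid series for diagnostics."""

    midline_px: float
    centroid_px: np.ndarray


# ---------------------------------------------------------------------------
# Midline
# ---------------------------------------------------------------------------

def find_midline(mmode: MMode) -> MidlineResult:
    """Median over frames of the per-frame intensity centroid along space.

    Frames with zero total intensity contribute no centroid (NaN in the
    diagnostic series) and are excluded from the median.
    """
    matrix = np.asarray(mmode.matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("empty M-mode")
    totals = matrix.sum(axis=0)
    if np.all(totals == 0):
        raise ValueError("all-zero M-mode; no intensity to locate a midline")

    rows = np.arange(matrix.shape[0], dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        centroids = (rows @ matrix) / totals
    centroids[totals == 0] = np.nan
    midline = float(np.nanmedian(centroids))
    return MidlineResult(midline_px=midline, centroid_px=centroids)


# ---------------------------------------------------------------------------
# Cardiogram extraction
# ---------------------------------------------------------------------------

def _parabolic_offset(y_minus: np.ndarray, y0: np.ndarray, y_plus: np.ndarray) -> np.ndarray:
    """Sub-pixel offset of a peak from a 3-point parabola, clamped to [-0.5, 0.5]."""
    denom = y_minus - 2.0 * y0 + y_plus
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = 0.5 * (y_minus - y_plus) / denom
    delta = np.where((denom < 0) & np.isfinite(delta), delta, 0.0)
    return np.clip(delta, -0.5, 0.5)


def _argmax_nearest_midline(region: np.ndarray, prefer_last: bool) -> np.ndarray:
    """Per-frame argmax over rows; exact ties resolved toward the midline.

    For the upper region the midline is below (largest row index wins);
    for the lower region it is above (smallest index, plain argmax).
    """
    if prefer_last:
        return region.shape[0] - 1 - np.argmax(region[::-1], axis=0)
    return np.argmax(region, axis=0)


def extract_cardiogram(
    mmode: MMode,
    midline: float | MidlineResult | None = None,
    *,
    sigma: float = 1.0,
    subpixel: bool = True,
    signal_floor_frac: float = SIGNAL_FLOOR_FRAC,
    min_separation_px: float = MIN_WALL_SEPARATION_PX,
    max_low_signal_frac: float = 0.5,
) -> Cardiogram:
    """Locate both walls in every frame and return the diameter trace.

    Parameters
    ----------
    mmode:
        Space x time M-mode matrix.
    midline:
        Midline position in span pixels; computed via :func:`find_midline`
        when omitted.  Must lie strictly inside the span.
    sigma:
        Gaussian smoothing width (px) applied to each spatial profile before
        peak search.  0 disables smoothing.
    subpixel:
        Refine each integer peak with a parabola through the peak and its
        two neighbours.
    signal_floor_frac:
        A wall peak must exceed the per-frame median intensity by this
        fraction of the global p95-p5 intensity range, otherwise the frame
        is flagged ``low_signal``.  Relative thresholds keep the extraction
        invariant to intensity scaling and robust to photobleaching.
    """
    matrix = np.asarray(mmode.matrix, dtype=float)
    n_space, n_frames = matrix.shape

    if midline is None:
        midline = find_midline(mmode)
    if isinstance(midline, MidlineResult):
        midline = midline.midline_px
    mid_idx = int(round(midline))
    if not (0 < mid_idx < n_space - 1):
        raise ValueError(f"midline {midline} not strictly inside the span (0, {n_space - 1})")

    smoothed = gaussian_filter1d(matrix, sigma, axis=0) if sigma > 0 else matrix

    # The midline pixel itself is excluded from both searches so that the two
    # walls cannot collapse onto a single pixel at systole.
    upper_region = smoothed[:mid_idx, :]
    lower_region = smoothed[mid_idx + 1 :, :]

    iu = _argmax_nearest_midline(upper_region, prefer_last=True)
    il = _argmax_nearest_midline(lower_region, prefer_last=False) + mid_idx + 1

    cols = np.arange(n_frames)
    upper = iu.astype(float)
    lower = il.astype(float)
    if subpixel:
        ok_u = (iu > 0) & (iu < mid_idx - 1)
        if ok_u.any():
            upper[ok_u] = iu[ok_u] + _parabolic_offset(
                smoothed[iu[ok_u] - 1, cols[ok_u]],
                smoothed[iu[ok_u], cols[ok_u]],
                smoothed[iu[ok_u] + 1, cols[ok_u]],
            )
        ok_l = (il > mid_idx + 1) & (il < n_space - 1)
        if ok_l.any():
            lower[ok_l] = il[ok_l] + _parabolic_offset(
                smoothed[il[ok_l] - 1, cols[ok_l]],
                smoothed[il[ok_l], cols[ok_l]],
                smoothed[il[ok_l] + 1, cols[ok_l]],
            )

    # Signal floor: per-frame wall contrast relative to the global intensity range.
    p95, p5 = np.percentile(smoothed, [95, 5])
    scale = p95 - p5
    frame_bg = np.median(smoothed, axis=0)
    peak_u = smoothed[iu, cols]
    peak_l = smoothed[il, cols]
    contrast = np.minimum(peak_u, peak_l) - frame_bg
    low = contrast <= signal_floor_frac * scale
    low |= (lower - upper) < min_separation_px

    n_low = int(low.sum())
    if n_low > max_low_signal_frac * n_frames:
        raise NoWallSignalError(
            f"{n_low}/{n_frames} frames below the wall-signal floor"
        )

    if n_low:
        good = np.flatnonzero(~low)
        bad = np.flatnonzero(low)
        upper[bad] = np.interp(bad, good, upper[good])
        lower[bad] = np.interp(bad, good, lower[good])

    quality = np.where(low, QUALITY_LOW, QUALITY_OK).astype("<U10")
    diameter_px = np.abs(lower - upper)
    return Cardiogram(
        time_s=np.arange(n_frames) * mmode.dt_s,
        upper_wall_px=upper,
        lower_wall_px=lower,
        diameter_px=diameter_px,
        diameter_um=diameter_px * mmode.pixel_size_um,
        midline_px=float(midline),
        quality=quality,
        pixel_size_um=mmode.pixel_size_um,
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def write_cardiogram(cardiogram: Cardiogram, csv_path, json_path=None, options: dict | None = None):
    """Write the cardiogram as CSV (one row per frame) plus a JSON sidecar."""
    import json as _json
    from pathlib import Path

    import pandas as pd

    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {
            "frame": np.arange(cardiogram.n_frames),
            "time_s": cardiogram.time_s,
            "upper_wall_px": cardiogram.upper_wall_px,
            "lower_wall_px": cardiogram.lower_wall_px,
            "diameter_px": cardiogram.diameter_px,
            "diameter_um": cardiogram.diameter_um,
            "quality": cardiogram.quality,
        }
    )
    df.to_csv(csv_path, index=False, float_format="%.10g")
    if json_path is not None:
        meta = {
            "midline_px": cardiogram.midline_px,
            "pixel_size_um": cardiogram.pixel_size_um,
            "options": options or {},
        }
        Path(json_path).write_text(_json.dumps(meta, indent=2))
    return csv_path


def read_cardiogram(csv_path, pixel_size_um: float | None = None) -> Cardiogram:
    """Read a cardiogram CSV written by :func:`write_cardiogram`."""
    import pandas as pd

    df = pd.read_csv(csv_path)
    d_px = df["diameter_px"].to_numpy(float)
    d_um = df["diameter_um"].to_numpy(float)
    if pixel_size_um is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = d_um / d_px
        finite = ratios[np.isfinite(ratios)]
        pixel_size_um = float(finite[0]) if finite.size else 1.0
    return Cardiogram(
        time_s=df["time_s"].to_numpy(float),
        upper_wall_px=df["upper_wall_px"].to_numpy(float),
        lower_wall_px=df["lower_wall_px"].to_numpy(float),
        diameter_px=d_px,
        diameter_um=d_um,
        midline_px=float("nan"),
        quality=df["quality"].to_numpy(str).astype("<U10"),
        pixel_size_um=pixel_size_um,
    )
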
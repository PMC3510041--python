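"""Beat-event detection and heart-performance metrics.

End-diastole is the maximally relaxed (widest) heart state and end-systole
the maximally contracted (narrowest) one; on the diameter trace they are the
local maxima and minima respectively.  From the detected events the standard
per-fly measures are computed:

* Heart Period (HP) -- the mean time between successive end-diastolic
  events, in ms.
* Heart Rate (HR) -- 1000 / HP, in Hz.
* Arrhythmicity Index (AI) -- the standard deviation of the
  diastole-to-diastole intervals normalized to their median; 0 for a
  perfectly regular heart.
* End-Diastolic / End-Systolic Diameter (EDD / ESD) -- mean diameter over
  the respective events, in um.

Taken literally, "all local maxima and minima" would include every noise
wiggle, so the detector adds two configurable guards (both can be set to 0
to recover the literal reading): a prominence threshold expressed as a
fraction of the p95-p5 trace range, and a refractory separation between
successive same-type events.  Alternation is then enforced by discarding
the less extreme of two consecutive same-type events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .stackio import FrameStack
from .walltrace import Cardiogram

__all__ = [
    "BeatEvents",
    "HeartMetrics",
    "TooFewBeatsError",
    "DIASTOLE",
    "SYSTOLE",
    "detect_beats",
    "estimate_period_s",
    "compute_metrics",
    "analyze_stack",
    "interval_statistics",
]

DIASTOLE = "diastole"
SYSTOLE = "systole"

#: Default prominence threshold as a fraction of the p95-p5 diameter range.
PROM_FRAC = 0.10

#: Default minimum separation (frames) between successive same-type events.
REFRACTORY_FRAMES = 2

#: Bounds (s) on the automatic detection-smoothing width.
SMOOTH_SIGMA_BOUNDS_S = (0.005, 0.040)

#: Fallback smoothing width (s) when the beat period cannot be estimated.
SMOOTH_SIGMA_FALLBACK_S = 0.010


class TooFewBeatsError(RuntimeError):
    """Raised when fewer than two end-diastolic events are found."""


@dataclass
class BeatEvents:
    """Ordered, strictly alternating beat events."""

    time_s: np.ndarray
    kind: np.ndarray           # DIASTOLE / SYSTOLE per event
    diameter_um: np.ndarray
    frame_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.kind = np.asarray(self.kind)
        self.diameter_um = np.asarray(self.diameter_um, dtype=float)
        if not (len(self.time_s) == len(self.kind) == len(self.diameter_um)):
            raise ValueError("event arrays must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("event times must be strictly increasing")
        if any(self.kind[i] == self.kind[i + 1] for i in range(len(self.kind) - 1)):
            raise ValueError("event types must strictly alternate")

    @property
    def n_diastoles(self) -> int:
        return int(np.sum(self.kind == DIASTOLE))

    @property
    def n_systoles(self) -> int:
        return int(np.sum(self.kind == SYSTOLE))

    def diastole_times_s(self) -> np.ndarray:
        return self.time_s[self.kind == DIASTOLE]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.time_s, "type": self.kind, "diameter_um": self.diameter_um}
        )


@dataclass
class HeartMetrics:
    """Per-fly heart-performance metrics.

    Metrics that cannot be computed from the available events are NaN with a
    machine-readable reason in ``flags`` -- flies are never silently dropped.
    """

    hp_ms: float
    hr_hz: float
    ai: float
    edd_um: float
    esd_um: float
    n_beats: int
    intervals_ms: np.ndarray
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "hp_ms": self.hp_ms,
            "hr_hz": self.hr_hz,
            "ai": self.ai,
            "edd_um": self.edd_um,
            "esd_um": self.esd_um,
            "n_beats": self.n_beats,
            "flags": ";".join(f"{k}:{v}" for k, v in self.flags.items()),
        }


# ---------------------------------------------------------------------------
# Interval statistics (shared definition; the simulator uses it for truth)
# ---------------------------------------------------------------------------

def interval_statistics(intervals_ms: np.ndarray) -> tuple[float, float]:
    """(HP, AI) from a list of diastole-to-diastole intervals in ms.

    HP is the arithmetic mean.  AI is the sample standard deviation (n-1
    denominator) divided by the median; NaN with fewer than 2 intervals.
    """
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    if intervals_ms.size == 0:
        return math.nan, math.nan
    hp = float(np.mean(intervals_ms))
    if intervals_ms.size < 2:
        return hp, math.nan
    med = float(np.median(intervals_ms))
    if med == 0:
        return hp, math.nan
    ai = float(np.std(intervals_ms, ddof=1) / med)
    return hp, ai


# ---------------------------------------------------------------------------
# Beat detection
# ---------------------------------------------------------------------------

def estimate_period_s(diameter: np.ndarray, dt_s: float) -> float | None:
    """Coarse beat-period estimate by hysteresis crossing counting.

    Counts traversals from below the 25th to above the 75th percentile of
    the trace (a Schmitt trigger), which a full beat performs once and
    noise almost never does; the period is duration / crossings.  Robust to
    both noise and arrhythmia, unlike autocorrelation.  Returns ``None``
    when fewer than two beats are seen.
    """
    d = np.asarray(diameter, dtype=float)
    q25, q75 = np.percentile(d, [25, 75])
    if not q75 > q25:
        return None
    m = np.where(d > q75, 1, np.where(d < q25, -1, 0))
    m = m[m != 0]
    if m.size < 2:
        return None
    ups = int(np.sum((m[1:] == 1) & (m[:-1] == -1)))
    if ups < 2:
        return None
    return d.size * dt_s / ups


def detect_beats(
    cardiogram: Cardiogram,
    *,
    prom_frac: float = PROM_FRAC,
    refractory_frames: int = REFRACTORY_FRAMES,
    smooth_sigma_s: float | str = "auto",
) -> BeatEvents:
    """Find end-diastolic (maxima) and end-systolic (minima) events.

    The diameter trace is smoothed for detection only; event diameters are
    always read from the unsmoothed trace.  With ``smooth_sigma_s="auto"``
    (default) the smoothing width adapts to the beat: one tenth of the
    period estimated by :func:`estimate_period_s`, clipped to 5--40 ms, so
    that slow noisy hearts get enough noise suppression while fast
    arrhythmic ones keep their shortest beats resolved.  Pass 0 to disable
    smoothing.  Plateau extrema are located at the plateau centre.  Raises
    :class:`TooFewBeatsError` with fewer than two diastoles.
    """
    d = np.asarray(cardiogram.diameter_um, dtype=float)
    if d.size < 3:
        raise TooFewBeatsError("need at least 3 frames of usable signal")

    if smooth_sigma_s == "auto":
        period = estimate_period_s(d, cardiogram.dt_s)
        lo, hi = SMOOTH_SIGMA_BOUNDS_S
        smooth_sigma_s = (
            float(np.clip(period / 10.0, lo, hi)) if period else SMOOTH_SIGMA_FALLBACK_S
        )
    if smooth_sigma_s > 0 and cardiogram.n_frames >= 2:
        sigma_frames = smooth_sigma_s / cardiogram.dt_s
        ds = gaussian_filter1d(d, sigma_frames) if sigma_frames > 0.2 else d
    else:
        ds = d

    p95, p5 = np.percentile(ds, [95, 5])
    scale = p95 - p5
    prominence = prom_frac * scale if (prom_frac > 0 and scale > 0) else None
    distance = refractory_frames if refractory_frames >= 1 else None

    maxima, _ = find_peaks(ds, prominence=prominence, distance=distance)
    minima, _ = find_peaks(-ds, prominence=prominence, distance=distance)

    idx = np.concatenate([maxima, minima])
    kinds = np.concatenate(
        [np.full(maxima.size, DIASTOLE), np.full(minima.size, SYSTOLE)]
    )
    order = np.argsort(idx, kind="stable")
    idx, kinds = idx[order], kinds[order]

    # Alternation repair: of two consecutive same-type events keep the more
    # extreme one (wider diastole, narrower systole) on the detection trace.
    kept_idx: list[int] = []
    kept_kind: list[str] = []
    for i, k in zip(idx, kinds):
        if kept_kind and kept_kind[-1] == k:
            prev = kept_idx[-1]
            better = ds[i] > ds[prev] if k == DIASTOLE else ds[i] < ds[prev]
            if better:
                kept_idx[-1] = int(i)
        else:
            kept_idx.append(int(i))
            kept_kind.append(str(k))

    frame_index = np.asarray(kept_idx, dtype=int)
    kind = np.asarray(kept_kind)

    # Re-localize events near the raw trace: heavy detection smoothing
    # shifts the extrema of an asymmetric waveform, so each event is moved
    # to the extremum of a lightly smoothed (5 ms) trace within the window
    # bounded by the midpoints to its neighbours (windows are disjoint, so
    # order is preserved).  The light smoothing suppresses per-sample noise
    # without reintroducing a shift.  A no-op when detection ran unsmoothed.
    if ds is not d and frame_index.size:
        # light smoothing scaled to the beat: period/30, floor 5 ms
        sigma_refine_s = max(0.005, smooth_sigma_s / 3.0)
        sigma_refine = sigma_refine_s / cardiogram.dt_s
        dr = gaussian_filter1d(d, sigma_refine) if sigma_refine > 0.2 else d
        refined = frame_index.copy()
        for j, (i, k) in enumerate(zip(frame_index, kind)):
            left = (frame_index[j - 1] + i) // 2 + 1 if j > 0 else 0
            right = (i + frame_index[j + 1]) // 2 if j < frame_index.size - 1 else d.size - 1
            seg = dr[left : right + 1]
            refined[j] = left + (np.argmax(seg) if k == DIASTOLE else np.argmin(seg))
        frame_index = refined

    if int(np.sum(kind == DIASTOLE)) < 2:
        raise TooFewBeatsError(
            f"found {int(np.sum(kind == DIASTOLE))} diastolic events; need >= 2"
        )

    return BeatEvents(
        time_s=cardiogram.time_s[frame_index],
        kind=kind,
        diameter_um=d[frame_index],
        frame_index=frame_index,
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_metrics(events: BeatEvents) -> HeartMetrics:
    """Heart-performance metrics from detected events.

    HP needs >= 2 diastoles, AI >= 3; partial results carry flags for the
    metrics that remain undefined.
    """
    flags: dict[str, str] = {}
    d_times = events.diastole_times_s()
    intervals_ms = np.diff(d_times) * 1000.0

    hp_ms, ai = interval_statistics(intervals_ms)
    if intervals_ms.size < 1:
        flags["hp"] = "needs >= 2 diastoles"
    if intervals_ms.size < 2:
        flags["ai"] = "needs >= 3 diastoles"
    hr_hz = 1000.0 / hp_ms if hp_ms and not math.isnan(hp_ms) else math.nan

    dia_d = events.diameter_um[events.kind == DIASTOLE]
    sys_d = events.diameter_um[events.kind == SYSTOLE]
    if dia_d.size:
        edd_um = float(np.mean(dia_d))
    else:
        edd_um, flags["edd"] = math.nan, "no diastolic events"
    if sys_d.size:
        esd_um = float(np.mean(sys_d))
    else:
        esd_um, flags["esd"] = math.nan, "no systolic events"

    return HeartMetrics(
        hp_ms=hp_ms,
        hr_hz=hr_hz,
        ai=ai,
        edd_um=edd_um,
        esd_um=esd_um,
        n_beats=int(intervals_ms.size),
        intervals_ms=intervals_ms,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

def analyze_stack(
    stack: FrameStack,
    *,
    zone=None,
    midline: float | None = None,
    sigma_px: float = 1.0,
    subpixel: bool = True,
    prom_frac: float = PROM_FRAC,
    refractory_frames: int = REFRACTORY_FRAMES,
    smooth_sigma_s: float | str = "auto",
    keep_intermediates: bool = False,
):
    """Full pipeline: stack -> zone -> M-mode -> cardiogram -> events -> metrics.

    Returns :class:`HeartMetrics`, or ``(metrics, intermediates)`` with
    ``keep_intermediates=True`` where intermediates is a dict with keys
    ``zone``, ``mmode``, ``midline``, ``cardiogram``, ``events``.  Stage
    errors propagate annotated with the stage name.
    """
    from . import stackio, walltrace

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # annotate and re-raise
            exc.add_note(f"pipeline stage: {name}")
            raise

    if zone is None:
        zone = _stage("locate_zone", stackio.locate_zone, stack)
    mmode = _stage("build_mmode", stackio.build_mmode, stack, zone)
    mid = (
        _stage("find_midline", walltrace.find_midline, mmode)
        if midline is None
        else midline
    )
    cardiogram = _stage(
        "extract_cardiogram",
        walltrace.extract_cardiogram,
        mmode,
        mid,
        sigma=sigma_px,
        subpixel=subpixel,
    )
    events = _stage(
        "detect_beats",
        detect_beats,
        cardiogram,
        prom_frac=prom_frac,
        refractory_frames=refractory_frames,
        smooth_sigma_s=smooth_sigma_s,
    )
    metrics = _stage("compute_metrics", compute_metrics, events)

    if keep_intermediates:
        return metrics, {
            "zone": zone,
            "mmode": mmode,
            "midline": mid,
            "cardiogram": cardiogram,
            "events": events,
        }
    return metrics
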
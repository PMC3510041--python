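"""Synthetic heart-beat data with known ground truth.

Every downstream stage has a generator here that emulates its input:

* :func:`simulate_beat_train` -- stochastic diastole/systole event trains
  with a chosen mean period and coefficient of variation;
* :func:`render_cardiogram` -- the per-frame diameter trace a perfect wall
  tracker would produce, optionally with additive noise;
* :func:`render_video` -- a fluorescence stack with two bright wall bands
  oscillating about a midline (the paper-faithful default imaging setting
  is 1000 frames at 32 frames/s);
* :func:`simulate_cohort` -- aging cohorts of per-fly metrics lying on
  planted linear age trends plus between-fly noise;
* :func:`simulate_gene_lists` -- identifier sets with an exactly planted
  overlap inside a fixed universe.

All generators are deterministic given a seed, and the recorded truth is
the *realized* statistic of the drawn sample (e.g. the AI of the drawn
intervals, by the same definition the estimator uses), not the nominal
parameter -- so recovery tests have exact targets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .beatmetrics import DIASTOLE, SYSTOLE, interval_statistics
from .stackio import FrameStack, write_stack
from .walltrace import Cardiogram

__all__ = [
    "BeatTrainParams",
    "GeometryParams",
    "AgingModel",
    "GroundTruth",
    "simulate_beat_train",
    "render_cardiogram",
    "render_video",
    "simulate_cohort",
    "simulate_gene_lists",
    "write_truth",
]

DISTRIBUTIONS = ("gamma", "lognormal", "constant")


@dataclass(frozen=True)
class BeatTrainParams:
    """Generative parameters of a beat train.

    ``mean_period_ms`` and ``cv_period`` set the first two moments of the
    i.i.d. diastole-to-diastole intervals; ``systole_phase`` places each
    systolic event at that fraction of the interval after the diastole.
    The gamma default has positive support and an exactly tunable CV.
    """

    mean_period_ms: float = 150.0
    cv_period: float = 0.1
    n_beats: int = 30
    distribution: str = "gamma"
    systole_phase: float = 0.4

    def __post_init__(self) -> None:
        if not self.mean_period_ms > 0:
            raise ValueError("mean_period_ms must be positive")
        if self.cv_period < 0:
            raise ValueError("cv_period must be >= 0")
        if self.n_beats < 2:
            raise ValueError("n_beats must be >= 2")
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(
                f"unknown distribution {self.distribution!r}; choose from {DISTRIBUTIONS}"
            )
        if not 0 < self.systole_phase < 1:
            raise ValueError("systole_phase must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class GeometryParams:
    """Imaging geometry and noise for rendering cardiograms and videos.

    ``noise_sigma`` is additive Gaussian noise on pixel *intensities* in the
    rendered video; ``trace_noise_um`` is additive Gaussian noise on the
    rendered diameter trace (length units) -- the two live on different
    scales, so they are separate knobs.  ``bleach_tau_frames`` is the
    exponential photobleaching constant (``inf`` disables bleaching) and
    ``drift_px_per_frame`` a linear drift of the tube centre in the video
    (it cancels in the diameter, so the cardiogram is unaffected).
    """

    edd_um: float = 70.0
    esd_um: float = 45.0
    wall_sigma_px: float = 2.0
    midline_row: float = 40.0
    image_height_px: int = 80
    image_width_px: int = 40
    pixel_size_um: float = 1.0
    frame_rate_hz: float = 32.0
    noise_sigma: float = 0.0
    trace_noise_um: float = 0.0
    bleach_tau_frames: float = math.inf
    drift_px_per_frame: float = 0.0
    noise_model: str = "gaussian"
    wall_amplitude: float = 1000.0
    background: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.esd_um <= self.edd_um:
            raise ValueError("need 0 < esd_um <= edd_um")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.noise_model not in ("gaussian", "poisson", "none"):
            raise ValueError("noise_model must be 'gaussian', 'poisson' or 'none'")


@dataclass
class GroundTruth:
    """Event table and realized metric values of a generated beat train."""

    event_times_ms: np.ndarray
    event_types: np.ndarray          # DIASTOLE / SYSTOLE
    intervals_ms: np.ndarray         # diastole-to-diastole
    hp_true_ms: float
    ai_true: float
    event_diameters_um: np.ndarray | None = None
    diameter_trace_um: np.ndarray | None = None
    frame_times_s: np.ndarray | None = None
    edd_true_um: float = math.nan
    esd_true_um: float = math.nan

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times_ms) <= 0):
            raise ValueError("event times must be strictly increasing")
        types = list(self.event_types)
        if any(a == b for a, b in zip(types, types[1:])):
            raise ValueError("event types must alternate")

    def diastole_times_ms(self) -> np.ndarray:
        return self.event_times_ms[self.event_types == DIASTOLE]


# ---------------------------------------------------------------------------
# Beat trains
# ---------------------------------------------------------------------------

def _draw_intervals(params: BeatTrainParams, rng: np.random.Generator, n: int) -> np.ndarray:
    m, cv = params.mean_period_ms, params.cv_period
    if params.distribution == "constant" or cv == 0:
        return np.full(n, m)
    if params.distribution == "gamma":
        shape = 1.0 / cv**2
        return rng.gamma(shape, m * cv**2, size=n)
    # lognormal with exact mean m and CV cv
    s2 = math.log1p(cv**2)
    mu = math.log(m) - s2 / 2.0
    return rng.lognormal(mu, math.sqrt(s2), size=n)


def simulate_beat_train(params: BeatTrainParams, seed: int) -> GroundTruth:
    """Draw a beat train: ``n_beats`` diastoles with i.i.d. intervals.

    The first diastole is at t = 0.  Systoles are placed at
    ``systole_phase`` of each interval.  ``hp_true_ms`` and ``ai_true`` are
    the realized statistics of the drawn intervals (shared definition with
    the estimator), so a cv of 0 yields ``ai_true == 0`` exactly.
    """
    rng = np.random.default_rng(seed)
    intervals = _draw_intervals(params, rng, params.n_beats - 1)
    dia_times = np.concatenate([[0.0], np.cumsum(intervals)])
    sys_times = dia_times[:-1] + params.systole_phase * intervals

    times = np.concatenate([dia_times, sys_times])
    types = np.concatenate(
        [np.full(dia_times.size, DIASTOLE), np.full(sys_times.size, SYSTOLE)]
    )
    order = np.argsort(times, kind="stable")
    hp, ai = interval_statistics(intervals)
    return GroundTruth(
        event_times_ms=times[order],
        event_types=types[order],
        intervals_ms=intervals,
        hp_true_ms=hp,
        ai_true=ai,
    )


# ---------------------------------------------------------------------------
# Cardiogram rendering
# ---------------------------------------------------------------------------

def _clean_trace(truth: GroundTruth, geom: GeometryParams) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless per-frame diameter trace sampled at the frame rate.

    The waveform interpolates between ``edd_um`` at diastoles and ``esd_um``
    at systoles with a raised-cosine segment per event pair, which is smooth
    and has its extrema exactly at the event times.
    """
    if truth.event_times_ms.size == 0:
        raise ValueError("empty event list")
    t_ms = truth.event_times_ms
    values = np.where(truth.event_types == DIASTOLE, geom.edd_um, geom.esd_um)

    # Configuration check: the *typical* event spacing must exceed one frame
    # period.  Individual short gaps in a stochastic train merely alias (the
    # extremum is not resolved at that frame rate), which is a property of
    # the sampling, not an invalid configuration.
    median_gap_ms = float(np.median(np.diff(t_ms))) if t_ms.size > 1 else math.inf
    if median_gap_ms < 1000.0 / geom.frame_rate_hz:
        raise ValueError(
            f"frame rate {geom.frame_rate_hz} Hz too low to separate events "
            f"typically {median_gap_ms:.2f} ms apart"
        )

    n_frames = int(math.floor(t_ms[-1] / 1000.0 * geom.frame_rate_hz)) + 1
    frame_t_s = np.arange(n_frames) / geom.frame_rate_hz
    ft_ms = frame_t_s * 1000.0

    seg = np.clip(np.searchsorted(t_ms, ft_ms, side="right") - 1, 0, t_ms.size - 2)
    t0, t1 = t_ms[seg], t_ms[seg + 1]
    v0, v1 = values[seg], values[seg + 1]
    phase = np.clip((ft_ms - t0) / (t1 - t0), 0.0, 1.0)
    trace = v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * phase))
    # beyond the last event hold its value
    trace[ft_ms >= t_ms[-1]] = values[-1]
    return frame_t_s, trace


def render_cardiogram(
    truth: GroundTruth, geom: GeometryParams, seed: int
) -> tuple[Cardiogram, GroundTruth]:
    """Render the diameter trace a perfect tracker would extract.

    Returns the (possibly noisy) :class:`~flyheart.walltrace.Cardiogram`
    and the truth updated in place with the clean trace and realized
    diameter statistics.
    """
    rng = np.random.default_rng(seed)
    frame_t_s, clean = _clean_trace(truth, geom)

    truth.frame_times_s = frame_t_s
    truth.diameter_trace_um = clean
    truth.event_diameters_um = np.where(
        truth.event_types == DIASTOLE, geom.edd_um, geom.esd_um
    )
    truth.edd_true_um = geom.edd_um
    truth.esd_true_um = geom.esd_um

    noisy = clean.copy()
    if geom.trace_noise_um > 0:
        noisy = noisy + rng.normal(0.0, geom.trace_noise_um, size=noisy.shape)
    return (
        Cardiogram.from_diameter(frame_t_s, noisy, pixel_size_um=geom.pixel_size_um),
        truth,
    )


# ---------------------------------------------------------------------------
# Video rendering
# ---------------------------------------------------------------------------

def render_video(truth: GroundTruth, geom: GeometryParams, seed: int) -> FrameStack:
    """Render a fluorescence stack of the beating heart tube.

    Each frame holds two bright wall bands (Gaussian intensity profiles of
    width ``wall_sigma_px``) centred at ``midline_row +- d(t)/2`` over a dark
    background, uniform along the horizontal tube axis, with optional
    photobleaching, centre drift and photon noise.
    """
    rng = np.random.default_rng(seed)
    if truth.diameter_trace_um is None:
        frame_t_s, clean = _clean_trace(truth, geom)
        truth.frame_times_s = frame_t_s
        truth.diameter_trace_um = clean
        truth.edd_true_um = geom.edd_um
        truth.esd_true_um = geom.esd_um
        truth.event_diameters_um = np.where(
            truth.event_types == DIASTOLE, geom.edd_um, geom.esd_um
        )
    d_px = truth.diameter_trace_um / geom.pixel_size_um
    n_frames = d_px.size
    h, w = geom.image_height_px, geom.image_width_px

    centers = geom.midline_row + geom.drift_px_per_frame * np.arange(n_frames)
    upper = centers - d_px / 2.0
    lower = centers + d_px / 2.0
    if upper.min() < 0 or lower.max() > h - 1:
        raise ValueError(
            "geometry out of bounds: midline +- edd/2 (plus drift) must stay inside the frame"
        )

    rows = np.arange(h, dtype=float)
    s2 = 2.0 * geom.wall_sigma_px**2
    profile = np.exp(-((rows[None, :] - upper[:, None]) ** 2) / s2)
    profile += np.exp(-((rows[None, :] - lower[:, None]) ** 2) / s2)

    if math.isfinite(geom.bleach_tau_frames):
        profile *= np.exp(-np.arange(n_frames) / geom.bleach_tau_frames)[:, None]

    frames = geom.background + geom.wall_amplitude * profile  # (n, H)
    frames = np.repeat(frames[:, :, None], w, axis=2)

    if geom.noise_model == "gaussian" and geom.noise_sigma > 0:
        frames = frames + rng.normal(0.0, geom.noise_sigma, size=frames.shape)
    elif geom.noise_model == "poisson":
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)

    return FrameStack(
        frames=frames,
        frame_rate_hz=geom.frame_rate_hz,
        pixel_size_um=geom.pixel_size_um,
        source_path="<synthetic>",
    )


def write_video(
    truth: GroundTruth,
    geom: GeometryParams,
    stack: FrameStack,
    outdir: str | Path,
    seed: int,
    stem: str = "synthetic_heart",
) -> dict[str, Path]:
    """Write a rendered stack as 16-bit TIFF plus sidecar JSON and truth CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tif = outdir / f"{stem}.tif"
    write_stack(stack, tif, extra_meta={"seed": seed, "geometry": asdict(geom)})
    paths = {"tiff": tif, "sidecar": tif.with_suffix(".json")}
    paths.update(write_truth(truth, outdir, stem=stem))
    return paths


def write_truth(truth: GroundTruth, outdir: str | Path, stem: str = "synthetic_heart") -> dict[str, Path]:
    """CSV event table (time_ms, type, diameter_um) and per-frame trace."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events_csv = outdir / f"{stem}_events.csv"
    diam = (
        truth.event_diameters_um
        if truth.event_diameters_um is not None
        else np.full(truth.event_times_ms.size, np.nan)
    )
    pd.DataFrame(
        {"time_ms": truth.event_times_ms, "type": truth.event_types, "diameter_um": diam}
    ).to_csv(events_csv, index=False, float_format="%.10g")
    out = {"events": events_csv}

    if truth.diameter_trace_um is not None:
        trace_csv = outdir / f"{stem}_trace.csv"
        pd.DataFrame(
            {
                "frame": np.arange(truth.diameter_trace_um.size),
                "time_s": truth.frame_times_s,
                "diameter_um": truth.diameter_trace_um,
            }
        ).to_csv(trace_csv, index=False, float_format="%.10g")
        out["trace"] = trace_csv
    return out


# ---------------------------------------------------------------------------
# Aging cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgingModel:
    """Linear age trends per condition plus between-fly noise.

    ``conditions`` maps condition name -> metric -> (value at age 0, slope
    per day).  Defaults emulate control flies: HP rising from ~150 ms at 10
    days by ~2.4 ms/day, AI near 0.1 rising slowly, EDD ~70 um falling by
    ~0.27 um/day -- the magnitudes seen in aging cohorts of this assay.
    """

    conditions: tuple = (
        ("control", (("hp_ms", (130.0, 2.4)), ("ai", (0.10, 0.0015)), ("edd_um", (72.0, -0.27)))),
    )
    noise_sd: tuple = (("hp_ms", 20.0), ("ai", 0.05), ("edd_um", 5.0))

    @classmethod
    def from_dicts(cls, conditions: dict, noise_sd: dict) -> "AgingModel":
        return cls(
            conditions=tuple(
                (name, tuple(sorted(metrics.items()))) for name, metrics in conditions.items()
            ),
            noise_sd=tuple(sorted(noise_sd.items())),
        )

    def condition_dict(self) -> dict:
        return {name: dict(metrics) for name, metrics in self.conditions}

    def noise_dict(self) -> dict:
        return dict(self.noise_sd)

    def planted_slopes(self) -> dict:
        return {
            name: {metric: slope for metric, (_, slope) in metrics.items()}
            for name, metrics in ((n, dict(m)) for n, m in self.conditions)
        }


def simulate_cohort(
    model: AgingModel | None = None,
    n_per_group: int = 30,
    ages: tuple = (10, 30, 45, 60),
    seed: int = 0,
):
    """Per-fly metric records on planted linear age trends.

    Returns a DataFrame with columns fly_id, condition, age_days and one
    column per metric; the planted slopes are recorded in
    ``df.attrs["planted_slopes"]``.  Default group sizes (30 flies per age,
    ages 10/30/45/60 days) match typical cohorts of this assay.
    """
    import pandas as pd

    if model is None:
        model = AgingModel()
    ages = tuple(ages)
    if len(ages) < 2:
        raise ValueError("need at least 2 ages")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")

    rng = np.random.default_rng(seed)
    noise = model.noise_dict()
    rows = []
    for cond, metrics in model.condition_dict().items():
        for age in ages:
            for i in range(n_per_group):
                rec = {
                    "fly_id": f"{cond}_a{age}_f{i:03d}",
                    "condition": cond,
                    "age_days": age,
                }
                for metric, (v0, slope) in metrics.items():
                    sd = noise.get(metric, 0.0)
                    rec[metric] = v0 + slope * age + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                rows.append(rec)
    df = pd.DataFrame(rows)
    df.attrs["planted_slopes"] = model.planted_slopes()
    return df


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------

def simulate_gene_lists(
    universe_size: int,
    set_sizes: tuple[int, int],
    planted_overlap: int,
    seed: int = 0,
):
    """Two gene sets with an exactly planted overlap inside a universe.

    Returns ``(query, reference, universe)`` as
    :class:`~flyheart.enrich.GeneSet` objects with FlyBase-style
    identifiers.
    """
    from .enrich import GeneSet

    size_a, size_b = set_sizes
    k = planted_overlap
    if not 0 <= k <= min(size_a, size_b):
        raise ValueError("planted_overlap must be within [0, min(set sizes)]")
    if max(size_a, size_b) > universe_size:
        raise ValueError("set sizes cannot exceed the universe size")
    if size_a + size_b - k > universe_size:
        raise ValueError("sets of these sizes cannot have so small an overlap in this universe")

    rng = np.random.default_rng(seed)
    ids = np.array([f"FBgn{i + 1:07d}" for i in range(universe_size)])
    perm = rng.permutation(universe_size)
    shared = perm[:k]
    only_a = perm[k : size_a]
    only_b = perm[size_a : size_a + (size_b - k)]

    query = GeneSet("query", frozenset(ids[np.concatenate([shared, only_a]).astype(int)]))
    reference = GeneSet("reference", frozenset(ids[np.concatenate([shared, only_b]).astype(int)]))
    universe = GeneSet("universe", frozenset(ids))
    return query, reference, universe
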
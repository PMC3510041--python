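"""Video-stack input and M-mode construction.

A recording of a GFP-labelled beating heart tube is a stack of grayscale
frames.  The analysis reduces the stack to an *M-mode*: a space x time matrix
obtained by extracting the same one-pixel-wide line from every frame and
aligning those lines horizontally.  Heart-wall motion then appears as two
bright oscillating traces.

The acquisition line is positioned automatically.  By convention the heart
tube axis is horizontal in the frame, so candidate lines are single-pixel
image columns; the chosen column is the one whose summed per-pixel temporal
variance is largest (wall motion dominates the temporal variance), with ties
broken toward the image centre.  The analysed segment (span) along the line
is clipped to pixels whose time-mean intensity exceeds an Otsu background
threshold, dilated by a small margin.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

__all__ = [
    "FrameStack",
    "AcquisitionZone",
    "MMode",
    "NoMotionError",
    "load_stack",
    "locate_zone",
    "build_mmode",
    "write_stack",
    "write_mmode",
    "read_mmode",
]

#: ITU-R BT.709 luminance weights used when converting colour AVI frames.
_LUMA = np.array([0.2126, 0.7152, 0.0722])

#: Minimum span length (pixels) along the acquisition line.
MIN_SPAN_PX = 8

#: Margin (pixels) by which the Otsu-thresholded bright segment is dilated.
SPAN_MARGIN_PX = 3


class NoMotionError(RuntimeError):
    """Raised when no temporal variance above the floor is found (static stack)."""


@dataclass
class FrameStack:
    """A 3-D intensity volume (n_frames x height x width) with metadata."""

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float
    source_path: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (frames, height, width), got ndim={self.frames.ndim}")
        if self.frames.shape[0] < 2:
            raise ValueError("a stack needs at least 2 frames")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration_s(self) -> float:
        """Total recording duration, n_frames / frame_rate."""
        return self.n_frames / self.frame_rate_hz


@dataclass(frozen=True)
class AcquisitionZone:
    """The one-pixel-wide acquisition line and the analysed segment along it.

    ``orientation`` is ``"column"`` when the line is an image column (the
    default; horizontal tube axis) or ``"row"``.  ``index`` is the pixel
    coordinate of the line and ``span`` the inclusive interval analysed
    along it.
    """

    orientation: str
    index: int
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.orientation not in ("column", "row"):
            raise ValueError(f"orientation must be 'column' or 'row', got {self.orientation!r}")
        lo, hi = self.span
        if lo > hi:
            raise ValueError("span must be (lo, hi) with lo <= hi")

    @property
    def span_length(self) -> int:
        return self.span[1] - self.span[0] + 1


@dataclass
class MMode:
    """Space x time intensity matrix cut along the acquisition line."""

    matrix: np.ndarray          # (span_length, n_frames)
    dt_s: float                 # 1 / frame_rate_hz
    pixel_size_um: float
    zone: AcquisitionZone | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("M-mode matrix must be 2-D (space, time)")
        if not self.dt_s > 0:
            raise ValueError("dt_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    @property
    def time_s(self) -> np.ndarray:
        """Frame timestamps in seconds from frame 0."""
        return np.arange(self.n_frames) * self.dt_s


# ---------------------------------------------------------------------------
# Reading stacks
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def load_stack(
    path: str | Path,
    frame_rate_hz: float | None = None,
    pixel_size_um: float | None = None,
) -> FrameStack:
    """Read a multi-page TIFF (or AVI) as a :class:`FrameStack`.

    Integer pixel data are preserved losslessly.  Metadata precedence:
    a sidecar JSON file (same stem, ``.json`` suffix, written by the
    simulator or a previous run) overrides the caller-supplied values,
    which in turn stand in when no sidecar exists.  A missing frame rate
    is a hard error -- it is never guessed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        frames = tifffile.imread(path)
    elif suffix == ".avi":
        import imageio.v3 as iio

        frames = np.asarray(iio.imread(path))
        if frames.ndim == 4:  # colour -> luminance
            frames = frames[..., :3] @ _LUMA
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")

    if frames.ndim == 2:
        raise ValueError(f"{path.name}: single-page file; a stack needs at least 2 frames")
    if frames.ndim != 3:
        raise ValueError(f"{path.name}: expected grayscale pages, got shape {frames.shape}")

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        frame_rate_hz = meta.get("frame_rate_hz", frame_rate_hz)
        pixel_size_um = meta.get("pixel_size_um", pixel_size_um)

    if frame_rate_hz is None:
        raise ValueError(
            f"{path.name}: frame rate unknown; supply frame_rate_hz or a sidecar JSON"
        )
    if pixel_size_um is None:
        warnings.warn(
            f"{path.name}: pixel size unknown; defaulting to 1 um/px "
            "(diameters will be in pixel units)",
            stacklevel=2,
        )
        pixel_size_um = 1.0

    return FrameStack(
        frames=frames,
        frame_rate_hz=float(frame_rate_hz),
        pixel_size_um=float(pixel_size_um),
        source_path=str(path),
    )


def write_stack(stack: FrameStack, path: str | Path, extra_meta: dict | None = None) -> Path:
    """Write a stack as a 16-bit multi-page grayscale TIFF plus sidecar JSON."""
    path = Path(path)
    data = np.clip(np.rint(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "frame_rate_hz": stack.frame_rate_hz,
        "pixel_size_um": stack.pixel_size_um,
        "n_frames": int(stack.n_frames),
    }
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Zone location
# ---------------------------------------------------------------------------

def _principal_orientation(mean_img: np.ndarray) -> str:
    """Orientation of the acquisition line transverse to the bright region axis."""
    thr = threshold_otsu(mean_img)
    ys, xs = np.nonzero(mean_img > thr)
    if ys.size < 2:
        return "column"
    coords = np.stack([ys - ys.mean(), xs - xs.mean()])
    cov = coords @ coords.T / ys.size
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]  # (dy, dx) of the tube axis
    # Horizontal tube axis -> transverse line is a column.
    return "column" if abs(axis[1]) >= abs(axis[0]) else "row"


def locate_zone(
    stack: FrameStack,
    *,
    auto_orient: bool = False,
    margin: int = SPAN_MARGIN_PX,
    min_span: int = MIN_SPAN_PX,
) -> AcquisitionZone:
    """Automatically position the acquisition line.

    Scores every candidate line (image columns by default) by the sum of
    per-pixel temporal variance along it and returns the argmax, ties broken
    toward the image centre.  The span is clipped to pixels whose time-mean
    intensity exceeds the Otsu background threshold, dilated by ``margin``.

    Raises :class:`NoMotionError` when the largest per-pixel temporal
    variance is below the motion floor (static stack).
    """
    frames = np.asarray(stack.frames, dtype=float)
    n = frames.shape[0]
    if n < 16:
        warnings.warn(f"only {n} frames; zone location is unreliable below 16", stacklevel=2)

    orientation = "column"
    mean_img = frames.mean(axis=0)
    if auto_orient:
        orientation = _principal_orientation(mean_img)

    var_img = frames.var(axis=0)
    scale = float(frames.max() - frames.min())
    if scale == 0 or var_img.max() < (1e-6 * scale) ** 2:
        raise NoMotionError("no temporal variance above floor; is the heart beating?")

    # axis 0 = rows, axis 1 = columns; a 'column' line sums variance over rows
    sum_axis = 0 if orientation == "column" else 1
    scores = var_img.sum(axis=sum_axis)
    best = scores.max()
    candidates = np.flatnonzero(scores == best)
    centre = (scores.size - 1) / 2.0
    index = int(candidates[np.argmin(np.abs(candidates - centre))])

    profile = mean_img[:, index] if orientation == "column" else mean_img[index, :]
    thr = threshold_otsu(mean_img)
    bright = np.flatnonzero(profile > thr)
    if bright.size == 0:
        lo, hi = 0, profile.size - 1
    else:
        lo = max(0, int(bright[0]) - margin)
        hi = min(profile.size - 1, int(bright[-1]) + margin)
    # enforce the minimum span, expanding symmetrically
    while hi - lo + 1 < min_span:
        if lo > 0:
            lo -= 1
        if hi < profile.size - 1:
            hi += 1
        if lo == 0 and hi == profile.size - 1:
            break
    if hi - lo + 1 < min_span:
        raise ValueError(f"image too small for a {min_span}-px span along the line")

    return AcquisitionZone(orientation=orientation, index=index, span=(lo, hi))


# ---------------------------------------------------------------------------
# M-mode construction
# ---------------------------------------------------------------------------

def build_mmode(stack: FrameStack, zone: AcquisitionZone) -> MMode:
    """Build the M-mode by extracting the zone line from every frame.

    Column t of the matrix is the zone line's pixel values from frame t,
    restricted to the span -- a pure selection with no interpolation or
    smoothing.
    """
    n, h, w = stack.shape
    lo, hi = zone.span
    limit = h if zone.orientation == "column" else w
    cross = w if zone.orientation == "column" else h
    if not (0 <= zone.index < cross) or not (0 <= lo <= hi < limit):
        raise ValueError(f"zone {zone} out of bounds for stack shape {stack.shape}")

    if zone.orientation == "column":
        matrix = stack.frames[:, lo : hi + 1, zone.index].T
    else:
        matrix = stack.frames[:, zone.index, lo : hi + 1].T

    return MMode(
        matrix=np.ascontiguousarray(matrix),
        dt_s=1.0 / stack.frame_rate_hz,
        pixel_size_um=stack.pixel_size_um,
        zone=zone,
    )


# ---------------------------------------------------------------------------
# M-mode persistence
# ---------------------------------------------------------------------------

def write_mmode(mmode: MMode, tsv_path: str | Path, png_path: str | Path | None = None) -> Path:
    """Write the M-mode matrix as TSV (rows = space, columns = time).

    Metadata (dt, pixel size, zone) go into ``#``-prefixed header lines so
    the file round-trips through :func:`read_mmode`.  Optionally renders a
    PNG for visual inspection.
    """
    tsv_path = Path(tsv_path)
    header = [f"# dt_s={mmode.dt_s!r}", f"# pixel_size_um={mmode.pixel_size_um!r}"]
    if mmode.zone is not None:
        z = mmode.zone
        header.append(f"# zone={z.orientation},{z.index},{z.span[0]},{z.span[1]}")
    with open(tsv_path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, mmode.matrix, delimiter="\t", fmt="%.10g")

    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 3))
        ax.imshow(
            mmode.matrix,
            cmap="gray",
            aspect="auto",
            extent=(0, mmode.n_frames * mmode.dt_s, mmode.matrix.shape[0], 0),
        )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("position along line (px)")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return tsv_path


def read_mmode(tsv_path: str | Path) -> MMode:
    """Read an M-mode TSV written by :func:`write_mmode`."""
    tsv_path = Path(tsv_path)
    meta: dict[str, str] = {}
    with open(tsv_path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        matrix = np.loadtxt(fh, delimiter="\t", ndmin=2)

    zone = None
    if "zone" in meta:
        orient, idx, lo, hi = meta["zone"].split(",")
        zone = AcquisitionZone(orient, int(idx), (int(lo), int(hi)))
    return MMode(
        matrix=matrix,
        dt_s=float(meta.get("dt_s", "nan")),
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        zone=zone,
    )
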
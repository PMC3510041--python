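"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity from its definition by exhaustive
computation, without calling the implementation under test (beyond shared
trivial numpy primitives).
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

DIASTOLE = "diastole"
SYSTOLE = "systole"


# ---------------------------------------------------------------------------
# Local-extrema scan (plateaus at centre, priority distance selection,
# prominence by walking to the nearest higher terrain on each side)
# ---------------------------------------------------------------------------

def local_maxima_bruteforce(x: np.ndarray) -> list[int]:
    """All interior local maxima; a plateau yields its centre (rounded down)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    peaks = []
    i = 1
    while i < n - 1:
        if x[i - 1] < x[i]:
            j = i + 1
            while j < n - 1 and x[j] == x[i]:
                j += 1
            if x[j] < x[i]:
                peaks.append((i + (j - 1)) // 2)
                i = j
        i += 1
    return peaks


def prominence_bruteforce(x: np.ndarray, peak: int) -> float:
    """Peak height above the higher of the two bases.

    Each base is the minimum between the peak and the nearest strictly
    higher sample (or the signal end) on that side.
    """
    x = np.asarray(x, dtype=float)
    left_min = x[peak]
    i = peak
    while i >= 0 and x[i] <= x[peak]:
        left_min = min(left_min, x[i])
        i -= 1
    right_min = x[peak]
    i = peak
    while i < x.size and x[i] <= x[peak]:
        right_min = min(right_min, x[i])
        i += 1
    return x[peak] - max(left_min, right_min)


def select_by_distance_bruteforce(peaks: list[int], heights: np.ndarray, distance: int) -> list[int]:
    """Greedy keep-highest selection: peaks closer than ``distance`` to an
    already-kept higher-priority peak are removed (equal heights: the later
    peak has priority)."""
    peaks = np.asarray(peaks)
    keep = np.ones(peaks.size, dtype=bool)
    order = np.argsort(heights, kind="stable")
    for i in range(peaks.size - 1, -1, -1):
        j = order[i]
        if not keep[j]:
            continue
        k = j - 1
        while k >= 0 and peaks[j] - peaks[k] < distance:
            keep[k] = False
            k -= 1
        k = j + 1
        while k < peaks.size and peaks[k] - peaks[j] < distance:
            keep[k] = False
            k += 1
    return [int(p) for p in peaks[keep]]


def find_extrema_bruteforce(x: np.ndarray, prominence: float | None, distance: int | None) -> list[int]:
    """Local maxima of x filtered by distance, then prominence."""
    x = np.asarray(x, dtype=float)
    peaks = local_maxima_bruteforce(x)
    if distance is not None and distance >= 1 and peaks:
        peaks = select_by_distance_bruteforce(peaks, x[peaks], math.ceil(distance))
    if prominence is not None:
        peaks = [p for p in peaks if prominence_bruteforce(x, p) >= prominence]
    return peaks


def detect_beats_bruteforce(diameter: np.ndarray, prom_frac: float = 0.10, refractory: int = 2):
    """Exhaustive beat detection: extrema scan + greedy alternation repair.

    Returns (frame_indices, kinds) on the raw trace.
    """
    d = np.asarray(diameter, dtype=float)
    p95, p5 = np.percentile(d, [95, 5])
    scale = p95 - p5
    prom = prom_frac * scale if (prom_frac > 0 and scale > 0) else None
    dist = refractory if refractory >= 1 else None
    maxima = find_extrema_bruteforce(d, prom, dist)
    minima = find_extrema_bruteforce(-d, prom, dist)

    merged = sorted([(i, DIASTOLE) for i in maxima] + [(i, SYSTOLE) for i in minima])
    kept: list[tuple[int, str]] = []
    for i, k in merged:
        if kept and kept[-1][1] == k:
            prev = kept[-1][0]
            better = d[i] > d[prev] if k == DIASTOLE else d[i] < d[prev]
            if better:
                kept[-1] = (i, k)
        else:
            kept.append((i, k))
    idx = np.array([i for i, _ in kept], dtype=int)
    kinds = np.array([k for _, k in kept])
    return idx, kinds


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum by full enumeration
# ---------------------------------------------------------------------------

def wilcoxon_exact_bruteforce(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating all C(n, n_a) assignments.

    p = 2 * min(P(U <= u_obs), P(U >= u_obs)) capped at 1, with U the
    Mann-Whitney statistic of group a.  Valid for tie-free data.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    combined = np.concatenate([a, b])
    ranks = combined.argsort().argsort() + 1  # tie-free ranks
    ra = ranks[: a.size]
    u_obs = ra.sum() - a.size * (a.size + 1) / 2

    n = combined.size
    us = []
    all_ranks = np.arange(1, n + 1)
    for comb in itertools.combinations(range(n), a.size):
        w = all_ranks[list(comb)].sum()
        us.append(w - a.size * (a.size + 1) / 2)
    us = np.asarray(us, dtype=float)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


# ---------------------------------------------------------------------------
# Hypergeometric tail by exact rational enumeration
# ---------------------------------------------------------------------------

def hypergeom_tail_bruteforce(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) summed with exact rational arithmetic."""
    total = math.comb(N, n)
    return sum(
        (Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
         for i in range(k, min(K, n) + 1)),
        Fraction(0),
    )


# ---------------------------------------------------------------------------
# Zone location by exhaustive search
# ---------------------------------------------------------------------------

def best_variance_column_bruteforce(frames: np.ndarray) -> int:
    """Column with the largest summed per-pixel temporal variance; ties
    resolved toward the image centre."""
    frames = np.asarray(frames, dtype=float)
    _, h, w = frames.shape
    scores = []
    for x in range(w):
        s = 0.0
        for y in range(h):
            s += frames[:, y, x].var()
        scores.append(s)
    scores = np.asarray(scores)
    best = scores.max()
    ties = np.flatnonzero(np.isclose(scores, best, rtol=1e-12, atol=0))
    centre = (w - 1) / 2
    return int(ties[np.argmin(np.abs(ties - centre))])


# ---------------------------------------------------------------------------
# Midline by direct recomputation
# ---------------------------------------------------------------------------

def midline_bruteforce(matrix: np.ndarray) -> float:
    """Median over frames of per-frame intensity centroids, from the definition."""
    matrix = np.asarray(matrix, dtype=float)
    centroids = []
    rows = np.arange(matrix.shape[0])
    for t in range(matrix.shape[1]):
        col = matrix[:, t]
        tot = col.sum()
        if tot > 0:
            centroids.append(float((rows * col).sum() / tot))
    return float(np.median(centroids))
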
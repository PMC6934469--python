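"""Polyline geometry on vessel centerlines.

A vessel centerline is an ordered sequence of planar points (pixel units,
raster convention: origin top-left, y increasing downward). This module
provides the geometric substrate of the tortuosity metric: smoothing of
integer-pixel traces, arc and chord lengths, discrete curvature signs, and
the decomposition of a centerline into maximal subsegments of constant-sign
curvature (the stretches between convexity changes).

The discrete curvature sign at an interior point is the sign of the z
component of the cross product of the two difference vectors meeting there;
it is parameter-free and orientation-consistent. Collinear (zero-sign)
points are absorbed into adjacent runs, and runs shorter than a configurable
noise guard ``min_run`` are merged into their longer neighbour, so pixel
jitter does not create spurious one-point convexity changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractViolationError, InvalidCenterlineError

logger = logging.getLogger(__name__)

# relative tolerance below which a cross product counts as an exact zero
_SIGN_EPS = 1e-12


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidCenterlineError(f"points must have shape (N, 2), got {pts.shape}")
    if pts.shape[0] < 2:
        raise InvalidCenterlineError(f"a centerline needs >= 2 points, got {pts.shape[0]}")
    if not np.all(np.isfinite(pts)):
        raise InvalidCenterlineError("centerline contains non-finite coordinates")
    return pts


@dataclass(frozen=True)
class Centerline:
    """An ordered planar polyline tracing one vessel.

    Invariants: at least two points, consecutive points distinct, hence
    positive arc length (and arc length >= chord length by the triangle
    inequality).
    """

    points: np.ndarray
    vessel_id: str = ""

    def __post_init__(self) -> None:
        pts = _as_points(self.points)
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps == 0.0):
            raise InvalidCenterlineError(
                f"vessel {self.vessel_id!r}: consecutive points must be distinct"
            )
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class SubSegment:
    """A maximal constant-sign-curvature stretch of a parent centerline.

    ``start_index``/``end_index`` are inclusive positions into the parent
    point array; neighbouring subsegments share their boundary point.
    """

    start_index: int
    end_index: int
    sign: int
    arc_length: float
    chord_length: float

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ContractViolationError("subsegment must span at least one step")


def smooth_centerline(points, window: int = 5, vessel_id: str = "") -> Centerline:
    """Smooth a raw (typically integer-pixel) trace with a centered moving average.

    Endpoints are preserved exactly; each interior point is replaced by the
    mean of the points in a window centered on it, the window shrinking
    symmetrically near the ends. ``window=1`` returns the input unchanged.
    Smoothing is a convex combination of the input points, so collinear
    inputs stay collinear.
    """
    pts = _as_points(points)
    if window < 1 or window % 2 == 0:
        raise ContractViolationError(f"window must be odd and >= 1, got {window}")
    n = pts.shape[0]
    if window == 1 or n <= 2:
        return Centerline(_dedupe(pts), vessel_id=vessel_id)
    half = window // 2
    out = pts.copy()
    for i in range(1, n - 1):
        h = min(half, i, n - 1 - i)
        out[i] = pts[i - h : i + h + 1].mean(axis=0)
    return Centerline(_dedupe(out), vessel_id=vessel_id)


def _dedupe(pts: np.ndarray) -> np.ndarray:
    """Drop exactly-coincident consecutive points (can arise from raw traces)."""
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if not np.any(steps == 0.0):
        return pts
    keep = np.concatenate([[True], steps > 0.0])
    out = pts[keep]
    if out.shape[0] < 2:
        raise InvalidCenterlineError("centerline collapses to a single point")
    return out


def arc_length(c: Centerline | np.ndarray) -> float:
    """Total polyline length: the sum of Euclidean step lengths (pixels)."""
    pts = c.points if isinstance(c, Centerline) else _as_points(c)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def chord_length(c: Centerline | np.ndarray, start_index: int = 0, end_index: int = -1) -> float:
    """Euclidean distance between two points of the polyline (default: endpoints)."""
    pts = c.points if isinstance(c, Centerline) else _as_points(c)
    n = pts.shape[0]
    start = start_index if start_index >= 0 else n + start_index
    end = end_index if end_index >= 0 else n + end_index
    if not (0 <= start < n and 0 <= end < n):
        raise IndexError(f"indices ({start_index}, {end_index}) out of range for {n} points")
    if end <= start:
        raise ContractViolationError("end_index must exceed start_index")
    return float(np.linalg.norm(pts[end] - pts[start]))


def curvature_signs(c: Centerline | np.ndarray) -> np.ndarray:
    """Discrete curvature sign at each interior point.

    The sign at interior point i is the sign of the z component of
    (p_i - p_{i-1}) x (p_{i+1} - p_i); exact zeros (collinear triples)
    are reported as 0. Returns an empty array for fewer than 3 points.
    """
    pts = c.points if isinstance(c, Centerline) else _as_points(c)
    if pts.shape[0] < 3:
        return np.zeros(0, dtype=int)
    v = np.diff(pts, axis=0)
    cross = v[:-1, 0] * v[1:, 1] - v[:-1, 1] * v[1:, 0]
    scale = np.linalg.norm(v[:-1], axis=1) * np.linalg.norm(v[1:], axis=1)
    signs = np.sign(cross).astype(int)
    signs[np.abs(cross) <= _SIGN_EPS * scale] = 0
    return signs


def _sign_runs(signs: np.ndarray, min_run: int) -> list[tuple[int, list[int]]]:
    """Run-length structure over nonzero signs with noise-guard merging.

    Returns a list of (sign, interior-indices) runs. Interior indices are
    1-based positions into the parent point array (index i labels point i).
    Zero-sign points do not form runs of their own: they are absorbed when
    subsegment boundaries are placed between runs.
    """
    nz = np.nonzero(signs)[0]
    if nz.size == 0:
        return []
    runs: list[tuple[int, list[int]]] = []
    cur_sign = int(signs[nz[0]])
    cur: list[int] = [int(nz[0]) + 1]
    for k in nz[1:]:
        s = int(signs[k])
        if s == cur_sign:
            cur.append(int(k) + 1)
        else:
            runs.append((cur_sign, cur))
            cur_sign, cur = s, [int(k) + 1]
    runs.append((cur_sign, cur))

    # noise guard: merge runs spanning fewer than min_run interior points
    # into their longer neighbour (ties: the preceding one), then coalesce.
    while len(runs) > 1:
        lengths = [len(idx) for _, idx in runs]
        short = [i for i, L in enumerate(lengths) if L < min_run]
        if not short:
            break
        i = min(short, key=lambda j: (lengths[j], j))
        if i == 0:
            j = 1
        elif i == len(runs) - 1:
            j = i - 1
        else:
            j = i - 1 if lengths[i - 1] >= lengths[i + 1] else i + 1
        sign_j = runs[j][0]
        merged_idx = sorted(runs[i][1] + runs[j][1])
        lo, hi = min(i, j), max(i, j)
        runs[lo:hi + 1] = [(sign_j, merged_idx)]
        # coalesce neighbours that now share a sign
        k = 0
        while k < len(runs) - 1:
            if runs[k][0] == runs[k + 1][0]:
                runs[k:k + 2] = [(runs[k][0], runs[k][1] + runs[k + 1][1])]
            else:
                k += 1
    return runs


def decompose_constant_sign(
    c: Centerline | np.ndarray, min_run: int = 3
) -> list[SubSegment]:
    """Split a centerline into maximal constant-sign-curvature subsegments.

    The subsegments partition the polyline, neighbouring subsegments sharing
    their boundary point, so their arc lengths sum to the vessel arc length.
    A straight (or two-point) vessel is a single subsegment. Boundaries
    between runs of opposite sign are placed midway through any intervening
    collinear stretch.
    """
    pts = c.points if isinstance(c, Centerline) else _as_points(c)
    n = pts.shape[0]
    last = n - 1
    signs = curvature_signs(pts)
    runs = _sign_runs(signs, min_run=min_run)

    if not runs:
        return [_make_subsegment(pts, 0, last, sign=1)]

    boundaries = [0]
    for (_, idx_a), (_, idx_b) in zip(runs[:-1], runs[1:]):
        e, f = idx_a[-1], idx_b[0]
        boundaries.append((e + f + 1) // 2)
    boundaries.append(last)

    segs = []
    for k, (sign, _) in enumerate(runs):
        segs.append(_make_subsegment(pts, boundaries[k], boundaries[k + 1], sign))
    return segs


def _make_subsegment(pts: np.ndarray, start: int, end: int, sign: int) -> SubSegment:
    arc = arc_length(pts[start : end + 1])
    chord = float(np.linalg.norm(pts[end] - pts[start]))
    if chord == 0.0:
        logger.warning(
            "degenerate subsegment: coincident endpoints at indices (%d, %d)", start, end
        )
    return SubSegment(start_index=start, end_index=end, sign=sign,
                      arc_length=arc, chord_length=chord)
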
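"""Diameter tracking, collapsibility index and RAP categorisation.

Per frame, the cleaned lumen mask is reduced to a centerline (pruned
skeleton), the measurement site is located at a fixed arc-length distance
from the cavo-atrial junction end (clinical convention: about 2 cm), and
the diameter is the maximal contiguous in-mask chord through the site
perpendicular to the local centerline tangent, converted to millimetres.

The per-frame series is smoothed with a Savitzky-Golay filter; the
collapsibility index is computed from the smoothed curve's absolute
extrema:

    cIVC = (dIVC_max - dIVC_min) / dIVC_max * 100%

and the (dIVC_max, cIVC) pair is mapped to a right-atrial-pressure
category under either guideline rule set:

    dIVC <= 21 mm, cIVC > 50%  ->  ASE 3 mmHg,  NIH 5 mmHg
    dIVC <= 21 mm, otherwise   ->  ASE 8 mmHg,  NIH 10 mmHg
    dIVC >  21 mm, cIVC > 50%  ->  ASE 15 mmHg, NIH 15 mmHg
    dIVC >  21 mm, otherwise   ->  ASE 15 mmHg, NIH 20 mmHg

Boundary ties follow the printed predicates: exactly 21 mm counts as
"<= 21 mm"; exactly 50% falls to the low-collapsibility row (">50%" is
strict).  The diameter entering the table is dIVC_max (the maximal,
end-expiration diameter, as in guideline practice).
"""

from __future__ import annotations

import dataclasses
import heapq
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import savgol_filter
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import skeletonize

__all__ = [
    "MeasurementConfig",
    "DiameterCurve",
    "CollapseResult",
    "RapEstimate",
    "ShapeError",
    "SiteError",
    "MeasurementError",
    "CurveError",
    "extract_centerline",
    "locate_site",
    "measure_diameter",
    "measure_clip",
    "build_curve",
    "collapse_index",
    "estimate_rap",
]


class ShapeError(ValueError):
    """Region is not an elongated vessel-like blob."""


class SiteError(ValueError):
    """Measurement site lies beyond the visible vessel."""


class MeasurementError(ValueError):
    """Chord measurement failed (site outside the mask)."""


class CurveError(ValueError):
    """Too few valid per-frame diameters to build a curve."""


@dataclasses.dataclass
class MeasurementConfig:
    """Where and how the diameter is measured.

    site_distance_mm : arc-length distance of the measurement site from
        the cavo-atrial junction (default 20 mm ~ the clinical 2 cm site).
    savgol_window, savgol_order : Savitzky-Golay smoothing of the frame
        series; window must be odd and larger than the order.
    alternative_sites_mm : additional caudal sites for site-variation
        analyses (1, 3, 4, 5 cm).
    """

    site_distance_mm: float = 20.0
    savgol_window: int = 11
    savgol_order: int = 3
    alternative_sites_mm: Tuple[float, ...] = (10.0, 30.0, 40.0, 50.0)

    def __post_init__(self) -> None:
        if self.savgol_window % 2 == 0 or self.savgol_window < 5:
            raise ValueError("savgol_window must be odd and >= 5")
        if not (0 <= self.savgol_order < self.savgol_window):
            raise ValueError("savgol_order must be < savgol_window")


@dataclasses.dataclass
class DiameterCurve:
    raw: np.ndarray  # per-frame dIVC mm; NaN where the frame was rejected
    smooth: np.ndarray
    idx_max: int
    idx_min: int

    @property
    def dIVC_max(self) -> float:
        return float(self.smooth[self.idx_max])

    @property
    def dIVC_min(self) -> float:
        return float(self.smooth[self.idx_min])


@dataclasses.dataclass
class CollapseResult:
    cIVC: float  # percent
    dIVC_max: float  # mm
    dIVC_min: float  # mm


@dataclasses.dataclass
class RapEstimate:
    criterion: str  # "ASE" | "NIH"
    rap_mmHg: int
    dIVC_used_mm: float
    cIVC_pct: float


# ---------------------------------------------------------------------------
# geometry


def extract_centerline(mask: np.ndarray) -> np.ndarray:
    """Ordered (row, col) path along the pruned skeleton of an elongated mask.

    The morphological skeleton is reduced to its single longest geodesic
    path by a double Dijkstra sweep; the result runs end to end and lies
    inside the mask.  A blob with major/minor axis ratio < 2 raises
    :class:`ShapeError`.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ShapeError("empty mask")
    lab = cc_label(mask, connectivity=2)
    props = regionprops(lab)
    if len(props) != 1:
        raise ShapeError("mask must have a single component; clean it first")
    rp = props[0]
    minor = max(rp.axis_minor_length, 1.0)
    if rp.axis_major_length / minor < 2.0:
        raise ShapeError(
            f"region is not elongated (axis ratio "
            f"{rp.axis_major_length / minor:.2f} < 2)"
        )
    skel = skeletonize(mask)
    pts = np.column_stack(np.nonzero(skel))
    if len(pts) < 2:
        raise ShapeError("skeleton degenerate")
    index = {tuple(p): i for i, p in enumerate(map(tuple, pts))}

    def neighbors(i: int):
        r, c = pts[i]
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    yield j, math.hypot(dr, dc)

    def farthest(src: int):
        dist = np.full(len(pts), np.inf)
        prev = np.full(len(pts), -1)
        dist[src] = 0.0
        pq = [(0.0, src)]
        while pq:
            d, i = heapq.heappop(pq)
            if d > dist[i]:
                continue
            for j, w in neighbors(i):
                nd = d + w
                if nd < dist[j]:
                    dist[j] = nd
                    prev[j] = i
                    heapq.heappush(pq, (nd, j))
        dist[np.isinf(dist)] = -1.0
        far = int(np.argmax(dist))
        return far, prev

    a, _ = farthest(0)
    b, prev = farthest(a)
    path = []
    i = b
    while i != -1:
        path.append(tuple(int(x) for x in pts[i]))
        i = int(prev[i]) if i != a else -1
    path.reverse()
    return _extend_to_boundary(np.asarray(path, dtype=int), mask)


def _extend_to_boundary(path: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extrapolate both path ends along their tangents to the mask edge.

    The morphological skeleton stops about half a vessel width short of
    each end; extending it restores the full visible centerline so the
    junction end truly reaches the vessel opening.
    """
    h, w = mask.shape
    if len(path) < 2:
        return path

    def extend(end: np.ndarray, inner: np.ndarray):
        tangent = (end - inner).astype(float)
        n = np.linalg.norm(tangent)
        if n == 0:
            return []
        tangent /= n
        out, p = [], end.astype(float)
        for _ in range(max(h, w)):
            p = p + tangent
            r, c = int(round(p[0])), int(round(p[1]))
            if not (0 <= r < h and 0 <= c < w and mask[r, c]):
                break
            if not out or out[-1] != (r, c):
                out.append((r, c))
        return out

    k = min(4, len(path) - 1)
    head = extend(path[0], path[k])
    tail = extend(path[-1], path[-1 - k])
    return np.asarray(head[::-1] + [tuple(p) for p in path] + tail, dtype=int)


def _orient_to_junction(path: np.ndarray, junction_end: str) -> np.ndarray:
    """Put the junction-end endpoint first."""
    first, last = path[0], path[-1]
    key = {
        "right": lambda p: -p[1], "left": lambda p: p[1],
        "top": lambda p: p[0], "bottom": lambda p: -p[0],
        "auto": lambda p: -p[1],  # default: junction on the right edge
    }[junction_end]
    if key(first) > key(last):
        return path[::-1]
    return path


def locate_site(
    centerline: np.ndarray, junction_end: str, site_distance_mm: float,
    mm_per_px: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Point and unit tangent at a given arc-length from the junction end.

    The tangent is taken by central differences over +-3 path points
    around the site.  Raises :class:`SiteError` when the visible vessel is
    shorter than the requested distance.
    """
    path = _orient_to_junction(np.asarray(centerline, dtype=float), junction_end)
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s = site_distance_mm / mm_per_px
    if s > arc[-1]:
        raise SiteError(
            f"site at {site_distance_mm} mm ({s:.1f} px) beyond centerline "
            f"length {arc[-1]:.1f} px"
        )
    i = int(np.searchsorted(arc, s, side="right") - 1)
    i = min(i, len(path) - 2) if len(path) > 1 else 0
    if len(path) == 1:
        site = path[0].copy()
    else:
        t = 0.0 if seg[i] == 0 else (s - arc[i]) / seg[i]
        site = path[i] + t * (path[i + 1] - path[i])
    lo, hi = max(0, i - 3), min(len(path) - 1, i + 3)
    tangent = path[hi] - path[lo]
    norm = np.linalg.norm(tangent)
    if norm == 0:
        raise SiteError("degenerate tangent at measurement site")
    return site, tangent / norm


def measure_diameter(
    mask: np.ndarray, site: np.ndarray, tangent: np.ndarray, mm_per_px: float,
    step_px: float = 0.25,
) -> float:
    """Maximal contiguous in-mask chord through the site, perpendicular to
    the tangent, in millimetres."""
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    site = np.asarray(site, dtype=float)
    normal = np.array([-tangent[1], tangent[0]], dtype=float)
    normal /= np.linalg.norm(normal)

    def inside(p: np.ndarray) -> bool:
        # half-up rounding: pixel (r, c) covers [r-0.5, r+0.5) x [c-0.5, c+0.5)
        r, c = math.floor(p[0] + 0.5), math.floor(p[1] + 0.5)
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    if not inside(site):
        raise MeasurementError(f"measurement site {site} lies outside the mask")
    n_max = int(math.hypot(h, w) / step_px) + 2
    ends = []
    for sign in (+1.0, -1.0):
        k = 0
        while k < n_max and inside(site + sign * (k + 1) * step_px * normal):
            k += 1
        # bisect the in/out bracket to locate the mask edge precisely
        lo, hi = k * step_px, (k + 1) * step_px
        for _ in range(24):
            mid = 0.5 * (lo + hi)
            if inside(site + sign * mid * normal):
                lo = mid
            else:
                hi = mid
        ends.append(0.5 * (lo + hi))
    return (ends[0] + ends[1]) * mm_per_px


def measure_clip(
    masks: np.ndarray, mm_per_px: float, junction_end: str = "right",
    config: Optional[MeasurementConfig] = None,
    site_distance_mm: Optional[float] = None,
) -> np.ndarray:
    """Per-frame diameters (mm) for a mask stack; NaN where a frame fails.

    Frames whose mask is empty, not elongated, too short for the site, or
    otherwise unmeasurable contribute NaN — out-of-plane artifacts must not
    masquerade as collapse.
    """
    config = config or MeasurementConfig()
    site_mm = config.site_distance_mm if site_distance_mm is None else site_distance_mm
    out = np.full(len(masks), np.nan)
    for i, m in enumerate(masks):
        try:
            path = extract_centerline(m)
            site, tangent = locate_site(path, junction_end, site_mm, mm_per_px)
            out[i] = measure_diameter(m, site, tangent, mm_per_px)
        except (ShapeError, SiteError, MeasurementError):
            continue
    return out


# ---------------------------------------------------------------------------
# curve, collapsibility, RAP


def build_curve(diameters, config: Optional[MeasurementConfig] = None) -> DiameterCurve:
    """Interpolate missing frames, smooth, and locate the absolute extrema.

    Interior NaNs are linearly interpolated; leading/trailing NaNs are held
    at the nearest valid value.  The smoothed curve is clamped at zero; the
    extrema are its global maximum and minimum.
    """
    config = config or MeasurementConfig()
    raw = np.asarray(diameters, dtype=float)
    valid = np.isfinite(raw)
    if valid.sum() < config.savgol_window:
        raise CurveError(
            f"only {int(valid.sum())} valid frames; need >= {config.savgol_window}"
        )
    filled = raw.copy()
    idx = np.arange(len(raw))
    filled[~valid] = np.interp(idx[~valid], idx[valid], raw[valid])
    smooth = savgol_filter(filled, config.savgol_window, config.savgol_order)
    smooth = np.clip(smooth, 0.0, None)
    return DiameterCurve(
        raw=raw, smooth=smooth,
        idx_max=int(np.argmax(smooth)), idx_min=int(np.argmin(smooth)),
    )


def collapse_index(curve) -> CollapseResult:
    """Collapsibility index from a curve's extrema (or a (max, min) pair)."""
    if isinstance(curve, DiameterCurve):
        d_max, d_min = curve.dIVC_max, curve.dIVC_min
    else:
        d_max, d_min = float(curve[0]), float(curve[1])
    if not d_max > 0:
        raise ValueError("cIVC undefined: dIVC_max must be positive")
    civc = 100.0 * (d_max - d_min) / d_max
    return CollapseResult(cIVC=civc, dIVC_max=d_max, dIVC_min=d_min)


_RAP_TABLE: Dict[str, Tuple[int, int, int, int]] = {
    # rows: (<=21 & >50), (<=21 & otherwise), (>21 & >50), (>21 & otherwise)
    "ASE": (3, 8, 15, 15),
    "NIH": (5, 10, 15, 20),
}


def estimate_rap(dIVC_used_mm: float, cIVC_pct: float, criterion: str) -> RapEstimate:
    """Map (dIVC, cIVC) to a RAP category under the named criterion."""
    criterion = criterion.upper()
    if criterion not in _RAP_TABLE:
        raise ValueError(f"unknown criterion {criterion!r}; use 'ASE' or 'NIH'")
    if dIVC_used_mm < 0:
        raise ValueError("dIVC must be non-negative")
    if not (0 <= cIVC_pct <= 100):
        raise ValueError("cIVC must be in [0, 100] percent")
    small = dIVC_used_mm <= 21.0
    collapsing = cIVC_pct > 50.0
    row = (0 if collapsing else 1) if small else (2 if collapsing else 3)
    return RapEstimate(
        criterion=criterion, rap_mmHg=_RAP_TABLE[criterion][row],
        dIVC_used_mm=float(dIVC_used_mm), cIVC_pct=float(cIVC_pct),
    )
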
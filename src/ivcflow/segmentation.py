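"""IVC region segmentation, mask cleanup and boundary tracing.

Two segmentation paths produce a per-frame binary lumen mask:

* a trainable per-pixel classifier (multiscale intensity features +
  logistic regression), deterministic given its seed; and
* a training-free classical fallback — inverted Otsu thresholding
  restricted to the darkest sufficiently elongated connected component —
  which is bit-reproducible and carries the geometry tests.

The cleaned mask's ordered outer boundary is extracted with Moore-Neighbor
tracing under Jacob's stopping criterion: the walk around the 8-neighbour-
hood ends when the start pixel is re-entered from the same direction it was
first entered, which avoids premature termination on pinched shapes.
Digital topology: foreground 8-connected, background 4-connected.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from sklearn.linear_model import LogisticRegression

__all__ = [
    "Contour",
    "ContourError",
    "SegmenterModel",
    "train_segmenter",
    "segment_frame",
    "segment_clip",
    "clean_mask",
    "trace_contour",
    "outer_boundary_bruteforce",
]

# clockwise Moore neighbourhood starting from the West neighbour:
# W, NW, N, NE, E, SE, S, SW as (drow, dcol)
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_EIGHT = np.ones((3, 3), dtype=bool)


class ContourError(ValueError):
    pass


@dataclasses.dataclass
class Contour:
    """Ordered closed boundary; consecutive points are 8-adjacent."""

    points: List[Tuple[int, int]]  # (row, col)
    closed: bool = True

    def __post_init__(self) -> None:
        pts = self.points
        for a, b in zip(pts, pts[1:]):
            if a == b:
                raise ContourError("consecutive duplicate contour points")
            if max(abs(a[0] - b[0]), abs(a[1] - b[1])) > 1:
                raise ContourError(f"contour points {a} and {b} not 8-adjacent")
        if self.closed and len(pts) > 1:
            a, b = pts[0], pts[-1]
            if max(abs(a[0] - b[0]), abs(a[1] - b[1])) > 1:
                raise ContourError("closed contour endpoints not 8-adjacent")

    def __len__(self) -> int:
        return len(self.points)

    def pixel_set(self) -> set:
        return set(self.points)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=int)


# ---------------------------------------------------------------------------
# mask cleanup


def clean_mask(mask: np.ndarray) -> np.ndarray:
    """Keep the largest 8-connected component, fill holes, open with 3x3.

    Iterated to a fixed point so the operation is idempotent even when the
    opening splits the component.  An empty input yields an empty output.
    """
    mask = np.asarray(mask).astype(bool)
    for _ in range(8):
        out = _clean_once(mask)
        if np.array_equal(out, mask):
            return out
        mask = out
    return mask


def _clean_once(mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    lab, n = ndimage.label(mask, structure=_EIGHT)
    if n > 1:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    # fill 4-connected background pockets enclosed by foreground
    mask = ndimage.binary_fill_holes(mask)
    mask = ndimage.binary_opening(mask, structure=np.ones((3, 3), dtype=bool))
    return mask.astype(bool)


# ---------------------------------------------------------------------------
# Moore-Neighbor boundary tracing


def trace_contour(mask: np.ndarray) -> Contour:
    """Trace the ordered outer boundary of a single-component mask.

    Starts from the first foreground pixel in raster order and walks the
    Moore neighbourhood clockwise, re-scanning from the backtrack pixel;
    terminates on Jacob's criterion (start re-entered from the initial
    entry direction).  The traced pixel set equals the set of foreground
    pixels 8-adjacent to the exterior background.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ContourError("cannot trace an empty mask")
    _, n = ndimage.label(mask, structure=_EIGHT)
    if n != 1:
        raise ContourError(
            f"mask has {n} 8-connected components; apply clean_mask first"
        )
    h, w = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    rs, cs = np.nonzero(mask)
    start = (int(rs[0]), int(cs[0]))  # raster order: smallest row, then col
    if mask.sum() == 1:
        return Contour([start], closed=True)

    # initial backtrack is the raster-order predecessor (always background)
    def step(point, backtrack):
        """Clockwise Moore scan from backtrack; next boundary pixel."""
        dr, dc = backtrack[0] - point[0], backtrack[1] - point[1]
        k = _MOORE.index((dr, dc))
        for i in range(1, 9):
            cand = _MOORE[(k + i) % 8]
            r, c = point[0] + cand[0], point[1] + cand[1]
            if fg(r, c):
                prev = _MOORE[(k + i - 1) % 8]
                return (r, c), (point[0] + prev[0], point[1] + prev[1])
        return None, None  # isolated pixel (cannot happen here)

    boundary: List[Tuple[int, int]] = [start]
    point, backtrack = start, (start[0], start[1] - 1)
    seen = set()  # walk states (pixel, backtrack); a repeat closes the cycle
    max_steps = 16 * (mask.sum() + 2) + 32
    for _ in range(int(max_steps)):
        state = (point, backtrack)
        if state in seen:
            break  # Jacob's criterion: same pixel entered the same way again
        seen.add(state)
        nxt, bt = step(point, backtrack)
        if nxt is None:
            break
        entry_dir = (nxt[0] - point[0], nxt[1] - point[1])
        if entry_dir[0] != 0 and entry_dir[1] != 0:
            # diagonal move: the elbow pixel on the inside of the turn is
            # also exterior-facing (the other elbow was just scanned and is
            # background); record it so no outer-boundary pixel is skipped
            for elbow in ((point[0] + entry_dir[0], point[1]),
                          (point[0], point[1] + entry_dir[1])):
                if fg(*elbow) and boundary[-1] != elbow:
                    boundary.append(elbow)
        if boundary[-1] != nxt:
            boundary.append(nxt)
        point, backtrack = nxt, bt
    else:  # pragma: no cover - safety net
        raise ContourError("boundary walk failed to terminate")

    if len(boundary) > 1 and boundary[-1] == start:
        boundary.pop()
    return Contour(boundary, closed=True)


def outer_boundary_bruteforce(mask: np.ndarray) -> set:
    """Independent oracle: foreground pixels 8-adjacent to the exterior.

    The exterior is found by 4-connected flood fill of the background from
    a 1-px pad; enclosed holes are therefore not part of it.
    """
    mask = np.asarray(mask).astype(bool)
    padded = np.pad(mask, 1)
    four = ndimage.generate_binary_structure(2, 1)
    bg_lab, _ = ndimage.label(~padded, structure=four)
    exterior = bg_lab == bg_lab[0, 0]
    near_ext = ndimage.binary_dilation(exterior, structure=_EIGHT)
    boundary = padded & near_ext
    rs, cs = np.nonzero(boundary[1:-1, 1:-1])
    return set(zip(rs.tolist(), cs.tolist()))


# ---------------------------------------------------------------------------
# segmenters


@dataclasses.dataclass
class SegmenterModel:
    """Per-pixel lumen classifier over multiscale intensity features."""

    clf: LogisticRegression
    sigmas: Tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    threshold: float = 0.5
    seed: int = 0

    def predict_proba(self, frame: np.ndarray) -> np.ndarray:
        X = _pixel_features(np.asarray(frame, dtype=float), self.sigmas)
        p = self.clf.predict_proba(X.reshape(-1, X.shape[-1]))[:, 1]
        return p.reshape(frame.shape)

    def predict(self, frame: np.ndarray) -> np.ndarray:
        return self.predict_proba(frame) >= self.threshold


def _pixel_features(frame: np.ndarray, sigmas: Sequence[float]) -> np.ndarray:
    feats = [frame]
    for s in sigmas:
        sm = ndimage.gaussian_filter(frame, s)
        feats.append(sm)
        feats.append(np.sqrt(np.clip(
            ndimage.gaussian_filter(frame**2, s) - sm**2, 0, None)))
    return np.stack(feats, axis=-1)


def train_segmenter(
    corpus,
    config: Optional[dict] = None,
    seed: int = 0,
    pixels_per_frame: int = 2000,
    max_frames: int = 60,
) -> SegmenterModel:
    """Fit the per-pixel classifier on paired frames + masks of a corpus.

    Pixels are subsampled per frame (foreground-balanced) with a seeded RNG;
    the solver is deterministic, so identical seeds give identical models.
    """
    config = config or {}
    sigmas = tuple(config.get("sigmas", (1.0, 2.0, 4.0, 8.0)))
    frames, masks = [], []
    for clip, seq in zip(corpus.clips, corpus.masks):
        for f, m in zip(clip.frames, seq.masks):
            if m.any():
                frames.append(f)
                masks.append(m)
    if not frames:
        raise ValueError("corpus has no frames with non-empty masks")
    rng = np.random.default_rng(seed)
    if len(frames) > max_frames:
        keep = rng.choice(len(frames), size=max_frames, replace=False)
        frames = [frames[i] for i in keep]
        masks = [masks[i] for i in keep]
    Xs, ys = [], []
    for f, m in zip(frames, masks):
        X = _pixel_features(np.asarray(f, dtype=float), sigmas)
        X = X.reshape(-1, X.shape[-1])
        y = m.ravel().astype(int)
        pos = np.nonzero(y)[0]
        neg = np.nonzero(y == 0)[0]
        n_half = pixels_per_frame // 2
        pos = rng.choice(pos, size=min(n_half, len(pos)), replace=False)
        neg = rng.choice(neg, size=min(n_half, len(neg)), replace=False)
        idx = np.concatenate([pos, neg])
        Xs.append(X[idx])
        ys.append(y[idx])
    X = np.concatenate(Xs)
    y = np.concatenate(ys)
    clf = LogisticRegression(max_iter=500, C=10.0, random_state=seed)
    clf.fit(X, y)
    return SegmenterModel(clf=clf, sigmas=sigmas, seed=seed)


def _fallback_segment(frame: np.ndarray) -> np.ndarray:
    """Inverted Otsu threshold restricted to the darkest elongated component."""
    frame = np.asarray(frame, dtype=float)
    if frame.max() - frame.min() < 1e-6:
        return np.zeros(frame.shape, dtype=bool)
    thr = threshold_otsu(frame)
    dark = frame < thr
    if not dark.any():
        return np.zeros(frame.shape, dtype=bool)
    lab = cc_label(dark, connectivity=2)
    best, best_score = None, -np.inf
    for rp in regionprops(lab, intensity_image=frame):
        if rp.area < 16:
            continue
        minor = max(rp.axis_minor_length, 1.0)
        elong = rp.axis_major_length / minor
        if elong < 2.0:
            continue
        darkness = 1.0 - rp.intensity_mean
        score = darkness * np.log(rp.area)
        if score > best_score:
            best, best_score = rp.label, score
    if best is None:  # no elongated candidate: largest dark blob
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        if sizes.max() == 0:
            return np.zeros(frame.shape, dtype=bool)
        best = int(np.argmax(sizes))
    return lab == best


def segment_frame(method, frame: np.ndarray) -> np.ndarray:
    """Segment one frame with a trained model or the classical fallback.

    ``method`` is a :class:`SegmenterModel` or the string ``"fallback"``.
    A blank frame yields an empty mask, not an error.
    """
    if isinstance(method, SegmenterModel):
        return method.predict(frame)
    if method == "fallback":
        return _fallback_segment(frame)
    raise ValueError(f"unknown segmentation method {method!r}")


def segment_clip(method, clip, clean: bool = True) -> np.ndarray:
    """Segment every frame of a clip; optionally clean each mask."""
    out = np.zeros(clip.frames.shape, dtype=bool)
    for i, f in enumerate(clip.frames):
        m = segment_frame(method, f)
        out[i] = clean_mask(m) if clean else m
    return out
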
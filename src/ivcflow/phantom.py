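"""Synthetic B-mode-like phantoms with known geometry and dynamics.

Every downstream stage (view retrieval, segmentation, diameter tracking,
collapsibility, RAP) is tested against clips generated here, because no
patient data ships with the package.  A phantom IVC clip contains a dark,
mildly curved tubular lumen on multiplicative speckle; the local lumen
width oscillates with a respiratory cycle

    d(t) = d_min + (d_max - d_min) * (1 + cos(2*pi*t/T_resp)) / 2

so the true diameter curve, its extrema and the collapsibility index are
known exactly.  Decoy views (parasternal-long-axis-, apical-four-chamber-
and Doppler-like) are geometric look-alikes with distinct pixel statistics,
sufficient to exercise classifier separability and open-set rejection; they
are not anatomical renderings.

Generation is bit-deterministic given (params, seed).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .media_io import MaskSequence, VideoClip

__all__ = ["PhantomParams", "DiameterTruth", "CorpusSpec", "Corpus",
           "make_clip", "make_corpus"]

VIEWS = ("ivc", "plax_like", "a4c_like", "doppler_like")


@dataclasses.dataclass
class PhantomParams:
    """Generator knobs; defaults emulate a 20 s subcostal acquisition.

    Diameters are end-expiration (``d_max_mm``) and end-inspiration
    (``d_min_mm``) lumen widths.  ``quality="bad"`` applies a stated
    degradation: heavy blur (sigma >= 3 px) or lumen contrast <= 0.15.
    """

    d_max_mm: float = 18.0
    d_min_mm: float = 9.0
    resp_period_s: float = 4.0
    n_cycles: int = 5
    mm_per_px: float = 0.25
    frame_rate_hz: float = 30.0
    image_size: Tuple[int, int] = (600, 800)
    speckle_scale: float = 0.3
    lumen_contrast: float = 0.85
    quality: str = "good"
    view: str = "ivc"
    junction_end: str = "right"
    dropout_frames: Sequence[int] = ()
    bad_blur_sigma: float = 3.0
    bad_contrast: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}")
        if self.quality not in ("good", "bad"):
            raise ValueError("quality must be 'good' or 'bad'")
        if self.d_min_mm > self.d_max_mm:
            raise ValueError("d_min_mm must not exceed d_max_mm")
        if self.view == "ivc" and self.d_min_mm / self.mm_per_px < 3:
            raise ValueError(
                f"lumen at minimum is {self.d_min_mm / self.mm_per_px:.1f} px "
                "wide; need >= 3 px"
            )
        if self.quality == "bad" and not (
            self.bad_blur_sigma >= 3 or self.bad_contrast <= 0.15
        ):
            raise ValueError("bad quality requires blur sigma >= 3 or contrast <= 0.15")

    @property
    def n_frames(self) -> int:
        return max(1, round(self.n_cycles * self.resp_period_s * self.frame_rate_hz))


@dataclasses.dataclass
class DiameterTruth:
    """Ground-truth diameter dynamics of a generated clip."""

    d_mm: np.ndarray  # per-frame true lumen width, mm
    dIVC_max_mm: float
    dIVC_min_mm: float
    cIVC_pct: float
    idx_max: int
    idx_min: int


def _true_diameters(p: PhantomParams) -> np.ndarray:
    t = np.arange(p.n_frames) / p.frame_rate_hz
    return p.d_min_mm + (p.d_max_mm - p.d_min_mm) * (
        1 + np.cos(2 * math.pi * t / p.resp_period_s)
    ) / 2.0


def _centerline(p: PhantomParams) -> np.ndarray:
    """Continuous centerline polyline (row, col), junction at the right edge.

    A mild quadratic arc: the tube enters horizontally from the right edge
    and bows by ~8% of the image height over its run, so centerline
    extraction is exercised on a genuinely curved vessel.
    """
    h, w = p.image_size
    n = 8 * w
    # extend past the junction edge so the lumen opens through it
    x = np.linspace(-0.1 * w, w + 0.5 * max(p.d_max_mm / p.mm_per_px, 8), n)
    span = w
    y = 0.5 * h + 0.08 * h * ((w - x) / span) ** 2
    pts = np.column_stack([y, x])
    return pts


_ORIENT = {"right": lambda a, hw: a,
           "left": lambda a, hw: a[..., ::-1],
           "bottom": lambda a, hw: np.swapaxes(a, -1, -2),
           "top": lambda a, hw: np.swapaxes(a, -1, -2)[..., ::-1, :]}


def _orient_stack(stack: np.ndarray, junction_end: str) -> np.ndarray:
    """Map a canonical junction-at-right stack to the requested orientation."""
    if junction_end in ("right", "auto"):
        return stack
    if junction_end == "left":
        return stack[..., ::-1]
    if junction_end == "bottom":
        return np.swapaxes(stack, -1, -2)
    if junction_end == "top":
        return np.swapaxes(stack, -1, -2)[..., ::-1, :]
    raise ValueError(junction_end)


def _speckle(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Rayleigh-like multiplicative speckle texture, mean ~1."""
    raw = rng.rayleigh(scale=scale, size=shape)
    raw = gaussian_filter(raw, 1.0)
    return raw / raw.mean()


def _decoy_overlay(view: str, h: int, w: int) -> np.ndarray:
    """Deterministic geometric overlay in [-1, 1] for non-IVC views."""
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    overlay = np.zeros((h, w))
    if view == "plax_like":
        # bright septal band across the middle, dark chambers above/below
        band = np.exp(-((yy - 0.5 * h) / (0.06 * h)) ** 2)
        chamber1 = ((yy - 0.3 * h) / (0.12 * h)) ** 2 + ((xx - 0.45 * w) / (0.25 * w)) ** 2 < 1
        chamber2 = ((yy - 0.72 * h) / (0.12 * h)) ** 2 + ((xx - 0.55 * w) / (0.25 * w)) ** 2 < 1
        overlay = 1.5 * band - 0.9 * chamber1 - 0.9 * chamber2
    elif view == "a4c_like":
        # four dark chambers separated by a bright cross (septum/AV plane)
        cross = np.exp(-((xx - 0.5 * w) / (0.04 * w)) ** 2) + np.exp(
            -((yy - 0.55 * h) / (0.04 * h)) ** 2
        )
        overlay = 1.2 * cross - 0.8
        sector = (yy > 0.12 * h) & (np.abs(xx - 0.5 * w) < 0.15 * w + 0.55 * yy)
        overlay = np.where(sector, overlay, 0.8)  # bright outside sector
    elif view == "doppler_like":
        # bright spectral strip along the bottom third, dark sector above
        strip = yy > 0.66 * h
        spectral = strip * (0.8 + 0.6 * np.sin(2 * math.pi * xx / (0.08 * w)) *
                            np.exp(-((yy - 0.85 * h) / (0.1 * h)) ** 2))
        overlay = spectral - 0.5 * (~strip)
    return overlay


def make_clip(params: PhantomParams):
    """Generate one phantom clip.

    Returns ``(clip, masks, truth, labels)``: the normalised
    :class:`~ivcflow.media_io.VideoClip`, the exact lumen
    :class:`~ivcflow.media_io.MaskSequence` (empty for decoy views and
    dropout frames), the :class:`DiameterTruth` (``None`` for decoys), and a
    ``{"view": ..., "quality": ...}`` label dict.
    """
    p = params
    h, w = p.image_size
    rng = np.random.default_rng(p.seed)
    n_t = p.n_frames

    frames = np.empty((n_t, h, w))
    masks = np.zeros((n_t, h, w), dtype=bool)
    truth: Optional[DiameterTruth] = None

    bg = _speckle(rng, (h, w), p.speckle_scale)
    contrast = p.lumen_contrast if p.quality == "good" else min(
        p.lumen_contrast, p.bad_contrast
    )
    blur = 0.8 if p.quality == "good" else max(0.8, p.bad_blur_sigma)

    if p.view == "ivc":
        d_mm = _true_diameters(p)
        pts = _centerline(p)
        yy, xx = np.mgrid[0:h, 0:w]
        grid = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
        dist = cKDTree(pts).query(grid, workers=-1)[0].reshape(h, w)
        edge = 0.7  # px; soft lumen boundary before blur
        dropout = set(int(i) for i in p.dropout_frames)
        for i in range(n_t):
            r = d_mm[i] / (2.0 * p.mm_per_px)
            if i in dropout:
                img = bg.copy()
            else:
                soft = 1.0 / (1.0 + np.exp((dist - r) / edge))
                img = bg * (1.0 - contrast * soft)
                masks[i] = dist <= r
            frames[i] = gaussian_filter(img, blur)
        imax = int(np.argmax(d_mm))
        imin = int(np.argmin(d_mm))
        civc = 100.0 * (d_mm[imax] - d_mm[imin]) / d_mm[imax]
        truth = DiameterTruth(d_mm, float(d_mm[imax]), float(d_mm[imin]),
                              float(civc), imax, imin)
        frames = _orient_stack(frames, p.junction_end)
        masks = _orient_stack(masks, p.junction_end)
    else:
        overlay = _decoy_overlay(p.view, h, w)
        for i in range(n_t):
            flicker = 1.0 + 0.05 * math.sin(2 * math.pi * i / max(n_t, 2))
            img = np.clip(bg * (1.0 + 0.8 * contrast * overlay * flicker), 0, None)
            frames[i] = gaussian_filter(img, blur)

    frames = frames - frames.min()
    peak = frames.max()
    if peak > 0:
        frames = frames / peak
    clip = VideoClip(
        np.ascontiguousarray(frames), p.frame_rate_hz, p.mm_per_px,
        source_id=f"phantom-{p.view}-{p.quality}-seed{p.seed}",
        junction_end=p.junction_end if p.junction_end != "auto" else "right",
    )
    seq = MaskSequence(np.ascontiguousarray(masks), aligned_to=clip.source_id)
    labels = {"view": p.view, "quality": p.quality}
    return clip, seq, truth, labels


# ---------------------------------------------------------------------------
# corpus


@dataclasses.dataclass
class CorpusSpec:
    """Per-class clip counts and parameter ranges for a labelled corpus.

    ``holdout_views`` are generated but never assigned to the training
    partition, so open-set rejection can be exercised on a class the
    classifier has never seen.  The train fraction follows a floor rule:
    ``n_train = floor(train_frac * n)`` per (view, quality) stratum.
    """

    counts: Dict[str, int] = dataclasses.field(
        default_factory=lambda: {"ivc": 12, "plax_like": 8, "a4c_like": 8,
                                 "doppler_like": 6}
    )
    bad_fraction: float = 0.25
    holdout_views: Tuple[str, ...] = ("doppler_like",)
    train_frac: float = 0.7
    n_frames: int = 8
    image_size: Tuple[int, int] = (96, 128)
    mm_per_px: float = 0.5
    frame_rate_hz: float = 10.0
    resp_period_s: float = 4.0
    d_max_range_mm: Tuple[float, float] = (12.0, 24.0)
    civc_range_pct: Tuple[float, float] = (20.0, 80.0)

    def __post_init__(self) -> None:
        if not self.counts or all(v <= 0 for v in self.counts.values()):
            raise ValueError("corpus spec must request at least one clip")
        for view in self.counts:
            if view not in VIEWS:
                raise ValueError(f"unknown view {view!r}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be >= 0")


@dataclasses.dataclass
class Corpus:
    clips: List[VideoClip]
    masks: List[MaskSequence]
    truths: List[Optional[DiameterTruth]]
    labels: List[Dict[str, str]]
    split: List[str]  # "train" | "test" per clip

    def subset(self, split: str) -> "Corpus":
        keep = [i for i, s in enumerate(self.split) if s == split]
        return Corpus(
            [self.clips[i] for i in keep], [self.masks[i] for i in keep],
            [self.truths[i] for i in keep], [self.labels[i] for i in keep],
            [self.split[i] for i in keep],
        )

    def frames_and_labels(self):
        """Flatten to per-frame arrays for classifier training."""
        frames, views, quals = [], [], []
        for clip, lab in zip(self.clips, self.labels):
            for f in clip.frames:
                frames.append(f)
                views.append(lab["view"])
                quals.append(lab["quality"])
        return frames, views, quals

    def __len__(self) -> int:
        return len(self.clips)


def make_corpus(spec: CorpusSpec, seed: int = 0) -> Corpus:
    """Generate a reproducible labelled corpus with a train/test partition."""
    rng = np.random.default_rng(seed)
    clips, masks, truths, labels, split = [], [], [], [], []
    n_cycles = max(1, round(spec.n_frames / (spec.resp_period_s * spec.frame_rate_hz)))
    for view in sorted(spec.counts):
        n = spec.counts[view]
        if n == 0:
            continue
        n_bad = int(round(spec.bad_fraction * n))
        qualities = ["bad"] * n_bad + ["good"] * (n - n_bad)
        # stratified floor-rule split inside each (view, quality) stratum
        assigns = {}
        for q in ("good", "bad"):
            nq = qualities.count(q)
            if view in spec.holdout_views:
                assigns[q] = ["test"] * nq
            else:
                n_train = math.floor(spec.train_frac * nq)
                order = rng.permutation(nq)
                a = np.array(["test"] * nq, dtype=object)
                a[order[:n_train]] = "train"
                assigns[q] = list(a)
        used = {"good": 0, "bad": 0}
        for k, q in enumerate(qualities):
            d_max = float(rng.uniform(*spec.d_max_range_mm))
            civc = float(rng.uniform(*spec.civc_range_pct))
            d_min = d_max * (1.0 - civc / 100.0)
            d_min = max(d_min, 3.05 * spec.mm_per_px)
            p = PhantomParams(
                d_max_mm=d_max, d_min_mm=d_min,
                resp_period_s=spec.resp_period_s, n_cycles=n_cycles,
                mm_per_px=spec.mm_per_px, frame_rate_hz=spec.frame_rate_hz,
                image_size=spec.image_size, quality=q, view=view,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            clip, seq, truth, lab = make_clip(p)
            # trim/pad to the requested frame count
            clip.frames = clip.frames[: spec.n_frames]
            seq.masks = seq.masks[: spec.n_frames]
            if truth is not None:
                d = truth.d_mm[: spec.n_frames]
                imax, imin = int(np.argmax(d)), int(np.argmin(d))
                truth = DiameterTruth(
                    d, float(d[imax]), float(d[imin]),
                    100.0 * (d[imax] - d[imin]) / d[imax], imax, imin)
            clips.append(clip)
            masks.append(seq)
            truths.append(truth)
            labels.append(lab)
            split.append(assigns[q][used[q]])
            used[q] += 1
    return Corpus(clips, masks, truths, labels, split)
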
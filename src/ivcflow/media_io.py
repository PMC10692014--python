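"""Reading and writing of clips, masks and reports.

Clips arrive either as DICOM cine loops or as ``.npz`` raw-array containers
(arrays ``frames`` (T,H,W) or (T,H,W,C), optional scalars ``frame_rate_hz``
and ``mm_per_px``).  All frames are normalised to intensities in [0, 1] and
carry an isotropic mm-per-pixel calibration; a clip without a resolvable
calibration is a hard error, never a silent default.

Coordinate convention throughout the package: 0-based, row-major
(row = y, col = x), pixel-centre geometry.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "VideoClip",
    "MaskSequence",
    "ReferenceTable",
    "ClipReport",
    "FormatError",
    "CalibrationError",
    "AlignmentError",
    "load_clip",
    "load_masks",
    "write_masks",
    "write_report",
    "read_report",
    "load_reference_table",
]

JUNCTION_ENDS = ("left", "right", "top", "bottom", "auto")


class FormatError(ValueError):
    """Input file is not a readable clip/mask container."""


class CalibrationError(ValueError):
    """No mm-per-pixel calibration could be resolved for a clip."""


class AlignmentError(ValueError):
    """A mask sequence does not match the shape of its clip."""


@dataclasses.dataclass
class VideoClip:
    """A calibrated grayscale pixel-frame sequence.

    frames : (T, H, W) float array, intensities in [0, 1]
    frame_rate_hz : acquisition frame rate
    mm_per_px : isotropic physical pixel size in millimetres
    junction_end : image edge from which the vessel enters toward the
        cavo-atrial junction ("left"/"right"/"top"/"bottom"/"auto")
    """

    frames: np.ndarray
    frame_rate_hz: float
    mm_per_px: float
    source_id: str = ""
    junction_end: str = "right"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T×H×W, got shape {self.frames.shape}")
        t, h, w = self.frames.shape
        if t < 1 or h < 32 or w < 32:
            raise ValueError(f"clip too small: T={t}, H={h}, W={w} (need T≥1, H,W≥32)")
        if not (self.mm_per_px > 0):
            raise CalibrationError(f"mm_per_px must be positive, got {self.mm_per_px}")
        if not (self.frame_rate_hz > 0):
            raise ValueError("frame_rate_hz must be positive")
        if self.junction_end not in JUNCTION_ENDS:
            raise ValueError(f"junction_end must be one of {JUNCTION_ENDS}")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities outside [0,1]: range [{lo}, {hi}]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape


@dataclasses.dataclass
class MaskSequence:
    """Per-frame binary masks aligned to a clip."""

    masks: np.ndarray
    aligned_to: str = ""

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks).astype(bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be T×H×W")

    def check_alignment(self, clip: VideoClip) -> None:
        if self.masks.shape != clip.frames.shape:
            raise AlignmentError(
                f"mask shape {self.masks.shape} != clip shape {clip.frames.shape}"
            )


@dataclasses.dataclass
class ClipReport:
    """Clip-level pipeline result: decision, diameters, collapsibility, RAP."""

    source_id: str
    view_label: str
    quality_label: str
    analyzable: bool
    rejection_reason: Optional[str] = None
    frame_index: Optional[list] = None
    dIVC_mm_raw: Optional[list] = None
    dIVC_mm_smooth: Optional[list] = None
    dIVC_max_mm: Optional[float] = None
    dIVC_min_mm: Optional[float] = None
    cIVC_pct: Optional[float] = None
    rap_mmHg: Optional[dict] = None  # criterion name -> category in mmHg


def _normalize(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 4:  # color: luminance by channel mean
        frames = frames.mean(axis=-1)
    lo, hi = frames.min(), frames.max()
    if hi > lo:
        frames = (frames - lo) / (hi - lo)
    else:
        frames = np.zeros_like(frames)
    return frames


def _dicom_mm_per_px(ds) -> Optional[float]:
    """Resolve isotropic mm/px from DICOM ultrasound-region attributes.

    Ultrasound regions carry PhysicalDeltaX/Y in cm per pixel (DICOM US
    convention); PixelSpacing, when present, is already mm.  If x/y spacing
    differs by more than 1% the caller resamples to isotropic pixels.
    """
    regions = getattr(ds, "SequenceOfUltrasoundRegions", None)
    if regions:
        for region in regions:
            dx = getattr(region, "PhysicalDeltaX", None)
            dy = getattr(region, "PhysicalDeltaY", None)
            if dx is not None and dy is not None:
                return abs(float(dx)) * 10.0, abs(float(dy)) * 10.0  # cm -> mm
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is not None and len(spacing) == 2:
        return float(spacing[1]), float(spacing[0])  # (row, col) -> (dx, dy)
    return None


def _resample_isotropic(frames: np.ndarray, dx: float, dy: float):
    """Resample to square pixels at the finer of the two spacings."""
    from scipy.ndimage import zoom

    target = min(dx, dy)
    zy, zx = dy / target, dx / target
    frames = np.stack([zoom(f, (zy, zx), order=1) for f in frames])
    return np.clip(frames, 0.0, 1.0), target


def load_clip(
    path,
    calibration_override: Optional[float] = None,
    junction_end: str = "right",
    frame_rate_hz: Optional[float] = None,
) -> VideoClip:
    """Load a clip from DICOM or an ``.npz`` raw-array container.

    ``calibration_override`` (mm/px) wins over any in-file calibration; a
    DICOM without spacing attributes and no override raises
    :class:`CalibrationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if calibration_override is not None and not calibration_override > 0:
        raise CalibrationError("calibration_override must be positive")

    if path.suffix.lower() == ".npz":
        try:
            data = np.load(path)
            frames = data["frames"]
        except Exception as exc:
            raise FormatError(f"unreadable raw container {path}: {exc}") from exc
        mm = calibration_override
        if mm is None and "mm_per_px" in data:
            mm = float(data["mm_per_px"])
        if mm is None:
            raise CalibrationError(f"{path}: no mm_per_px in container and no override")
        fr = frame_rate_hz
        if fr is None:
            fr = float(data["frame_rate_hz"]) if "frame_rate_hz" in data else 30.0
        return VideoClip(_normalize(frames), fr, mm, source_id=path.stem,
                         junction_end=junction_end)

    # otherwise treat as DICOM
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        frames = ds.pixel_array
    except Exception as exc:
        raise FormatError(f"unreadable DICOM {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    frames = _normalize(frames)

    if calibration_override is not None:
        mm = calibration_override
    else:
        spacing = _dicom_mm_per_px(ds)
        if spacing is None:
            raise CalibrationError(
                f"{path}: DICOM has no physical-spacing attributes; "
                "pass calibration_override"
            )
        dx, dy = spacing
        if abs(dx - dy) > 0.01 * min(dx, dy):
            frames, mm = _resample_isotropic(frames, dx, dy)
        else:
            mm = (dx + dy) / 2.0
    fr = frame_rate_hz
    if fr is None:
        fr = float(getattr(ds, "CineRate", 0) or 0)
        if fr <= 0:
            ft = float(getattr(ds, "FrameTime", 0) or 0)  # ms
            fr = 1000.0 / ft if ft > 0 else 30.0
    return VideoClip(frames, fr, mm, source_id=path.stem, junction_end=junction_end)


# ---------------------------------------------------------------------------
# masks


def write_masks(seq: MaskSequence, path) -> None:
    """Write a mask sequence as a directory of 8-bit PNGs (frame_0000.png …)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(seq.masks):
        iio.imwrite(path / f"frame_{i:04d}.png", (m.astype(np.uint8) * 255))
    meta = {"aligned_to": seq.aligned_to, "n_frames": int(seq.masks.shape[0])}
    (path / "masks.json").write_text(json.dumps(meta))


def load_masks(path, expected_shape: Optional[tuple] = None) -> MaskSequence:
    """Load a PNG-per-frame mask directory; lossless round-trip with write_masks."""
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"not a mask directory: {path}")
    files = sorted(path.glob("frame_*.png"))
    if not files:
        raise FormatError(f"no frame_*.png files in {path}")
    masks = np.stack([iio.imread(f) > 127 for f in files])
    aligned_to = ""
    meta_file = path / "masks.json"
    if meta_file.exists():
        aligned_to = json.loads(meta_file.read_text()).get("aligned_to", "")
    seq = MaskSequence(masks, aligned_to=aligned_to)
    if expected_shape is not None and tuple(masks.shape) != tuple(expected_shape):
        raise AlignmentError(
            f"mask shape {masks.shape} != declared clip shape {tuple(expected_shape)}"
        )
    return seq


# ---------------------------------------------------------------------------
# reports


def write_report(report: ClipReport, path) -> None:
    """Write a clip report as JSON plus a per-frame diameter CSV.

    ``<path>.json`` holds the clip-level decision and summary numbers
    (diameters in mm, collapsibility in percent, RAP categories in mmHg);
    ``<path>.csv`` holds columns frame_index, dIVC_mm_raw, dIVC_mm_smooth.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    summary = {
        "source_id": report.source_id,
        "view_label": report.view_label,
        "quality_label": report.quality_label,
        "analyzable": report.analyzable,
        "rejection_reason": report.rejection_reason,
        "dIVC_max_mm": _round6(report.dIVC_max_mm),
        "dIVC_min_mm": _round6(report.dIVC_min_mm),
        "cIVC_pct": _round6(report.cIVC_pct),
        "rap_mmHg": report.rap_mmHg,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    idx = report.frame_index if report.frame_index is not None else []
    raw = report.dIVC_mm_raw if report.dIVC_mm_raw is not None else []
    smooth = report.dIVC_mm_smooth if report.dIVC_mm_smooth is not None else []
    df = pd.DataFrame(
        {"frame_index": idx, "dIVC_mm_raw": raw, "dIVC_mm_smooth": smooth}
    )
    df.to_csv(path.with_suffix(".csv"), index=False, float_format="%.6f")


def read_report(path) -> ClipReport:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        summary = json.load(fh)
    df = pd.read_csv(path.with_suffix(".csv"))
    rap = summary.get("rap_mmHg")
    return ClipReport(
        source_id=summary["source_id"],
        view_label=summary["view_label"],
        quality_label=summary["quality_label"],
        analyzable=summary["analyzable"],
        rejection_reason=summary.get("rejection_reason"),
        frame_index=df["frame_index"].tolist(),
        dIVC_mm_raw=df["dIVC_mm_raw"].tolist(),
        dIVC_mm_smooth=df["dIVC_mm_smooth"].tolist(),
        dIVC_max_mm=summary.get("dIVC_max_mm"),
        dIVC_min_mm=summary.get("dIVC_min_mm"),
        cIVC_pct=summary.get("cIVC_pct"),
        rap_mmHg={k: int(v) for k, v in rap.items()} if rap else None,
    )


def _round6(x):
    return None if x is None else round(float(x), 6)


def load_reference_table(path) -> pd.DataFrame:
    """Load a CSV of manual reference measurements and validate its ranges."""
    df = pd.read_csv(path)
    required = {
        "source_id", "manual_dIVC_max_mm", "manual_dIVC_min_mm",
        "manual_cIVC_pct", "manual_RAP_mmHg", "criterion",
    }
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"reference table missing columns: {sorted(missing)}")
    if (df["manual_dIVC_max_mm"] < 0).any() or (df["manual_dIVC_min_mm"] < 0).any():
        raise ValueError("negative manual diameters in reference table")
    if ((df["manual_cIVC_pct"] < 0) | (df["manual_cIVC_pct"] > 100)).any():
        raise ValueError("manual cIVC outside [0, 100] in reference table")
    allowed = {"ASE": {3, 8, 15}, "NIH": {5, 10, 15, 20}}
    for crit, sub in df.groupby("criterion"):
        if crit not in allowed:
            raise ValueError(f"unknown criterion {crit!r} in reference table")
        bad = set(sub["manual_RAP_mmHg"]) - allowed[crit]
        if bad:
            raise ValueError(f"invalid RAP values {sorted(bad)} for criterion {crit}")
    return df
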
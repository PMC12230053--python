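"""Camera method: frame assembly, marker calibration, contour width extraction.

Reconstructs a full leaf image from conveyor frames (the camera is fixed and
the belt moves the leaf through the field of view), converts pixels to
centimetres via a round reference marker of known diameter, and measures the
blade width in evenly spaced segments perpendicular to the travel axis.
Only the outer contour counts: interior holes and fissures from pest or wind
damage are filled before measuring, so defects never change reported widths.

Conventions: travel axis = image x; positions are reported from the leaf tip
(the narrower end, auto-detected); widths at segment centers, one record per
segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color, feature, filters, measure

from .shape_model import normalize_profile

__all__ = [
    "VisionConfig",
    "CalibrationMetric",
    "SegmentMeasurement",
    "LeafMeasurement",
    "CalibrationError",
    "EmptyDetectionError",
    "AssemblyError",
    "assemble_leaf_image",
    "calibrate_from_marker",
    "extract_leaf_contour",
    "leaf_mask",
    "measure_segments",
    "process_video",
]

log = logging.getLogger(__name__)

MARKER_CM = 2.47


class CalibrationError(RuntimeError):
    """No usable reference marker found in the image."""


class EmptyDetectionError(RuntimeError):
    """No leaf-like object above the area threshold."""


class AssemblyError(RuntimeError):
    """Frame-to-frame displacement could not be estimated."""


@dataclass
class VisionConfig:
    """Segmentation and preprocessing thresholds.

    Hue is HSV hue in [0, 1].  The defaults match a green leaf on an
    unsaturated background with a teal-green marker; all windows are
    adjustable for other recordings.
    """

    leaf_hue: tuple[float, float] = (0.20, 0.42)
    marker_hue: tuple[float, float] = (0.43, 0.60)
    min_saturation: float = 0.15
    min_leaf_area_px: int = 200
    min_marker_area_px: int = 30
    marker_circularity: float = 0.85
    marker_cm: float = MARKER_CM
    blur_sigma: float = 0.0  # Gaussian blur of the binary mask before contouring
    use_canny: bool = False  # optional edge-detection path
    canny_sigma: float = 2.0
    max_shift_px: int = 64  # displacement search window for assembly


@dataclass(frozen=True)
class CalibrationMetric:
    px_per_cm: float
    marker_px: float
    marker_cm: float = MARKER_CM

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")


@dataclass(frozen=True)
class SegmentMeasurement:
    index: int  # 1-based from the tip
    position_cm: float  # segment-center distance from the tip
    width_cm: float


@dataclass
class LeafMeasurement:
    segments: list[SegmentMeasurement]
    length_cm: float
    max_width_cm: float
    n_segments: int
    calibration: CalibrationMetric

    def to_frame(self, **ids) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "position_cm": [s.position_cm for s in self.segments],
                "width_cm": [s.width_cm for s in self.segments],
            }
        )
        for k, v in ids.items():
            df.insert(0, k, v)
        return df


# ---------------------------------------------------------------- segmentation


def _hsv(image: np.ndarray) -> np.ndarray:
    if image.dtype == np.uint8:
        image = image / 255.0
    return color.rgb2hsv(image)


def _hue_mask(hsv: np.ndarray, hue: tuple[float, float], min_sat: float) -> np.ndarray:
    h, s = hsv[..., 0], hsv[..., 1]
    return (h >= hue[0]) & (h <= hue[1]) & (s >= min_sat)


def leaf_mask(image: np.ndarray, cfg: VisionConfig | None = None) -> np.ndarray:
    """Filled binary mask of the largest leaf-hued object.

    Interior holes are filled (outer-edge-only measurement); among several
    candidate contours above the area threshold the largest is kept and the
    rest logged.
    """
    cfg = cfg or VisionConfig()
    raw = _hue_mask(_hsv(image), cfg.leaf_hue, cfg.min_saturation)
    labels, n = ndimage.label(raw)
    if n == 0:
        raise EmptyDetectionError("no leaf-hued pixels found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= cfg.min_leaf_area_px) + 1
    if keep.size == 0:
        raise EmptyDetectionError(
            f"no object above area threshold {cfg.min_leaf_area_px} px"
        )
    if keep.size > 1:
        log.info("leaf detection: %d candidate objects, keeping largest", keep.size)
    best = keep[np.argmax(sizes[keep - 1])]
    return ndimage.binary_fill_holes(labels == best)


def extract_leaf_contour(
    image: np.ndarray, cfg: VisionConfig | None = None
) -> np.ndarray:
    """Outer contour polygon of the leaf as an (N, 2) array of (row, col).

    Interior contours (holes, fissures) are discarded by hole-filling before
    contour extraction.  With ``use_canny`` the filled mask is smoothed and
    edge-detected first (the classical blur + edge path); the binary-mask
    path is the default.
    """
    cfg = cfg or VisionConfig()
    mask = leaf_mask(image, cfg)
    level = mask.astype(float)
    if cfg.blur_sigma > 0:
        level = filters.gaussian(level, cfg.blur_sigma)
    if cfg.use_canny:
        edges = feature.canny(level, sigma=cfg.canny_sigma)
        # close the edge ring back into a region, then contour it
        filled = ndimage.binary_fill_holes(ndimage.binary_closing(edges, iterations=2))
        level = filled.astype(float)
    contours = measure.find_contours(level, 0.5)
    if not contours:
        raise EmptyDetectionError("no contour found at the 0.5 level")
    return max(contours, key=len)


# ---------------------------------------------------------------- calibration


def calibrate_from_marker(
    image: np.ndarray, cfg: VisionConfig | None = None
) -> CalibrationMetric:
    """Detect the round reference marker and compute px/cm.

    Candidates are marker-hued regions; scanning bottom-to-top, the first
    one with circularity 4*pi*A/P^2 above the threshold is the marker.  Its
    pixel width (area-equivalent diameter) divided by the known physical
    width (2.47 cm) gives the calibration metric.
    """
    cfg = cfg or VisionConfig()
    raw = _hue_mask(_hsv(image), cfg.marker_hue, cfg.min_saturation)
    labels = measure.label(raw)
    props = [p for p in measure.regionprops(labels) if p.area >= cfg.min_marker_area_px]
    props.sort(key=lambda p: -p.centroid[0])  # bottom of the image first
    for p in props:
        if p.perimeter == 0:
            continue
        circularity = 4 * np.pi * p.area / p.perimeter**2
        if circularity >= cfg.marker_circularity:
            # area-equivalent diameter: sub-pixel accurate for a rasterized
            # disk, unlike the bounding-box width
            width_px = float(2.0 * np.sqrt(p.area / np.pi))
            return CalibrationMetric(width_px / cfg.marker_cm, width_px, cfg.marker_cm)
    raise CalibrationError(
        "no circular reference marker found: cannot convert pixels to cm "
        "(check marker hue window and circularity threshold)"
    )


# ------------------------------------------------------------------- assembly


def _foreground_profile(frame: np.ndarray, cfg: VisionConfig) -> np.ndarray:
    """Per-column count of saturated (non-background) pixels."""
    hsv = _hsv(frame)
    return (hsv[..., 1] >= cfg.min_saturation).sum(axis=0).astype(float)


def _displacement(p_prev: np.ndarray, p_cur: np.ndarray, max_shift: int) -> int | None:
    """Signed shift d maximizing the zero-mean normalized cross-correlation
    of p_cur(x) with p_prev(x - d).

    Plain correlation would favor the zero lag for smooth, wide profiles
    (larger overlap mass); the normalized form keys on the profile's shape,
    i.e. the leaf's entering and leaving edges.
    """
    w = p_prev.size
    best_d, best_score = None, -np.inf
    for d in range(-max_shift, max_shift + 1):
        if d >= 0:
            a, b = p_cur[d:], p_prev[: w - d]
        else:
            a, b = p_cur[:d], p_prev[-d:]
        if a.size < max(8, w - max_shift):
            continue
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        if denom <= 0:
            continue
        score = float(a @ b) / denom
        if score > best_score:
            best_score, best_d = score, d
    if best_d is None or best_score <= 0.2:
        return None
    return best_d


def assemble_leaf_image(
    frames: Iterable[np.ndarray],
    cfg: VisionConfig | None = None,
    belt_speed: float | None = None,
) -> np.ndarray:
    """Stitch conveyor frames into one composite containing the whole leaf.

    Frame-to-frame displacement along the travel axis is estimated by 1-D
    cross-correlation of foreground column profiles; a known belt speed
    (px/frame, positive in the travel direction) may override estimation.
    Reversed frame order is handled transparently: displacements are signed,
    so the composite is identical.  Raises AssemblyError when no displacement
    can be estimated for any adjacent pair with content.
    """
    cfg = cfg or VisionConfig()
    content: list[tuple[int, np.ndarray]] = []  # (frame index, frame with foreground)
    estimates: list[int] = []
    prev_profile: np.ndarray | None = None
    n_frames = 0
    for t, frame in enumerate(frames):
        n_frames += 1
        profile = _foreground_profile(frame, cfg)
        if prev_profile is not None and belt_speed is None:
            if prev_profile.sum() > 0 and profile.sum() > 0:
                d = _displacement(prev_profile, profile, cfg.max_shift_px)
                if d is not None and d != 0:
                    estimates.append(d)
        if profile.sum() > 0:
            content.append((t, frame))
        prev_profile = profile
    if not content:
        raise EmptyDetectionError("no frame contains foreground content")

    # The belt runs at constant speed: use the robust (median) per-pair
    # displacement for every frame interval, which also bridges intervals
    # where only background is visible.
    if belt_speed is not None:
        speed = float(belt_speed)
    elif len(content) == 1:
        speed = 0.0
    elif estimates:
        speed = float(np.median(estimates))
    else:
        raise AssemblyError(
            "displacement estimation failed for every adjacent frame pair "
            "(no overlap or no content edges)"
        )
    # frame t's window sits speed*t further back along the belt
    kept = [(int(round(-speed * t)), frame) for t, frame in content]

    h, w = kept[0][1].shape[:2]
    offs = np.array([o for o, _ in kept])
    lo = int(offs.min())
    canvas_w = int(offs.max()) + w - lo
    canvas = np.empty((h, canvas_w, 3), dtype=np.uint8)
    # background fill: the median border color of the first kept frame
    border = np.concatenate([kept[0][1][:, 0, :], kept[0][1][:, -1, :]])
    canvas[:] = np.median(border, axis=0).astype(np.uint8)
    for o, frame in kept:
        canvas[:, o - lo : o - lo + w] = frame
    log.debug("assembled %d/%d frames into %dx%d composite", len(kept), n_frames, h, canvas_w)
    return canvas


# ---------------------------------------------------------------- measurement


def _tip_on_left(mask: np.ndarray) -> bool:
    cols = np.flatnonzero(mask.any(axis=0))
    widths = mask[:, cols].sum(axis=0)
    k = max(1, len(cols) // 10)
    return widths[:k].mean() <= widths[-k:].mean()


def measure_segments(
    image_or_mask: np.ndarray,
    calibration: CalibrationMetric,
    n_segments: int = 100,
    cfg: VisionConfig | None = None,
) -> list[SegmentMeasurement]:
    """Widths at the centers of ``n_segments`` equal slices, tip to base.

    Width is the count of foreground pixels along the perpendicular at the
    segment's center column (robust to serrated edges), converted to cm via
    the calibration metric.  Exactly ``n_segments`` records are returned.
    """
    if n_segments < 3:
        raise ValueError("n_segments must be >= 3")
    if calibration is None:
        raise CalibrationError("calibration metric is required")
    if image_or_mask.ndim == 3:
        mask = leaf_mask(image_or_mask, cfg)
    else:
        mask = ndimage.binary_fill_holes(image_or_mask.astype(bool))
    cols = np.flatnonzero(mask.any(axis=0))
    if cols.size == 0:
        raise EmptyDetectionError("empty leaf mask")
    x0, x1 = cols[0], cols[-1]
    n_cols = x1 - x0 + 1
    length_cm = n_cols / calibration.px_per_cm
    tip_left = _tip_on_left(mask)

    out = []
    for i in range(1, n_segments + 1):
        frac = (i - 0.5) / n_segments  # segment center, relative tip distance
        if tip_left:
            c = x0 + frac * (n_cols - 1)
        else:
            c = x1 - frac * (n_cols - 1)
        width_px = int(mask[:, int(round(c))].sum())
        out.append(
            SegmentMeasurement(i, frac * length_cm, width_px / calibration.px_per_cm)
        )
    return out


def measure_leaf(
    image: np.ndarray,
    calibration: CalibrationMetric,
    n_segments: int = 100,
    cfg: VisionConfig | None = None,
) -> LeafMeasurement:
    segs = measure_segments(image, calibration, n_segments, cfg)
    mask = leaf_mask(image, cfg) if image.ndim == 3 else image.astype(bool)
    cols = np.flatnonzero(mask.any(axis=0))
    length_cm = (cols[-1] - cols[0] + 1) / calibration.px_per_cm
    return LeafMeasurement(
        segments=segs,
        length_cm=length_cm,
        max_width_cm=max(s.width_cm for s in segs),
        n_segments=n_segments,
        calibration=calibration,
    )


# ------------------------------------------------------------------- pipeline


def _resolve_frames(source) -> Iterable[np.ndarray]:
    if isinstance(source, (str, Path)):
        import imageio.v3 as iio

        paths = sorted(Path(source).glob("*.png"))
        if not paths:
            raise FileNotFoundError(f"no PNG frames under {source}")
        return (iio.imread(p) for p in paths)
    return source


def process_video(
    source,
    n_segments: int = 100,
    cfg: VisionConfig | None = None,
    belt_speed: float | None = None,
    cultivar: str = "",
    plant: str = "",
    rank: int = 0,
) -> tuple[LeafMeasurement, pd.DataFrame]:
    """End-to-end camera method: frames -> composite -> calibration ->
    contour -> segment widths -> profile rows.

    ``source`` may be a directory of PNG frames, a FrameSequence, or any
    iterable of RGB arrays.  Deterministic for fixed input and options.
    Stage failures propagate with the stage name attached.
    """
    cfg = cfg or VisionConfig()
    stage = "assemble"
    try:
        composite = assemble_leaf_image(_resolve_frames(source), cfg, belt_speed)
        stage = "calibrate"
        calib = calibrate_from_marker(composite, cfg)
        stage = "measure"
        leaf = measure_leaf(composite, calib, n_segments, cfg)
    except Exception as e:
        raise type(e)(f"[stage: {stage}] {e}") from e
    rows = leaf.to_frame(
        cultivar=cultivar, plant=plant, rank=rank, method="camera"
    )
    return leaf, rows


def profile_from_measurement(leaf: LeafMeasurement, **ids):
    """Normalize a LeafMeasurement into a relative WidthProfile for fitting."""
    pos = np.array([s.position_cm for s in leaf.segments])
    wid = np.array([s.width_cm for s in leaf.segments])
    return normalize_profile(pos, wid, **ids)
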
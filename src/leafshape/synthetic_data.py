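"""Ground-truth-known synthetic inputs: leaves, conveyor frames, weather.

Emulates the measurement setting of a belt-fed leaf-area meter with an
overhead camera: a single flattened maize leaf travels across the field of
view on a transparent conveyor, preceded by a round reference marker of known
physical diameter (2.47 cm) used for pixel-to-cm calibration.  Silhouettes
are drawn from the sine leaf-shape family, so every rendered pixel has a
known analytic counterpart; the generator also produces the sparse manual
width samplings used for method comparison and daily weather series that
drive thermal-time development.

Colors follow a simple hue model: gray background, green leaf, teal-green
marker, distinguishable by hue/saturation thresholds (the real method is
validated by green/non-green contrast).  Leaves are rendered flat — the real
device flattens them with pressure rollers — with no perspective distortion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .shape_model import ShapeParams, WidthProfile, normalize_profile

__all__ = [
    "Defect",
    "SyntheticLeafSpec",
    "SceneSpec",
    "WeatherSeries",
    "FrameSequence",
    "LEAF_RGB",
    "MARKER_RGB",
    "BACKGROUND_RGB",
    "MARKER_DIAMETER_CM",
    "make_leaf_mask",
    "render_video_frames",
    "sample_manual_points",
    "make_weather",
    "random_leaf_specs",
]

MARKER_DIAMETER_CM = 2.47

# Rendering palette (uint8 RGB).  Background is unsaturated; leaf and marker
# occupy disjoint hue windows (~0.33 vs ~0.47 in HSV).
BACKGROUND_RGB = (204, 204, 204)
LEAF_RGB = (60, 150, 60)
MARKER_RGB = (40, 170, 150)


@dataclass(frozen=True)
class Defect:
    """Interior hole (pest/wind damage): circle strictly inside the blade.

    position_rel : relative distance from the tip along the blade, in (0, 1)
    radius_cm    : hole radius
    offset_rel   : lateral offset as a fraction of the local half-width
    """

    position_rel: float
    radius_cm: float
    offset_rel: float = 0.0


@dataclass
class SyntheticLeafSpec:
    length_cm: float
    max_width_cm: float
    shape: ShapeParams
    defects: tuple[Defect, ...] = ()
    edge_noise_sd: float = 0.0  # px, jitter of the outline half-width
    rank: int = 1
    cultivar: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.max_width_cm <= 0:
            raise ValueError("leaf dimensions must be positive")
        if self.max_width_cm >= self.length_cm:
            raise ValueError("max_width_cm must be smaller than length_cm")


@dataclass
class SceneSpec:
    """Conveyor recording geometry (camera fixed, belt moves objects in +x)."""

    px_per_cm: float = 20.0
    frame_size: tuple[int, int] = (1920, 1080)  # (width, height) px
    fps: int = 60
    duration_s: float = 30.0
    belt_speed: float = 4.0  # px per frame
    marker_diameter_cm: float = MARKER_DIAMETER_CM
    noise_sd: float = 0.0  # intensity noise, uint8 counts
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class WeatherSeries:
    """Daily (tmin, tmax) in deg C, used for growing-degree-day accumulation."""

    tmin: np.ndarray
    tmax: np.ndarray
    start_day: int = 1

    def __post_init__(self) -> None:
        self.tmin = np.asarray(self.tmin, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        if self.tmin.size == 0 or self.tmin.size != self.tmax.size:
            raise ValueError("tmin and tmax must be equal-length, non-empty")
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax must be >= tmin for every day")

    def __len__(self) -> int:
        return int(self.tmin.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": np.arange(self.start_day, self.start_day + len(self)),
                "tmin": self.tmin,
                "tmax": self.tmax,
            }
        )


def make_leaf_mask(
    spec: SyntheticLeafSpec, px_per_cm: float
) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterize a leaf silhouette; return (binary mask, ground-truth table).

    The mask has the tip at column 0 and the base at the last column; the
    midrib runs horizontally through the vertical center.  The ground-truth
    table lists the *outer* width at every column (``column_px, width_px,
    width_cm``) measured on the silhouette before defect insertion, so
    interior holes never change it.
    """
    n_cols = int(round(spec.length_cm * px_per_cm))
    w_px = spec.max_width_cm * px_per_cm
    if w_px < 8:
        raise ValueError(
            f"resolution too coarse: max width {w_px:.1f} px < 8 px "
            f"({spec.max_width_cm} cm at {px_per_cm} px/cm)"
        )
    n_rows = int(np.ceil(w_px)) + 4
    rng = np.random.default_rng(spec.seed)

    # half-width of the outline at every column center, in px
    l_rel = (np.arange(n_cols) + 0.5) / n_cols
    w_rel = np.sin(np.pi * l_rel / (2.0 * spec.shape.a)) ** spec.shape.alpha
    half = 0.5 * w_px * w_rel
    if spec.edge_noise_sd > 0:
        half = np.maximum(0.0, half + rng.normal(0.0, spec.edge_noise_sd, n_cols))

    cy = (n_rows - 1) / 2.0
    rows = np.arange(n_rows)[:, None]
    outline = np.abs(rows - cy) < half[None, :]

    width_px = outline.sum(axis=0)
    truth = pd.DataFrame(
        {
            "column_px": np.arange(n_cols),
            "width_px": width_px,
            "width_cm": width_px / px_per_cm,
        }
    )

    mask = outline.copy()
    for d in spec.defects:
        cx = d.position_rel * n_cols
        local_half = np.interp(cx, np.arange(n_cols) + 0.5, half)
        cyd = cy + d.offset_rel * local_half
        r = d.radius_cm * px_per_cm
        if r >= local_half:
            raise ValueError("defect not strictly interior to the silhouette")
        cols = np.arange(n_cols)[None, :]
        hole = (rows - cyd) ** 2 + (cols - cx) ** 2 < r**2
        mask &= ~hole
    return mask, truth


class FrameSequence:
    """Lazy, indexable sequence of conveyor frames (uint8 RGB, H x W x 3).

    Frames are rendered on demand from a pre-composed world strip, so a 30 s
    recording never has to be materialized at once.  ``offsets_px[t]`` is the
    ground-truth world-x coordinate of frame t's left edge (it decreases by
    ``belt_speed`` per frame: the window sweeps backwards over the strip,
    which is how objects move forward across a fixed camera).
    """

    def __init__(self, strip: np.ndarray, scene: SceneSpec):
        self._strip = strip
        self.scene = scene
        fw, fh = scene.frame_size
        if strip.shape[0] != fh:
            raise ValueError("strip height must equal frame height")
        self.n_frames = scene.n_frames
        # at t=0 the leading content edge (strip end) sits at screen x=0
        self.offsets_px = strip.shape[1] - scene.belt_speed * np.arange(self.n_frames)

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, t: int) -> np.ndarray:
        if t < 0:
            t += self.n_frames
        if not (0 <= t < self.n_frames):
            raise IndexError(t)
        fw, fh = self.scene.frame_size
        frame = np.empty((fh, fw, 3), dtype=np.uint8)
        frame[:] = BACKGROUND_RGB
        x0 = int(round(self.offsets_px[t]))
        s0, s1 = max(0, x0), min(self._strip.shape[1], x0 + fw)
        if s1 > s0:
            frame[:, s0 - x0 : s1 - x0] = self._strip[:, s0:s1]
        if self.scene.noise_sd > 0:
            rng = np.random.default_rng((self.scene.seed, t))
            noise = rng.normal(0.0, self.scene.noise_sd, frame.shape)
            frame = np.clip(frame.astype(float) + noise, 0, 255).astype(np.uint8)
        return frame

    def __iter__(self):
        return (self[t] for t in range(self.n_frames))

    def save_png(self, out_dir: str | Path) -> list[Path]:
        import imageio.v3 as iio

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for t in range(self.n_frames):
            p = out_dir / f"frame_{t:05d}.png"
            iio.imwrite(p, self[t])
            paths.append(p)
        return paths


def render_video_frames(
    mask: np.ndarray, scene: SceneSpec
) -> FrameSequence:
    """Compose the world strip (marker leading the leaf, tip first) and wrap
    it in a lazy frame sequence.

    The marker is a single filled circle of distinct hue placed ahead of the
    leaf along the travel direction and low in the frame, so that a detector
    scanning bottom-to-top meets it first.  Raises if the leaf does not fit
    the frame height or the belt is stationary.
    """
    if scene.belt_speed < 1:
        raise ValueError("belt_speed must be >= 1 px/frame")
    fw, fh = scene.frame_size
    lh, lw = mask.shape
    if lh > fh:
        raise ValueError(f"leaf height {lh} px exceeds frame height {fh} px")
    d_px = scene.marker_diameter_cm * scene.px_per_cm
    gap = int(round(4 * scene.px_per_cm))
    margin = int(round(2 * scene.px_per_cm))
    strip_w = margin + lw + gap + int(np.ceil(d_px)) + margin
    strip = np.empty((fh, strip_w, 3), dtype=np.uint8)
    strip[:] = BACKGROUND_RGB

    # leaf: tip toward larger x (leads after the marker), vertically centered
    y0 = (fh - lh) // 2
    leaf = np.flip(mask, axis=1)  # tip now at the right edge of the block
    strip[y0 : y0 + lh, margin : margin + lw][leaf] = LEAF_RGB

    # marker: ahead of the tip, low in the frame
    mcx = margin + lw + gap + d_px / 2.0
    mcy = fh - margin - d_px / 2.0
    if mcy - d_px / 2.0 < 0:
        raise ValueError("marker does not fit the frame")
    yy = np.arange(fh)[:, None]
    xx = np.arange(strip_w)[None, :]
    marker = (xx - mcx) ** 2 + (yy - mcy) ** 2 < (d_px / 2.0) ** 2
    strip[marker] = MARKER_RGB
    return FrameSequence(strip, scene)


def sample_manual_points(
    truth: pd.DataFrame,
    n_points: int,
    px_per_cm: float,
    **ids,
) -> WidthProfile:
    """Sparse ruler-style sampling of a ground-truth width table.

    ``n_points`` evenly spaced segment points from tip to base along the
    midrib (6..12, as in destructive manual protocols); the first point is
    the tip with width 0 by convention.  Returns a normalized profile.
    """
    if not (6 <= n_points <= 12):
        raise ValueError(f"n_points must be in [6, 12], got {n_points}")
    length_cm = len(truth) / px_per_cm
    pos_cm = np.linspace(0.0, length_cm, n_points)
    col_centers = (truth["column_px"].to_numpy() + 0.5) / px_per_cm
    widths = np.interp(pos_cm, col_centers, truth["width_cm"].to_numpy())
    widths[0] = 0.0
    return normalize_profile(pos_cm, widths, **ids)


def make_weather(
    n_days: int,
    mode: str = "constant",
    tmin: float = 12.0,
    tmax: float = 20.0,
    amplitude: float = 6.0,
    noise_sd: float = 0.0,
    period_days: float = 365.0,
    seed: int = 0,
) -> WeatherSeries:
    """Daily weather series driving thermal time.

    ``constant`` repeats (tmin, tmax) every day; ``sinusoidal`` modulates both
    by a seasonal sine of the given amplitude plus optional Gaussian noise.
    Reproducible for a fixed seed.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if tmax < tmin:
        raise ValueError("tmax must be >= tmin")
    days = np.arange(n_days, dtype=float)
    if mode == "constant":
        lo = np.full(n_days, float(tmin))
        hi = np.full(n_days, float(tmax))
    elif mode == "sinusoidal":
        rng = np.random.default_rng(seed)
        season = amplitude * np.sin(2 * np.pi * days / period_days)
        lo = tmin + season + rng.normal(0, noise_sd, n_days)
        hi = tmax + season + rng.normal(0, noise_sd, n_days)
        hi = np.maximum(hi, lo)
    else:
        raise ValueError(f"unknown weather mode {mode!r}")
    return WeatherSeries(lo, hi)


def random_leaf_specs(
    n: int,
    seed: int,
    length_range: tuple[float, float] = (35.0, 70.0),
    lw_ratio_range: tuple[float, float] = (7.0, 12.0),
    alpha_range: tuple[float, float] = (0.55, 1.2),
    a_range: tuple[float, float] = (0.55, 0.95),
) -> list[SyntheticLeafSpec]:
    """Random valid leaf specs spanning the shape range seen in maize."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        length = rng.uniform(*length_range)
        width = length / rng.uniform(*lw_ratio_range)
        shape = ShapeParams(rng.uniform(*alpha_range), rng.uniform(*a_range))
        specs.append(
            SyntheticLeafSpec(
                length_cm=length,
                max_width_cm=width,
                shape=shape,
                rank=i + 1,
                cultivar=f"synthetic-{i:02d}",
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs
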
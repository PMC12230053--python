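"""Canopy light-interception experiment: development, geometry, ray tracing.

Re-creates a maize light-capture simulation at desk scale: plants develop by
thermal time (growing degree days above a base temperature, one new leaf per
phyllochron), organs expand along a sigmoid, each leaf is meshed as 100
parallelograms whose widths follow the sine leaf-shape function with the
width rescaled so that blade area is identical across shapes, and the canopy
(6 rows x 14 plants, 0.75 m rows, 9 plants/m2) is illuminated by an hourly
course of direct sun for a given latitude and day of year plus 72 uniform
diffuse sky sources.  Monte-Carlo ray tracing with Lambertian leaf
reflection and transmission yields absorbed fractions per organ, rank and
plant; reporting is restricted to the central 2 x 4 plants to avoid border
effects.

The headline experiment is a 6 x 6 grid over shape parameters alpha and a in
{0.5 ... 1.0 step 0.1}: canopy interception per cell, normalized by the grid
maximum, isolates the pure effect of leaf shape at constant leaf area.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _mc
from .shape_model import ShapeParams, adjusted_width, area_coefficient
from .synthetic_data import WeatherSeries, make_weather

__all__ = [
    "DevelopmentConfig",
    "PlantArchitecture",
    "CanopyConfig",
    "LightConfig",
    "CanopyScene",
    "LightResult",
    "GridResult",
    "thermal_time",
    "expansion_fraction",
    "build_leaf_mesh",
    "build_plant_geometry",
    "build_canopy_scene",
    "sky_sources",
    "beam_source",
    "trace_light",
    "run_shape_grid",
    "default_weather",
    "GRID_VALUES",
]

GRID_VALUES = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


# -------------------------------------------------------------------- configs


@dataclass(frozen=True)
class DevelopmentConfig:
    """Thermal-time development parameters (degree days, deg C)."""

    t_base: float = 8.0
    phyllochron: float = 30.0
    k: float = 0.05  # sigmoid steepness, 1/degC-day
    t_half: float = 40.0  # degC-days to half of final size
    final_leaf_number: int = 17

    def __post_init__(self) -> None:
        if min(self.t_base, self.phyllochron, self.k, self.t_half) <= 0:
            raise ValueError("development parameters must be positive")
        if self.final_leaf_number < 1:
            raise ValueError("final_leaf_number must be >= 1")


def _default_lengths(n_ranks: int) -> np.ndarray:
    """Final blade length per rank (m): rising to a mid-canopy maximum then
    easing toward the flag leaf — the generic maize rank profile used when
    no measured per-rank table is supplied."""
    ranks = np.arange(1, n_ranks + 1)
    peak_rank = min(12, n_ranks)
    lengths = np.where(
        ranks <= peak_rank,
        0.25 + (0.95 - 0.25) * (ranks - 1) / max(peak_rank - 1, 1),
        0.95 + (0.80 - 0.95) * (ranks - peak_rank) / max(n_ranks - peak_rank, 1),
    )
    return lengths.astype(float)


@dataclass
class PlantArchitecture:
    """Per-rank dimensions and pose, identical for every plant in a scene."""

    final_length_m: np.ndarray = None  # (n_ranks,)
    lw_ratio: np.ndarray = None  # (n_ranks,)
    internode_length_m: float = 0.10
    internode_radius_m: float = 0.01
    divergence_deg: float = 160.0
    inclination_deg: float = 40.0  # midrib angle from horizontal at insertion
    n_panels: int = 100

    def __post_init__(self) -> None:
        if self.final_length_m is None:
            self.final_length_m = _default_lengths(17)
        self.final_length_m = np.asarray(self.final_length_m, dtype=float)
        if self.lw_ratio is None:
            self.lw_ratio = np.full(self.final_length_m.size, 10.0)
        self.lw_ratio = np.asarray(self.lw_ratio, dtype=float)
        if self.lw_ratio.size != self.final_length_m.size:
            raise ValueError("per-rank tables must have equal length")
        if np.any(self.final_length_m <= 0) or np.any(self.lw_ratio <= 0):
            raise ValueError("per-rank dimensions must be positive")

    @property
    def n_ranks(self) -> int:
        return int(self.final_length_m.size)


@dataclass(frozen=True)
class CanopyConfig:
    rows: int = 6
    plants_per_row: int = 14
    row_spacing_m: float = 0.75
    plant_spacing_m: float = 0.15
    reporting_rows: int = 2
    reporting_plants: int = 4

    @property
    def density(self) -> float:
        return 1.0 / (self.row_spacing_m * self.plant_spacing_m)

    @property
    def n_plants(self) -> int:
        return self.rows * self.plants_per_row


@dataclass(frozen=True)
class LightConfig:
    """Radiation and tracing parameters.

    Ray count and reflection depth default to desk-scale values
    (2e5 rays, depth 5); both can be raised toward the reference setting of
    2e8 rays and depth 30 when runtime allows.
    """

    n_rays: int = 200_000
    reflection_depth: int = 5
    diffuse_fraction: float = 0.2
    n_diffuse_rings: int = 6
    n_diffuse_azimuths: int = 12
    latitude_deg: float = 48.714
    day_of_year: int = 180
    leaf_reflectance: float = 0.0923
    leaf_transmittance: float = 0.0127
    seed: int = 0

    def __post_init__(self) -> None:
        if self.leaf_reflectance + self.leaf_transmittance >= 1:
            raise ValueError("reflectance + transmittance must be < 1")
        if not (0 <= self.diffuse_fraction <= 1):
            raise ValueError("diffuse_fraction must be in [0, 1]")


# ---------------------------------------------------------------- development


def default_weather(n_days: int = 81) -> WeatherSeries:
    """Constant 12/20 deg C days: 8 degC-day per day above the 8 deg C base,
    a plain mid-season regime under which all 17 ranks have appeared and
    nearly fully expanded by day 81."""
    return make_weather(n_days, "constant", tmin=12.0, tmax=20.0)


def thermal_time(
    weather: WeatherSeries, cfg: DevelopmentConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative growing degree days and per-rank leaf appearance days.

    Daily GDD = max(0, (tmin + tmax)/2 - t_base).  Leaf rank n appears on the
    first (1-based) day whose cumulative GDD reaches n * phyllochron, capped
    at final_leaf_number; ranks never reached get appearance day -1.
    """
    if len(weather) == 0:
        raise ValueError("weather series is empty")
    gdd = np.maximum(0.0, 0.5 * (weather.tmin + weather.tmax) - cfg.t_base)
    cum = np.cumsum(gdd)
    appear = np.full(cfg.final_leaf_number, -1, dtype=int)
    for n in range(1, cfg.final_leaf_number + 1):
        idx = np.searchsorted(cum, n * cfg.phyllochron)
        if idx < len(cum):
            appear[n - 1] = idx + 1  # 1-based day
    return cum, appear


def expansion_fraction(t: float | np.ndarray, cfg: DevelopmentConfig):
    """Sigmoid fraction of final organ size at thermal age t (degC-days)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("thermal age must be >= 0")
    f = 1.0 / (1.0 + np.exp(-cfg.k * (t - cfg.t_half)))
    return float(f) if f.ndim == 0 else f


# ------------------------------------------------------------------- geometry


def build_leaf_mesh(
    length_m: float,
    lw_ratio: float,
    shape: ShapeParams,
    n_panels: int = 100,
    inclination_deg: float = 40.0,
    azimuth_deg: float = 0.0,
    insertion_height_m: float = 0.0,
):
    """Mesh one blade as parallelogram panels following the shape function.

    Panel i (1 = tip) has width adjusted_width * relative_width(i/n, shape),
    evaluated at the same nodes as the 100-step area coefficient, so total
    mesh area equals length * adjusted_width * c(shape) exactly — and hence
    0.75 * length^2 / LWRatio for every shape: the area-normalization
    contract.  The midrib leaves the insertion at ``inclination_deg`` above
    horizontal and droops parabolically to horizontal at the tip.

    Returns (p0, e1, e2) arrays of shape (n_panels, 3), base-to-tip order.
    """
    if length_m <= 0 or lw_ratio <= 0:
        raise ValueError("length and LWRatio must be positive")
    # Riemann coefficient at the panel nodes themselves, so that the mesh
    # area L * w_max * mean(w_rel) is exactly 0.75 * L^2 / LWRatio for every
    # shape (and n_panels may be any size >= 1)
    nodes = np.arange(1, n_panels + 1) / n_panels
    c = float(np.mean(np.sin(np.pi * nodes / (2.0 * shape.a)) ** shape.alpha))
    w_max = adjusted_width(length_m, lw_ratio, c)

    # midrib nodes, base (s=0) to tip (s=L); angle tapers linearly with s
    theta0 = np.radians(inclination_deg)
    s_nodes = np.linspace(0.0, length_m, n_panels + 1)
    s_mid = 0.5 * (s_nodes[:-1] + s_nodes[1:])
    theta_mid = theta0 * (1.0 - s_mid / length_m)
    ds = length_m / n_panels
    az = np.radians(azimuth_deg)
    u = np.array([np.cos(az), np.sin(az), 0.0])
    v = np.array([-np.sin(az), np.cos(az), 0.0])
    run = np.cumsum(np.cos(theta_mid) * ds)
    rise = np.cumsum(np.sin(theta_mid) * ds)
    nodes = np.zeros((n_panels + 1, 3))
    nodes[1:] = run[:, None] * u[None, :]
    nodes[1:, 2] = rise
    nodes[:, 2] += insertion_height_m

    # width per base-indexed panel j: tip index i = n - j, node l_i = i/n from tip
    j = np.arange(n_panels)  # base panel index 0..n-1
    l_tip = (n_panels - j) / n_panels  # 1.0 at base panel 0 ... 1/n at tip panel
    w_rel = np.sin(np.pi * l_tip / (2.0 * shape.a)) ** shape.alpha
    widths = w_max * w_rel

    e1 = nodes[1:] - nodes[:-1]
    e2 = widths[:, None] * v[None, :]
    p0 = nodes[:-1] - 0.5 * e2
    return p0, e1, e2


def build_plant_geometry(
    day: int,
    weather: WeatherSeries,
    arch: PlantArchitecture,
    dev: DevelopmentConfig,
    shapes: ShapeParams | list[ShapeParams],
):
    """Geometry of one plant at a given (1-based) day after sowing.

    Returns a dict with parallelogram arrays (p0, e1, e2, quad_rank),
    stem cylinder segments (z0, z1, rank, radius), and per-rank leaf areas.
    Rank r (1-based) inserts at the top of internode r; organ r starts
    expanding on its appearance day.
    """
    if isinstance(shapes, ShapeParams):
        shapes = [shapes] * arch.n_ranks
    if len(shapes) != arch.n_ranks:
        raise ValueError(
            f"need one ShapeParams per rank ({arch.n_ranks}), got {len(shapes)}"
        )
    n_ranks = min(arch.n_ranks, dev.final_leaf_number)
    cum, appear = thermal_time(weather, dev)
    if day < 1 or day > len(weather):
        raise ValueError(f"day {day} outside the weather series")
    cum_today = cum[day - 1]

    p0s, e1s, e2s, ranks = [], [], [], []
    cz0, cz1, cranks = [], [], []
    leaf_area = np.zeros(n_ranks)
    z = 0.0
    for r in range(1, n_ranks + 1):
        d_app = appear[r - 1]
        if d_app < 0 or d_app > day:
            continue
        age = cum_today - cum[d_app - 1]
        f = expansion_fraction(age, dev)
        ilen = arch.internode_length_m * f
        cz0.append(z)
        cz1.append(z + ilen)
        cranks.append(r)
        z += ilen
        length = arch.final_length_m[r - 1] * f
        shape = shapes[r - 1]
        p0, e1, e2 = build_leaf_mesh(
            length,
            arch.lw_ratio[r - 1],
            shape,
            n_panels=arch.n_panels,
            inclination_deg=arch.inclination_deg,
            azimuth_deg=(r - 1) * arch.divergence_deg,
            insertion_height_m=z,
        )
        p0s.append(p0)
        e1s.append(e1)
        e2s.append(e2)
        ranks.append(np.full(arch.n_panels, r, dtype=np.int64))
        leaf_area[r - 1] = 0.75 * length**2 / arch.lw_ratio[r - 1]

    if p0s:
        p0 = np.concatenate(p0s)
        e1 = np.concatenate(e1s)
        e2 = np.concatenate(e2s)
        quad_rank = np.concatenate(ranks)
    else:
        p0 = np.zeros((0, 3))
        e1 = np.zeros((0, 3))
        e2 = np.zeros((0, 3))
        quad_rank = np.zeros(0, dtype=np.int64)
    return {
        "p0": p0,
        "e1": e1,
        "e2": e2,
        "quad_rank": quad_rank,
        "cyl_z0": np.asarray(cz0, dtype=float),
        "cyl_z1": np.asarray(cz1, dtype=float),
        "cyl_rank": np.asarray(cranks, dtype=np.int64),
        "cyl_radius": arch.internode_radius_m,
        "leaf_area": leaf_area,
        "height": z,
    }


@dataclass
class CanopyScene:
    """Instanced scene: one plant's primitives plus grid translations."""

    p0: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    quad_rank: np.ndarray
    cyl_z0: np.ndarray
    cyl_z1: np.ndarray
    cyl_rank: np.ndarray
    cyl_radius: float
    offsets: np.ndarray  # (n_inst, 3)
    reporting: np.ndarray  # (n_inst,) bool
    domain: tuple[float, float, float, float]  # x0, x1, y0, y1 ground rect
    reporting_area_m2: float
    n_ranks: int
    leaf_area_per_plant: float
    day: int = 0

    @property
    def z_top(self) -> float:
        if self.p0.size:
            z = max(
                float(self.p0[:, 2].max()),
                float((self.p0 + self.e1)[:, 2].max()),
            )
        else:
            z = float(self.cyl_z1.max()) if self.cyl_z1.size else 0.0
        return z + 0.05

    @property
    def n_primitives(self) -> int:
        return int(self.p0.shape[0] + self.cyl_z0.size) * self.offsets.shape[0]


def build_canopy_scene(
    day: int,
    weather: WeatherSeries,
    arch: PlantArchitecture | None = None,
    canopy: CanopyConfig | None = None,
    dev: DevelopmentConfig | None = None,
    shapes: ShapeParams | list[ShapeParams] = ShapeParams(0.85, 0.70),
) -> CanopyScene:
    """Place identical plants on the planting grid at the given day.

    Reporting is restricted to the central ``reporting_rows x
    reporting_plants`` block; the ground domain is the full planted
    footprint.
    """
    arch = arch or PlantArchitecture()
    canopy = canopy or CanopyConfig()
    dev = dev or DevelopmentConfig()
    geo = build_plant_geometry(day, weather, arch, dev, shapes)

    rs, ps = canopy.row_spacing_m, canopy.plant_spacing_m
    xs = (np.arange(canopy.rows) + 0.5) * rs
    ys = (np.arange(canopy.plants_per_row) + 0.5) * ps
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    offsets = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])

    r0 = (canopy.rows - canopy.reporting_rows) // 2
    p0_ = (canopy.plants_per_row - canopy.reporting_plants) // 2
    rep_rows = np.arange(r0, r0 + canopy.reporting_rows)
    rep_plants = np.arange(p0_, p0_ + canopy.reporting_plants)
    rep = np.zeros((canopy.rows, canopy.plants_per_row), dtype=bool)
    rep[np.ix_(rep_rows, rep_plants)] = True

    return CanopyScene(
        p0=geo["p0"],
        e1=geo["e1"],
        e2=geo["e2"],
        quad_rank=geo["quad_rank"],
        cyl_z0=geo["cyl_z0"],
        cyl_z1=geo["cyl_z1"],
        cyl_rank=geo["cyl_rank"],
        cyl_radius=geo["cyl_radius"],
        offsets=offsets,
        reporting=rep.ravel(),
        domain=(0.0, canopy.rows * rs, 0.0, canopy.plants_per_row * ps),
        reporting_area_m2=canopy.reporting_rows * rs * canopy.reporting_plants * ps,
        n_ranks=min(arch.n_ranks, dev.final_leaf_number),
        leaf_area_per_plant=float(geo["leaf_area"].sum()),
        day=day,
    )


# ------------------------------------------------------------------------ sky


def _solar_position(latitude_deg: float, doy: int, hour: float):
    """Solar elevation and azimuth (radians) from the standard declination
    delta = 23.45 deg * sin(2*pi*(284 + doy)/365) and the hour angle."""
    phi = np.radians(latitude_deg)
    delta = np.radians(23.45) * np.sin(2 * np.pi * (284 + doy) / 365.0)
    h = np.radians(15.0 * (hour - 12.0))
    sin_e = np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(h)
    e = np.arcsin(np.clip(sin_e, -1, 1))
    az = np.arctan2(
        np.sin(h), np.cos(h) * np.sin(phi) - np.tan(delta) * np.cos(phi)
    )  # 0 = south
    return e, az


def sky_sources(cfg: LightConfig) -> tuple[np.ndarray, np.ndarray]:
    """Direct (hourly) plus diffuse (ring x azimuth) sources.

    Returns (directions, weights): unit propagation vectors (downward, z<0)
    and weights summing to 1.  Direct weights follow sin(elevation) over the
    daylight hours (horizontal irradiance of a constant-intensity beam),
    scaled to 1 - diffuse_fraction; the diffuse sky has uniform radiance
    split over ``n_diffuse_rings`` elevation rings x ``n_diffuse_azimuths``
    directions, scaled to diffuse_fraction.
    """
    dirs, wts = [], []
    for hour in np.arange(0.5, 24.0, 1.0):
        e, az = _solar_position(cfg.latitude_deg, cfg.day_of_year, hour)
        if e <= 0:
            continue
        d = np.array(
            [-np.cos(e) * np.cos(az), -np.cos(e) * np.sin(az), -np.sin(e)]
        )
        dirs.append(d)
        wts.append(np.sin(e))
    wts = np.asarray(wts, dtype=float)
    wts *= (1.0 - cfg.diffuse_fraction) / wts.sum()
    dirs = list(dirs)
    wts = list(wts)

    nr, na = cfg.n_diffuse_rings, cfg.n_diffuse_azimuths
    edges = np.linspace(0.0, np.pi / 2, nr + 1)  # elevation ring edges
    ring_w = np.sin(edges[1:]) ** 2 - np.sin(edges[:-1]) ** 2  # uniform radiance
    centers = 0.5 * (edges[:-1] + edges[1:])
    dw = []
    dd = []
    for e, rw in zip(centers, ring_w):
        for azm in (np.arange(na) + 0.5) * 2 * np.pi / na:
            dd.append(
                np.array(
                    [-np.cos(e) * np.cos(azm), -np.cos(e) * np.sin(azm), -np.sin(e)]
                )
            )
            dw.append(rw / na)
    dw = np.asarray(dw)
    dw *= cfg.diffuse_fraction / dw.sum()
    dirs.extend(dd)
    wts.extend(dw.tolist())
    return np.asarray(dirs), np.asarray(wts)


def beam_source(zenith_deg: float = 0.0, azimuth_deg: float = 0.0):
    """A single collimated source (for controlled transport experiments)."""
    z = np.radians(zenith_deg)
    a = np.radians(azimuth_deg)
    d = np.array([np.sin(z) * np.cos(a), np.sin(z) * np.sin(a), -np.cos(z)])
    return d[None, :], np.array([1.0])


# -------------------------------------------------------------------- tracing


@dataclass
class LightResult:
    """Absorbed radiant energy per organ, rank and plant from one run.

    Energies are in units of (incoming horizontal irradiance x m2); dividing
    by a ground area gives an interception fraction.
    """

    absorbed_leaf: np.ndarray  # (n_inst, n_ranks + 1), col 0 unused
    absorbed_internode: np.ndarray
    soil: float
    escaped: float
    truncated: float
    emitted: float
    reporting: np.ndarray
    reporting_area_m2: float

    @property
    def canopy_interception(self) -> float:
        """Fraction of light incoming on the reporting ground area that is
        absorbed by the reporting plants' leaves (daily, all sources)."""
        return float(
            self.absorbed_leaf[self.reporting].sum() / self.reporting_area_m2
        )

    @property
    def rank_interception(self) -> np.ndarray:
        per_rank = self.absorbed_leaf[self.reporting].sum(axis=0)
        return per_rank[1:] / self.reporting_area_m2

    @property
    def absorbed_fraction(self) -> float:
        """Scene-wide fraction of emitted energy absorbed by leaves."""
        return float(self.absorbed_leaf.sum() / self.emitted)

    def energy_balance(self) -> tuple[float, float]:
        total = (
            self.absorbed_leaf.sum()
            + self.absorbed_internode.sum()
            + self.soil
            + self.escaped
            + self.truncated
        )
        return float(total), float(self.emitted)


def _launch_rects(scene: CanopyScene, dirs: np.ndarray, z_top: float):
    """Per-source horizontal launch rectangles at the scene top.

    All sources launch over the planted footprint: incoming radiation is the
    flux through the stand's top plane.  The surrounding field is dark and
    the side faces are open (rays leaving the stand escape); reporting on the
    central plants keeps the resulting border effects out of the summary
    statistics.
    """
    x0d, x1d, y0d, y1d = scene.domain
    n = dirs.shape[0]
    lx0 = np.full(n, x0d)
    ly0 = np.full(n, y0d)
    lw = np.full(n, x1d - x0d)
    lh = np.full(n, y1d - y0d)
    return lx0, ly0, lw, lh


def trace_light(
    scene: CanopyScene,
    cfg: LightConfig,
    sources: tuple[np.ndarray, np.ndarray] | None = None,
    use_bvh: bool = True,
) -> LightResult:
    """Monte-Carlo transport of the source set through the scene.

    Per leaf hit the ray reflects with probability ``leaf_reflectance``
    (Lambertian, incidence side), transmits with ``leaf_transmittance``
    (Lambertian, far side), else is absorbed; stem hits and the soil absorb
    fully; paths are truncated after ``reflection_depth`` scattering events.
    Deterministic for a fixed seed.
    """
    if scene.p0.shape[0] == 0 and scene.cyl_z0.size == 0:
        raise ValueError("scene has no geometry")
    if cfg.n_rays < 10_000:
        raise ValueError("n_rays must be >= 1e4")
    dirs, wts = sources if sources is not None else sky_sources(cfg)
    dirs = np.ascontiguousarray(dirs, dtype=float)
    wts = np.asarray(wts, dtype=float)
    if np.any(dirs[:, 2] >= 0):
        raise ValueError("source directions must point downward")

    z_top = scene.z_top
    lx0, ly0, lw, lh = _launch_rects(scene, dirs, z_top)
    n_s = np.maximum(1, np.round(cfg.n_rays * wts / wts.sum()).astype(np.int64))
    # energy per ray: weight * launch area / rays  (unit horizontal flux)
    e_s = wts * lw * lh / n_s

    corners = scene.p0[:, None, :] + np.stack(
        [
            np.zeros_like(scene.e1),
            scene.e1,
            scene.e2,
            scene.e1 + scene.e2,
        ],
        axis=1,
    )
    if scene.p0.shape[0]:
        local_min = corners.reshape(-1, 3).min(axis=0)
        local_max = corners.reshape(-1, 3).max(axis=0)
    else:
        local_min = np.zeros(3)
        local_max = np.zeros(3)
    if scene.cyl_z0.size:
        r = scene.cyl_radius
        local_min = np.minimum(local_min, [-r, -r, float(scene.cyl_z0.min())])
        local_max = np.maximum(local_max, [r, r, float(scene.cyl_z1.max())])
    inst_min = scene.offsets + local_min
    inst_max = scene.offsets + local_max

    nrm = np.cross(scene.e1, scene.e2)
    norms = np.linalg.norm(nrm, axis=1, keepdims=True)
    nrm = nrm / np.where(norms > 0, norms, 1.0)

    bvh = _mc.build_bvh(scene.p0, scene.e1, scene.e2)
    n_slots = scene.n_ranks + 1
    abs_leaf = np.zeros((scene.offsets.shape[0], max(n_slots, 1)))
    abs_cyl = np.zeros_like(abs_leaf)
    soil, escaped, truncated, emitted = _mc.trace_kernel(
        np.ascontiguousarray(scene.p0),
        np.ascontiguousarray(scene.e1),
        np.ascontiguousarray(scene.e2),
        np.ascontiguousarray(nrm),
        scene.quad_rank,
        *bvh,
        scene.cyl_z0,
        scene.cyl_z1,
        scene.cyl_rank,
        float(scene.cyl_radius),
        np.ascontiguousarray(scene.offsets),
        np.ascontiguousarray(inst_min),
        np.ascontiguousarray(inst_max),
        dirs,
        n_s,
        e_s,
        lx0,
        ly0,
        lw,
        lh,
        float(z_top),
        float(cfg.leaf_reflectance),
        float(cfg.leaf_transmittance),
        int(cfg.reflection_depth),
        int(cfg.seed % (2**31 - 1)),
        use_bvh,
        abs_leaf,
        abs_cyl,
    )
    return LightResult(
        absorbed_leaf=abs_leaf,
        absorbed_internode=abs_cyl,
        soil=soil,
        escaped=escaped,
        truncated=truncated,
        emitted=emitted,
        reporting=scene.reporting,
        reporting_area_m2=scene.reporting_area_m2,
    )


# ------------------------------------------------------------------ shape grid


@dataclass
class GridResult:
    alphas: np.ndarray
    a_values: np.ndarray
    interception: np.ndarray  # (n_alpha, n_a) mean over repetitions
    se: np.ndarray  # Monte-Carlo standard error from paired runs
    leaf_area: np.ndarray  # per-plant blade area per cell

    @property
    def relative(self) -> np.ndarray:
        """Each cell divided by the grid maximum (max cell = 1)."""
        return self.interception / self.interception.max()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.round(self.relative, 4),
            index=pd.Index(self.alphas, name="alpha"),
            columns=pd.Index(self.a_values, name="a"),
        )
        return df


def run_shape_grid(
    alphas=GRID_VALUES,
    a_values=GRID_VALUES,
    day: int = 81,
    weather: WeatherSeries | None = None,
    arch: PlantArchitecture | None = None,
    canopy: CanopyConfig | None = None,
    dev: DevelopmentConfig | None = None,
    light: LightConfig | None = None,
    n_reps: int = 2,
    seed: int = 0,
) -> GridResult:
    """Canopy interception over the (alpha, a) shape grid, relative to max.

    Every cell uses the identical architecture; the width adjustment holds
    blade area constant across shapes, so differences isolate leaf shape.
    Each cell is simulated ``n_reps`` times (default twice) with distinct
    seeds to estimate the Monte-Carlo standard error.
    """
    weather = weather or default_weather(max(day, 81))
    light = light or LightConfig()
    alphas = np.asarray(alphas, dtype=float)
    a_values = np.asarray(a_values, dtype=float)
    vals = np.zeros((alphas.size, a_values.size))
    ses = np.zeros_like(vals)
    areas = np.zeros_like(vals)
    for i, alpha in enumerate(alphas):
        for j, a in enumerate(a_values):
            a_eff = max(a, 0.5 + 1e-9)  # grid includes the open bound a=0.5
            shape = ShapeParams(float(alpha), float(a_eff))
            try:
                scene = build_canopy_scene(day, weather, arch, canopy, dev, shape)
            except Exception as e:
                raise RuntimeError(
                    f"shape grid cell (alpha={alpha}, a={a}) failed: {e}"
                ) from e
            runs = []
            for rep in range(n_reps):
                cell_seed = (seed * 7919 + i * 613 + j * 61 + rep) % (2**31 - 1)
                res = trace_light(scene, replace(light, seed=cell_seed))
                runs.append(res.canopy_interception)
            runs = np.asarray(runs)
            vals[i, j] = runs.mean()
            ses[i, j] = runs.std(ddof=1) / np.sqrt(n_reps) if n_reps > 1 else np.nan
            areas[i, j] = scene.leaf_area_per_plant
    return GridResult(alphas, a_values, vals, ses, areas)
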
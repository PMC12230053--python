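"""Canopy simulation tests: development, geometry, sky, and transport.

Transport checks use controlled scenes with closed-form expectations
(occlusion, two-layer transmission, Beer-Lambert extinction) and a
brute-force intersection oracle for the BVH.
"""

import numpy as np
import pytest

from leafshape.canopy_sim import (
    CanopyConfig,
    CanopyScene,
    DevelopmentConfig,
    LightConfig,
    PlantArchitecture,
    beam_source,
    build_canopy_scene,
    build_leaf_mesh,
    default_weather,
    expansion_fraction,
    run_shape_grid,
    sky_sources,
    thermal_time,
    trace_light,
)
from leafshape.shape_model import ShapeParams
from leafshape.synthetic_data import make_weather

DEV = DevelopmentConfig()


def assert_energy_balance(res):
    total, emitted = res.energy_balance()
    assert total == pytest.approx(emitted, rel=1e-9)


def flat_scene(p0, e1, e2, domain=(0.0, 1.0, 0.0, 1.0)):
    """Single-instance scene of bare parallelograms over absorbing soil."""
    n = p0.shape[0]
    return CanopyScene(
        p0=p0,
        e1=e1,
        e2=e2,
        quad_rank=np.ones(n, dtype=np.int64),
        cyl_z0=np.zeros(0),
        cyl_z1=np.zeros(0),
        cyl_rank=np.zeros(0, dtype=np.int64),
        cyl_radius=0.0,
        offsets=np.zeros((1, 3)),
        reporting=np.array([True]),
        domain=domain,
        reporting_area_m2=(domain[1] - domain[0]) * (domain[3] - domain[2]),
        n_ranks=1,
        leaf_area_per_plant=float(np.linalg.norm(np.cross(e1, e2), axis=1).sum()),
    )


def square_leaf(cx, cy, z, side):
    p0 = np.array([[cx - side / 2, cy - side / 2, z]])
    e1 = np.array([[side, 0.0, 0.0]])
    e2 = np.array([[0.0, side, 0.0]])
    return p0, e1, e2


def random_leaf_layer(lai, side, seed, z_range=(0.2, 0.8)):
    rng = np.random.default_rng(seed)
    n = int(round(lai / side**2))
    cx = rng.uniform(0, 1, n)
    cy = rng.uniform(0, 1, n)
    z = rng.uniform(*z_range, n)
    p0 = np.column_stack([cx - side / 2, cy - side / 2, z])
    e1 = np.tile([side, 0.0, 0.0], (n, 1))
    e2 = np.tile([0.0, side, 0.0], (n, 1))
    return p0, e1, e2


BLACK = dict(leaf_reflectance=1e-12, leaf_transmittance=1e-12)


class TestDevelopment:
    def test_daily_gdd(self):
        w = make_weather(1, "constant", tmin=10, tmax=20)
        cum, _ = thermal_time(w, DEV)
        assert cum[0] == pytest.approx(7.0)

    def test_gdd_floor_at_zero(self):
        w = make_weather(1, "constant", tmin=5, tmax=5)
        cum, _ = thermal_time(w, DEV)
        assert cum[0] == 0.0

    def test_leaf_appearance_schedule(self):
        w = default_weather(81)  # 8 degC-day per day
        _, appear = thermal_time(w, DEV)
        assert appear[0] == 4  # 30 degC-d reached on day 4
        assert appear[9] == 38  # 300 degC-d on day 38
        assert appear[16] == 64

    @pytest.mark.parametrize(
        "t,expected",
        [(40.0, 0.5), (0.0, 1 / (1 + np.e**2)), (2000.0, 1.0)],
    )
    def test_expansion_fraction(self, t, expected):
        assert expansion_fraction(t, DEV) == pytest.approx(expected, abs=1e-6)


class TestLeafMesh:
    def test_area_identical_across_shapes(self):
        areas = []
        for shape in (ShapeParams(0.5, 0.501), ShapeParams(1.0, 1.0), ShapeParams(0.85, 0.7)):
            p0, e1, e2 = build_leaf_mesh(1.0, 10.0, shape)
            areas.append(np.linalg.norm(np.cross(e1, e2), axis=1).sum())
        expected = 0.75 * 1.0**2 / 10.0
        np.testing.assert_allclose(areas, expected, rtol=0.005)

    def test_max_panel_width_and_position(self):
        shape = ShapeParams(0.85, 0.7)
        p0, e1, e2 = build_leaf_mesh(1.0, 10.0, shape)
        widths = np.linalg.norm(e2, axis=1)
        expected_max = 0.1 * 0.75 / 0.7525871828932218
        assert widths.max() == pytest.approx(expected_max, rel=1e-6)
        # widest panel ~70% of the length from the tip = 30% from the base
        assert np.argmax(widths) == pytest.approx(0.3 * 100, abs=2)

    def test_single_panel_rectangle_limit(self):
        shape = ShapeParams(1.0, 1.0)  # c evaluates to w(1) = 1 at one step
        p0, e1, e2 = build_leaf_mesh(0.8, 10.0, shape, n_panels=1)
        area = np.linalg.norm(np.cross(e1, e2), axis=1).sum()
        assert area == pytest.approx(0.8 * (0.75 * 0.8 / 10.0))


class TestCanopyScene:
    def test_plant_count_and_density(self):
        cfg = CanopyConfig()
        assert cfg.n_plants == 84
        # 0.75 m rows at 0.15 m in-row spacing: 9 plants/m2 up to the
        # rounding of the in-row spacing
        assert cfg.density == pytest.approx(9.0, rel=0.02)

    def test_pre_emergence_day_has_no_leaves(self):
        scene = build_canopy_scene(3, default_weather(81), shapes=ShapeParams(0.85, 0.7))
        assert scene.leaf_area_per_plant == 0.0
        assert scene.p0.shape[0] == 0

    def test_day_81_all_ranks_present(self):
        scene = build_canopy_scene(81, default_weather(81), shapes=ShapeParams(0.85, 0.7))
        assert set(np.unique(scene.quad_rank)) == set(range(1, 18))
        assert scene.offsets.shape[0] == 84

    def test_leaf_area_constant_across_shapes(self):
        areas = [
            build_canopy_scene(81, default_weather(81), shapes=s).leaf_area_per_plant
            for s in (ShapeParams(0.5, 0.501), ShapeParams(1.0, 1.0))
        ]
        assert areas[0] == pytest.approx(areas[1], rel=0.005)


class TestSky:
    def test_weights_normalized(self):
        dirs, wts = sky_sources(LightConfig())
        assert wts.sum() == pytest.approx(1.0)
        assert np.all(dirs[:, 2] < 0)

    def test_diffuse_share(self):
        cfg = LightConfig()
        dirs, wts = sky_sources(cfg)
        n_diffuse = cfg.n_diffuse_rings * cfg.n_diffuse_azimuths
        assert n_diffuse == 72
        assert wts[-n_diffuse:].sum() == pytest.approx(0.2)

    def test_noon_elevation(self):
        cfg = LightConfig()
        dirs, wts = sky_sources(cfg)
        direct = dirs[: -cfg.n_diffuse_rings * cfg.n_diffuse_azimuths]
        elev = np.degrees(np.arcsin(-direct[:, 2]))
        # solar noon at lat 48.714, DOY 180: ~64.4 deg by the standard
        # declination formula
        assert elev.max() == pytest.approx(64.4, abs=1.0)


class TestTransport:
    def test_single_opaque_leaf_full_occlusion(self):
        scene = flat_scene(*square_leaf(0.5, 0.5, 1.0, 2.0))
        res = trace_light(
            scene, LightConfig(n_rays=50_000, **BLACK, seed=1), sources=beam_source(0.0)
        )
        assert res.absorbed_fraction == pytest.approx(1.0, abs=1e-6)
        assert_energy_balance(res)

    def test_two_layer_transmission_ratio(self):
        top = square_leaf(0.5, 0.5, 2.0, 2.0)
        bottom = square_leaf(0.5, 0.5, 1.0, 12.0)  # oversized: catches scatter
        p0 = np.vstack([top[0], bottom[0]])
        e1 = np.vstack([top[1], bottom[1]])
        e2 = np.vstack([top[2], bottom[2]])
        scene = flat_scene(p0, e1, e2)
        scene.quad_rank = np.array([1, 2], dtype=np.int64)
        scene.n_ranks = 2
        tau = 0.0127
        res = trace_light(
            scene,
            LightConfig(
                n_rays=400_000, leaf_reflectance=1e-12, leaf_transmittance=tau, seed=2
            ),
            sources=beam_source(0.0),
        )
        by_rank = res.absorbed_leaf.sum(axis=0)
        ratio = by_rank[2] / by_rank[1]
        n_transmitted = 400_000 * tau
        se = tau / np.sqrt(n_transmitted)
        assert ratio == pytest.approx(tau, abs=3 * se + 1e-4)
        assert_energy_balance(res)

    @pytest.mark.parametrize("lai", [0.5, 1.0, 2.0, 4.0])
    def test_beer_lambert_extinction(self, lai):
        """Random horizontal black leaves under a vertical beam follow
        1 - exp(-LAI), within 3 SE over placement replicates."""
        vals = []
        for rep in range(5):
            scene = flat_scene(
                *random_leaf_layer(lai, side=0.02, seed=100 * rep + int(10 * lai)),
                domain=(0.1, 0.9, 0.1, 0.9),
            )
            res = trace_light(
                scene,
                LightConfig(n_rays=50_000, **BLACK, seed=rep),
                sources=beam_source(0.0),
            )
            assert_energy_balance(res)
            vals.append(res.absorbed_fraction)
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert mean == pytest.approx(1 - np.exp(-lai), abs=3 * se + 0.005)

    def test_interception_monotone_in_lai(self):
        means = []
        for lai in (0.5, 1.0, 2.0, 4.0):
            scene = flat_scene(
                *random_leaf_layer(lai, side=0.02, seed=7), domain=(0.1, 0.9, 0.1, 0.9)
            )
            res = trace_light(
                scene, LightConfig(n_rays=50_000, **BLACK, seed=3), sources=beam_source(0.0)
            )
            means.append(res.absorbed_fraction)
        assert np.all(np.diff(means) > 0)

    def test_absorption_monotone_in_reflection_depth(self):
        p0 = np.vstack([square_leaf(0.5, 0.5, z, 4.0)[0] for z in (1.0, 2.0, 3.0)])
        e1 = np.tile([4.0, 0.0, 0.0], (3, 1))
        e2 = np.tile([0.0, 4.0, 0.0], (3, 1))
        scene = flat_scene(p0, e1, e2)
        vals = []
        for depth in (0, 2, 6):
            res = trace_light(
                scene,
                LightConfig(
                    n_rays=100_000,
                    reflection_depth=depth,
                    leaf_reflectance=0.3,
                    leaf_transmittance=0.2,
                    seed=4,
                ),
                sources=beam_source(0.0),
            )
            assert_energy_balance(res)
            vals.append(res.absorbed_leaf.sum() / res.emitted)
        assert vals[1] > vals[0] + 0.01
        assert vals[2] > vals[1] + 0.005

    def test_bvh_matches_brute_force(self):
        scene = flat_scene(
            *random_leaf_layer(1.0, side=0.05, seed=11), domain=(0.1, 0.9, 0.1, 0.9)
        )
        cfg = LightConfig(n_rays=20_000, seed=5)
        a = trace_light(scene, cfg, sources=beam_source(20.0), use_bvh=True)
        b = trace_light(scene, cfg, sources=beam_source(20.0), use_bvh=False)
        np.testing.assert_array_equal(a.absorbed_leaf, b.absorbed_leaf)
        assert a.soil == b.soil and a.escaped == b.escaped


@pytest.fixture(scope="module")
def scene():
    return build_canopy_scene(81, default_weather(81), shapes=ShapeParams(0.85, 0.7))


class TestCanopyRuns:
    def test_study_sky_interception_is_a_fraction(self, scene):
        res = trace_light(scene, LightConfig(n_rays=200_000, seed=6))
        assert_energy_balance(res)
        assert 0.0 < res.canopy_interception <= 1.0
        assert 0.0 <= res.absorbed_fraction <= 1.0
        assert np.all(res.rank_interception >= 0)

    def test_seed_stability_at_high_ray_count(self, scene):
        vals = [
            trace_light(scene, LightConfig(n_rays=2_000_000, seed=s)).canopy_interception
            for s in (11, 12)
        ]
        assert abs(vals[0] - vals[1]) < 0.005

    def test_small_shape_grid_contract(self):
        res = run_shape_grid(
            alphas=[0.5, 1.0],
            a_values=[0.5, 1.0],
            light=LightConfig(n_rays=50_000),
            n_reps=1,
            seed=3,
        )
        rel = res.relative
        assert rel.max() == 1.0
        assert np.all((rel > 0) & (rel <= 1.0))
        np.testing.assert_allclose(res.leaf_area, res.leaf_area.flat[0], rtol=0.005)
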
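"""Scene construction, point location, and analytic ray tracing."""

import numpy as np
import pytest

from fiberaif import (
    Scene,
    Volume,
    build_human_wrist_scene,
    build_mouse_tail_scene,
    build_validation_tube_scene,
    subtended_source_volume_ml,
)


@pytest.fixture(scope="module")
def mouse():
    return build_mouse_tail_scene("F18")


class TestLocate:
    def test_tail_axis_is_bone(self, mouse):
        assert mouse.locate((0.0, 0.0, 5.0)).role == "bone"

    def test_artery_center(self, mouse):
        v = mouse.volume("artery")
        assert mouse.locate(v.center).role == "source_artery"

    def test_outside_world_raises(self, mouse):
        with pytest.raises(ValueError):
            mouse.locate((10_000.0, 0.0, 0.0))

    def test_air_gap_between_tail_and_fiber(self, mouse):
        assert mouse.locate((0.0, -1.65, 0.0)).role == "air"


class TestRaySegments:
    def test_perpendicular_chord_equals_diameter(self, mouse):
        fiber = mouse.volume("fiber")
        y = fiber.center[1]
        segs = mouse.ray_segments((-5.0, y, 0.0), (1.0, 0.0, 0.0), 10.0)
        fiber_segs = [(b - a) for v, a, b in segs if v.role == "fiber"]
        assert len(fiber_segs) == 1
        assert fiber_segs[0] == pytest.approx(2.0 * fiber.radius, abs=1e-9)

    def test_miss_gives_single_air_segment(self, mouse):
        segs = mouse.ray_segments((0.0, -100.0, 0.0), (1.0, 0.0, 0.0), 50.0)
        assert len(segs) == 1
        assert segs[0][0].role == "air"

    def test_total_length_conserved(self, mouse):
        rng = np.random.default_rng(7)
        for _ in range(20):
            o = rng.uniform(-3.0, 3.0, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            segs = mouse.ray_segments(o, d, 25.0)
            assert sum(b - a for _, a, b in segs) == pytest.approx(25.0, abs=1e-9)
            # contiguity
            for (_, _, b0), (_, a1, _) in zip(segs[:-1], segs[1:]):
                assert a1 == pytest.approx(b0, abs=1e-12)

    def test_against_step_marching_oracle(self, mouse):
        """Analytic boundaries agree with brute-force 1 um marching."""
        rng = np.random.default_rng(42)
        step = 1e-3  # mm
        L = 6.0
        for _ in range(100):
            o = rng.uniform([-3.0, -3.5, -2.0], [3.0, 2.0, 2.0])
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            segs = mouse.ray_segments(o, d, L)
            ts = np.arange(0.0, L, step)
            pts = o[None, :] + ts[:, None] * d[None, :]
            names = [mouse.locate(p).name for p in pts]
            # oracle volume sequence (collapse runs)
            marched = [names[0]]
            boundaries = []
            for t, nm in zip(ts, names):
                if nm != marched[-1]:
                    marched.append(nm)
                    boundaries.append(t)
            assert [s[0].name for s in segs] == marched
            analytic = [a for _, a, _ in segs[1:]]
            assert len(analytic) == len(boundaries)
            for ta, tb in zip(analytic, boundaries):
                assert abs(ta - tb) <= step + 1e-9

    def test_non_unit_direction_rejected(self, mouse):
        with pytest.raises(ValueError):
            mouse.ray_segments((0.0, 0.0, 0.0), (1.0, 1.0, 0.0), 5.0)


class TestMouseScene:
    def test_vein_to_artery_activity_ratio_is_12(self, mouse):
        """Three veins at twice the diameter: 12x the activity of the artery
        at equal concentration."""
        artery = mouse.volume("artery").volume_mm3() * mouse.activity["artery"]
        veins = sum(v.volume_mm3() * mouse.activity[v.name]
                    for v in mouse.volumes_by_role("source_vein"))
        assert veins / artery == pytest.approx(12.0, rel=1e-12)

    def test_artery_axis_depth(self, mouse):
        # 0.1 mm surface gap + 0.05 mm radius below the 1.6 mm tail surface
        assert mouse.volume("artery").center[1] == pytest.approx(-1.45)

    def test_volume_count_by_role(self, mouse):
        counts = {}
        for v in mouse.volumes:
            counts[v.role] = counts.get(v.role, 0) + 1
        assert counts == {"air": 1, "tissue": 1, "bone": 1, "source_artery": 1,
                          "source_vein": 3, "fiber": 1, "source_body": 1}

    def test_builders_are_pure(self):
        a = build_mouse_tail_scene("F18").to_config()
        b = build_mouse_tail_scene("F18").to_config()
        assert a == b

    def test_config_roundtrip(self, mouse):
        restored = Scene.from_config(mouse.to_config())
        assert restored.to_config() == mouse.to_config()


class TestWristScene:
    def test_reference_depth(self):
        s = build_human_wrist_scene("Ga68")
        artery = s.volume("artery")
        # vessel surface sits 2 mm below the 40 mm wrist surface
        assert artery.center[1] - artery.radius == pytest.approx(-38.0)
        assert len(s.volumes_by_role("fiber")) == 1
        assert s.volumes_by_role("fiber")[0].shape == "cylinder"

    def test_four_square_fibers_tile_4mm(self):
        s = build_human_wrist_scene("Ga68", n_fibers=4, fiber_shape="square")
        fibers = s.volumes_by_role("fiber")
        assert len(fibers) == 4
        xs = sorted(f.center[0] for f in fibers)
        assert xs == pytest.approx([-1.5, -0.5, 0.5, 1.5])
        total_cross = sum(f.edges[0] * f.edges[1] for f in fibers)
        assert total_cross == pytest.approx(4.0)

    def test_zero_depth_touches_skin(self):
        s = build_human_wrist_scene("Ga68", vessel_depth_mm=0.0)
        artery = s.volume("artery")
        assert artery.center[1] - artery.radius == pytest.approx(-40.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            build_human_wrist_scene("Ga68", n_fibers=5)
        with pytest.raises(ValueError):
            build_human_wrist_scene("Ga68", n_fibers=2, fiber_shape="round")


class TestValidationTube:
    def test_source_volume_is_70_ul(self):
        for iso in ("F18", "Ga68"):
            s = build_validation_tube_scene(iso)
            assert s.volume("tube").volume_mm3() == pytest.approx(70.0)
            assert subtended_source_volume_ml(s) == pytest.approx(0.070)

    def test_fiber_shape_per_isotope(self):
        assert build_validation_tube_scene("F18").volume("fiber").shape == "box"
        assert build_validation_tube_scene("Ga68").volume("fiber").shape == "cylinder"

    def test_wall_and_gap_stack(self):
        s = build_validation_tube_scene("F18")
        fiber_top = s.volume("fiber").center[1] + s.volume("fiber").edges[1] / 2
        source_face = s.volume("tube").center[1] - s.volume("tube").edges[1] / 2
        assert source_face - fiber_top == pytest.approx(0.4)

    def test_unknown_isotope(self):
        with pytest.raises(ValueError):
            build_validation_tube_scene("C11")


def test_uniform_sampling_centroid(mouse):
    rng = np.random.default_rng(3)
    for name in ("tail", "body", "fiber"):
        v = mouse.volume(name)
        pts = mouse.sample_in_volume(v, 20_000, rng)
        scale = max(v.radius, v.length)
        assert np.allclose(pts.mean(axis=0), v.center,
                           atol=4.0 * scale / np.sqrt(12 * 20_000) + 1e-2)
        assert all(v.contains(p) for p in pts[:100])


def test_volume_validation():
    with pytest.raises(ValueError):
        Volume("bad", "cylinder", (0, 0, 0), "water", "tissue", 1,
               radius=-1.0, length=5.0)
    with pytest.raises(ValueError):
        Volume("bad", "cylinder", (0, 0, 0), "water", "tissue", 1,
               axis=(0, 0, 2), radius=1.0, length=5.0)
    with pytest.raises(ValueError):
        Volume("bad", "box", (0, 0, 0), "water", "nonsense", 1, edges=(1, 1, 1))
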
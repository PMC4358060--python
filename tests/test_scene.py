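"""Dot-cloud geometry, optical size, FOE gain law and frustum visibility."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import vectionsim as vs
from vectionsim.errors import ConfigurationError, DomainError
from vectionsim.scene import (DEFAULT_EDGE, DEFAULT_INNER_RADIUS,
                              _azimuth_elevation, _rotate_yaw)

CONDS = vs.CONDITIONS


class TestCloudSampling:
    def test_deterministic_given_seed(self, small_scene):
        a = vs.generate_cloud(small_scene, seed=7)
        b = vs.generate_cloud(small_scene, seed=7)
        np.testing.assert_array_equal(a.positions, b.positions)
        c = vs.generate_cloud(small_scene, seed=8)
        assert not np.array_equal(a.positions, c.positions)

    def test_distances_within_default_shell(self):
        cfg = vs.SceneConfig(n_dots=20000)
        d = vs.generate_cloud(cfg, seed=0).distances()
        # inner radius derived by inverting the optical-size formula at 2.5 deg
        assert d.min() >= 0.2999
        assert d.max() <= 3.0
        assert len(d) == cfg.n_dots

    def test_volume_uniform_shell_occupancy(self):
        # closed-form shell-volume ratio vs the Monte-Carlo count
        cfg = vs.SceneConfig(n_dots=100_000)
        d = vs.generate_cloud(cfg, seed=1).distances()
        p = (1.5**3 - cfg.inner_radius**3) / (cfg.outer_radius**3
                                              - cfg.inner_radius**3)
        se = math.sqrt(p * (1 - p) / cfg.n_dots)
        assert abs((d <= 1.5).mean() - p) < 3 * se

    def test_invalid_radii_rejected(self):
        with pytest.raises(ConfigurationError):
            vs.SceneConfig(inner_radius=3.0, outer_radius=0.3)


class TestOpticalSize:
    def test_derived_size_constraints(self):
        # the square side is fixed by the 0.25 deg far-size constraint, the
        # inner radius by the 2.5 deg near-size constraint
        assert vs.optical_size(DEFAULT_EDGE, 3.0) == pytest.approx(0.25, abs=1e-9)
        assert vs.optical_size(DEFAULT_EDGE, DEFAULT_INNER_RADIUS) == \
            pytest.approx(2.5, abs=1e-9)
        assert vs.optical_size(0.0131, 3.0) == pytest.approx(0.250, abs=5e-4)

    def test_size_range_over_default_shell(self):
        cfg = vs.SceneConfig(n_dots=50_000)
        cloud = vs.generate_cloud(cfg, seed=2)
        size = vs.optical_size(cfg.edge_length, cloud.distances())
        assert size.min() >= 0.25 - 0.01
        assert size.max() <= 2.5 + 0.01

    @given(st.floats(0.05, 50.0), st.floats(0.05, 50.0))
    def test_strictly_decreasing_in_distance(self, d1, d2):
        if d1 == d2:
            return
        lo, hi = sorted((d1, d2))
        assert vs.optical_size(0.013, lo) > vs.optical_size(0.013, hi)

    def test_vanishes_at_large_distance(self):
        assert vs.optical_size(0.013, 1e9) < 1e-6

    def test_domain_errors(self):
        for edge, dist in [(0.0, 1.0), (-1.0, 1.0), (0.01, 0.0)]:
            with pytest.raises(DomainError):
                vs.optical_size(edge, dist)


class TestFoeGainLaw:
    @pytest.mark.parametrize("cond, yaw, spat, rel", [
        (vs.CONTRALATERAL, 30.0, 0.0, -30.0),
        (vs.IPSILATERAL, 10.0, 20.0, 10.0),
        (vs.PURE_RADIAL, 17.0, 17.0, 0.0),
        (vs.CONTRALATERAL, 0.0, 0.0, 0.0),
        (vs.IPSILATERAL, 0.0, 0.0, 0.0),
    ])
    def test_named_cases(self, cond, yaw, spat, rel):
        s, r = vs.foe_azimuth(cond, yaw)
        assert s == pytest.approx(spat, abs=1e-12)
        assert r == pytest.approx(rel, abs=1e-12)

    @given(st.floats(-180, 180))
    def test_gain_law_difference_is_head_yaw(self, yaw):
        for cond in CONDS:
            s, r = vs.foe_azimuth(cond, yaw)
            assert s == cond.k * yaw
            assert s - r == pytest.approx(yaw, abs=1e-9)

    def test_condition_name_gain_bijection(self):
        assert {c.name: c.k for c in CONDS} == {
            "contralateral": 0, "pure_radial": 1, "ipsilateral": 2}
        with pytest.raises(ConfigurationError):
            vs.CouplingCondition("contralateral", 2)


class TestProjection:
    def test_forward_dot_at_zero_yaw(self, small_scene):
        cloud = vs.DotCloud(np.array([[0.0, 0.0, -1.0]]), 0.013)
        flow = vs.project(cloud, 0.0, vs.PURE_RADIAL, small_scene)
        assert flow.azimuth[0] == pytest.approx(0.0, abs=1e-12)
        assert flow.elevation[0] == pytest.approx(0.0, abs=1e-12)
        assert flow.visible[0]

    def test_contralateral_world_stationarity(self, small_scene):
        cloud = vs.generate_cloud(small_scene, seed=3)
        base = vs.project(cloud, 0.0, vs.CONTRALATERAL, small_scene)
        for yaw in (-40.0, -7.3, 12.0, 33.0):
            flow = vs.project(cloud, yaw, vs.CONTRALATERAL, small_scene)
            delta = np.abs(flow.spatiotopic_azimuth - base.spatiotopic_azimuth)
            assert np.max(delta) < 1e-9

    def test_yaw_only_matches_scalar_angle_arithmetic(self):
        # equatorial dots: projection must reduce to plain azimuth addition
        az0 = np.array([-120.0, -45.0, 0.0, 10.0, 90.0, 170.0])
        a = np.radians(az0)
        pos = np.column_stack((-np.sin(a), np.zeros_like(a), -np.cos(a)))
        cloud = vs.DotCloud(2.0 * pos, 0.013)
        cfg = vs.SceneConfig(n_dots=6)
        for cond in CONDS:
            for yaw in (-25.0, 13.7, 60.0):
                flow = vs.project(cloud, yaw, cond, cfg)
                expect = (az0 + (cond.k - 1) * yaw + 180.0) % 360.0 - 180.0
                np.testing.assert_allclose(flow.azimuth, expect, atol=1e-9)

    def test_passive_playback_mirror_equivalence(self):
        # the head-relative FOE path under contralateral coupling is the
        # sign-flip of the ipsilateral path for the same yaw trace
        yaw_trace = 21.8 * np.sin(2 * np.pi * 0.53 * np.arange(0, 4, 0.05))
        for yaw in yaw_trace:
            _, rel_contra = vs.foe_azimuth(vs.CONTRALATERAL, yaw)
            _, rel_ipsi = vs.foe_azimuth(vs.IPSILATERAL, yaw)
            assert rel_contra == pytest.approx(-rel_ipsi, abs=1e-12)

    def test_translation_flow_streams_from_foe(self, small_scene):
        # angular velocity vanishes along the heading axis, peaks abeam
        pos = np.array([[0.0, 0.0, -2.0], [2.0, 0.0, 0.0], [0.0, 0.0, 2.0]])
        cloud = vs.DotCloud(pos, 0.013)
        flow = vs.project(cloud, 0.0, vs.PURE_RADIAL, small_scene)
        assert flow.angular_velocity[0] == pytest.approx(0.0, abs=1e-9)
        assert flow.angular_velocity[2] == pytest.approx(0.0, abs=1e-9)
        assert flow.angular_velocity[1] == pytest.approx(
            math.degrees(small_scene.translation_speed / 2.0), rel=1e-9)


class TestTranslation:
    def test_zero_dt_identity(self, small_scene):
        cloud = vs.generate_cloud(small_scene, seed=4)
        out = vs.advance_translation(cloud, 0.0, small_scene,
                                     np.random.default_rng(0))
        np.testing.assert_array_equal(out.positions, cloud.positions)

    def test_forward_displacement_kinematics(self, small_scene):
        cloud = vs.generate_cloud(small_scene, seed=5)
        out = vs.advance_translation(cloud, 0.1, small_scene,
                                     np.random.default_rng(0))
        d_new = np.linalg.norm(cloud.positions
                               + np.array([0, 0, 0.1]), axis=1)
        kept = (d_new >= small_scene.inner_radius) & \
               (d_new <= small_scene.outer_radius)
        # surviving dots: forward coordinate (-z) reduced by exactly v*dt
        np.testing.assert_allclose(
            out.positions[kept, 2] - cloud.positions[kept, 2], 0.1, atol=1e-12)
        np.testing.assert_array_equal(out.positions[kept, :2],
                                      cloud.positions[kept, :2])

    def test_long_run_count_constant_and_stationary(self, small_scene):
        rng = np.random.default_rng(6)
        cloud = vs.generate_cloud(small_scene, seed=6)
        hists = []
        for step in range(400):
            cloud = vs.advance_translation(cloud, 0.05, small_scene, rng)
            assert cloud.n_dots == small_scene.n_dots
            d = cloud.distances()
            assert d.min() >= small_scene.inner_radius - 1e-9
            assert d.max() <= small_scene.outer_radius + 1e-9
            if step >= 200 and step % 50 == 0:
                hists.append(np.histogram(d, bins=6,
                                          range=(0.3, 3.0))[0] / cloud.n_dots)
        # occupancy histogram stable once the transient has washed out
        spread = np.ptp(np.array(hists), axis=0)
        assert spread.max() < 0.05


class TestVisibility:
    def test_cone_matches_solid_angle_ratio(self):
        cfg = vs.SceneConfig(n_dots=100_000, frustum_model="cone")
        cloud = vs.generate_cloud(cfg, seed=7)
        frac = vs.visible_fraction(cloud, 0.0, vs.PURE_RADIAL, cfg)
        p = (1 - math.cos(math.radians(55.0))) / 2  # ~0.2132
        se = math.sqrt(p * (1 - p) / cfg.n_dots)
        assert abs(frac - p) < 3 * se

    def test_default_binocular_fraction_near_twenty_percent(self):
        cfg = vs.SceneConfig(n_dots=100_000)
        cloud = vs.generate_cloud(cfg, seed=8)
        frac = vs.visible_fraction(cloud, 0.0, vs.CONTRALATERAL, cfg)
        assert 0.18 < frac < 0.22

    def test_visible_flags_respect_frustum(self, small_scene):
        cloud = vs.generate_cloud(small_scene, seed=9)
        flow = vs.project(cloud, 25.0, vs.IPSILATERAL, small_scene)
        # every visible dot lies in front of the observer within the widest
        # possible half-field (diagonal/2 + eye offset)
        limit = small_scene.fov_diagonal / 2 + small_scene.eye_yaw_offset + 1
        ang = np.degrees(np.arccos(np.cos(np.radians(flow.azimuth))
                                   * np.cos(np.radians(flow.elevation))))
        assert np.all(ang[flow.visible] < limit)

    def test_empty_cloud_rejected(self, small_scene):
        empty = vs.DotCloud(np.empty((0, 3)), 0.013)
        with pytest.raises(DomainError):
            vs.visible_fraction(empty, 0.0, vs.PURE_RADIAL, small_scene)
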
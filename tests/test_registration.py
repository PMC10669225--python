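import numpy as np
import pytest

from artikin.articulator import ARTICULATOR_FRAME
from artikin.errors import (
    DegenerateGeometryError,
    InvalidArgumentError,
    RegistrationQualityWarning,
)
from artikin.registration import (
    MarkerPoseStream,
    ReferencePlane,
    build_articulator_frame,
    fit_sphere,
    icp_register,
    kabsch_align,
    lower_point_in_articulator,
    track_landmark_trajectory,
)
from artikin.transforms import FramedTransform, compose, identity, invert

from conftest import random_rigid_transform


def sphere_points(center, radius, n, rng, hemisphere=False):
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    if hemisphere:
        d[:, 2] = np.abs(d[:, 2])
    return np.asarray(center) + radius * d


class TestFitSphere:
    def test_axis_points_of_unit_sphere(self):
        pts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
        fit = fit_sphere(pts)
        assert fit.center == pytest.approx([0, 0, 0], abs=1e-12)
        assert fit.radius == pytest.approx(1.0, abs=1e-12)
        assert fit.rms_error < 1e-12

    def test_noise_free_hemisphere_recovery(self, rng):
        center, radius = np.array([12.0, -3.0, 40.0]), 9.5
        fit = fit_sphere(sphere_points(center, radius, 80, rng, hemisphere=True))
        assert fit.center == pytest.approx(center, abs=1e-9)
        assert fit.radius == pytest.approx(radius, abs=1e-9)
        assert fit.rms_error < 1e-9

    def test_coplanar_points_are_degenerate(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 1, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(pts)

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(np.eye(3))


class TestBuildArticulatorFrame:
    def test_canonical_landmarks_give_identity(self):
        t, plane = build_articulator_frame([55, 0, 0], [-55, 0, 0], [0, 80, 0],
                                           kind="camper")
        assert np.allclose(t.matrix, np.eye(4), atol=1e-12)
        assert plane.kind == "camper"
        assert abs(plane.signed_distance([3.0, 7.0, 0.0])) < 1e-9

    def test_recovers_applied_rigid_transform(self, rng):
        # apply-then-recover oracle
        cr, cl, ant = np.array([55.0, 0, 0]), np.array([-55.0, 0, 0]), np.array([0.0, 80, 0])
        for _ in range(10):
            g = random_rigid_transform(rng)
            t, plane = build_articulator_frame(g.apply(cr), g.apply(cl), g.apply(ant))
            assert np.allclose(t.matrix, invert(g).matrix, atol=1e-9)
            # the three defining landmarks lie on the plane
            for p in (g.apply(cr), g.apply(cl), g.apply(ant)):
                assert abs(plane.signed_distance(p)) < 1e-9

    def test_equivariance_under_pre_transform(self, rng):
        cr, cl, ant = np.array([51.0, 4, 2]), np.array([-58.0, 1, -3]), np.array([2.0, 85, 10])
        t0, _ = build_articulator_frame(cr, cl, ant)
        g = random_rigid_transform(rng)
        t1, _ = build_articulator_frame(g.apply(cr), g.apply(cl), g.apply(ant))
        assert np.allclose(t1.matrix, (t0.matrix @ invert(g).matrix), atol=1e-9)

    def test_swapped_condyles_flip_x(self):
        t, _ = build_articulator_frame([-55, 0, 0], [55, 0, 0], [0, 80, 0])
        assert t.apply([55.0, 0, 0]) == pytest.approx([-55.0, 0, 0], abs=1e-9)

    def test_collinear_landmarks_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            build_articulator_frame([55, 0, 0], [-55, 0, 0], [10, 0, 0])

    def test_plane_normal_must_be_unit(self):
        with pytest.raises(InvalidArgumentError):
            ReferencePlane("frankfurt", [0, 0, 0], [0, 0, 2.0])


class TestKabsch:
    def test_identity_for_matching_clouds(self, rng):
        pts = rng.uniform(-30, 30, size=(12, 3))
        t = kabsch_align(pts, pts)
        assert np.allclose(t.matrix, np.eye(4), atol=1e-9)

    def test_recovers_known_transform(self, rng):
        pts = rng.uniform(-30, 30, size=(15, 3))
        g = random_rigid_transform(rng)
        t = kabsch_align(pts, g.apply(pts))
        assert np.allclose(t.matrix, g.matrix, atol=1e-9)

    def test_collinear_source_degenerate(self):
        src = np.outer(np.arange(5.0), [1.0, 2.0, 0.5])
        with pytest.raises(DegenerateGeometryError):
            kabsch_align(src, src + 1.0)

    def test_reflection_correspondence_returns_proper_rotation(self, rng):
        # brute-force over the SVD sign flip: det must stay +1, residual > 0
        pts = rng.uniform(-10, 10, size=(20, 3))
        mirrored = pts * [-1.0, 1.0, 1.0]
        t = kabsch_align(pts, mirrored)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(t.apply(pts) - mirrored) > 1.0


class TestICP:
    def test_identical_clouds(self, rng):
        cloud = rng.uniform(-40, 40, size=(60, 3))
        result = icp_register(cloud, cloud)
        assert result.rms < 1e-12
        assert np.allclose(result.transform.matrix, np.eye(4), atol=1e-9)

    def test_small_perturbation_recovered(self, rng):
        cloud = rng.uniform(-40, 40, size=(300, 3)) * [1.0, 0.7, 0.4]
        g = random_rigid_transform(rng, max_angle=np.radians(5.0), max_shift=2.0)
        result = icp_register(cloud, g.apply(cloud))
        moved = result.transform.apply(cloud)
        assert np.sqrt(np.mean(np.sum((moved - g.apply(cloud)) ** 2, axis=1))) < 1e-4

    def test_rms_history_non_increasing(self, rng):
        cloud = rng.uniform(-40, 40, size=(200, 3)) * [1.0, 0.6, 0.3]
        g = random_rigid_transform(rng, max_angle=np.radians(10.0), max_shift=5.0)
        result = icp_register(cloud, g.apply(cloud))
        hist = np.array(result.rms_history)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_non_overlapping_clouds_warn_not_raise(self, rng):
        a = rng.uniform(-10, 10, size=(50, 3))
        b = rng.uniform(-10, 10, size=(50, 3)) + [500.0, 0, 0]
        with pytest.warns(RegistrationQualityWarning):
            result = icp_register(a, b, quality_threshold=0.5)
        assert not result.quality_ok

    def test_small_clouds_rejected(self):
        with pytest.raises(InvalidArgumentError):
            icp_register(np.zeros((5, 3)), np.zeros((50, 3)))


def make_stream(entries):
    return MarkerPoseStream(tuple(entries))


class TestMarkerChain:
    def test_identity_chain_is_identity(self):
        up = identity("marker_up", "camera")
        low = identity("marker_low", "camera")
        stream = make_stream([(0.0, up, low), (1.0, up, low)])
        t_0_up = identity("marker_up", ARTICULATOR_FRAME)
        p = np.array([3.0, -1.0, 2.0])
        assert lower_point_in_articulator(p, 0.0, stream, t_0_up) == pytest.approx(p)

    def test_comoving_markers_give_constant_output(self, rng):
        # upper and lower markers rigidly co-moving: relative pose constant
        rel = random_rigid_transform(rng)
        t_0_up = FramedTransform(random_rigid_transform(rng).matrix,
                                 "marker_up", ARTICULATOR_FRAME)
        entries = []
        for i in range(5):
            body = random_rigid_transform(rng)  # common motion
            up = FramedTransform(body.matrix, "marker_up", "camera")
            low = FramedTransform(body.matrix @ rel.matrix, "marker_low", "camera")
            entries.append((float(i), up, low))
        traj = track_landmark_trajectory([1.0, 2.0, 3.0], make_stream(entries), t_0_up)
        assert np.max(np.ptp(traj.points, axis=0)) < 1e-9

    def test_camera_motion_cancels(self, rng):
        # multiply every camera-side transform by a per-sample wobble
        t_0_up = FramedTransform(random_rigid_transform(rng).matrix,
                                 "marker_up", ARTICULATOR_FRAME)
        base, wobbled = [], []
        for i in range(6):
            up = random_rigid_transform(rng)
            low = random_rigid_transform(rng)
            w = random_rigid_transform(rng)
            base.append((float(i),
                         FramedTransform(up.matrix, "marker_up", "camera"),
                         FramedTransform(low.matrix, "marker_low", "camera")))
            wobbled.append((float(i),
                            FramedTransform(w.matrix @ up.matrix, "marker_up", "camera"),
                            FramedTransform(w.matrix @ low.matrix, "marker_low", "camera")))
        p = np.array([5.0, -2.0, 8.0])
        a = track_landmark_trajectory(p, make_stream(base), t_0_up)
        b = track_landmark_trajectory(p, make_stream(wobbled), t_0_up)
        assert np.max(np.abs(a.points - b.points)) < 1e-9

    def test_nearest_sample_lookup_and_range_check(self):
        up = identity("marker_up", "camera")
        low = identity("marker_low", "camera")
        stream = make_stream([(0.0, up, low), (1.0, up, low)])
        assert stream.nearest(0.4)[0] == 0.0
        assert stream.nearest(0.6)[0] == 1.0
        with pytest.raises(InvalidArgumentError):
            stream.nearest(5.0)

    def test_timestamps_must_strictly_increase(self):
        up = identity("marker_up", "camera")
        low = identity("marker_low", "camera")
        with pytest.raises(InvalidArgumentError):
            make_stream([(0.0, up, low), (0.0, up, low)])
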
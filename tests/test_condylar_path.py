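import numpy as np
import pytest
import warnings
from scipy.interpolate import BSpline

from artikin.condylar_path import (
    CondylarPathModel,
    NurbsCurve,
    evaluate_nurbs,
    evaluate_path,
    fit_condylar_path,
    fit_horizontal_line,
    fit_nurbs,
    fit_sagittal_quadratic,
    nurbs_basis,
)
from artikin.errors import (
    DomainExtrapolationWarning,
    InsufficientDataError,
    InvalidArgumentError,
)
from artikin.trajectory import Trajectory


def quad_points(a, b, c, ys, x=3.0):
    return np.column_stack([np.full_like(ys, x), ys, a * ys**2 + b * ys + c])


class TestSagittalQuadratic:
    def test_exact_interpolation(self):
        ys = np.linspace(0, 8, 12)
        a, b, c, rms, incl = fit_sagittal_quadratic(quad_points(0.02, -0.6, 3.0, ys))
        assert (a, b, c) == pytest.approx((0.02, -0.6, 3.0), abs=1e-9)
        assert rms < 1e-9
        # slope at the rest point (first sample, y=0) is b
        assert incl == pytest.approx(np.degrees(np.arctan(0.6)), abs=1e-9)

    def test_horizontal_path_has_zero_inclination(self):
        ys = np.linspace(0, 5, 6)
        a, b, _, _, incl = fit_sagittal_quadratic(quad_points(0.0, 0.0, -2.0, ys))
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert incl == pytest.approx(0.0, abs=1e-12)

    def test_too_few_distinct_y(self):
        pts = np.array([[0, 1.0, 2.0], [0, 1.0, 2.1], [0, 2.0, 2.2]])
        with pytest.raises(InsufficientDataError):
            fit_sagittal_quadratic(pts)

    def test_noisy_inclination_recovery(self, rng):
        # Monte-Carlo with known ground truth
        truth_incl = 35.0
        b = -np.tan(np.radians(truth_incl))
        ys = np.linspace(0, 10, 200)
        pts = quad_points(-0.01, b, 0.0, ys)
        pts[:, 2] += rng.normal(0, 0.1, ys.size)
        *_, incl = fit_sagittal_quadratic(pts, rest_y=0.0)
        assert abs(incl - truth_incl) < 0.5


class TestHorizontalLine:
    def test_exact_bennett_angle(self):
        ys = np.linspace(0, 3, 10)
        pts = np.column_stack([np.tan(np.radians(15.0)) * ys, ys, np.zeros_like(ys)])
        m, k, rms, bennett = fit_horizontal_line(pts)
        assert bennett == pytest.approx(15.0, abs=1e-9)
        assert rms < 1e-12

    def test_sagittal_motion_has_zero_bennett(self):
        ys = np.linspace(0, 3, 10)
        pts = np.column_stack([np.full_like(ys, 55.0), ys, np.zeros_like(ys)])
        *_, bennett = fit_horizontal_line(pts)
        assert bennett == pytest.approx(0.0, abs=1e-12)

    def test_too_few_distinct_y(self):
        with pytest.raises(InsufficientDataError):
            fit_horizontal_line(np.array([[1.0, 2.0, 0.0], [1.5, 2.0, 0.0]]))

    def test_noisy_bennett_recovery(self, rng):
        truth = 12.0
        ys = np.linspace(0, 3, 200)
        pts = np.column_stack([np.tan(np.radians(truth)) * ys + 55.0, ys, np.zeros_like(ys)])
        pts[:, 0] += rng.normal(0, 0.1, ys.size)
        *_, bennett = fit_horizontal_line(pts)
        assert abs(bennett - truth) < 0.5


class TestNurbsBasis:
    def test_degree_zero_is_span_indicator(self):
        knots = [0.0, 0.0, 0.5, 1.0, 1.0]
        assert nurbs_basis(0.25, 1, 0, [0.0, 0.25, 0.5, 0.75, 1.0]) == 1.0
        assert nurbs_basis(0.6, 1, 0, [0.0, 0.25, 0.5, 0.75, 1.0]) == 0.0

    @pytest.mark.parametrize("u", [0.0, 0.11, 0.5, 0.73, 1.0])
    def test_partition_of_unity(self, u):
        p = 3
        knots = np.array([0, 0, 0, 0, 0.3, 0.5, 0.8, 1, 1, 1, 1], float)
        total = sum(nurbs_basis(u, j, p, knots) for j in range(len(knots) - p - 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_bspline(self):
        # independent recursive-evaluation oracle via scipy
        p = 3
        knots = np.array([0, 0, 0, 0, 0.2, 0.4, 0.7, 1, 1, 1, 1], float)
        n = len(knots) - p - 1
        for u in (0.05, 0.35, 0.5, 0.91):
            ours = np.array([nurbs_basis(u, j, p, knots) for j in range(n)])
            theirs = BSpline.design_matrix([u], knots, p).toarray()[0]
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_out_of_range_parameter(self):
        knots = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
        with pytest.raises(InvalidArgumentError):
            nurbs_basis(1.5, 0, 3, knots)


class TestNurbsCurve:
    def make_curve(self, weights):
        ctrl = np.array([[0, 0, 0], [1, 2, 0], [3, 2, 1], [4, 0, 1], [6, -1, 2]], float)
        knots = np.array([0, 0, 0, 0, 0.5, 1, 1, 1, 1], float)
        return NurbsCurve(3, ctrl, np.asarray(weights, float), knots)

    def test_clamped_endpoints(self):
        c = self.make_curve([1, 1, 1, 1, 1])
        assert c.evaluate(0.0) == pytest.approx(c.control_points[0])
        assert c.evaluate(1.0) == pytest.approx(c.control_points[-1])

    def test_rational_evaluation_matches_direct_summation(self):
        # brute-force weighted-summation oracle with non-uniform weights
        c = self.make_curve([1.0, 0.5, 2.0, 1.5, 0.8])
        for u in (0.13, 0.42, 0.77):
            basis = np.array([nurbs_basis(u, j, 3, c.knots) for j in range(5)])
            oracle = (basis * c.weights) @ c.control_points / (basis @ c.weights)
            assert c.evaluate(u) == pytest.approx(oracle, abs=1e-12)

    def test_convex_hull_property(self, rng):
        # with positive weights every curve point is a convex combination
        # of the control points: coefficients non-negative, summing to 1
        c = self.make_curve([1.0, 0.5, 2.0, 1.5, 0.8])
        for u in rng.uniform(0, 1, 50):
            basis = np.array([nurbs_basis(u, j, 3, c.knots) for j in range(5)])
            coeff = basis * c.weights / (basis @ c.weights)
            assert np.all(coeff >= -1e-12)
            assert coeff.sum() == pytest.approx(1.0, abs=1e-12)
            assert c.evaluate(u) == pytest.approx(coeff @ c.control_points, abs=1e-12)

    def test_weights_must_be_positive(self):
        with pytest.raises(InvalidArgumentError):
            self.make_curve([1.0, -0.5, 2.0, 1.5, 0.8])

    def test_parameter_range_enforced(self):
        c = self.make_curve([1, 1, 1, 1, 1])
        with pytest.raises(InvalidArgumentError):
            c.evaluate(1.2)


class TestFitCondylarPath:
    def make_trajs(self, a=-0.01, incl=35.0, bennett=12.0, n=30, noise=0.0, rng=None):
        b = -np.tan(np.radians(incl))
        ys = np.linspace(0, 8, n)
        prot = np.column_stack([np.full_like(ys, 55.0), ys, a * ys**2 + b * ys])
        yl = np.linspace(0, 3, n)
        lat = np.column_stack([np.tan(np.radians(bennett)) * yl + 55.0, yl,
                               a * yl**2 + b * yl])
        if noise and rng is not None:
            prot = prot + rng.normal(0, noise, prot.shape)
            lat = lat + rng.normal(0, noise, lat.shape)
        t = np.arange(n) / 100.0
        return (Trajectory(t, prot), Trajectory(t, lat))

    def test_noise_free_fit_reproduces_generator(self):
        prot, lat = self.make_trajs()
        model = fit_condylar_path(prot, lat, "right", rest_y=0.0)
        assert model.bennett_angle == pytest.approx(12.0, abs=1e-9)
        assert model.inclination_angle == pytest.approx(35.0, abs=1e-9)
        for y in np.linspace(0, 8, 15):
            x, z = evaluate_path(model, y)
            assert z == pytest.approx(-0.01 * y**2 - np.tan(np.radians(35.0)) * y, abs=1e-6)
        x, _ = evaluate_path(model, 2.0)
        assert x == pytest.approx(np.tan(np.radians(12.0)) * 2.0 + 55.0, abs=1e-6)

    def test_cubic_nurbs_reproduces_straight_line(self):
        t = np.arange(20) / 100.0
        line = np.outer(np.linspace(0, 1, 20), [1.0, 2.0, -0.5]) + [55.0, 0.0, 0.0]
        prot = Trajectory(t, line)
        lat = Trajectory(t[:5], line[:5])
        model = fit_condylar_path(prot, lat, "right")
        for u in np.linspace(0, 1, 11):
            p = evaluate_nurbs(model, u)
            # point must lie on the line: distance to it vanishes
            d = np.linalg.norm(np.cross(p - line[0], line[-1] - line[0]))
            d /= np.linalg.norm(line[-1] - line[0])
            assert d < 1e-9

    def test_two_point_protrusion_insufficient(self):
        t = np.array([0.0, 0.1])
        pts = np.array([[55.0, 0, 0], [55.0, 1, -0.5]])
        traj = Trajectory(t, pts)
        with pytest.raises(InsufficientDataError):
            fit_condylar_path(traj, traj, "right")

    def test_rest_point_on_path_within_rms(self):
        prot, lat = self.make_trajs()
        model = fit_condylar_path(prot, lat, "right", rest_y=0.0)
        x, z = evaluate_path(model, 0.0)
        assert abs(x - 55.0) <= model.horizontal_rms + 1e-9
        assert abs(z - 0.0) <= model.sagittal_rms + 1e-9

    def test_angle_estimates_invariant_to_uniform_time_resampling(self):
        prot, lat = self.make_trajs(n=40)
        model = fit_condylar_path(prot, lat, "right", rest_y=0.0)
        sub_p = Trajectory(prot.t[::2], prot.points[::2])
        sub_l = Trajectory(lat.t[::2], lat.points[::2])
        resampled = fit_condylar_path(sub_p, sub_l, "right", rest_y=0.0)
        assert resampled.bennett_angle == pytest.approx(model.bennett_angle, abs=1e-9)
        assert resampled.inclination_angle == pytest.approx(model.inclination_angle, abs=1e-9)


class TestEvaluatePath:
    def test_extrapolation_is_linear_endpoint_extension(self):
        prot, lat = TestFitCondylarPath().make_trajs()
        model = fit_condylar_path(prot, lat, "right", rest_y=0.0)
        a, b, c = model.sagittal_coeffs
        hi = model.y_domain[1]
        with pytest.warns(DomainExtrapolationWarning):
            x, z = evaluate_path(model, hi + 2.0)
        # symbolic extension: value + slope continuation from the endpoint
        z_edge = a * hi**2 + b * hi + c
        slope = 2 * a * hi + b
        assert z == pytest.approx(z_edge + 2.0 * slope, abs=1e-12)
        m, k = model.horizontal_coeffs
        assert x == pytest.approx(m * (hi + 2.0) + k, abs=1e-12)

    def test_inside_domain_matches_polynomials(self):
        prot, lat = TestFitCondylarPath().make_trajs()
        model = fit_condylar_path(prot, lat, "right", rest_y=0.0)
        a, b, c = model.sagittal_coeffs
        m, k = model.horizontal_coeffs
        y = 0.5 * (model.y_domain[0] + model.y_domain[1])
        with warnings.catch_warnings():
            warnings.simplefilter("error", DomainExtrapolationWarning)
            x, z = evaluate_path(model, y)
        assert z == pytest.approx(a * y**2 + b * y + c, abs=1e-12)
        assert x == pytest.approx(m * y + k, abs=1e-12)
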
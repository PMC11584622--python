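import math

import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize

from svmewma import (
    DataError,
    LabeledSet,
    PatientRecord,
    SeparabilityError,
    StandardizationError,
    fit_svr,
    margin_of,
    predict_svr,
    solve_max_margin,
    sr_svm,
)
from svmewma.svm import linear_kernel, rbf_kernel


# ---------------------------------------------------------------------------
# independent QP oracles (generic constrained solver on the explicit duals)

def qp_margin_oracle(X, y):
    """Brute-force solution of the hard-margin dual via SLSQP."""
    K = (y[:, None] * X) @ (y[:, None] * X).T

    def obj(a):
        return 0.5 * a @ K @ a - a.sum()

    def grad(a):
        return K @ a - 1.0

    res = minimize(
        obj, np.full(len(y), 0.1), jac=grad, method="SLSQP",
        bounds=[(0, None)] * len(y),
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert res.success, res.message
    return res.x, obj(res.x)


def qp_svr_oracle(X, y, C, eps, kernel):
    """Brute-force eps-SVR dual (2n box-constrained variables) via SLSQP."""
    n = len(y)
    K = kernel(X, X)
    s = np.r_[np.ones(n), -np.ones(n)]
    p = np.r_[eps - y, eps + y]

    def obj(l):
        b = l[:n] - l[n:]
        return 0.5 * b @ K @ b + p @ l

    def grad(l):
        b = l[:n] - l[n:]
        return np.r_[K @ b, -(K @ b)] + p

    res = minimize(
        obj, np.full(2 * n, C / 4), jac=grad, method="SLSQP",
        bounds=[(0, C)] * (2 * n),
        constraints=[LinearConstraint(s, 0, 0)],
        options={"maxiter": 3000, "ftol": 1e-14},
    )
    assert res.success, res.message
    return res.x, obj(res.x)


def random_separable_instance(rng, d, l, gap=0.4):
    """A linearly separable labeled set with margin at least ``gap``."""
    while True:
        w = rng.standard_normal(d)
        w /= np.linalg.norm(w)
        b = rng.uniform(-0.5, 0.5)
        X = rng.uniform(-2, 2, size=(4 * l, d))
        m = X @ w + b
        keep = np.abs(m) >= gap
        X, m = X[keep][:l], m[keep][:l]
        if len(X) == l and len(np.unique(np.sign(m))) == 2:
            return LabeledSet(X, np.sign(m))


# ---------------------------------------------------------------------------

class TestMaxMargin:
    def test_symmetric_two_point_problem(self):
        cls = solve_max_margin(LabeledSet([[-1.0], [1.0]], [-1, 1]))
        assert cls.omega[0] == pytest.approx(1.0, abs=1e-9)
        assert cls.b == pytest.approx(0.0, abs=1e-9)
        assert margin_of(cls) == pytest.approx(2.0, abs=1e-9)

    def test_six_point_toy_set_matches_qp_oracle(self):
        X = np.array([[0, 0], [1, 0], [0, 1], [3, 3], [4, 3], [3, 4]], float)
        y = np.array([-1, -1, -1, 1, 1, 1], float)
        cls = solve_max_margin(LabeledSet(X, y), tol=1e-12)
        a_ref, obj_ref = qp_margin_oracle(X, y)
        assert cls.objective == pytest.approx(obj_ref, abs=1e-6)
        w_ref = (a_ref * y) @ X
        assert np.allclose(cls.omega, w_ref, atol=1e-5)

    def test_scaling_points_rescales_normal_and_margin(self):
        X = np.array([[0, 0], [1, 0], [3, 3], [4, 3]], float)
        y = np.array([-1, -1, 1, 1], float)
        c = 3.0
        c1 = solve_max_margin(LabeledSet(X, y), tol=1e-12)
        c2 = solve_max_margin(LabeledSet(c * X, y), tol=1e-12)
        assert np.allclose(c2.omega, c1.omega / c, atol=1e-8)
        assert margin_of(c2) == pytest.approx(c * margin_of(c1), rel=1e-8)

    def test_agrees_with_oracle_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            d = int(rng.integers(1, 4))
            l = int(rng.integers(4, 13))
            data = random_separable_instance(rng, d, l)
            cls = solve_max_margin(data, tol=1e-12)
            _, obj_ref = qp_margin_oracle(data.X, data.y)
            assert cls.objective <= obj_ref + 1e-6
            # canonical form: nearest point at functional margin 1
            f = data.y * cls.decision_function(data.X)
            assert f.min() == pytest.approx(1.0, abs=1e-6)

    def test_kkt_conditions_hold(self):
        rng = np.random.default_rng(5)
        data = random_separable_instance(rng, 2, 10)
        cls = solve_max_margin(data, tol=1e-12)
        assert np.all(cls.alphas >= -1e-12)
        assert abs(cls.alphas @ data.y) < 1e-8
        # complementary slackness: alpha_i > 0 => point on the margin
        f = data.y * cls.decision_function(data.X)
        on_margin = np.abs(f - 1.0) < 1e-6
        assert np.all(on_margin[cls.alphas > 1e-8 * cls.alphas.max()])

    def test_margin_identity_sum_of_class_distances(self):
        rng = np.random.default_rng(8)
        data = random_separable_instance(rng, 2, 8)
        cls = solve_max_margin(data, tol=1e-12)
        d = np.abs(cls.decision_function(data.X)) / np.linalg.norm(cls.omega)
        total = d[data.y < 0].min() + d[data.y > 0].min()
        assert margin_of(cls) == pytest.approx(total, rel=1e-8)

    def test_srm_style_distance_bound_on_unit_scale_data(self):
        """With well-separated points of norm ~1, no point lies nearer
        than 1/max||x|| to the hyperplane."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            data = random_separable_instance(rng, 2, 8, gap=0.9)
            cls = solve_max_margin(data, tol=1e-12)
            A = float(np.linalg.norm(data.X, axis=1).max())
            nearest = 1.0 / np.linalg.norm(cls.omega)
            assert nearest >= 1.0 / A - 1e-9

    def test_non_separable_raises(self):
        with pytest.raises(SeparabilityError):
            solve_max_margin(LabeledSet([[0.0], [0.05], [0.1]], [1, -1, 1]))

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            LabeledSet([[0.0], [1.0]], [1, 1])


class TestSvr:
    def test_realizable_line_inside_tube(self):
        x = np.arange(8, dtype=float)
        f = fit_svr(x, 2 * x, kernel="linear", C=100.0, epsilon=0.01, tol=1e-9)
        assert np.max(np.abs(2 * x - f.predict(x))) <= 0.01 + 1e-6
        # extrapolating to x=10: the minimum-norm fit may tilt the slope
        # within the tube, so the error can reach eps * (2*10/7 - 1)
        assert f.predict(10.0) == pytest.approx(20.0, abs=0.01 * 13 / 7 + 1e-6)

    def test_constant_target_gives_constant_predictor(self):
        x = np.arange(5, dtype=float)
        f = fit_svr(x, np.full(5, 3.0), kernel="rbf", C=1.0, epsilon=0.1, tol=1e-9)
        assert np.allclose(f.predict(x), 3.0, atol=1e-9)

    def test_dual_matches_qp_oracle(self):
        rng = np.random.default_rng(13)
        for kernel_name in ("linear", "rbf"):
            for _ in range(5):
                n = int(rng.integers(4, 9))
                x = np.sort(rng.uniform(0, 5, n))
                y = np.sin(x) + 0.3 * rng.standard_normal(n)
                gamma = 0.7
                fit = fit_svr(x, y, kernel=kernel_name, C=2.0, epsilon=0.15,
                              gamma=gamma, tol=1e-10)
                kern = (
                    linear_kernel
                    if kernel_name == "linear"
                    else lambda A, B: rbf_kernel(A, B, gamma)
                )
                _, obj_ref = qp_svr_oracle(x.reshape(-1, 1), y, 2.0, 0.15, kern)
                assert fit.objective <= obj_ref + 1e-6

    def test_dual_feasibility(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0, 10, 30)
        y = 0.5 * x + rng.standard_normal(30)
        fit = fit_svr(x, y, C=1.5, epsilon=0.1, tol=1e-8)
        assert np.all(np.abs(fit.beta) <= 1.5 + 1e-9)
        assert abs(fit.beta.sum()) < 1e-6

    def test_matches_sklearn_predictions(self):
        sklearn_svm = pytest.importorskip("sklearn.svm")
        rng = np.random.default_rng(19)
        x = rng.uniform(0, 10, 60)
        y = np.log1p(x) + 0.2 * rng.standard_normal(60)
        gamma = 0.3
        mine = fit_svr(x, y, kernel="rbf", C=2.0, epsilon=0.1, gamma=gamma, tol=1e-9)
        ref = sklearn_svm.SVR(kernel="rbf", C=2.0, epsilon=0.1, gamma=gamma, tol=1e-8)
        ref.fit(x.reshape(-1, 1), y)
        grid = np.linspace(0, 10, 25)
        assert np.allclose(mine.predict(grid), ref.predict(grid.reshape(-1, 1)), atol=1e-3)

    def test_prediction_equals_kernel_expansion(self):
        rng = np.random.default_rng(23)
        x = rng.uniform(0, 5, 20)
        y = x**0.5 + 0.1 * rng.standard_normal(20)
        fit = fit_svr(x, y, kernel="rbf", C=1.0, epsilon=0.05, gamma=0.4)
        pts = rng.uniform(0, 5, 7)
        expansion = rbf_kernel(pts.reshape(-1, 1), fit.X, 0.4) @ fit.beta + fit.b
        assert np.allclose(predict_svr(fit, pts), expansion, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        fit = fit_svr(np.arange(5.0), np.arange(5.0), kernel="linear")
        with pytest.raises(DataError):
            fit.predict(np.zeros((3, 2)))


class TestSrSvm:
    @staticmethod
    def _fixed_predictor():
        # a valid SVR fit whose predictions at 0..2 we can control exactly
        return fit_svr(np.array([0.0, 1.0, 2.0]), np.zeros(3), kernel="linear",
                       C=1.0, epsilon=10.0)

    def test_hand_standardization(self):
        fit = self._fixed_predictor()  # predicts ~0 everywhere
        recs = [
            PatientRecord(parsonnet=0, time_days=math.exp(1.0), censored=False),
            PatientRecord(parsonnet=1, time_days=math.exp(2.0), censored=False),
            PatientRecord(parsonnet=2, time_days=math.exp(3.0), censored=False),
        ]
        series = sr_svm(recs, fit)
        assert np.allclose(series.values, [-1.0, 0.0, 1.0], atol=1e-9)
        assert series.mean == pytest.approx(2.0, abs=1e-9)
        assert series.sd == pytest.approx(1.0, abs=1e-9)

    def test_phase1_always_mean0_sd1(self, phase1_cohort, svr_fit_phase1):
        series = sr_svm(phase1_cohort, svr_fit_phase1)
        assert abs(series.values.mean()) < 1e-8
        assert abs(series.values.std(ddof=1) - 1.0) < 1e-8

    def test_phase2_uses_phase1_constants(self, phase1_cohort, svr_fit_phase1):
        p1 = sr_svm(phase1_cohort, svr_fit_phase1)
        sub = phase1_cohort[:100]
        p2 = sr_svm(sub, svr_fit_phase1, phase1_stats=(p1.mean, p1.sd))
        direct = sr_svm(phase1_cohort, svr_fit_phase1).values[:100]
        assert np.allclose(p2.values, direct, atol=1e-12)

    def test_zero_variance_residuals_raise(self):
        fit = self._fixed_predictor()
        recs = [
            PatientRecord(parsonnet=i, time_days=math.exp(1.0), censored=False)
            for i in range(3)
        ]
        with pytest.raises(StandardizationError):
            sr_svm(recs, fit)
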
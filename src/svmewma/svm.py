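"""Support-vector machinery: maximal-margin classification and eps-SVR.

Two dual quadratic programs are solved here with one SMO-style solver:

* the hard-margin classification dual

      min_a  1/2 sum_ij a_i a_j y_i y_j <x_i, x_j> - sum_i a_i
      s.t.   a_i >= 0,  sum_i a_i y_i = 0,

  whose solution gives the separating hyperplane w* = sum a_i y_i x_i and
  offset b* = -1/2 <w*, x_r + x_s> with x_r, x_s support vectors from each
  class, and the geometric margin 2 / ||w||;

* the eps-insensitive support-vector regression dual (box constraints
  0 <= a_i, a_i* <= C and sum (a_i - a_i*) = 0), used to predict log
  survival from the Parsonnet score.  Its standardized residuals (SR-SVM)
  feed the SVM-based monitoring chart.

Both are instances of  min 1/2 l'Ql + p'l  s.t.  sum_i s_i l_i = 0,
0 <= l_i <= C_i,  with Q_vw = s_v s_w K(x_bv, x_bw); the solver below works
on that generic form using maximal-violating-pair / second-order working-set
selection with an incrementally maintained gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aft import ResidualSeries
from .cohort import PatientRecord
from .exceptions import (
    ConfigurationError,
    ConvergenceError,
    DataError,
    SeparabilityError,
    StandardizationError,
)

__all__ = [
    "LabeledSet",
    "MarginClassifier",
    "SVRFit",
    "solve_max_margin",
    "margin_of",
    "fit_svr",
    "predict_svr",
    "sr_svm",
    "linear_kernel",
    "rbf_kernel",
    "median_heuristic_gamma",
]

_ALPHA_CAP = 1e8  # hard-margin multipliers past this indicate non-separable data
_TAU = 1e-12


# ---------------------------------------------------------------------------
# kernels

def linear_kernel(X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    return np.asarray(X) @ np.asarray(Z).T


def rbf_kernel(X: np.ndarray, Z: np.ndarray, gamma: float) -> np.ndarray:
    if gamma <= 0:
        raise ConfigurationError("rbf gamma must be > 0")
    X, Z = np.atleast_2d(X), np.atleast_2d(Z)
    d2 = (
        (X * X).sum(axis=1)[:, None]
        + (Z * Z).sum(axis=1)[None, :]
        - 2.0 * X @ Z.T
    )
    return np.exp(-gamma * np.maximum(d2, 0.0))


def median_heuristic_gamma(X: np.ndarray, max_points: int = 1024) -> float:
    """gamma = 1 / (2 h^2) with h the median nonzero pairwise distance.

    A deterministic evenly-strided subsample caps the pairwise cost.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n > max_points:
        X = X[:: max(1, n // max_points)][:max_points]
    d2 = (
        (X * X).sum(axis=1)[:, None]
        + (X * X).sum(axis=1)[None, :]
        - 2.0 * X @ X.T
    )
    d = np.sqrt(np.maximum(d2[np.triu_indices_from(d2, k=1)], 0.0))
    d = d[d > 0]
    if d.size == 0:
        return 1.0
    h = float(np.median(d))
    return 1.0 / (2.0 * h * h)


# ---------------------------------------------------------------------------
# generic SMO solver

def _smo(
    K: np.ndarray,
    bidx: np.ndarray,
    s: np.ndarray,
    p: np.ndarray,
    C: np.ndarray,
    tol: float,
    max_iter: int,
    alpha_cap: float | None = None,
):
    """Minimize 1/2 l'Ql + p'l subject to sum s_i l_i = 0, 0 <= l <= C.

    ``Q[v, w] = s[v] s[w] K[bidx[v], bidx[w]]``; only the base kernel matrix
    ``K`` is stored.  Returns ``(l, n_iter, kkt_gap)``.
    """
    m = s.size
    lam = np.zeros(m)
    G = p.astype(float).copy()  # gradient of the objective at lam
    Kd = K[bidx, bidx]
    gap = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        ms = -s * G
        up = ((s > 0) & (lam < C)) | ((s < 0) & (lam > 0))
        low = ((s > 0) & (lam > 0)) | ((s < 0) & (lam < C))
        if not up.any() or not low.any():
            gap = 0.0
            break
        ms_up = np.where(up, ms, -np.inf)
        i = int(np.argmax(ms_up))
        m_up = ms_up[i]
        ms_low = np.where(low, ms, np.inf)
        M_low = float(ms_low.min())
        gap = m_up - M_low
        if gap <= tol:
            break

        # second-order choice of j among violating candidates
        Krow_i = K[bidx[i]][bidx]  # K(x_bi, x_bv) for all variables v
        cand = low & (ms < m_up)
        bvec = m_up - ms
        avec = np.maximum(Kd[i] + Kd - 2.0 * Krow_i, _TAU)
        score = np.where(cand, -(bvec * bvec) / avec, np.inf)
        j = int(np.argmin(score))

        a = avec[j]
        b = -(m_up - ms[j])  # = s_i G_i - s_j G_j, negative for a violating pair
        t = -b / a
        # feasibility bounds on the step t (lam_i += s_i t, lam_j -= s_j t)
        if s[i] > 0:
            lo_t, hi_t = -lam[i], C[i] - lam[i]
        else:
            lo_t, hi_t = lam[i] - C[i], lam[i]
        if s[j] > 0:
            lo_t, hi_t = max(lo_t, lam[j] - C[j]), min(hi_t, lam[j])
        else:
            lo_t, hi_t = max(lo_t, -lam[j]), min(hi_t, C[j] - lam[j])
        t = float(np.clip(t, lo_t, hi_t))
        if t == 0.0:
            break  # numerically stalled at the active set boundary

        lam[i] += s[i] * t
        lam[j] -= s[j] * t
        np.clip(lam, 0.0, C, out=lam)
        Krow_j = K[bidx[j]][bidx]
        G += (t * s) * (Krow_i - Krow_j)

        if alpha_cap is not None and (lam[i] > alpha_cap or lam[j] > alpha_cap):
            raise SeparabilityError(
                "dual variables diverged: the data are not linearly separable "
                "(hard margin has no solution)"
            )
    else:
        raise ConvergenceError(
            f"SMO did not reach tolerance {tol:g} in {max_iter} iterations "
            f"(KKT gap {gap:.3g})"
        )
    return lam, it, gap


def _dual_objective(K, bidx, s, p, lam) -> float:
    q = s * lam
    v = np.zeros(K.shape[0])
    np.add.at(v, bidx, q)
    return float(0.5 * v @ K @ v + p @ lam)


def _check_separable(X: np.ndarray, y: np.ndarray) -> None:
    """Raise when no hyperplane satisfies y_i (<w, x_i> + b) >= 1.

    Strict linear separability is an LP feasibility question in (w, b);
    solving it up front gives a clean error instead of a diverging dual.
    """
    from scipy.optimize import linprog

    l, d = X.shape
    # variables (w, b); constraints -y_i (x_i . w + b) <= -1
    A = -y[:, None] * np.column_stack([X, np.ones(l)])
    res = linprog(
        c=np.zeros(d + 1),
        A_ub=A,
        b_ub=-np.ones(l),
        bounds=[(None, None)] * (d + 1),
        method="highs",
    )
    if not res.success:
        raise SeparabilityError(
            "data are not linearly separable; the hard-margin problem is infeasible"
        )


# ---------------------------------------------------------------------------
# hard-margin classification

@dataclass(frozen=True)
class LabeledSet:
    """Binary-labeled points for maximal-margin classification."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise DataError("X and y lengths differ")
        if not set(np.unique(y)) <= {-1.0, 1.0}:
            raise DataError("labels must be in {-1, +1}")
        if len(np.unique(y)) < 2:
            raise DataError("both classes must be present")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def l(self) -> int:
        return self.y.size


@dataclass(frozen=True)
class MarginClassifier:
    """Canonical-form separating hyperplane <w, x> + b with its multipliers."""

    omega: np.ndarray
    b: float
    alphas: np.ndarray
    support_indices: np.ndarray
    objective: float

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, dtype=float)) @ self.omega + self.b


def solve_max_margin(
    data: LabeledSet, tol: float = 1e-10, max_iter: int = 100_000
) -> MarginClassifier:
    """Solve the hard-margin dual QP and recover the canonical hyperplane.

    Raises :class:`SeparabilityError` when the two classes cannot be split
    by a hyperplane (the dual is then unbounded).
    """
    X, y = data.X, data.y
    l = data.l
    _check_separable(X, y)
    K = linear_kernel(X, X)
    bidx = np.arange(l)
    C = np.full(l, np.inf)
    lam, _, _ = _smo(K, bidx, y, -np.ones(l), C, tol, max_iter, alpha_cap=_ALPHA_CAP)

    omega = (lam * y) @ X
    amax = lam.max()
    if amax <= 0:
        raise SeparabilityError("degenerate dual solution (all multipliers zero)")
    support = np.flatnonzero(lam > 1e-8 * amax)
    # x_r, x_s: the support vector with the largest multiplier in each class
    pos = support[y[support] > 0]
    neg = support[y[support] < 0]
    if pos.size == 0 or neg.size == 0:
        raise SeparabilityError("no support vector in one class; data not separable")
    r = pos[np.argmax(lam[pos])]
    s_ = neg[np.argmax(lam[neg])]
    b = -0.5 * float(omega @ (X[r] + X[s_]))
    obj = _dual_objective(K, bidx, y, -np.ones(l), lam)
    return MarginClassifier(
        omega=omega, b=b, alphas=lam, support_indices=support, objective=obj
    )


def margin_of(cls: MarginClassifier) -> float:
    """Geometric margin 2 / ||w|| of a canonical-form classifier."""
    norm = float(np.linalg.norm(cls.omega))
    if norm <= 0:
        raise DataError("zero normal vector: degenerate classifier")
    return 2.0 / norm


# ---------------------------------------------------------------------------
# eps-insensitive support-vector regression

@dataclass(frozen=True)
class SVRFit:
    """Dual solution of eps-SVR: f(x) = sum_i beta_i K(x_i, x) + b."""

    X: np.ndarray  # training inputs, (n, d)
    beta: np.ndarray  # alpha_i - alpha_i^* per training point
    b: float
    kernel: str
    gamma: float | None
    C: float
    epsilon: float
    objective: float
    n_iter: int = 0

    def _k(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.X.shape[1]:
            raise DataError(
                f"input dimension {Z.shape[1]} != training dimension {self.X.shape[1]}"
            )
        if self.kernel == "linear":
            return linear_kernel(Z, self.X)
        return rbf_kernel(Z, self.X, self.gamma)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        if x.ndim <= 1 and self.X.shape[1] == 1:
            x = x.reshape(-1, 1)
        out = self._k(x) @ self.beta + self.b
        return float(out[0]) if scalar else out

    @property
    def support_indices(self) -> np.ndarray:
        return np.flatnonzero(np.abs(self.beta) > 1e-10 * max(self.C, 1.0))


def fit_svr(
    x,
    y,
    kernel: str = "rbf",
    C: float = 1.0,
    epsilon: float = 0.1,
    gamma: float | None = None,
    tol: float = 1e-4,
    max_iter: int = 2_000_000,
) -> SVRFit:
    """Fit eps-insensitive SVR by solving its dual QP.

    Defaults: rbf kernel with the median-pairwise-distance bandwidth, C=1,
    eps=0.1.  ``tol`` is the KKT gap at which the SMO loop stops; tighten it
    (e.g. 1e-9) when exact agreement with a reference QP solution is needed
    on small problems.
    """
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    yv = np.asarray(y, dtype=float).ravel()
    n = yv.size
    if X.shape[0] != n:
        raise DataError("x and y lengths differ")
    if n < 2:
        raise DataError("need at least 2 points to fit SVR")
    if C <= 0:
        raise ConfigurationError("C must be > 0")
    if epsilon < 0:
        raise ConfigurationError("epsilon must be >= 0")
    if kernel not in ("linear", "rbf"):
        raise ConfigurationError(f"unsupported kernel {kernel!r}")
    if kernel == "rbf":
        if gamma is None:
            gamma = median_heuristic_gamma(X)
        if gamma <= 0:
            raise ConfigurationError("rbf gamma must be > 0")
        K = rbf_kernel(X, X, gamma)
    else:
        gamma = None
        K = linear_kernel(X, X)

    # 2n variables: (alpha_1..n | alpha*_1..n), signs (+1 | -1)
    bidx = np.r_[np.arange(n), np.arange(n)]
    s = np.r_[np.ones(n), -np.ones(n)]
    p = np.r_[epsilon - yv, epsilon + yv]
    Cv = np.full(2 * n, float(C))
    lam, n_iter, _ = _smo(K, bidx, s, p, Cv, tol, max_iter)
    beta = lam[:n] - lam[n:]

    # offset b from the KKT conditions: free alpha => y - f = +eps,
    # free alpha* => y - f = -eps; fall back to the midpoint of the
    # feasible interval when no multiplier is strictly inside the box.
    f0 = K @ beta
    free_hi = (lam[:n] > 1e-8 * C) & (lam[:n] < C * (1 - 1e-8))
    free_lo = (lam[n:] > 1e-8 * C) & (lam[n:] < C * (1 - 1e-8))
    b_vals = np.r_[yv[free_hi] - f0[free_hi] - epsilon, yv[free_lo] - f0[free_lo] + epsilon]
    if b_vals.size:
        b = float(b_vals.mean())
    else:
        # bounds: for alpha_i = 0 need y - f - b <= eps, alpha_i = C need >= eps, etc.
        r = yv - f0
        ub = np.r_[r[lam[:n] <= 1e-8 * C] + epsilon, r[lam[n:] >= C * (1 - 1e-8)] + epsilon]
        lb = np.r_[r[lam[:n] >= C * (1 - 1e-8)] - epsilon, r[lam[n:] <= 1e-8 * C] - epsilon]
        hi = float(ub.min()) if ub.size else 0.0
        lo = float(lb.max()) if lb.size else 0.0
        b = 0.5 * (lo + hi)

    obj = _dual_objective(K, bidx, s, p, lam)
    return SVRFit(
        X=X, beta=beta, b=b, kernel=kernel, gamma=gamma, C=float(C),
        epsilon=float(epsilon), objective=obj, n_iter=n_iter,
    )


def predict_svr(fit: SVRFit, x) -> np.ndarray:
    """Evaluate the fitted regression function, vectorized over inputs."""
    return fit.predict(x)


def sr_svm(
    cohort: list[PatientRecord],
    fit: SVRFit,
    phase1_stats: tuple[float, float] | None = None,
) -> ResidualSeries:
    """Standardized SVM-regression residuals (SR-SVM).

    Raw residual r_t = log T_t - f(P_t) on uncensored records.  When
    ``phase1_stats`` is None the cohort itself is the Phase-I pool and the
    residuals are standardized by their own mean and sample SD (n-1
    denominator); the returned series records those constants so Phase-II
    streams can be standardized identically by passing ``(mean, sd)``.
    """
    recs = [r for r in cohort if not r.censored]
    if len(recs) < 2:
        raise DataError("need at least 2 uncensored records for SR-SVM")
    p = np.array([r.parsonnet for r in recs], dtype=float)
    logt = np.log([r.time_days for r in recs])
    raw = logt - fit.predict(p)
    if phase1_stats is None:
        mean, sd = float(raw.mean()), float(raw.std(ddof=1))
    else:
        mean, sd = map(float, phase1_stats)
    if sd <= 1e-12:
        raise StandardizationError(
            "raw SVM residuals have zero spread; the model interpolates the "
            "training data - increase epsilon or decrease C"
        )
    return ResidualSeries(values=(raw - mean) / sd, source="SR_SVM", mean=mean, sd=sd)
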
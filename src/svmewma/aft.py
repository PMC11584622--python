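"""Accelerated failure time (AFT) risk adjustment and its standardized residuals.

The Phase-I model is the log-linear AFT regression

    log T_t = beta0 + beta1 * P_t (+ group effects) + sigma * eps_t,

fitted by maximum likelihood with right-censored records contributing
survivor-function terms.  The monitored quantity is the standardized
residual

    e_t = (log T_t - x_t' beta) / sigma,

often written w_t and called SR-AFT: under the in-control model it has mean
zero and unit standard deviation, so downward shifts in survival show up as
a downward drift of the residual stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

from .cohort import PatientRecord, error_distribution
from .exceptions import DataError, FittingError

__all__ = ["AFTFit", "ResidualSeries", "fit_aft", "sr_aft"]

_MIN_LOG_SIGMA = -30.0


@dataclass(frozen=True)
class ResidualSeries:
    """A stream of standardized residuals plus the pool statistics behind it.

    ``mean``/``sd`` are the statistics of the residual pool used downstream:
    the clip level xi of the one-sided EWMA is the pool mean and the control
    limit width scales with the pool SD.  For SVM residuals standardized
    against a Phase-I pool, ``mean``/``sd`` are the *raw* Phase-I statistics
    so Phase-II streams can be standardized with the same constants.
    """

    values: np.ndarray
    source: str  # "SR_AFT" | "SR_SVM"
    mean: float
    sd: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size and not np.all(np.isfinite(v)):
            raise DataError("residual series contains non-finite values")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class AFTFit:
    """Maximum-likelihood estimates of the log-linear survival model."""

    beta0: float
    beta1: float
    sigma: float
    extra_betas: dict = field(default_factory=dict)
    loglik: float = float("nan")
    n_used: int = 0
    n_censored_used: int = 0
    error_dist: str = "standard_normal"

    def linear_predictor(self, cohort: list[PatientRecord]) -> np.ndarray:
        """x_t' beta for each record (intercept + Parsonnet + group dummies)."""
        p = np.array([r.parsonnet for r in cohort], dtype=float)
        mu = self.beta0 + self.beta1 * p
        if self.extra_betas:
            for i, r in enumerate(cohort):
                mu[i] += self.extra_betas.get(f"group:{r.group}", 0.0)
        return mu


def _design(cohort: list[PatientRecord], include_groups: bool):
    p = np.array([r.parsonnet for r in cohort], dtype=float)
    cols = [np.ones_like(p), p]
    names: list[str] = []
    if include_groups:
        labels = sorted({r.group for r in cohort if r.group is not None})
        # drop the first label as the reference level
        for g in labels[1:]:
            cols.append(np.array([1.0 if r.group == g else 0.0 for r in cohort]))
            names.append(f"group:{g}")
    return np.column_stack(cols), names


def _neg_loglik(theta, X, y, cens, dist):
    beta = theta[:-1]
    sigma = np.exp(np.clip(theta[-1], _MIN_LOG_SIGMA, 30.0))
    z = (y - X @ beta) / sigma
    ll = np.where(cens, dist.logsf(z), dist.logpdf(z) - np.log(sigma))
    return -float(ll.sum())


def fit_aft(
    cohort: list[PatientRecord],
    error_dist: str = "standard_normal",
    include_groups: bool = False,
) -> AFTFit:
    """Censored maximum-likelihood fit of the AFT model.

    Censored records enter through the survivor function, so 30-day
    censoring does not bias the coefficients.  The optimizer starts from the
    ordinary least squares fit on the uncensored records, which makes the
    result deterministic given the data.  For uncensored cohorts with normal
    errors the MLE has the closed form of OLS with the n-denominator sigma,
    which is used directly.
    """
    if not cohort:
        raise DataError("empty cohort")
    dist = error_distribution(error_dist)
    y = np.log([r.time_days for r in cohort])
    cens = np.array([r.censored for r in cohort])
    X, extra_names = _design(cohort, include_groups)
    n, k = X.shape
    n_unc = int((~cens).sum())
    if n_unc < 2:
        raise FittingError(
            f"need at least 2 uncensored records to fit the AFT model, got {n_unc}"
        )

    Xu, yu = X[~cens], y[~cens]
    beta_ols, *_ = np.linalg.lstsq(Xu, yu, rcond=None)
    resid = yu - Xu @ beta_ols
    sigma_ols = float(np.sqrt((resid @ resid) / max(n_unc, 1)))

    if not cens.any() and error_dist == "standard_normal":
        # exact MLE: OLS coefficients, n-denominator sigma
        sigma = max(sigma_ols, 1e-12)
        ll = -_neg_loglik(np.r_[beta_ols, np.log(sigma)], X, y, cens, dist)
        beta = beta_ols
    else:
        theta0 = np.r_[beta_ols, np.log(max(sigma_ols, 1e-6))]
        res = optimize.minimize(
            _neg_loglik,
            theta0,
            args=(X, y, cens, dist),
            method="BFGS",
            options={"maxiter": 500, "gtol": 1e-8},
        )
        if not np.all(np.isfinite(res.x)):
            raise FittingError(f"AFT fit did not converge: {res.message}")
        # BFGS may stop on precision loss very close to the optimum; only a
        # genuinely large gradient counts as failure.
        if not res.success and np.max(np.abs(res.jac)) > 1e-2 * max(1.0, abs(res.fun)):
            raise FittingError(
                f"AFT fit did not converge: {res.message} (|grad|={np.abs(res.jac).max():.3g})"
            )
        beta = res.x[:-1]
        sigma = float(np.exp(res.x[-1]))
        ll = -float(res.fun)

    return AFTFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        sigma=float(sigma),
        extra_betas=dict(zip(extra_names, beta[2:].tolist())),
        loglik=ll,
        n_used=n,
        n_censored_used=int(cens.sum()),
        error_dist=error_dist,
    )


def _conditional_tail_mean(dist, c: float) -> float:
    """E[eps | eps > c] for the fitted error law."""
    sf = dist.sf(c)
    if sf <= 0:
        return c
    val, _ = integrate.quad(lambda u: u * dist.pdf(u), c, np.inf)
    return val / sf


def sr_aft(
    cohort: list[PatientRecord],
    fit: AFTFit,
    censored_policy: str = "exclude",
) -> ResidualSeries:
    """Standardized AFT residuals e_t = (log T_t - x_t' beta) / sigma.

    The residual is undefined for a censored time (log T is only a lower
    bound), so censored records are excluded by default.  The alternative
    policy ``impute_conditional`` replaces a censored residual by the
    conditional expectation E[eps | eps > c_t] under the fitted error law.
    """
    if fit.sigma <= 0:
        raise FittingError("fit.sigma must be > 0 to standardize residuals")
    if any(r.time_days <= 0 for r in cohort):
        raise DataError("non-positive survival time in cohort")
    if censored_policy not in ("exclude", "impute_conditional"):
        raise DataError(f"unknown censored_policy {censored_policy!r}")

    mu = fit.linear_predictor(cohort)
    logt = np.log([r.time_days for r in cohort])
    e = (logt - mu) / fit.sigma
    cens = np.array([r.censored for r in cohort])

    if censored_policy == "exclude":
        e = e[~cens]
    else:
        dist = error_distribution(fit.error_dist)
        for i in np.flatnonzero(cens):
            e[i] = _conditional_tail_mean(dist, e[i])

    if e.size == 0:
        raise DataError("no residuals left after censoring policy was applied")
    sd = float(e.std(ddof=1)) if e.size > 1 else 0.0
    return ResidualSeries(values=e, source="SR_AFT", mean=float(e.mean()), sd=sd)
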
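"""Monte-Carlo run-length engine: ARL/SDRL estimation and L calibration.

Residual streams are drawn i.i.d. with replacement from a Phase-I pool
(bootstrap) or, for closed-form oracle work, from a standard normal law.  A
shift of magnitude delta is applied in the signaling (downward) direction:
the monitored stream is v_t - delta, so larger shifts are detected faster
by the lower-sided chart.

Common random numbers
---------------------
Control-limit calibration bisects on L and needs the estimated ARL to be a
monotone, noise-free function of L across evaluations.  The engine therefore
draws residuals through a counter-based pseudo-random mapping u(run, step)
(a SplitMix64-style 64-bit mixer keyed by the evaluation seed): replication
r sees exactly the same residual stream whatever L is, so the estimated
run-length of each replication is non-decreasing in L and so is the ARL.
The mapping is also what makes estimates exactly reproducible for a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aft import ResidualSeries
from .chart import ChartConfig, ewma_sigma_inf, run_chart
from .exceptions import CalibrationError, ConfigurationError, DataError

__all__ = [
    "ResidualPool",
    "GaussianPool",
    "ShiftGrid",
    "DEFAULT_SHIFT_GRID",
    "RunLengthSummary",
    "CalibrationResult",
    "simulate_run_length",
    "estimate_rl_profile",
    "calibrate_L",
    "shift_table",
    "compare_charts",
    "chart_config_for",
]

#: The shift-magnitude grid used for the published run-length tables.
DEFAULT_SHIFT_GRID = (
    0.0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.10,
    0.40, 1.00, 2.00,
)

_PCT_LABELS = ("P05", "P10", "P25", "P50", "P75", "P90", "P95")
_PCT_Q = (5, 10, 25, 50, 75, 90, 95)


@dataclass(frozen=True)
class ResidualPool:
    """A Phase-I pool of standardized residuals to bootstrap streams from."""

    values: np.ndarray
    source: str = "SR_SVM"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size == 0:
            raise DataError("empty residual pool")
        if not np.all(np.isfinite(v)):
            raise DataError("residual pool contains non-finite values")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_series(cls, series: ResidualSeries) -> "ResidualPool":
        return cls(values=series.values, source=series.source)

    @property
    def mu(self) -> float:
        return float(self.values.mean())

    @property
    def sigma(self) -> float:
        return float(self.values.std(ddof=1))


class GaussianPool:
    """Parametric standard-normal residual stream (closed-form oracle work)."""

    source = "NORMAL"
    mu = 0.0
    sigma = 1.0
    values = None


@dataclass(frozen=True)
class ShiftGrid:
    """Ascending grid of nonnegative shift magnitudes delta."""

    deltas: tuple[float, ...] = DEFAULT_SHIFT_GRID

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.deltas)
        if any(x < 0 for x in d):
            raise ConfigurationError("shift magnitudes must be >= 0")
        if list(d) != sorted(d):
            raise ConfigurationError("shift grid must be sorted ascending")
        object.__setattr__(self, "deltas", d)


@dataclass(frozen=True)
class RunLengthSummary:
    """ARL, SDRL and percentiles of a simulated run-length sample."""

    arl: float
    sdrl: float
    percentiles: dict
    reps: int
    censored_runs: int
    seed: int

    @property
    def se(self) -> float:
        """Monte-Carlo standard error of the ARL estimate."""
        return self.sdrl / math.sqrt(self.reps)


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated control coefficient and the ARL it achieves."""

    L: float
    arl0_hat: float
    se: float
    target: float
    reps: int
    seed: int
    n_evals: int
    config: ChartConfig


# ---------------------------------------------------------------------------
# counter-based uniform/normal/bootstrap draws (SplitMix64 finalizer)

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_C1 = np.uint64(0xBF58476D1CE4E5B9)
_C2 = np.uint64(0x94D049BB133111EB)
_SHIFT_RUN = np.uint64(22)  # horizon (<= 2^20 steps) and one sub-draw bit below


def _mix64(z: np.ndarray) -> np.ndarray:
    z = z.copy()
    z ^= z >> np.uint64(30)
    z *= _C1
    z ^= z >> np.uint64(27)
    z *= _C2
    z ^= z >> np.uint64(31)
    return z


def _uniform(seed: np.uint64, run_ids: np.ndarray, t: int, j: int) -> np.ndarray:
    counter = (run_ids.astype(np.uint64) << _SHIFT_RUN) | np.uint64(2 * t + j)
    z = _mix64(seed + counter * _GOLDEN)
    return (z >> np.uint64(11)).astype(np.float64) * (2.0 ** -53)


def _draw(pool, seed, run_ids, t: int) -> np.ndarray:
    if isinstance(pool, GaussianPool):
        u1 = np.maximum(_uniform(seed, run_ids, t, 0), 1e-300)
        u2 = _uniform(seed, run_ids, t, 1)
        return np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)
    u = _uniform(seed, run_ids, t, 0)
    idx = np.minimum((u * pool.values.size).astype(np.int64), pool.values.size - 1)
    return pool.values[idx]


def _run_lengths(pool, cfg: ChartConfig, delta: float, reps: int, seed: int):
    """Vectorized run lengths of ``reps`` independent chart runs.

    Replication r's residual stream is a fixed function of ``(seed, r)``,
    independent of the chart parameters (common random numbers).
    """
    if cfg.horizon >= 2**21:
        raise ConfigurationError(
            "horizon must be < 2^21 so (run, step) counters stay disjoint"
        )
    seed_u = np.uint64(int(seed) & 0xFFFFFFFFFFFFFFFF)
    lam, xi = cfg.lam, cfg.xi
    one_m = 1.0 - lam
    rl = np.zeros(reps, dtype=np.int64)
    ids = np.arange(reps, dtype=np.int64)
    F = np.full(reps, float(cfg.z0))
    if cfg.limit_mode == "asymptotic":
        limit_at = lambda t: cfg.mu_e - cfg.L * ewma_sigma_inf(lam, cfg.sigma_e)
    else:
        base = cfg.mu_e
        amp = cfg.L * cfg.sigma_e * math.sqrt(lam / (2.0 - lam))
        limit_at = lambda t: base - amp * math.sqrt(1.0 - one_m ** (2.0 * t))
    t = 0
    while ids.size and t < cfg.horizon:
        t += 1
        v = _draw(pool, seed_u, ids, t) - delta
        F = np.minimum(lam * v + one_m * F, xi)
        sig = F < limit_at(t)
        if sig.any():
            rl[ids[sig]] = t
            keep = ~sig
            ids = ids[keep]
            F = F[keep]
    censored = ids.size
    rl[ids] = cfg.horizon
    return rl, censored


def _stream_for_run(pool, seed: int, run_id: int, n_steps: int) -> np.ndarray:
    """The exact residual stream replication ``run_id`` sees (test hook)."""
    seed_u = np.uint64(int(seed) & 0xFFFFFFFFFFFFFFFF)
    ids = np.array([run_id], dtype=np.int64)
    return np.array([_draw(pool, seed_u, ids, t)[0] for t in range(1, n_steps + 1)])


# ---------------------------------------------------------------------------
# public engine API

def _seed_from(rng) -> int:
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(rng, (int, np.integer)):
        return int(rng)
    return int(rng.integers(0, 2**63 - 1))


def simulate_run_length(pool, cfg: ChartConfig, delta: float, rng) -> tuple[int, bool]:
    """One chart run on a bootstrapped (shifted) residual stream.

    Scalar counterpart of the vectorized engine: draws through the supplied
    numpy Generator and runs :func:`run_chart` step by step.
    """
    if delta < 0:
        raise ConfigurationError("shift magnitude delta must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    def stream():
        while True:
            if isinstance(pool, GaussianPool):
                chunk = rng.standard_normal(256)
            else:
                chunk = pool.values[rng.integers(0, pool.values.size, 256)]
            yield from chunk - delta

    res = run_chart(stream(), cfg, record_path=False)
    return res.run_length, res.signaled


def estimate_rl_profile(
    pool, cfg: ChartConfig, delta: float, reps: int, rng=None
) -> RunLengthSummary:
    """ARL/SDRL/percentiles over ``reps`` simulated run lengths.

    Percentiles use linear interpolation between order statistics, so they
    can take fractional values.  Runs that reach the horizon are counted at
    the horizon and reported in ``censored_runs``.
    """
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    if delta < 0:
        raise ConfigurationError("shift magnitude delta must be >= 0")
    seed = _seed_from(rng)
    rl, censored = _run_lengths(pool, cfg, delta, reps, seed)
    pct = np.percentile(rl, _PCT_Q)  # linear interpolation (numpy default)
    return RunLengthSummary(
        arl=float(rl.mean()),
        sdrl=float(rl.std(ddof=1)) if reps > 1 else 0.0,
        percentiles=dict(zip(_PCT_LABELS, map(float, pct))),
        reps=reps,
        censored_runs=censored,
        seed=seed,
    )


def chart_config_for(
    pool,
    lam: float,
    L: float,
    xi: float | None = None,
    limit_mode: str = "time_varying",
    horizon: int = 1_000_000,
) -> ChartConfig:
    """Chart configuration whose clip level and limit scale come from the pool."""
    return ChartConfig(
        lam=lam,
        L=L,
        xi=pool.mu if xi is None else xi,
        mu_e=pool.mu,
        sigma_e=pool.sigma,
        limit_mode=limit_mode,
        horizon=horizon,
    )


def calibrate_L(
    pool,
    lam: float,
    target_arl0: float,
    reps: int = 20_000,
    rng=None,
    tol: float | None = None,
    L_bounds: tuple[float, float] = (0.2, 8.0),
    xi: float | None = None,
    limit_mode: str = "time_varying",
    horizon: int = 1_000_000,
    max_iter: int = 80,
) -> CalibrationResult:
    """Find the control coefficient L achieving a target in-control ARL.

    Brackets then bisects on L.  Every ARL evaluation reuses the same
    evaluation seed (common random numbers), which makes the estimated
    ARL(L) curve a non-decreasing step function and the search monotone.
    The bracket is grown upward from ``L_bounds[0]`` in small multiplicative
    steps, so no evaluation ever lands at an L whose ARL is orders of
    magnitude beyond the target; evaluations are additionally truncated at
    25x the target run length, which is immaterial near the optimum
    (P(RL > 25 ARL) ~ e^-25 for a near-geometric run length) but keeps
    overshooting evaluations cheap.  Default tolerance:
    ``max(1, 0.5% of target)``.
    """
    if target_arl0 <= 1:
        raise CalibrationError("target in-control ARL must be > 1")
    if tol is None:
        tol = max(1.0, 0.005 * target_arl0)
    seed = _seed_from(rng)
    min_floor = 30
    if isinstance(pool, ResidualPool) and pool.values.size < min_floor:
        raise DataError(
            f"residual pool of size {pool.values.size} is below the "
            f"calibration floor of {min_floor}"
        )
    cal_horizon = int(min(horizon, max(10_000, math.ceil(25 * target_arl0))))

    def arl_at(L: float) -> float:
        cfg = chart_config_for(pool, lam, L, xi=xi, limit_mode=limit_mode, horizon=cal_horizon)
        rl, _ = _run_lengths(pool, cfg, 0.0, reps, seed)
        return float(rl.mean())

    n_evals = 0
    lo, hi = L_bounds
    f_lo = arl_at(lo)
    n_evals += 1
    if f_lo > target_arl0:
        raise CalibrationError(
            f"ARL at the lower bound L={lo} is already {f_lo:.1f} > target"
        )
    f_hi, hi = f_lo, lo
    while f_hi < target_arl0:
        if hi >= L_bounds[1]:
            raise CalibrationError(
                f"could not bracket the target ARL below L={L_bounds[1]}: "
                f"ARL({hi:.2f}) = {f_hi:.1f}"
            )
        lo, f_lo = hi, f_hi
        hi = min(hi * 1.25, L_bounds[1])
        f_hi = arl_at(hi)
        n_evals += 1

    best_L, best_f = (lo, f_lo) if abs(f_lo - target_arl0) < abs(f_hi - target_arl0) else (hi, f_hi)
    for _ in range(max_iter):
        if abs(best_f - target_arl0) <= tol or hi - lo < 1e-6:
            break
        mid = 0.5 * (lo + hi)
        f_mid = arl_at(mid)
        n_evals += 1
        if abs(f_mid - target_arl0) < abs(best_f - target_arl0):
            best_L, best_f = mid, f_mid
        if f_mid < target_arl0:
            lo = mid
        else:
            hi = mid

    cfg = chart_config_for(pool, lam, best_L, xi=xi, limit_mode=limit_mode, horizon=horizon)
    rl, _ = _run_lengths(pool, cfg, 0.0, reps, seed)
    se = float(rl.std(ddof=1)) / math.sqrt(reps)
    return CalibrationResult(
        L=float(best_L),
        arl0_hat=float(rl.mean()),
        se=se,
        target=float(target_arl0),
        reps=reps,
        seed=seed,
        n_evals=n_evals,
        config=cfg,
    )


def shift_table(
    pool, cfg: ChartConfig, grid: ShiftGrid | tuple = DEFAULT_SHIFT_GRID,
    reps: int = 20_000, rng=None,
) -> pd.DataFrame:
    """Run-length profile over a shift grid, one row per delta.

    Columns follow the published table layout:
    ``shift, ARL, SDRL, P05, P10, P25, P50, P75, P90, P95``.
    """
    if not isinstance(grid, ShiftGrid):
        grid = ShiftGrid(tuple(grid))
    rng = np.random.default_rng(rng) if not hasattr(rng, "integers") else rng
    rows = []
    for delta in grid.deltas:
        s = estimate_rl_profile(pool, cfg, delta, reps, rng)
        rows.append(
            {"shift": delta, "ARL": s.arl, "SDRL": s.sdrl, **s.percentiles}
        )
    return pd.DataFrame(rows, columns=["shift", "ARL", "SDRL", *_PCT_LABELS])


def compare_charts(
    pool_aft: ResidualPool,
    pool_svm: ResidualPool,
    lam: float,
    target_arl0: float,
    grid: ShiftGrid | tuple = DEFAULT_SHIFT_GRID,
    reps: int = 20_000,
    calib_reps: int | None = None,
    rng=None,
) -> pd.DataFrame:
    """Head-to-head ARL/SDRL of the SVM-residual vs AFT-residual charts.

    Each chart is calibrated separately to the same in-control ARL, then
    profiled over the shift grid (comparison-table layout).
    """
    rng = np.random.default_rng(rng) if not hasattr(rng, "integers") else rng
    calib_reps = calib_reps or reps
    out = None
    for name, pool in (("SVM_EWMA", pool_svm), ("RAEWMA", pool_aft)):
        cal = calibrate_L(pool, lam, target_arl0, reps=calib_reps, rng=rng)
        tab = shift_table(pool, cal.config, grid, reps, rng)
        tab = tab.rename(columns={"ARL": f"{name}_ARL", "SDRL": f"{name}_SDRL"})
        tab = tab[["shift", f"{name}_ARL", f"{name}_SDRL"]]
        out = tab if out is None else out.merge(tab, on="shift")
    return out
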
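"""One-sided (clipped) EWMA chart statistics and control limits.

The plain EWMA recursion is z_t = lam * v_t + (1 - lam) * z_{t-1}.  For
survival monitoring only *decreases* matter, so the statistic is clipped
from above at xi (the mean of the Phase-I residual pool):

    F_t = min(lam * v_t + (1 - lam) * F_{t-1}, xi),

and the chart signals when F_t falls below the lower control limit

    LCL_t = mu_e - L * sigma_e * sqrt(lam / (2 - lam) * (1 - (1 - lam)^(2t))),

where (mu_e, sigma_e) are the Phase-I residual mean and SD and L is the
control coefficient calibrated to the target in-control ARL.  The
time-varying square-root factor is the exact standard deviation of the
unclipped EWMA after t steps; ``asymptotic`` mode freezes it at its t->inf
limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .exceptions import ConfigurationError, DataError

__all__ = [
    "ChartConfig",
    "RunResult",
    "ewma_step",
    "clipped_ewma_step",
    "ewma_sigma",
    "lcl",
    "run_chart",
]


def _check_lam(lam: float) -> None:
    if not 0.0 < lam <= 1.0:
        raise ConfigurationError(f"smoothing constant lam must be in (0, 1], got {lam}")


@dataclass(frozen=True)
class ChartConfig:
    """Everything needed to run the one-sided EWMA chart on a residual stream."""

    lam: float
    L: float
    xi: float = 0.0
    mu_e: float = 0.0
    sigma_e: float = 1.0
    z0: float | None = None  # default: xi (the in-control residual mean)
    limit_mode: str = "time_varying"  # or "asymptotic"
    horizon: int = 1_000_000

    def __post_init__(self) -> None:
        _check_lam(self.lam)
        if self.L < 0:
            raise ConfigurationError("control coefficient L must be >= 0")
        if self.sigma_e <= 0:
            raise ConfigurationError("sigma_e must be > 0")
        if self.horizon < 1:
            raise ConfigurationError("horizon must be >= 1")
        if self.limit_mode not in ("time_varying", "asymptotic"):
            raise ConfigurationError(f"unknown limit_mode {self.limit_mode!r}")
        if self.z0 is None:
            z0 = self.xi if np.isfinite(self.xi) else self.mu_e
            object.__setattr__(self, "z0", float(z0))


@dataclass(frozen=True)
class RunResult:
    """Trajectory of one chart run and where (if at all) it signaled."""

    run_length: int
    signaled: bool
    statistic_path: np.ndarray | None = None
    lcl_path: np.ndarray | None = None


def ewma_step(prev: float, v: float, lam: float) -> float:
    """One plain EWMA update: lam * v + (1 - lam) * prev."""
    _check_lam(lam)
    return lam * v + (1.0 - lam) * prev


def clipped_ewma_step(prev: float, v: float, lam: float, xi: float) -> float:
    """One-sided update: the EWMA value capped from above at xi."""
    return min(ewma_step(prev, v, lam), xi)


def ewma_sigma(t, lam: float, sigma_e: float):
    """Exact SD of the EWMA statistic after t steps (vectorized over t)."""
    _check_lam(lam)
    t_arr = np.asarray(t)
    if np.any(t_arr < 1):
        raise ConfigurationError("t must be >= 1")
    var_factor = lam / (2.0 - lam) * (1.0 - (1.0 - lam) ** (2.0 * t_arr))
    out = sigma_e * np.sqrt(var_factor)
    return float(out) if np.isscalar(t) else out


def ewma_sigma_inf(lam: float, sigma_e: float) -> float:
    """Asymptotic (t -> inf) SD of the EWMA statistic."""
    _check_lam(lam)
    return sigma_e * float(np.sqrt(lam / (2.0 - lam)))


def lcl(t, cfg: ChartConfig):
    """Lower control limit at step t (vectorized over t)."""
    if cfg.limit_mode == "asymptotic":
        val = cfg.mu_e - cfg.L * ewma_sigma_inf(cfg.lam, cfg.sigma_e)
        return val if np.isscalar(t) else np.full(np.shape(t), val)
    return cfg.mu_e - cfg.L * ewma_sigma(t, cfg.lam, cfg.sigma_e)


def run_chart(
    residuals: Iterable[float], cfg: ChartConfig, record_path: bool = True
) -> RunResult:
    """Run the one-sided chart over a residual stream.

    Signals at the first t with F_t < LCL_t; a stream that runs out (or hits
    ``cfg.horizon``) without signaling is a censored run with ``signaled``
    False and ``run_length`` equal to the number of observations consumed.
    """
    F = float(cfg.z0)
    path: list[float] = []
    lims: list[float] = []
    t = 0
    signaled = False
    for v in residuals:
        t += 1
        F = clipped_ewma_step(F, float(v), cfg.lam, cfg.xi)
        limit = lcl(t, cfg)
        if record_path:
            path.append(F)
            lims.append(limit)
        if F < limit:
            signaled = True
            break
        if t >= cfg.horizon:
            break
    if t == 0:
        raise DataError("empty residual stream")
    return RunResult(
        run_length=t,
        signaled=signaled,
        statistic_path=np.array(path) if record_path else None,
        lcl_path=np.array(lims) if record_path else None,
    )
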
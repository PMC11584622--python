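"""Synthetic cardiac-surgery cohorts.

The generator emulates the data structure assumed by risk-adjusted survival
monitoring: each patient carries a preoperative Parsonnet risk score
``P`` (integer, 0-100) and a post-surgery survival time ``T`` that follows a
log-linear accelerated failure time (AFT) law

    log T = beta0 + beta1 * P + sigma * eps,

with ``eps`` an i.i.d. error term.  Follow-up stops at a fixed horizon
(30 days by default), so longer survival times are right-censored at the
horizon.  The default coefficients (5.07026, -0.03348, 0.57) are the
published Phase-I estimates for the classic cardiac-surgery monitoring
dataset, which makes cohorts drawn here statistically comparable to that
setting without access to the original patient records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, DataError

__all__ = [
    "PARSONNET_MAX",
    "DEFAULT_BETA0",
    "DEFAULT_BETA1",
    "DEFAULT_SIGMA",
    "PatientRecord",
    "ParsonnetDist",
    "CohortConfig",
    "sample_parsonnet",
    "simulate_survival",
    "apply_censoring",
    "generate_cohort",
    "expected_censored_fraction",
    "error_distribution",
]

PARSONNET_MAX = 100

#: Published Phase-I AFT coefficients for the cardiac-surgery setting.
DEFAULT_BETA0 = 5.07026
DEFAULT_BETA1 = -0.03348
DEFAULT_SIGMA = 0.57

_ERROR_DISTS = {
    "standard_normal": stats.norm,
    "logistic": stats.logistic,
    "gumbel_min": stats.gumbel_l,
}


def error_distribution(name: str):
    """Return the frozen scipy distribution for an AFT error law name."""
    try:
        return _ERROR_DISTS[name]
    except KeyError:
        raise ConfigurationError(
            f"unsupported error distribution {name!r}; "
            f"choose one of {sorted(_ERROR_DISTS)}"
        ) from None


@dataclass(frozen=True)
class PatientRecord:
    """One surgery: risk score, observed follow-up and censoring status.

    ``true_time_days`` is the latent (uncensored) survival time; it is only
    populated for synthetic cohorts so oracle checks can compare against the
    generating process.  Model-fitting code never reads it.
    """

    parsonnet: int
    time_days: float
    censored: bool
    group: str | None = None
    true_time_days: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.parsonnet <= PARSONNET_MAX:
            raise DataError(
                f"parsonnet score {self.parsonnet} outside [0, {PARSONNET_MAX}]"
            )
        if not self.time_days > 0:
            raise DataError(f"non-positive survival time {self.time_days}")


class ParsonnetDist:
    """Distribution of Parsonnet scores on the integers 0..100.

    Three shapes are supported:

    ``truncated_geometric``
        geometric pmf ``(1-p)^k p`` truncated and renormalized to [0, 100],
        with ``p`` chosen so the *untruncated* mean equals ``mean``.  Real
        Parsonnet distributions are right-skewed with most mass near zero,
        which this shape mimics.
    ``point_mass``
        all mass on a single score (useful for oracle checks).
    ``pmf``
        an explicit probability vector over 0..100.
    """

    def __init__(self, kind: str, probs: np.ndarray, params: dict):
        self.kind = kind
        self.probs = probs
        self.params = params

    # -- constructors ------------------------------------------------------
    @classmethod
    def truncated_geometric(cls, mean: float = 10.0) -> "ParsonnetDist":
        if mean <= 0:
            raise ConfigurationError("truncated_geometric mean must be > 0")
        p = 1.0 / (1.0 + mean)
        k = np.arange(PARSONNET_MAX + 1)
        w = (1.0 - p) ** k * p
        return cls("truncated_geometric", w / w.sum(), {"mean": mean})

    @classmethod
    def point_mass(cls, value: int) -> "ParsonnetDist":
        value = int(value)
        if not 0 <= value <= PARSONNET_MAX:
            raise ConfigurationError(f"point mass {value} outside [0, {PARSONNET_MAX}]")
        w = np.zeros(PARSONNET_MAX + 1)
        w[value] = 1.0
        return cls("point_mass", w, {"value": value})

    @classmethod
    def from_pmf(cls, probs: Sequence[float]) -> "ParsonnetDist":
        w = np.asarray(probs, dtype=float)
        if w.shape != (PARSONNET_MAX + 1,) or np.any(w < 0) or w.sum() <= 0:
            raise ConfigurationError(
                f"pmf must be {PARSONNET_MAX + 1} nonnegative weights with positive sum"
            )
        return cls("pmf", w / w.sum(), {})

    @classmethod
    def from_spec(cls, spec) -> "ParsonnetDist":
        """Build from a flat dict spec, e.g. ``{"kind": "point_mass", "value": 5}``."""
        if isinstance(spec, cls):
            return spec
        if not isinstance(spec, Mapping) or "kind" not in spec:
            raise ConfigurationError(f"bad Parsonnet distribution spec: {spec!r}")
        kind = spec["kind"]
        if kind == "truncated_geometric":
            return cls.truncated_geometric(spec.get("mean", 10.0))
        if kind == "point_mass":
            return cls.point_mass(spec["value"])
        if kind == "pmf":
            return cls.from_pmf(spec["probs"])
        raise ConfigurationError(f"unsupported Parsonnet distribution kind {kind!r}")

    # -- queries -----------------------------------------------------------
    def mean(self) -> float:
        return float(np.arange(PARSONNET_MAX + 1) @ self.probs)

    def var(self) -> float:
        k = np.arange(PARSONNET_MAX + 1)
        m = self.mean()
        return float(((k - m) ** 2) @ self.probs)

    def to_spec(self) -> dict:
        return {"kind": self.kind, **self.params}


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to draw one reproducible synthetic cohort."""

    n: int
    beta0: float = DEFAULT_BETA0
    beta1: float = DEFAULT_BETA1
    sigma: float = DEFAULT_SIGMA
    error_dist: str = "standard_normal"
    parsonnet: ParsonnetDist = field(
        default_factory=ParsonnetDist.truncated_geometric
    )
    censor_horizon_days: float = 30.0
    seed: int = 0
    #: optional surgeon-group effects: label -> (probability, log-scale offset)
    groups: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigurationError("cohort size n must be >= 0")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if not self.censor_horizon_days > 0:
            raise ConfigurationError("censoring horizon must be > 0")
        error_distribution(self.error_dist)  # validate early
        object.__setattr__(
            self, "parsonnet", ParsonnetDist.from_spec(self.parsonnet)
        )
        if self.groups is not None:
            probs = [p for p, _ in self.groups.values()]
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError("group probabilities must sum to 1")

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "sigma": self.sigma,
            "error_dist": self.error_dist,
            "parsonnet": self.parsonnet.to_spec(),
            "censor_horizon_days": self.censor_horizon_days,
            "seed": self.seed,
        }
        if self.groups is not None:
            d["groups"] = {k: list(v) for k, v in self.groups.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "parsonnet" in d:
            d["parsonnet"] = ParsonnetDist.from_spec(d["parsonnet"])
        if d.get("groups"):
            d["groups"] = {k: tuple(v) for k, v in d["groups"].items()}
        return cls(**d)


def sample_parsonnet(n: int, dist: ParsonnetDist, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` integer Parsonnet scores from ``dist``."""
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    dist = ParsonnetDist.from_spec(dist)
    if n == 0:
        return np.empty(0, dtype=int)
    return rng.choice(PARSONNET_MAX + 1, size=n, p=dist.probs).astype(int)


def simulate_survival(
    scores: Sequence[int], cfg: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Latent survival times ``T = exp(beta0 + beta1*P + sigma*eps)`` in days."""
    p = np.asarray(scores, dtype=float)
    if p.size and (p.min() < 0 or p.max() > PARSONNET_MAX):
        raise DataError("Parsonnet scores outside [0, 100]")
    eps = _draw_errors(cfg.error_dist, p.size, rng)
    return np.exp(cfg.beta0 + cfg.beta1 * p + cfg.sigma * eps)


def _draw_errors(name: str, size: int, rng: np.random.Generator) -> np.ndarray:
    error_distribution(name)  # validate
    if name == "standard_normal":
        return rng.standard_normal(size)
    if name == "logistic":
        return rng.logistic(0.0, 1.0, size)
    # Gumbel minimum = mirrored numpy (maximum) Gumbel
    return -rng.gumbel(0.0, 1.0, size)


def apply_censoring(times: Sequence[float], horizon: float) -> tuple[np.ndarray, np.ndarray]:
    """Right-censor survival times at ``horizon`` days.

    Returns ``(time_days, censored)``; a time exactly equal to the horizon is
    an observed event (survival to the end of follow-up is recorded as such).
    """
    t = np.asarray(times, dtype=float)
    if t.size and t.min() <= 0:
        raise DataError("survival times must be positive")
    if not horizon > 0:
        raise ConfigurationError("censoring horizon must be > 0")
    censored = t > horizon
    return np.where(censored, horizon, t), censored


def generate_cohort(cfg: CohortConfig) -> list[PatientRecord]:
    """Draw a full synthetic cohort; identical config => identical cohort."""
    rng = np.random.default_rng(cfg.seed)
    scores = sample_parsonnet(cfg.n, cfg.parsonnet, rng)
    if cfg.groups is not None:
        labels = list(cfg.groups)
        probs = [cfg.groups[g][0] for g in labels]
        assign = rng.choice(len(labels), size=cfg.n, p=probs)
        offsets = np.array([cfg.groups[g][1] for g in labels])[assign]
        group_of = [labels[i] for i in assign]
    else:
        offsets = np.zeros(cfg.n)
        group_of = [None] * cfg.n
    true_t = simulate_survival(scores, cfg, rng) * np.exp(offsets)
    obs_t, cens = apply_censoring(true_t, cfg.censor_horizon_days)
    return [
        PatientRecord(
            parsonnet=int(scores[i]),
            time_days=float(obs_t[i]),
            censored=bool(cens[i]),
            group=group_of[i],
            true_time_days=float(true_t[i]),
        )
        for i in range(cfg.n)
    ]


def expected_censored_fraction(cfg: CohortConfig) -> float:
    """Analytic P(T > horizon) under ``cfg``, averaged over the score pmf.

    Equals ``E_P[SF((ln h - beta0 - beta1 P)/sigma)]``; surgeon-group offsets
    are averaged over with their probabilities.
    """
    dist = error_distribution(cfg.error_dist)
    k = np.arange(PARSONNET_MAX + 1)
    offsets = {None: (1.0, 0.0)}
    if cfg.groups is not None:
        offsets = dict(cfg.groups)
    frac = 0.0
    for _, (pr, off) in offsets.items():
        if cfg.sigma == 0:
            surv = (cfg.beta0 + cfg.beta1 * k + off > math.log(cfg.censor_horizon_days))
            frac += pr * float(surv @ cfg.parsonnet.probs)
        else:
            z = (math.log(cfg.censor_horizon_days) - cfg.beta0 - cfg.beta1 * k - off) / cfg.sigma
            frac += pr * float(dist.sf(z) @ cfg.parsonnet.probs)
    return frac
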
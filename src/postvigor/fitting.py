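"""Per-user maximum-likelihood estimation of the latency model.

Each user's three parameters (alpha, C, rho0) are estimated by minimizing
the trace negative log-likelihood with a derivative-free simplex search on a
bounded sigmoid transform of each parameter, restarted from several start
points.  One start is the closed-form no-learning solution (alpha ~ 0, C ~ 0,
rho0 = mean observed latency, the exponential MLE); the rest are drawn on
the transformed scale so they spread over orders of magnitude.  Fitted
learning rates can be winsorized before downstream statistics.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import rl_core
from .rl_core import ModelParams, POLICY_FLOOR_DAYS
from .trace_io import UserTrace

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Search configuration for per-user MLE.

    Bounds left as ``None`` are derived per trace: the cost bound scales
    with ``10 * max(likes) * mean(latency)`` and the rho0 bound with
    ``10 * max(latency)``.
    """

    alpha_bounds: tuple[float, float] = (0.0, 0.1)
    cost_bounds: tuple[float, float] | None = None
    rho0_bounds: tuple[float, float] | None = None
    restarts: int = 10
    tol: float = 1e-6
    maxiter: int = 400
    seed: int = 0
    utility_kind: str = "linear"
    winsor_limits: tuple[float, float] = (0.025, 0.975)
    min_posts: int = 10

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        for b in (self.alpha_bounds, self.cost_bounds, self.rho0_bounds):
            if b is not None and not b[0] < b[1]:
                raise ValueError("bounds must be positively ordered")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one per-user fit."""

    user_id: str
    params: ModelParams
    nll: float
    n_posts: int
    converged: bool
    n_restarts_used: int


class InsufficientDataError(ValueError):
    """Raised when a trace has too few posts to fit."""


def _trace_digest(trace: UserTrace) -> int:
    """Stable 63-bit digest of a trace's content (not its user_id), so
    identical data always gets identical restart draws."""
    h = hashlib.blake2b(digest_size=8)
    h.update(np.ascontiguousarray(trace.likes).tobytes())
    h.update(np.ascontiguousarray(np.nan_to_num(trace.latencies, nan=-1.0)).tobytes())
    return int.from_bytes(h.digest(), "little") >> 1


def _resolve_bounds(config: FitConfig, trace: UserTrace) -> list[tuple[float, float]]:
    lat = trace.latencies[1:]
    mean_lat = float(np.mean(lat))
    max_lat = float(np.max(lat))
    cost_b = config.cost_bounds or (0.0, 10.0 * max(1.0, float(trace.likes.max())) * mean_lat)
    rho0_b = config.rho0_bounds or (POLICY_FLOOR_DAYS, max(10.0 * max_lat, 10 * POLICY_FLOOR_DAYS))
    return [config.alpha_bounds, cost_b, rho0_b]


def _to_natural(x: np.ndarray, bounds: list[tuple[float, float]]) -> np.ndarray:
    return np.array([lo + (hi - lo) * expit(xi) for xi, (lo, hi) in zip(x, bounds)])


def _to_transformed(p: np.ndarray, bounds: list[tuple[float, float]]) -> np.ndarray:
    out = []
    for pi, (lo, hi) in zip(p, bounds):
        frac = np.clip((pi - lo) / (hi - lo), 1e-12, 1 - 1e-12)
        out.append(logit(frac))
    return np.array(out)


def fit_user(trace: UserTrace, config: FitConfig = FitConfig()) -> FitResult:
    """Fit (alpha, C, rho0) to one preprocessed trace by multi-start MLE.

    Raises :class:`InsufficientDataError` below ``config.min_posts`` posts
    (default 10, the usual trace-data inclusion rule).
    """
    if trace.latencies is None:
        raise ValueError("trace has no latencies; run compute_latencies first")
    if trace.n_posts < config.min_posts:
        raise InsufficientDataError(
            f"user {trace.user_id!r}: {trace.n_posts} posts < required {config.min_posts}"
        )
    bounds = _resolve_bounds(config, trace)
    us = np.ascontiguousarray(
        np.atleast_1d(rl_core.utility(trace.likes, config.utility_kind)), dtype=np.float64
    )
    taus = np.ascontiguousarray(
        np.maximum(np.nan_to_num(trace.latencies, nan=1.0), rl_core.LATENCY_FLOOR_DAYS),
        dtype=np.float64,
    )

    def objective(x: np.ndarray) -> float:
        a, c, r0 = _to_natural(x, bounds)
        val = rl_core._nll_scalar(a, c, r0, taus, us, POLICY_FLOOR_DAYS)
        return val if np.isfinite(val) else 1e300  # keep the simplex sane

    mean_lat = float(np.mean(trace.latencies[1:]))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _trace_digest(trace)]))

    x_rho0_ml = _to_transformed(np.array([0.0, 0.0, mean_lat]), bounds)[2]
    # deterministic starts: the no-learning exponential MLE, and the same
    # point with a typical small learning rate (the likelihood is often
    # bimodal between a no-learning and a learning basin)
    starts = [np.array([-12.0, -12.0, x_rho0_ml])]
    if config.restarts > 1:
        x_alpha_typ = _to_transformed(np.array([1e-3, 0.0, mean_lat]), bounds)[0]
        starts.append(np.array([x_alpha_typ, -12.0, x_rho0_ml]))
    for _ in range(config.restarts - len(starts)):
        x_alpha = rng.uniform(-9.0, 2.0)
        x_cost = rng.uniform(-9.0, 2.0)
        x_rho0 = starts[0][2] + rng.normal(0.0, 1.0)
        starts.append(np.array([x_alpha, x_cost, x_rho0]))

    options = {"maxiter": config.maxiter, "xatol": 1e-4, "fatol": config.tol}
    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead", options=options)
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success)
    if not converged:  # polish: restart the simplex at the incumbent
        res = minimize(objective, best.x, method="Nelder-Mead", options=options)
        improvement = best.fun - res.fun
        if res.fun <= best.fun:
            best = res
        # converged in value if a fresh simplex cannot improve the optimum
        converged = bool(res.success) or improvement <= max(config.tol, 1e-8)
    a, c, r0 = _to_natural(best.x, bounds)
    params = ModelParams(alpha=float(a), cost=float(c), rho0=float(max(r0, POLICY_FLOOR_DAYS)),
                         utility_kind=config.utility_kind)
    return FitResult(
        user_id=trace.user_id,
        params=params,
        nll=float(best.fun),
        n_posts=trace.n_posts,
        converged=converged and bool(np.isfinite(best.fun)),
        n_restarts_used=config.restarts,
    )


def fit_cohort(cohort: Sequence[UserTrace], config: FitConfig = FitConfig()) -> list[FitResult]:
    """Fit every eligible user in a cohort; short traces are skipped and
    counted, failures logged."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    results: list[FitResult] = []
    n_short = 0
    for trace in cohort:
        try:
            results.append(fit_user(trace, config))
        except InsufficientDataError:
            n_short += 1
    if n_short:
        logger.info("fit_cohort: skipped %d user(s) with < %d posts", n_short, config.min_posts)
    n_failed = sum(not r.converged for r in results)
    if n_failed:
        logger.info("fit_cohort: %d of %d fits did not converge", n_failed, len(results))
    return results


def fits_to_frame(results: Sequence[FitResult]) -> pd.DataFrame:
    """Tabulate fit results in the standard fit-output schema."""
    return pd.DataFrame(
        {
            "user_id": [r.user_id for r in results],
            "alpha": [r.params.alpha for r in results],
            "cost": [r.params.cost for r in results],
            "rho0": [r.params.rho0 for r in results],
            "nll": [r.nll for r in results],
            "n_posts": [r.n_posts for r in results],
            "converged": [r.converged for r in results],
        }
    )


def winsorize(values, limits: tuple[float, float] = (0.025, 0.975)) -> np.ndarray:
    """Clip a series at its lower/upper quantile values (length preserved).

    ``limits`` are quantiles, 0 <= lower < upper <= 1; the default trims the
    outer 2.5% tails, the usual treatment of outlying fitted learning rates.
    """
    lo_q, hi_q = limits
    if not (0.0 <= lo_q < hi_q <= 1.0):
        raise ValueError("winsor limits must satisfy 0 <= lower < upper <= 1")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot winsorize an empty series")
    lo, hi = np.quantile(values, [lo_q, hi_q])
    return np.clip(values, lo, hi)
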
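"""Average-reward reinforcement-learning model of posting latencies.

The agent posts, receives likes, and chooses how long to wait before posting
again.  The waiting time (latency) tau is drawn from an exponential
distribution whose mean is the current policy rho, in days.  Each post yields
a net reward

    n_t = U(r_t) - C / tau_t,

the like utility minus an effort cost that grows as the response gets
quicker.  The net reward prediction error delta_t = n_t - Rbar_t compares the
outcome with the running average net reward rate Rbar (the opportunity cost
of slow responding), and a single learning rate alpha drives both the critic
and the actor:

    Rbar <- Rbar + alpha * delta
    rho  <- rho  + alpha * delta * (tau - rho)

so a faster-than-policy post that turns out better than average shortens the
policy (the agent speeds up) and vice versa.  The model has three free
parameters per user: alpha, the effort-cost coefficient C, and the initial
policy rho0.  alpha is the quantity of interest: it measures sensitivity to
social feedback.

The first post has no observed latency; its likes still update the state,
with tau = rho0 standing in for the effort-cost denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace_io import LATENCY_FLOOR_DAYS, UserTrace

#: Lower bound on the policy, in days; keeps the exponential mean positive.
POLICY_FLOOR_DAYS = 1e-3

UTILITY_KINDS = ("linear", "log1p")

_EPOCH = np.datetime64("2020-01-01T00:00:00", "s")


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the latency model.

    alpha : learning rate, unitless, >= 0 (empirical scale ~1e-4..1e-2).
    cost : effort-cost coefficient C, likes*days, >= 0.
    rho0 : initial policy, days, >= policy floor.
    utility_kind : 'linear' (u = likes) or 'log1p' (u = ln(1 + likes)).
    """

    alpha: float
    cost: float
    rho0: float
    utility_kind: str = "linear"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.cost < 0:
            raise ValueError("cost must be >= 0")
        if self.rho0 < POLICY_FLOOR_DAYS:
            raise ValueError(f"rho0 must be >= policy floor ({POLICY_FLOOR_DAYS})")
        if self.utility_kind not in UTILITY_KINDS:
            raise ValueError(f"unknown utility kind: {self.utility_kind!r}")


@dataclass
class AgentState:
    """Latent per-post state: current policy, average rate, last delta."""

    policy: float
    avg_rate: float = 0.0
    last_delta: float = 0.0


@dataclass
class LatentTrajectory:
    """Per-post latent arrays from a forward simulation (for oracle tests
    and figure regeneration)."""

    tau: np.ndarray
    likes: np.ndarray
    policy: np.ndarray
    net_reward: np.ndarray
    avg_rate: np.ndarray
    delta: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "post_index": np.arange(self.tau.size),
                "tau": self.tau,
                "likes": self.likes,
                "policy": self.policy,
                "net_reward": self.net_reward,
                "avg_rate": self.avg_rate,
                "delta": self.delta,
            }
        )


def utility(likes, kind: str = "linear"):
    """Like utility: identity or concave ln(1 + likes)."""
    likes = np.asarray(likes, dtype=float)
    if np.any(likes < 0):
        raise ValueError("likes must be non-negative")
    if kind == "linear":
        out = likes
    elif kind == "log1p":
        out = np.log1p(likes)
    else:
        raise ValueError(f"unknown utility kind: {kind!r}")
    return out if out.ndim else float(out)


def net_reward(u: float, cost: float, tau: float) -> float:
    """Net reward n = u - C/tau; the effort cost rises as latency shrinks."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return u - cost / tau


def prediction_error(n: float, avg_rate: float) -> float:
    """delta = n - Rbar."""
    return n - avg_rate


def update_avg_rate(avg_rate: float, delta: float, alpha: float) -> float:
    """Critic update: Rbar' = Rbar + alpha*delta (running average of net reward)."""
    return avg_rate + alpha * delta


def update_policy(
    policy: float,
    tau: float,
    delta: float,
    alpha: float,
    floor: float = POLICY_FLOOR_DAYS,
) -> float:
    """Actor update: rho' = max(floor, rho + alpha*delta*(tau - rho))."""
    return max(floor, policy + alpha * delta * (tau - policy))


def latency_loglik(tau, policy):
    """Log density of latency tau under Exp(mean = policy): -ln rho - tau/rho."""
    tau = np.asarray(tau, dtype=float)
    policy = np.asarray(policy, dtype=float)
    if np.any(tau <= 0) or np.any(policy <= 0):
        raise ValueError("tau and policy must be positive")
    out = -np.log(policy) - tau / policy
    return out if out.ndim else float(out)


def simulate_agent(
    params: ModelParams,
    likes_source,
    n_posts: int,
    rng: np.random.Generator,
    *,
    policy_floor: float = POLICY_FLOOR_DAYS,
    epoch: np.datetime64 = _EPOCH,
) -> tuple[UserTrace, LatentTrajectory]:
    """Simulate one agent forward for ``n_posts`` posts.

    ``likes_source`` is either an array-like of length ``n_posts`` or an
    object with a ``sample(rng, size)`` method (a likes environment).  The
    first post occurs at the epoch; each later post follows after a latency
    drawn from Exp(mean = current policy).  Timestamps are emitted at
    one-second resolution; the exact sampled latencies are returned in the
    latent trajectory.
    """
    if n_posts < 1:
        raise ValueError("n_posts must be >= 1")
    if hasattr(likes_source, "sample"):
        likes = np.asarray(likes_source.sample(rng, n_posts), dtype=np.int64)
    else:
        likes = np.asarray(likes_source, dtype=np.int64)
        if likes.size != n_posts:
            raise ValueError("likes sequence length must equal n_posts")

    u = np.atleast_1d(utility(likes, params.utility_kind))
    tau_arr = np.full(n_posts, np.nan)
    pol_arr = np.empty(n_posts)
    n_arr = np.empty(n_posts)
    rbar_arr = np.empty(n_posts)
    d_arr = np.empty(n_posts)

    state = AgentState(policy=params.rho0)
    t_days = 0.0
    times = np.empty(n_posts, dtype="datetime64[s]")
    for t in range(n_posts):
        if t == 0:
            tau = params.rho0  # stand-in: no observed latency for the first post
        else:
            tau = float(rng.exponential(scale=state.policy))
            tau = max(tau, policy_floor)
            tau_arr[t] = tau
            t_days += tau
        times[t] = epoch + np.timedelta64(int(round(t_days * 86_400.0)), "s")
        pol_arr[t] = state.policy
        n = net_reward(float(u[t]), params.cost, tau)
        d = prediction_error(n, state.avg_rate)
        n_arr[t], d_arr[t] = n, d
        state.avg_rate = update_avg_rate(state.avg_rate, d, params.alpha)
        state.policy = update_policy(state.policy, tau, d, params.alpha, floor=policy_floor)
        state.last_delta = d
        rbar_arr[t] = state.avg_rate

    trace = UserTrace(user_id="sim", timestamps=times, likes=likes)
    lat = np.concatenate([[np.nan], np.diff(times).astype("timedelta64[s]").astype(float) / 86_400.0])
    trace.latencies = np.maximum(lat, LATENCY_FLOOR_DAYS)
    trace.latencies[0] = np.nan
    traj = LatentTrajectory(tau_arr, likes, pol_arr, n_arr, rbar_arr, d_arr)
    return trace, traj


def _nll_scalar_py(
    alpha: float,
    cost: float,
    rho0: float,
    taus: np.ndarray,
    us: np.ndarray,
    policy_floor: float,
) -> float:
    """Fast scalar replay of the state recursion.

    ``taus``/``us`` are float arrays aligned per post; taus[0] is the
    undefined first latency and is ignored for the likelihood but the first
    post still updates state with tau = rho0.
    """
    rho = rho0
    rbar = 0.0
    # first post: likes update state; no latency term
    d = us[0] - cost / rho0 - rbar
    rbar += alpha * d
    # tau - rho = 0 for the first post, so the policy is unchanged
    nll = 0.0
    for t in range(1, taus.shape[0]):
        tau = taus[t]
        nll += math.log(rho) + tau / rho
        d = us[t] - cost / tau - rbar
        rbar += alpha * d
        rho += alpha * d * (tau - rho)
        if rho < policy_floor:
            rho = policy_floor
    return nll


try:  # JIT the likelihood inner loop when numba is available
    import numba

    _nll_scalar = numba.njit(cache=False, fastmath=False)(_nll_scalar_py)
except Exception:  # pragma: no cover - exercised only without numba
    _nll_scalar = _nll_scalar_py


def trace_nll(
    params: ModelParams,
    trace: UserTrace,
    *,
    policy_floor: float = POLICY_FLOOR_DAYS,
    latency_floor: float = LATENCY_FLOOR_DAYS,
) -> float:
    """Negative log-likelihood of one preprocessed trace under the model.

    Replays the deterministic state recursion over the observed (latency,
    likes) pairs, summing the exponential negative log-density for every
    defined latency.  The undefined first latency contributes nothing, but
    the first post's likes still update the state.
    """
    if trace.latencies is None:
        raise ValueError("trace has no latencies; run compute_latencies first")
    if trace.n_posts < 2:
        raise ValueError("need at least 2 posts to evaluate the likelihood")
    us = np.ascontiguousarray(np.atleast_1d(utility(trace.likes, params.utility_kind)), dtype=np.float64)
    taus = np.ascontiguousarray(
        np.maximum(np.nan_to_num(trace.latencies, nan=1.0), latency_floor), dtype=np.float64
    )
    return float(_nll_scalar(params.alpha, params.cost, params.rho0, taus, us, policy_floor))
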
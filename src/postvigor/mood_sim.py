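"""Mood dynamics under block reward schedules.

Mood is modelled as an exponentially weighted running average of the RL
model's net reward prediction errors:

    m_{t+1} = m_t + eta * (delta_t - m_t),    0 <= eta <= 1.

Because delta scales with the learning rate's effect on the average-rate
estimate, two agents that differ only in the core learning rate alpha show
different mood excursions when the likes environment shifts — the mechanism
by which higher feedback sensitivity produces larger mood swings.  The
headline simulation contrasts the two empirical group learning rates under
a high-reward (28–34 likes) then low-reward (6–18 likes) block schedule,
with the mood learning rate held constant across groups.

Mood is reported in delta units (like-utility), not rescaled to any
experimental mood slider.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import rl_core
from .rl_core import ModelParams
from .synthetic_cohort import RewardSchedule, schedule_likes


@dataclass(frozen=True)
class MoodParams:
    """Mood recursion parameters: learning rate eta in [0, 1], initial mood m0."""

    eta: float = 0.1
    m0: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must be in [0, 1]")
        if not np.isfinite(self.m0):
            raise ValueError("m0 must be finite")


@dataclass
class MoodTrajectory:
    """Aligned per-post arrays: likes, prediction error, mood, block label."""

    likes: np.ndarray
    delta: np.ndarray
    mood: np.ndarray
    block: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"post_index": np.arange(self.likes.size), "likes": self.likes,
             "delta": self.delta, "mood": self.mood, "block": self.block}
        )


def mood_update(m: float, eta: float, delta: float) -> float:
    """One mood step: m' = m + eta*(delta - m)."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must be in [0, 1]")
    return m + eta * (delta - m)


def _run_with_draws(
    params: ModelParams,
    mood: MoodParams,
    likes: np.ndarray,
    exp_quantiles: np.ndarray,
    block: np.ndarray,
) -> MoodTrajectory:
    """Deterministic mood run given pre-drawn likes and latency quantiles.

    ``exp_quantiles`` are standard-exponential draws; the realized latency of
    post t>0 is policy_t * exp_quantiles[t], so two parameterizations can be
    compared on common random numbers.
    """
    n = likes.size
    u = np.atleast_1d(rl_core.utility(likes, params.utility_kind))
    state = rl_core.AgentState(policy=params.rho0)
    m = mood.m0
    deltas = np.empty(n)
    moods = np.empty(n)
    for t in range(n):
        if t == 0:
            tau = params.rho0  # first post: no observed latency
        else:
            tau = max(state.policy * float(exp_quantiles[t]), rl_core.POLICY_FLOOR_DAYS)
        d = rl_core.prediction_error(
            rl_core.net_reward(float(u[t]), params.cost, tau), state.avg_rate
        )
        state.avg_rate = rl_core.update_avg_rate(state.avg_rate, d, params.alpha)
        state.policy = rl_core.update_policy(state.policy, tau, d, params.alpha)
        m = mood_update(m, mood.eta, d)
        deltas[t] = d
        moods[t] = m
    return MoodTrajectory(likes=likes, delta=deltas, mood=moods, block=block)


def simulate_mood_agent(
    params: ModelParams,
    mood: MoodParams,
    schedule: RewardSchedule,
    rng: np.random.Generator,
) -> MoodTrajectory:
    """Run the RL model forward under a block schedule, updating mood with
    each post's prediction error."""
    likes = schedule_likes(schedule, rng)
    q = rng.exponential(1.0, size=likes.size)
    return _run_with_draws(params, mood, likes, q, schedule.block_labels())


@dataclass
class MoodGroupSummary:
    """Two-group mood simulation: mean trajectories and per-simulation
    block-transition drops (mean mood in the later block minus the earlier)."""

    mean_trajectory_a: np.ndarray
    mean_trajectory_b: np.ndarray
    drops_a: np.ndarray
    drops_b: np.ndarray
    block: np.ndarray

    @property
    def mean_drop_a(self) -> float:
        return float(self.drops_a.mean())

    @property
    def mean_drop_b(self) -> float:
        return float(self.drops_b.mean())

    def to_dict(self) -> dict:
        return {
            "mean_drop_a": self.mean_drop_a,
            "mean_drop_b": self.mean_drop_b,
            "n_sims": int(self.drops_a.size),
            "mean_trajectory_a": self.mean_trajectory_a.tolist(),
            "mean_trajectory_b": self.mean_trajectory_b.tolist(),
        }


def _transition_drop(mood: np.ndarray, block: np.ndarray) -> float:
    """Mean mood in the final block minus mean mood in the first block."""
    first, last = block.min(), block.max()
    return float(mood[block == last].mean() - mood[block == first].mean())


def mood_group_sim(
    alpha_a: float,
    alpha_b: float,
    shared: ModelParams,
    mood: MoodParams,
    schedule: RewardSchedule,
    n_sims: int = 100,
    rng: np.random.Generator | None = None,
) -> MoodGroupSummary:
    """Simulate mood for two groups differing only in the core learning rate.

    Each simulation index uses common random numbers for both groups (same
    likes sequence and same exponential latency quantiles), so the group
    contrast isolates the effect of alpha.  The default 100 simulations per
    group mirrors the headline mood figure.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    rng = rng if rng is not None else np.random.default_rng()
    pa = replace(shared, alpha=alpha_a)
    pb = replace(shared, alpha=alpha_b)
    block = schedule.block_labels()
    traj_a = np.empty((n_sims, schedule.n_posts))
    traj_b = np.empty((n_sims, schedule.n_posts))
    drops_a = np.empty(n_sims)
    drops_b = np.empty(n_sims)
    for i in range(n_sims):
        likes = schedule_likes(schedule, rng)
        q = rng.exponential(1.0, size=likes.size)
        ta = _run_with_draws(pa, mood, likes, q, block)
        tb = _run_with_draws(pb, mood, likes, q, block)
        traj_a[i] = ta.mood
        traj_b[i] = tb.mood
        drops_a[i] = _transition_drop(ta.mood, block)
        drops_b[i] = _transition_drop(tb.mood, block)
    return MoodGroupSummary(
        mean_trajectory_a=traj_a.mean(axis=0),
        mean_trajectory_b=traj_b.mean(axis=0),
        drops_a=drops_a,
        drops_b=drops_b,
        block=block,
    )


def mood_diff_scores(baseline: float, post_hr: float, post_lr: float) -> tuple[float, float, float]:
    """Mood difference scores between the three measurement occasions,
    later minus earlier:

    T1 = post_hr - baseline, T2 = post_lr - post_hr, T3 = post_lr - baseline.

    Negative T2 means mood worsened when likes dropped from the high- to the
    low-reward block.
    """
    vals = (baseline, post_hr, post_lr)
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("all three mood measurements must be finite")
    return (post_hr - baseline, post_lr - post_hr, post_lr - baseline)
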
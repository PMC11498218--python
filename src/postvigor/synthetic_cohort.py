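"""Synthetic cohorts: parameter draws, likes environments, reward schedules.

Real posting-trace datasets are not redistributable, so simulated cohorts
stand in for them.  A cohort spec defines the generative distributions for a
group of agents: learning rates from a truncated normal (lower bound 0),
effort costs from a uniform, post counts from a rounded normal clamped at
the 10-post inclusion threshold, initial policies uniform over a range of
days, and a likes environment.  The stock adult/adolescent specs encode the
reference recovery-simulation design: alpha ~ TruncNormal(mean 0.002 or
0.003, SD 0.002, lower 0), C ~ Uniform(0, 1), n_posts ~ Normal(70, 20).

The likes environment for recovery studies defaults to a negative binomial
with mean 100 and dispersion 1 — heavy-tailed counts on the scale of the
empirical group means (207.5 and 97.28 likes).  The block reward schedule
mirrors the mood experiment: a high-reward block (28–34 likes per post)
followed by a low-reward block (6–18 likes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import rl_core
from .trace_io import UserTrace


@dataclass(frozen=True)
class LikesEnv:
    """Stationary like-count environment.

    family: 'negative_binomial' (mean, dispersion), 'lognormal' (mean,
    sigma of log), 'constant' (mean), or 'uniform' (low, high inclusive).
    """

    family: str = "negative_binomial"
    mean: float = 100.0
    dispersion: float = 1.0
    sigma: float = 1.0
    low: int = 0
    high: int = 0

    def __post_init__(self) -> None:
        if self.family not in {"negative_binomial", "lognormal", "constant", "uniform"}:
            raise ValueError(f"unknown likes family: {self.family!r}")
        if self.family in {"negative_binomial", "lognormal", "constant"} and self.mean <= 0:
            raise ValueError("likes mean must be positive")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "negative_binomial":
            k = self.dispersion
            p = k / (k + self.mean)
            return rng.negative_binomial(k, p, size=size).astype(np.int64)
        if self.family == "lognormal":
            mu = np.log(self.mean) - 0.5 * self.sigma**2  # mean-parameterized
            return np.round(rng.lognormal(mu, self.sigma, size=size)).astype(np.int64)
        if self.family == "constant":
            return np.full(size, int(round(self.mean)), dtype=np.int64)
        return rng.integers(self.low, self.high + 1, size=size).astype(np.int64)


@dataclass(frozen=True)
class Block:
    """One schedule block: ``n_posts`` posts with likes uniform on
    [low, high] inclusive."""

    n_posts: int
    low: int
    high: int

    def __post_init__(self) -> None:
        if self.n_posts < 1:
            raise ValueError("block duration must be >= 1 post")
        if self.high < self.low:
            raise ValueError("block like-range is empty")


@dataclass(frozen=True)
class RewardSchedule:
    """Ordered blocks of like ranges (the experiment's reward manipulation)."""

    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        if len(self.blocks) == 0:
            raise ValueError("schedule needs at least one block")

    @property
    def n_posts(self) -> int:
        return sum(b.n_posts for b in self.blocks)

    def block_labels(self) -> np.ndarray:
        return np.concatenate([np.full(b.n_posts, i, dtype=int) for i, b in enumerate(self.blocks)])


def hr_lr_schedule(posts_per_block: int = 10) -> RewardSchedule:
    """High-reward (28–34 likes) then low-reward (6–18 likes) blocks."""
    return RewardSchedule(
        (Block(posts_per_block, 28, 34), Block(posts_per_block, 6, 18))
    )


def schedule_likes(schedule: RewardSchedule, rng: np.random.Generator) -> np.ndarray:
    """Draw an integer likes sequence, uniform within each block's range."""
    return np.concatenate(
        [rng.integers(b.low, b.high + 1, size=b.n_posts) for b in schedule.blocks]
    ).astype(np.int64)


@dataclass(frozen=True)
class CohortSpec:
    """Generative distributions for one simulated group."""

    n_agents: int = 1000
    alpha_mean: float = 0.002
    alpha_sd: float = 0.002
    alpha_lower: float = 0.0
    cost_low: float = 0.0
    cost_high: float = 1.0
    nposts_mean: float = 70.0
    nposts_sd: float = 20.0
    nposts_min: int = 10
    rho0_low: float = 0.5
    rho0_high: float = 5.0
    likes_env: LikesEnv = field(default_factory=LikesEnv)
    seed: int | None = None
    label: str = "cohort"

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.alpha_sd < 0 or self.nposts_sd < 0:
            raise ValueError("distribution SDs must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["likes_env"] = asdict(self.likes_env)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        d = yaml.safe_load(Path(path).read_text())
        if "likes_env" in d and isinstance(d["likes_env"], dict):
            d["likes_env"] = LikesEnv(**d["likes_env"])
        return cls(**d)


def adult_spec(n_agents: int = 1000, **overrides) -> CohortSpec:
    """The recovery-study adult group (alpha mean 0.002)."""
    return CohortSpec(n_agents=n_agents, alpha_mean=0.002, label="adult", **overrides)


def adolescent_spec(n_agents: int = 1000, **overrides) -> CohortSpec:
    """The recovery-study adolescent group: identical except alpha mean 0.003."""
    return CohortSpec(n_agents=n_agents, alpha_mean=0.003, label="adolescent", **overrides)


def sample_cohort_params(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-agent generative parameters.

    Returns a frame with columns user_id, alpha, cost, rho0, n_posts.
    Learning rates come from the truncated normal (values below
    ``alpha_lower`` excluded); post counts are rounded normals clamped at
    ``nposts_min`` so every agent stays fit-eligible.
    """
    if spec.alpha_sd == 0:
        alpha = np.full(spec.n_agents, max(spec.alpha_mean, spec.alpha_lower))
    else:
        a = (spec.alpha_lower - spec.alpha_mean) / spec.alpha_sd
        alpha = stats.truncnorm.rvs(
            a, np.inf, loc=spec.alpha_mean, scale=spec.alpha_sd,
            size=spec.n_agents, random_state=rng,
        )
    cost = rng.uniform(spec.cost_low, spec.cost_high, size=spec.n_agents)
    rho0 = rng.uniform(spec.rho0_low, spec.rho0_high, size=spec.n_agents)
    if spec.nposts_sd == 0:
        n_posts = np.full(spec.n_agents, int(round(spec.nposts_mean)))
    else:
        n_posts = np.round(rng.normal(spec.nposts_mean, spec.nposts_sd, size=spec.n_agents))
    n_posts = np.maximum(n_posts, spec.nposts_min).astype(int)
    return pd.DataFrame(
        {
            "user_id": [f"{spec.label}-{i:04d}" for i in range(spec.n_agents)],
            "alpha": alpha,
            "cost": cost,
            "rho0": rho0,
            "n_posts": n_posts,
        }
    )


def simulate_cohort(
    params_table: pd.DataFrame, spec: CohortSpec, rng: np.random.Generator
) -> list[UserTrace]:
    """Simulate one trace per agent row under the spec's likes environment."""
    if len(params_table) == 0:
        raise ValueError("empty parameter table")
    traces: list[UserTrace] = []
    for row in params_table.itertuples(index=False):
        params = rl_core.ModelParams(alpha=row.alpha, cost=row.cost, rho0=row.rho0)
        trace, _ = rl_core.simulate_agent(params, spec.likes_env, int(row.n_posts), rng)
        trace.user_id = str(row.user_id)
        traces.append(trace)
    return traces


def truncnorm_mean(mean: float, sd: float, lower: float = 0.0) -> float:
    """Analytic mean of the truncated normal used for learning rates."""
    a = (lower - mean) / sd
    return float(stats.truncnorm.mean(a, np.inf, loc=mean, scale=sd))
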
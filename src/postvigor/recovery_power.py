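"""Parameter-recovery and power pipelines, plus the small statistics toolkit.

`recovery_study` simulates two cohorts that differ only in their generative
learning-rate distribution, fits every agent by MLE, and summarizes (i) how
well generative parameters are recovered (Pearson correlations) and (ii)
whether the group difference in fitted learning rates is detectable
(two-sample t, Cohen's d).  `power_curve` repeats the contrast at a grid of
group sizes to estimate rejection rates.

The toolkit covers the tests used around the model: Welch and pooled
(Student) two-sample t, Pearson correlation with n-2 df, Cohen's d with
df-weighted pooled SD, and the Mann-Whitney U with tie-corrected normal
p-value and rank-biserial effect size r = 1 - 2U/(n1*n2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fitting import FitConfig, fit_cohort, fits_to_frame
from .synthetic_cohort import CohortSpec, sample_cohort_params, simulate_cohort

logger = logging.getLogger(__name__)

_SIDES = {"two", "greater", "less"}


def _check_sided(sided: str) -> str:
    if sided == "one":  # alias: directional, first sample greater
        return "greater"
    if sided not in _SIDES:
        raise ValueError(f"sided must be one of {_SIDES} (or 'one'): {sided!r}")
    return sided


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


class PearsonResult(NamedTuple):
    r: float
    df: int
    p: float


class MannWhitneyResult(NamedTuple):
    u: float
    rank_biserial: float
    p: float


def _t_pvalue(t: float, df: float, sided: str) -> float:
    if sided == "two":
        return 2.0 * float(sps.t.sf(abs(t), df))
    if sided == "greater":
        return float(sps.t.sf(t, df))
    return float(sps.t.cdf(t, df))


def welch_t(x, y, sided: str = "two") -> TTestResult:
    """Welch two-sample t with Welch–Satterthwaite df; sign = mean(x)-mean(y)."""
    sided = _check_sided(sided)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples are degenerate (zero variance)")
    sx, sy = vx / x.size, vy / y.size
    t = (x.mean() - y.mean()) / math.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx**2 / (x.size - 1) + sy**2 / (y.size - 1))
    return TTestResult(float(t), float(df), _t_pvalue(t, df, sided))


def student_t(x, y, sided: str = "two") -> TTestResult:
    """Pooled-variance two-sample t with df = n1 + n2 - 2."""
    sided = _check_sided(sided)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    df = x.size + y.size - 2
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("degenerate pooled variance")
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / x.size + 1 / y.size))
    return TTestResult(float(t), float(df), _t_pvalue(t, df, sided))


def cohens_d(x, y) -> float:
    """Standardized mean difference with df-weighted pooled SD."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (x.size + y.size - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD")
    return float((x.mean() - y.mean()) / math.sqrt(sp2))


def pearson_r(x, y) -> PearsonResult:
    """Product-moment correlation; df = n - 2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("undefined correlation: zero variance")
    res = sps.pearsonr(x, y)
    return PearsonResult(float(res.statistic), x.size - 2, float(res.pvalue))


def mann_whitney(x, y) -> MannWhitneyResult:
    """Mann-Whitney U for the first sample with tie-corrected normal p
    (continuity-corrected, two-sided) and rank-biserial effect size."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("samples must be non-empty")
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mu = n1 * n2 / 2.0
    if sigma2 == 0:
        p = 1.0
    else:
        z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)  # continuity correction
        p = 2.0 * float(sps.norm.sf(max(z, 0.0)))
    return MannWhitneyResult(float(u1), rank_biserial(u1, n1, n2), min(p, 1.0))


def rank_biserial(u: float, n1: int, n2: int) -> float:
    """Rank-biserial effect size r = 1 - 2U/(n1*n2): the difference between
    the probabilities that a random (x, y) pair favors y versus x."""
    return float(1.0 - 2.0 * u / (n1 * n2))


# ---------------------------------------------------------------------------
# Recovery study


@dataclass
class RecoveryReport:
    """Summary of a two-group parameter-recovery simulation.

    Group contrasts are computed group A minus group B, with both the
    pooled-df (Student) and Welch conventions reported; correlations are
    generative-vs-fitted over the pooled, post-exclusion agents.
    """

    label_a: str
    label_b: str
    n_fitted: int
    n_excluded: int
    r_alpha: PearsonResult
    r_cost: PearsonResult
    mean_alpha_a: float
    mean_alpha_b: float
    mean_cost_a: float
    mean_cost_b: float
    alpha_student: TTestResult
    alpha_welch: TTestResult
    alpha_student_one_sided_p: float
    cost_student: TTestResult
    cost_welch: TTestResult
    alpha_cohens_d: float
    table: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "table"}
        for key in ("r_alpha", "r_cost", "alpha_student", "alpha_welch", "cost_student", "cost_welch"):
            d[key] = dict(getattr(self, key)._asdict())
        return d


def _exclude_boundary(frame: pd.DataFrame, alpha_hi: float) -> pd.DataFrame:
    """Drop non-converged fits and learning rates pinned at the upper search
    bound (symptom of a degenerate likelihood)."""
    ok = frame["converged"] & (frame["alpha"] < 0.99 * alpha_hi)
    return frame.loc[ok]


def recovery_study(
    spec_a: CohortSpec,
    spec_b: CohortSpec,
    fit_config: FitConfig,
    rng: np.random.Generator,
) -> RecoveryReport:
    """Simulate both cohorts, fit every agent, and summarize recovery.

    Aborts if more than half of the fits fail.
    """
    frames = []
    for spec, label in ((spec_a, spec_a.label), (spec_b, spec_b.label)):
        gen = sample_cohort_params(spec, rng)
        traces = simulate_cohort(gen, spec, rng)
        fits = fits_to_frame(fit_cohort(traces, fit_config))
        gen = gen.rename(columns={"alpha": "alpha_gen", "cost": "cost_gen", "rho0": "rho0_gen"})
        merged = gen.drop(columns=["n_posts"]).merge(fits, on="user_id")
        merged["group"] = label
        frames.append(merged)
    table = pd.concat(frames, ignore_index=True)
    n_total = len(table)
    kept = _exclude_boundary(table, fit_config.alpha_bounds[1])
    n_fitted = len(kept)
    if n_fitted < 0.5 * n_total:
        raise RuntimeError(
            f"fitting failure rate {1 - n_fitted / n_total:.0%} exceeds 50%; "
            "check the cohort specs and fit configuration"
        )
    a = kept[kept["group"] == spec_a.label]
    b = kept[kept["group"] == spec_b.label]
    alpha_student = student_t(a["alpha"], b["alpha"])
    return RecoveryReport(
        label_a=spec_a.label,
        label_b=spec_b.label,
        n_fitted=n_fitted,
        n_excluded=n_total - n_fitted,
        r_alpha=pearson_r(kept["alpha_gen"], kept["alpha"]),
        r_cost=pearson_r(kept["cost_gen"], kept["cost"]),
        mean_alpha_a=float(a["alpha"].mean()),
        mean_alpha_b=float(b["alpha"].mean()),
        mean_cost_a=float(a["cost"].mean()),
        mean_cost_b=float(b["cost"].mean()),
        alpha_student=alpha_student,
        alpha_welch=welch_t(a["alpha"], b["alpha"]),
        alpha_student_one_sided_p=student_t(a["alpha"], b["alpha"], sided="less").p,
        cost_student=student_t(a["cost"], b["cost"]),
        cost_welch=welch_t(a["cost"], b["cost"]),
        alpha_cohens_d=cohens_d(a["alpha"], b["alpha"]),
        table=kept.reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Power analysis


@dataclass(frozen=True)
class PowerRow:
    n_per_group: int
    reps: int
    rejection_rate: float
    ci_low: float
    ci_high: float


@dataclass
class PowerTable:
    alpha_level: float
    rows: list[PowerRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])


def _wilson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    z = float(sps.norm.ppf(0.5 + conf / 2))
    phat = k / n
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


def power_curve(
    spec_a: CohortSpec,
    spec_b: CohortSpec,
    fit_config: FitConfig,
    n_grid: Sequence[int],
    reps: int,
    rng: np.random.Generator,
    alpha_level: float = 0.05,
) -> PowerTable:
    """Monte-Carlo rejection rate of the one-sided fitted-alpha contrast
    (H1: group B's mean fitted alpha exceeds group A's) at each group size.

    Each replication simulates ``n`` fresh agents per group, fits them, and
    applies the one-sided Welch test at ``alpha_level``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    for n in n_grid:
        k = 0
        for rep in range(reps):
            sa = CohortSpec(**{**asdict_spec(spec_a), "n_agents": int(n)})
            sb = CohortSpec(**{**asdict_spec(spec_b), "n_agents": int(n)})
            fits = []
            for spec in (sa, sb):
                gen = sample_cohort_params(spec, rng)
                traces = simulate_cohort(gen, spec, rng)
                fr = fits_to_frame(fit_cohort(traces, fit_config))
                fr = _exclude_boundary(fr, fit_config.alpha_bounds[1])
                fits.append(fr["alpha"].to_numpy())
            res = welch_t(fits[0], fits[1], sided="less")
            k += res.p < alpha_level
        lo, hi = _wilson_ci(k, reps)
        rows.append(PowerRow(int(n), reps, k / reps, lo, hi))
    return PowerTable(alpha_level=alpha_level, rows=rows)


def asdict_spec(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["likes_env"] = spec.likes_env  # keep the dataclass, not a dict
    return d
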
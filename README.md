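# postvigor

An average-reward reinforcement-learning account of how social-media users
pace their posting in response to the likes they receive — as a tested,
reusable Python package for researchers working with digital trace data
(ordered posts with timestamps and like counts).

## The model

A user posts, receives `r` likes, and waits a latency `τ` (days) before
posting again.  `τ` is drawn from an exponential distribution whose mean is
the current *policy* `ρ`.  Each post yields a net reward

```
n_t = U(r_t) − C / τ_t
```

(like utility minus an effort cost that grows for quick responses).  The net
reward prediction error `δ_t = n_t − R̄_t` compares the outcome with the
running average net reward rate `R̄` — the opportunity cost of slow
responding — and a single learning rate `α` drives both updates:

```
R̄ ← R̄ + α δ_t
ρ ← ρ + α δ_t (τ_t − ρ)
```

Three free parameters per user — `α` (sensitivity to social feedback), `C`
(effort cost), and the initial policy `ρ0` — are estimated by maximum
likelihood on the observed (latency, likes) sequence.  A companion mood
model treats mood as an exponentially weighted running average of the
prediction errors, `m ← m + η(δ − m)`, which links feedback sensitivity to
mood swings when the reward environment shifts.

## What's in the box

| module | purpose |
| --- | --- |
| `postvigor.trace_io` | read/write/preprocess trace CSV/JSONL (carousel collapsing, 10-post filter, latency derivation) |
| `postvigor.rl_core` | the model's update rules, forward simulator, and trace log-likelihood |
| `postvigor.fitting` | per-user multi-start MLE, cohort fitting, winsorization |
| `postvigor.synthetic_cohort` | generative cohorts, likes environments, block reward schedules |
| `postvigor.recovery_power` | parameter-recovery studies, power curves, and the statistics toolkit (Welch/Student t, Pearson r, Cohen's d, Mann-Whitney U + rank-biserial) |
| `postvigor.mood_sim` | mood trajectories and two-group mood simulations |
| `postvigor.cli` | `postvigor simulate / fit / recover / power / mood` |

## Worked example

```python
import numpy as np
from postvigor import (FitConfig, adult_spec, sample_cohort_params,
                       simulate_cohort, fit_cohort, fits_to_frame)

rng = np.random.default_rng(0)
spec = adult_spec(n_agents=30)           # α ~ TruncNormal(0.002, 0.002, ≥0)
gen = sample_cohort_params(spec, rng)    # per-agent (α, C, ρ0, n_posts)
traces = simulate_cohort(gen, spec, rng)
fits = fits_to_frame(fit_cohort(traces, FitConfig(seed=1)))
merged = gen.rename(columns={"alpha": "alpha_gen"}).merge(fits, on="user_id")
print(merged[["alpha_gen", "alpha"]].mean())
print("recovery r:", np.corrcoef(merged.alpha_gen, merged.alpha)[0, 1].round(2))
```

prints (seeds as above)

```
alpha_gen    0.002796
alpha        0.002891
dtype: float64
recovery r: 0.92
```

i.e. the cohort's mean generative learning rate is ≈0.0028, the mean fitted
learning rate ≈0.0029, and generative and fitted values correlate at
r ≈ 0.9 on this 30-agent sample — the fitted `alpha` column is what group
contrasts (e.g. adolescents vs adults) are computed on.

The same pipeline runs from the shell:

```sh
postvigor simulate --spec adult.yaml --out traces.csv --seed 1
postvigor fit --input traces.csv --output fits.csv --seed 1
postvigor recover --spec-a adult.yaml --spec-b adolescent.yaml --seed 1 --out report.json
postvigor mood --n-sims 100 --seed 1 --out-summary mood.json
```

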
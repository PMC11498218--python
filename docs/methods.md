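# Methods

## Model

The package implements a response-vigor account of posting: an agent
maximizes its average net reward rate by adapting the mean of an exponential
latency distribution.  State per post `t` is the policy `ρ_t > 0` (days),
the average net reward rate `R̄_t`, and the last prediction error `δ_t`.
With like utility `U` (identity by default, optionally `ln(1+r)` for a
concave variant), the recursion is

    n_t  = U(r_t) − C/τ_t
    δ_t  = n_t − R̄_t
    R̄_{t+1} = R̄_t + α δ_t
    ρ_{t+1} = max(ρ_floor, ρ_t + α δ_t (τ_t − ρ_t))

The actor update couples the prediction error with the deviation of the
realized latency from the policy: a faster-than-policy post that turned out
better than average shortens the policy.  Critic and actor share the single
learning rate `α`, so the model has exactly three free parameters
(`α`, `C`, `ρ0`).  `R̄` is initialized at 0 (a fourth free parameter is
deliberately not introduced).  The exact update algebra is a design choice
of this package: it realizes the three stated ingredients (learning rate,
latency deviation, net reward prediction error) and the effort/opportunity
cost trade-off with the smallest parameterization; alternative
actor-critic factorizations with separate step sizes would add parameters
without being identifiable from latencies alone.

A user's first post has no defined latency.  Its likes still enter the
state, with `τ = ρ0` standing in for the effort-cost denominator; the
first-post latency contributes nothing to the likelihood.  The trace
negative log-likelihood replays the recursion over observed
(latency, likes) pairs and sums `ln ρ_t + τ_t/ρ_t` over the defined
latencies.

Numerical floors: policy and latencies are clamped at `1e−3` days
(≈ 86 s) so the exponential log-density stays finite; latencies are
expressed in days (86,400 s/day), timestamps in UTC at one-second
resolution.

## Preprocessing conventions

* Rows without a parseable timestamp are dropped at read time and counted.
* Carousel posts (runs of rows sharing one timestamp, each carrying the
  same like count) are collapsed to their first row, in file order.
* Users with fewer than 10 posts are excluded (configurable).
* Latencies are consecutive timestamp differences in days; the first
  latency is undefined (NaN); zero gaps that survive carousel collapsing
  are clamped to the floor.  The floor for tied non-carousel posts is a
  convention — trace datasets rarely document their timestamp resolution.

## Estimation

Per-user MLE minimizes the trace NLL over `(α, C, ρ0)` on a bounded
sigmoid transform of each parameter (search bounds: `α ∈ [0, 0.1]`,
`C ∈ [0, 10·max(likes)·mean(latency)]`, `ρ0 ∈ [floor, 10·max(latency)]`),
using Nelder-Mead with 10 restarts by default.  Two starts are
deterministic — the no-learning exponential MLE (`α≈0, C≈0, ρ0 = mean
latency`) and the same point with a typical small learning rate
(`α = 10⁻³`), because the likelihood is often bimodal between a
no-learning and a learning basin — and the rest are drawn uniformly on the
transformed scale, which spreads them over orders of magnitude.  If the
best start exhausts its iteration budget, a fresh simplex is restarted at
the incumbent; a fit counts as converged when the simplex criterion is met
or the restart cannot improve the optimum beyond tolerance.  Restart draws
are seeded from the configuration seed plus a digest of the trace content,
so identical data always produce identical fits regardless of position in
a cohort.

Fits flagged non-converged, and fits with `α` pinned at the upper search
bound, are excluded from downstream statistics with counts reported.  A
small number of traces genuinely sit on a degenerate ridge (tiny `α`,
very large `C`) where the likelihood improves indefinitely but negligibly;
these are the typical non-convergences.

Winsorization of fitted learning rates clips at the (0.025, 0.975)
quantiles by default, the usual treatment of a few extreme fitted values
before rank-sensitive downstream analyses.

## Synthetic cohorts

The generator emulates the statistical structure of large Instagram-style
trace datasets, which are not redistributable:

* learning rates: truncated normal, lower bound 0 (stock specs: mean
  0.002 "adult", 0.003 "adolescent", SD 0.002);
* effort costs: Uniform(0, 1);
* post counts: round(Normal(70, 20)) clamped at ≥ 10 so every simulated
  agent passes the inclusion filter;
* initial policies: Uniform(0.5, 5) days, bracketing the empirical group
  mean latencies (1.26 and 2.20 days);
* likes: negative binomial, mean 100, dispersion 1 — heavy-tailed counts
  on the scale between the empirical group means (97.28 and 207.5 likes).

The likes environment and the `ρ0` distribution are conventions of this
package: the recovery-study design does not pin them down.  They are configurable (negative-binomial, lognormal, constant, and
uniform families), and the recovery statistics depend on them — a more
dispersed or lower-mean environment weakens the identifiability of `α`.
What the generator does **not** emulate: posting-rate nonstationarity,
audience/follower growth, dependence of likes on latency or content, and
circadian or weekly rhythms.  Passing recovery tests therefore show that
the estimation machinery works under the model's own assumptions, not that
real trace data satisfy them.

## Recovery and power studies

`recovery_study` simulates two cohorts differing only in the generative
`α` distribution, fits every agent, excludes non-converged/boundary fits,
and reports pooled generative-vs-fitted Pearson correlations, per-group
fitted means, and the group contrasts.  Both pooled-df (Student) and
Welch t statistics are computed; the pooled variant is the headline number
for comparability with the integer `n−2`-style degrees of freedom
conventionally reported for such contrasts.  The directional hypothesis (adolescent
`α` above adult) is reported one-sided alongside the two-sided test.

`power_curve` repeats the one-sided Welch contrast on freshly simulated
cohorts of size `n` per group, `reps` times, and reports the rejection
fraction with a Wilson 95% interval.  `reps ≥ 1` is enforced (the
parameter-error case is `reps = 0`); meaningful estimates need tens to
hundreds of replications, and the bundled calibration check uses 200.

## Mood simulations

Mood is an exponentially weighted running average of prediction errors,
`m ← m + η(δ − m)`, with `η = 0.1` and `m0 = 0` by default (`η` is held
constant across groups; its value is a package default, chosen so the
mood horizon spans roughly ten posts).  The two-group simulation runs the
RL model under a block schedule — 10 posts at 28–34 likes, then 10 posts
at 6–18 likes by default, the high/low-reward experimental ranges with a
fixed per-block post count standing in for the experiment's time-boxed
blocks — and contrasts group learning rates 0.0009 vs 0.0006 (the
empirical group means) with 100 simulations per group.

Both groups share common random numbers within each simulation index
(identical likes sequences and identical exponential latency quantiles),
so the group contrast isolates the effect of `α`; this is a
variance-reduction choice, and with it the equal-`α` control is exactly
symmetric.  The transition statistic is the mean mood over the final
block minus the mean over the first block.  Because mood starts at 0 and
ramps toward the high-reward asymptote during the first block, this
statistic can be positive even when mood falls across the transition; the
group effect appears as the higher-`α` group's statistic being *smaller*
(its mood falls further when likes drop).  Mood is reported in δ-units
(like-utility), not rescaled to any experimental mood slider.  Difference
scores over three measurements (baseline, post-high, post-low) are
computed later-minus-earlier, so a negative high→low score means mood
worsened when likes dropped.

## Problem sizes and tolerances

Statistical tests in the suite run at sizes chosen to make their
conclusions stable under the fixed seeds: 100-seed batteries for
likelihood-oracle and consistency checks, 10,000-draw distributional
checks, 200 replications for type-I calibration of the power pipeline
(15 agents per group, ~30 posts each), and the full 1000+1000-agent
recovery study for the headline simulation.  Oracle comparisons are exact
to 1e−10; closed-form MLE equivalence is asserted within optimizer
tolerance (5%); Monte-Carlo assertions use 3–4 standard-error bands or
Wilson intervals.

## Known limitations

* The exponential latency family has no refractory period and memoryless
  hazards; real inter-post times show diurnal structure the model ignores.
* `α` and `C` are weakly identified on short traces; cost recovery in
  particular is poor below ~50 agents per group and its fitted scale can
  far exceed the generative Uniform(0, 1) range on individual users.
* Under this package's likes environment, per-agent recovery of `α` is
  substantially better (r ≈ 0.4–0.9 depending on scale) than the weak
  correlations sometimes reported for recovery simulations of this design; recovery quality
  is environment-dependent, so cross-study comparisons of recovery r
  should fix the environment first.
* The mood model has no direct empirical anchoring of `η` and reports
  mood in model units; only directional, not quantitative, claims are
  supported.
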
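import math

import numpy as np
import pytest
from scipy import integrate, optimize, stats

from postvigor import (
    ModelParams,
    latency_loglik,
    net_reward,
    prediction_error,
    simulate_agent,
    trace_nll,
    update_avg_rate,
    update_policy,
    utility,
    POLICY_FLOOR_DAYS,
)


class TestPrimitives:
    @pytest.mark.parametrize(
        "likes,kind,expected",
        [(23, "linear", 23.0), (0, "log1p", 0.0), (99, "log1p", math.log(100.0))],
    )
    def test_utility(self, likes, kind, expected):
        assert utility(likes, kind) == pytest.approx(expected, abs=1e-12)

    def test_utility_unknown_kind(self):
        with pytest.raises(ValueError):
            utility(3, "sqrt")

    def test_utility_monotone_in_likes(self):
        grid = np.arange(0, 200)
        for kind in ("linear", "log1p"):
            assert np.all(np.diff(utility(grid, kind)) >= 0)

    @pytest.mark.parametrize(
        "u,cost,tau,expected", [(23, 0, 1, 23.0), (23, 10, 2, 18.0), (0, 5, 0.5, -10.0)]
    )
    def test_net_reward(self, u, cost, tau, expected):
        assert net_reward(u, cost, tau) == expected

    def test_net_reward_rejects_nonpositive_latency(self):
        with pytest.raises(ValueError):
            net_reward(1.0, 1.0, 0.0)

    @pytest.mark.parametrize("n,rbar,expected", [(18, 5, 13.0), (7, 7, 0.0), (0, -2, 2.0)])
    def test_prediction_error(self, n, rbar, expected):
        assert prediction_error(n, rbar) == expected

    def test_avg_rate_update(self):
        assert update_avg_rate(0.0, 10.0, 0.1) == pytest.approx(1.0)
        assert update_avg_rate(3.0, 99.0, 0.0) == 3.0

    def test_avg_rate_geometric_convergence(self):
        """Repeated constant net reward: Rbar_k = n*(1-(1-alpha)^k)."""
        alpha, n = 0.2, 5.0
        rbar = 0.0
        for k in range(1, 30):
            rbar = update_avg_rate(rbar, prediction_error(n, rbar), alpha)
            assert rbar == pytest.approx(n * (1 - (1 - alpha) ** k), rel=1e-12)

    def test_policy_update_examples(self):
        assert update_policy(2.0, 1.5, 10.0, 0.001) == pytest.approx(1.995)
        assert update_policy(2.0, 1.5, 0.0, 0.01) == 2.0  # no surprise, no update
        assert update_policy(0.01, 5.0, -100.0, 0.5) == POLICY_FLOOR_DAYS  # clamped

    def test_policy_update_direction(self):
        # faster-than-policy post with positive surprise shortens the policy
        assert update_policy(2.0, 1.0, 5.0, 0.01) < 2.0
        # slower-than-policy post with positive surprise lengthens it
        assert update_policy(2.0, 3.0, 5.0, 0.01) > 2.0


class TestLatencyLoglik:
    def test_value(self):
        assert latency_loglik(2.0, 2.0) == pytest.approx(-math.log(2.0) - 1.0)

    @pytest.mark.parametrize("rho", [0.25, 1.0, 3.7])
    def test_density_normalizes(self, rho):
        total, _ = integrate.quad(lambda t: math.exp(latency_loglik(t, rho)), 1e-12, np.inf)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_mle_policy_equals_latency(self):
        tau = 1.7
        res = optimize.minimize_scalar(
            lambda r: -latency_loglik(tau, r), bounds=(1e-3, 50), method="bounded"
        )
        assert res.x == pytest.approx(tau, rel=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            latency_loglik(-1.0, 2.0)
        with pytest.raises(ValueError):
            latency_loglik(1.0, 0.0)


def reference_nll(params, trace):
    """Independent straight-line replay of the state recursion, composed from
    the public primitive operations (oracle for trace_nll)."""
    taus = trace.latencies
    us = np.atleast_1d(utility(trace.likes, params.utility_kind))
    rho, rbar = params.rho0, 0.0
    # first post: likes enter the state with tau = rho0; no likelihood term
    delta = prediction_error(net_reward(us[0], params.cost, params.rho0), rbar)
    rbar = update_avg_rate(rbar, delta, params.alpha)
    rho = update_policy(rho, params.rho0, delta, params.alpha)
    total = 0.0
    for t in range(1, len(us)):
        total -= latency_loglik(taus[t], rho)
        delta = prediction_error(net_reward(us[t], params.cost, taus[t]), rbar)
        rbar = update_avg_rate(rbar, delta, params.alpha)
        rho = update_policy(rho, taus[t], delta, params.alpha)
    return total


class TestTraceNLL:
    def test_zero_learning_rate_closed_form(self, make_trace):
        trace = make_trace([1.0, 2.0, 3.0], [0, 0, 0, 0])
        p = ModelParams(alpha=0.0, cost=0.0, rho0=2.0)
        assert trace_nll(p, trace) == pytest.approx(3 * math.log(2.0) + 6 / 2.0)

    def test_zero_learning_rate_minimized_at_mean_latency(self, make_trace):
        lats = [0.5, 1.5, 2.5, 4.0]
        trace = make_trace(lats, [3] * 5)
        mean = np.mean(lats)
        res = optimize.minimize_scalar(
            lambda r: trace_nll(ModelParams(0.0, 0.0, r), trace),
            bounds=(1e-3, 50),
            method="bounded",
        )
        assert res.x == pytest.approx(mean, rel=1e-4)

    def test_matches_independent_recursion(self, make_trace, rng):
        """Golden check: the fast likelihood equals a primitive-by-primitive
        replay to 1e-10 across random traces and parameters."""
        for _ in range(100):
            n = int(rng.integers(2, 40))
            lats = rng.exponential(2.0, size=n - 1) + 1e-3
            likes = rng.integers(0, 300, size=n)
            trace = make_trace(lats, likes)
            p = ModelParams(
                alpha=float(rng.uniform(0, 0.05)),
                cost=float(rng.uniform(0, 5)),
                rho0=float(rng.uniform(0.1, 8)),
                utility_kind="linear" if rng.random() < 0.5 else "log1p",
            )
            assert trace_nll(p, trace) == pytest.approx(reference_nll(p, trace), abs=1e-10)

    def test_requires_two_posts(self, make_trace):
        trace = make_trace([], [5])
        with pytest.raises(ValueError):
            trace_nll(ModelParams(0.0, 0.0, 1.0), trace)


class ConstantLikes:
    def __init__(self, value):
        self.value = value

    def sample(self, rng, size):
        return np.full(size, self.value, dtype=np.int64)


class TestSimulateAgent:
    def test_fixed_seed_reproducible(self, default_params):
        t1, _ = simulate_agent(default_params, ConstantLikes(20), 50, np.random.default_rng(5))
        t2, _ = simulate_agent(default_params, ConstantLikes(20), 50, np.random.default_rng(5))
        assert np.array_equal(t1.timestamps, t2.timestamps)
        assert np.array_equal(t1.likes, t2.likes)

    def test_zero_learning_rate_mean_latency(self):
        p = ModelParams(alpha=0.0, cost=0.0, rho0=2.0)
        _, traj = simulate_agent(p, ConstantLikes(10), 5000, np.random.default_rng(11))
        taus = traj.tau[1:]
        se = taus.std(ddof=1) / math.sqrt(taus.size)
        assert abs(taus.mean() - 2.0) < 3 * se

    def test_zero_learning_rate_latencies_are_iid_exponential(self):
        p = ModelParams(alpha=0.0, cost=0.0, rho0=1.5)
        _, traj = simulate_agent(p, ConstantLikes(10), 10_001, np.random.default_rng(2))
        ks = stats.kstest(traj.tau[1:], "expon", args=(0, 1.5))
        assert ks.pvalue > 0.01

    def test_reward_accelerates_engagement(self):
        """With zero cost and constant positive likes, early prediction errors
        are positive and the policy shortens on average (200 seeded runs)."""
        p = ModelParams(alpha=0.005, cost=0.0, rho0=2.0)
        end_policies, early_deltas = [], []
        for seed in range(200):
            _, traj = simulate_agent(p, ConstantLikes(30), 40, np.random.default_rng(seed))
            early_deltas.append(traj.delta[:5].mean())
            end_policies.append(traj.policy[-1])
        assert min(early_deltas) > 0
        assert np.mean(end_policies) < 2.0

    def test_policy_stays_above_floor(self, rng):
        p = ModelParams(alpha=0.05, cost=2.0, rho0=0.5)
        for seed in range(20):
            _, traj = simulate_agent(p, ConstantLikes(200), 200, np.random.default_rng(seed))
            assert np.all(traj.policy >= POLICY_FLOOR_DAYS)

    def test_simulated_trace_has_finite_nll(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            p = ModelParams(
                alpha=float(r.uniform(0, 0.02)),
                cost=float(r.uniform(0, 2)),
                rho0=float(r.uniform(0.5, 5)),
            )
            trace, _ = simulate_agent(p, ConstantLikes(int(r.integers(1, 300))), 60, r)
            assert np.isfinite(trace_nll(p, trace))

    def test_richer_environment_raises_early_prediction_errors(self):
        """Adding a constant to every like count raises mean delta over the
        first 10 posts (checked across seeds)."""
        p = ModelParams(alpha=0.002, cost=0.5, rho0=2.0)
        diffs = []
        for seed in range(50):
            _, lo = simulate_agent(p, ConstantLikes(50), 10, np.random.default_rng(seed))
            _, hi = simulate_agent(p, ConstantLikes(80), 10, np.random.default_rng(seed))
            diffs.append(hi.delta[:10].mean() - lo.delta[:10].mean())
        assert np.mean(diffs) > 0 and min(diffs) > 0

    def test_generative_params_beat_random_draws(self):
        """Expected NLL is lowest near the generative parameters: at
        n_posts=500 the generative parameter vector has lower mean NLL than
        each of 10 random draws over 100 seeds."""
        gen = ModelParams(alpha=0.003, cost=0.5, rho0=1.5)
        draw_rng = np.random.default_rng(77)
        rivals = [
            ModelParams(
                alpha=float(draw_rng.uniform(0, 0.02)),
                cost=float(draw_rng.uniform(0, 3)),
                rho0=float(draw_rng.uniform(0.2, 6)),
            )
            for _ in range(10)
        ]
        gen_nll = np.zeros(100)
        rival_nll = np.zeros((10, 100))
        for s in range(100):
            trace, _ = simulate_agent(gen, ConstantLikes(100), 500, np.random.default_rng(s))
            gen_nll[s] = trace_nll(gen, trace)
            for j, rp in enumerate(rivals):
                rival_nll[j, s] = trace_nll(rp, trace)
        assert np.all(rival_nll.mean(axis=1) > gen_nll.mean())

    def test_trajectory_frame_schema(self, default_params, rng):
        _, traj = simulate_agent(default_params, ConstantLikes(5), 12, rng)
        frame = traj.to_frame()
        assert list(frame.columns) == [
            "post_index", "tau", "likes", "policy", "net_reward", "avg_rate", "delta",
        ]
        assert len(frame) == 12
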
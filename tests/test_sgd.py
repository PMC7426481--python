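"""Controller arithmetic, variance metrics and descent behaviour on the
closed-form Gaussian quadratic oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcsgd import (
    GaussianQuadraticOracle,
    StrategyConfig,
    VarianceReport,
    estimate_variance,
    growth_factor,
    inner_product_test,
    norm_test,
    run_inversion,
    step_size,
)
from mcsgd.oracles import GradientSample


def _report(v_tot_sq, v_par_sq, mean=(1.0, 0.0)):
    return VarianceReport(np.asarray(mean, float), v_tot_sq, v_par_sq, 2)


class _FixedSampleOracle:
    """Oracle returning a preset list of gradient vectors (for metric checks)."""

    sample_granularity = 1
    min_sample = 1

    def __init__(self, grads):
        self.grads = [np.asarray(g, float) for g in grads]
        self.calls = 0

    def __call__(self, x, n, seed):
        g = self.grads[self.calls % len(self.grads)]
        self.calls += 1
        return GradientSample(grad=g, cost=0.0, sample_size=n, seed=seed)


class TestVarianceMetrics:
    def test_identical_samples_have_zero_variance(self):
        oracle = _FixedSampleOracle([[1.0, 2.0]])
        rep = estimate_variance(oracle, np.zeros(2), 10, 5, seed=0)
        assert rep.v_tot_sq == 0.0 and rep.v_par_sq == 0.0

    def test_orthogonal_deviations_give_zero_parallel_variance(self):
        # two samples, mean (3,4); deviations +/- c*(0.8,-0.6) orthogonal to mean
        c = 2.0
        oracle = _FixedSampleOracle(
            [[3 + 0.8 * c, 4 - 0.6 * c], [3 - 0.8 * c, 4 + 0.6 * c]]
        )
        rep = estimate_variance(oracle, np.zeros(2), 10, 2, seed=0)
        assert rep.v_par_sq == pytest.approx(0.0, abs=1e-12)
        assert rep.v_tot_sq == pytest.approx(2 * c**2 / 25)

    def test_zero_mean_gradient_is_degenerate_pass(self):
        oracle = _FixedSampleOracle([[1.0, 0.0], [-1.0, 0.0]])
        rep = estimate_variance(oracle, np.zeros(2), 10, 2, seed=0)
        assert rep.degenerate
        assert growth_factor(StrategyConfig(1, 1.0, gamma_tot=4.0), rep) == 1.0

    def test_gaussian_oracle_moments(self):
        """E[V_tot^2] ~ d sigma^2/(n ||gradF||^2), E[V_par^2] ~ sigma^2/(n ||gradF||^2)."""
        d, sigma, n = 30, 2.0, 50
        x_star = np.zeros(d)
        x = np.full(d, 1.0)  # ||gradF||^2 = d
        oracle = GaussianQuadraticOracle(x_star, sigma)
        reps = [estimate_variance(oracle, x, n, 200, seed=s) for s in range(5)]
        vt = np.mean([r.v_tot_sq for r in reps])
        vp = np.mean([r.v_par_sq for r in reps])
        assert vt == pytest.approx(d * sigma**2 / (n * d), rel=0.15)
        assert vp == pytest.approx(sigma**2 / (n * d), rel=0.3)

    def test_halving_law_is_exact_on_gaussian_oracle(self):
        """Doubling the sample size halves E[V_tot^2]."""
        d, sigma = 20, 3.0
        oracle = GaussianQuadraticOracle(np.zeros(d), sigma)
        x = np.full(d, 2.0)
        v1 = np.mean(
            [estimate_variance(oracle, x, 40, 300, seed=s).v_tot_sq for s in range(4)]
        )
        v2 = np.mean(
            [estimate_variance(oracle, x, 80, 300, seed=s + 50).v_tot_sq for s in range(4)]
        )
        assert v1 / v2 == pytest.approx(2.0, rel=0.1)

    @settings(deadline=None, max_examples=40)
    @given(
        seed=st.integers(0, 10**6),
        n_rep=st.integers(2, 12),
        d=st.integers(2, 8),
    )
    def test_parallel_never_exceeds_total(self, seed, n_rep, d):
        """Cauchy-Schwarz: V_par^2 <= V_tot^2 for arbitrary sample sets."""
        rng = np.random.default_rng(seed)
        grads = rng.normal(size=(n_rep, d)) * rng.lognormal(size=(n_rep, 1))
        oracle = _FixedSampleOracle(list(grads))
        rep = estimate_variance(oracle, np.zeros(d), 10, n_rep, seed=0)
        assert rep.v_par_sq <= rep.v_tot_sq + 1e-12


class TestTests:
    def test_norm_test_boundary(self):
        assert norm_test(_report(16.0, 1.0), 4.0)
        assert not norm_test(_report(32.0, 1.0), 4.0)
        assert norm_test(_report(0.0, 0.0), 0.5)

    def test_inner_product_test_boundary(self):
        assert inner_product_test(_report(200.0, 100.0), 10.0)
        assert inner_product_test(_report(1.0, 0.0), 10.0)
        assert not inner_product_test(_report(300.0, 101.0), 10.0)

    def test_anisotropic_noise_passes_inner_product_but_fails_norm(self):
        # noise orthogonal to the mean: large total variance, zero parallel
        rep = _report(40.0, 0.0)
        assert not norm_test(rep, 4.0)
        assert inner_product_test(rep, 4.0)


class TestStepSize:
    def test_strategy1_constant(self):
        cfg = StrategyConfig(1, 2.5, gamma_tot=4.0, test_every=None)
        assert step_size(cfg) == pytest.approx(1.0 / 42.5)

    def test_strategy3_adaptive(self):
        cfg = StrategyConfig(3, 50.0, gamma_par=10.0)
        assert step_size(cfg, _report(9.0, 1.0)) == pytest.approx(1.0 / (4 * 50))

    def test_strategy2_adaptive(self):
        cfg = StrategyConfig(2, 2.0, gamma_par=10.0)
        assert step_size(cfg, _report(3.0, 1.0)) == pytest.approx(1.0 / (4 * 2.0))

    def test_zero_noise_limit_recovers_deterministic_step(self):
        rep = _report(0.0, 0.0)
        for sid in (2, 3):
            cfg = StrategyConfig(sid, 5.0, gamma_par=1.0)
            assert step_size(cfg, rep) == pytest.approx(1.0 / 5.0)

    def test_step_size_ordering(self):
        # V_tot <= gamma_tot: strategy 2 steps at least as large as strategy 1
        L = 2.5
        for v_tot_sq in (0.5, 4.0, 15.9):
            a1 = step_size(StrategyConfig(1, L, gamma_tot=4.0, test_every=None))
            a2 = step_size(StrategyConfig(2, L, gamma_par=1.0), _report(v_tot_sq, 0.1))
            assert a2 >= a1
        # V_tot >= 1: strategy 3 steps at least as large as strategy 2
        for v_tot_sq in (1.0, 9.0, 100.0):
            a2 = step_size(StrategyConfig(2, L, gamma_par=1.0), _report(v_tot_sq, 0.1))
            a3 = step_size(StrategyConfig(3, L, gamma_par=1.0), _report(v_tot_sq, 0.1))
            assert a3 >= a2


class TestGrowthFactor:
    def test_strategy1_ratio(self):
        cfg = StrategyConfig(1, 2.5, gamma_tot=4.0, test_every=None)
        assert growth_factor(cfg, _report(32.0, 1.0)) == pytest.approx(2.0)

    def test_strategy3_sqrt_ratio(self):
        cfg = StrategyConfig(3, 50.0, gamma_par=10.0)
        assert growth_factor(cfg, _report(500.0, 400.0)) == pytest.approx(2.0)

    def test_strategy2_ratio(self):
        cfg = StrategyConfig(2, 1.0, gamma_par=2.0)
        assert growth_factor(cfg, _report(20.0, 12.0)) == pytest.approx(3.0)

    def test_pass_keeps_sample_size(self):
        cfg = StrategyConfig(1, 2.5, gamma_tot=4.0, test_every=None)
        assert growth_factor(cfg, _report(15.9, 1.0)) == 1.0

    def test_clamped_at_one(self):
        cfg = StrategyConfig(3, 1.0, gamma_par=2.0)
        # failing test with ratio < 1 cannot shrink the sample
        assert growth_factor(cfg, _report(100.0, 4.1)) >= 1.0


class TestStrategyConfigValidation:
    def test_missing_gamma_rejected(self):
        with pytest.raises(ValueError):
            StrategyConfig(1, 2.5)
        with pytest.raises(ValueError):
            StrategyConfig(3, 2.5, gamma_tot=4.0)

    def test_adaptive_strategies_need_tests(self):
        with pytest.raises(ValueError):
            StrategyConfig(2, 2.5, gamma_par=1.0, test_every=None)


class TestRunInversion:
    def test_budget_smaller_than_one_iteration(self):
        oracle = GaussianQuadraticOracle(np.zeros(3), 1.0)
        x0 = np.ones(3)
        cfg = StrategyConfig(1, 1.0, gamma_tot=1.0, test_every=None)
        x, trace = run_inversion(oracle, x0, cfg, s1=100, n_ph_budget=50, seed=0)
        assert len(trace) == 0 and trace.status == "budget_too_small"
        assert np.array_equal(x, x0)

    def test_adaptive_descent_converges_on_gaussian_oracle(self):
        """Strategy 1 descends geometrically, grows |S| when the norm test
        fails, and ends much closer to the minimum than it started."""
        d = 10
        oracle = GaussianQuadraticOracle(np.full(d, 3.0), sigma=2.0)
        x0 = np.zeros(d)
        cfg = StrategyConfig(1, 1.0, gamma_tot=0.7, test_every=5, n_rep=30)
        x, trace = run_inversion(
            oracle, x0, cfg, s1=2, n_ph_budget=1_000_000, seed=3,
            project_nonnegative=False,
        )
        df = trace.to_dataframe()
        assert np.linalg.norm(x - oracle.x_star) < 0.1 * np.linalg.norm(x0 - oracle.x_star)
        assert (np.diff(df.S_n) >= 0).all()
        assert df.S_n.iloc[-1] > df.S_n.iloc[0]  # noise forced growth

    def test_sample_grows_only_on_test_failure(self):
        d = 8
        oracle = GaussianQuadraticOracle(np.full(d, 1.0), sigma=1.0)
        cfg = StrategyConfig(3, 1.0, gamma_par=0.3, test_every=4, n_rep=20)
        _, trace = run_inversion(
            oracle, np.zeros(d), cfg, s1=4, n_ph_budget=200_000, seed=7,
            project_nonnegative=False,
        )
        df = trace.to_dataframe()
        tested = df[df.test_pass.notna()]
        for i in range(len(df) - 1):
            if df.S_n.iloc[i + 1] > df.S_n.iloc[i]:
                row = df.iloc[i]
                assert row.test_pass is False or row.test_pass == False  # noqa: E712
        assert (tested.kappa >= 1).all()

    def test_fixed_sample_stalls_at_noise_floor_adaptive_passes_below(self):
        """Fixed-sample SGD random-walks at its predicted cost floor; the
        adaptive controller descends below it."""
        d = 6
        sigma = 4.0
        oracle = GaussianQuadraticOracle(np.full(d, 5.0), sigma=sigma)
        x0 = np.zeros(d)
        s1 = 4
        fixed_cfg = StrategyConfig(1, 1.0, gamma_tot=2.0, test_every=None)
        alpha = step_size(fixed_cfg)
        floor = oracle.noise_floor_cost(alpha, s1)
        _, tr_fixed = run_inversion(
            oracle, x0, fixed_cfg, s1=s1, n_ph_budget=40_000, seed=1,
            project_nonnegative=False,
        )
        df = tr_fixed.to_dataframe()
        tail = df.F_Sn.iloc[-200:].mean()
        assert tail == pytest.approx(floor, rel=0.6)
        assert tail > 0.1 * floor  # genuinely stalled above zero

        adaptive_cfg = StrategyConfig(1, 1.0, gamma_tot=0.5, test_every=10, n_rep=30)
        x_ad, _ = run_inversion(
            oracle, x0, adaptive_cfg, s1=s1, n_ph_budget=40_000, seed=1,
            project_nonnegative=False,
        )
        assert oracle.true_cost(x_ad) < 0.2 * tail

    def test_zero_noise_reduces_to_plain_gd(self):
        d = 5
        oracle = GaussianQuadraticOracle(np.linspace(1, 2, d), sigma=0.0)
        cfg = StrategyConfig(2, 4.0, gamma_par=1.0, test_every=3, n_rep=5)
        x, trace = run_inversion(
            oracle, np.zeros(d), cfg, s1=1, n_ph_budget=100, seed=0,
            project_nonnegative=False,
        )
        df = trace.to_dataframe()
        assert np.allclose(df.alpha_n, 1.0 / 4.0)
        f = [oracle.true_cost(np.zeros(d))] + [c for c in df.F_Sn]
        assert all(b <= a + 1e-12 for a, b in zip(f, f[1:]))
        assert (df.S_n == 1).all()

    def test_trace_deterministic(self):
        oracle = GaussianQuadraticOracle(np.full(4, 2.0), sigma=1.0)
        cfg = StrategyConfig(3, 1.0, gamma_par=0.5, test_every=5, n_rep=10)
        runs = [
            run_inversion(oracle, np.zeros(4), cfg, 4, 20_000, seed=42,
                          project_nonnegative=False)[1].to_dataframe()
            for _ in range(2)
        ]
        assert runs[0].equals(runs[1])

    def test_cumulative_photons_equal_sum_of_samples(self):
        oracle = GaussianQuadraticOracle(np.full(3, 1.0), sigma=1.0)
        cfg = StrategyConfig(1, 1.0, gamma_tot=0.5, test_every=7, n_rep=8)
        _, trace = run_inversion(
            oracle, np.zeros(3), cfg, 5, 30_000, seed=2, project_nonnegative=False
        )
        df = trace.to_dataframe()
        assert df.cum_photons.iloc[-1] == df.S_n.sum()
        assert df.cum_photons.iloc[-1] <= 30_000

    def test_nonnegativity_projection(self):
        oracle = GaussianQuadraticOracle(np.array([-5.0, 5.0]), sigma=0.5)
        cfg = StrategyConfig(1, 1.0, gamma_tot=2.0, test_every=None)
        x, _ = run_inversion(oracle, np.array([1.0, 1.0]), cfg, 10, 50_000, seed=0)
        assert (x >= 0).all()
        assert x[0] == pytest.approx(0.0, abs=1e-9)
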
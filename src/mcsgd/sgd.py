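"""Adaptive-sample-size stochastic gradient descent.

The descent x_{n+1} = x_n - alpha_n * gradF_Sn(x_n) consumes a fixed photon
budget N_ph.  Periodically (every ``test_every`` iterations) the gradient
noise is measured from N_rep independent oracle repeats at the current sample
size: with sample mean gbar standing in for the true gradient,

    V_tot^2 = E||g - gbar||^2 / ||gbar||^2        (norm test metric)
    V_par^2 = E<g - gbar, gbar>^2 / ||gbar||^4    (inner product test metric)

The norm test passes when V_tot^2 <= gamma_tot^2, the inner product test when
V_par^2 <= gamma_par^2.  Three control strategies couple these metrics to the
step size and to multiplicative sample-size growth:

    strategy  step size alpha_n         growth factor kappa on test failure
    1         1 / ((1 + gamma_tot^2) L)  V_tot^2 / gamma_tot^2   (norm test)
    2         1 / ((1 + V_tot^2) L)      V_par^2 / gamma_par^2   (inner product)
    3         1 / ((1 + V_tot) L)        V_par / gamma_par       (inner product)

On a pass the sample size is unchanged.  As the measured noise vanishes,
strategies 2 and 3 recover the deterministic step 1/L.

The loop is oracle-agnostic: anything callable as ``oracle(x, n, seed) ->
GradientSample`` works, including the closed-form
:class:`GaussianQuadraticOracle` used for controller verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_seed
from .oracles import GradientSample
from .slab import AbsorptionField

__all__ = [
    "StrategyConfig",
    "VarianceReport",
    "DescentTrace",
    "GaussianQuadraticOracle",
    "estimate_variance",
    "norm_test",
    "inner_product_test",
    "step_size",
    "growth_factor",
    "run_inversion",
]


@dataclass(frozen=True)
class StrategyConfig:
    """Controller configuration: strategy id, thresholds, Lipschitz constant,
    metric cadence and repeat count.

    ``test_every=None`` disables metric evaluation entirely (plain fixed-step,
    fixed-sample SGD; strategy 1 only, since strategies 2-3 derive their step
    size from the measured noise).  ``count_metric_photons`` charges the
    N_rep * |S| metric photons against the budget; off by default.
    """

    strategy_id: int
    lipschitz_L: float
    gamma_tot: float | None = None
    gamma_par: float | None = None
    test_every: int | None = 10
    n_rep: int = 100
    count_metric_photons: bool = False

    def __post_init__(self) -> None:
        if self.strategy_id not in (1, 2, 3):
            raise ValueError("strategy_id must be 1, 2 or 3")
        if not self.lipschitz_L > 0:
            raise ValueError("lipschitz_L must be > 0")
        if self.strategy_id == 1:
            if self.gamma_tot is None or not self.gamma_tot > 0:
                raise ValueError("strategy 1 requires gamma_tot > 0")
        else:
            if self.gamma_par is None or not self.gamma_par > 0:
                raise ValueError(f"strategy {self.strategy_id} requires gamma_par > 0")
            if self.test_every is None:
                raise ValueError("strategies 2-3 need metric evaluations (test_every)")
        if self.test_every is not None and self.test_every < 1:
            raise ValueError("test_every must be >= 1 (or None)")
        if self.n_rep < 2:
            raise ValueError("n_rep must be >= 2")


@dataclass(frozen=True)
class VarianceReport:
    """Noise metrics from N_rep repeated oracle calls at one iterate."""

    mean_grad: np.ndarray
    v_tot_sq: float
    v_par_sq: float
    n_rep_used: int
    degenerate: bool = False  # ||mean_grad|| == 0: stationary sampled point

    @property
    def v_tot(self) -> float:
        return math.sqrt(self.v_tot_sq)

    @property
    def v_par(self) -> float:
        return math.sqrt(self.v_par_sq)


def estimate_variance(oracle, x, sample_size: int, n_rep: int, seed: int) -> VarianceReport:
    """Draw ``n_rep`` independent gradient samples at ``x`` and compute the
    relative variance metrics, using the repeat mean as the true-gradient
    proxy (a conservative stand-in: tests fail earlier than with the exact
    gradient).  Sample variances use the n_rep - 1 divisor."""
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    grads = np.array(
        [oracle(x, sample_size, child_seed(seed, j)).grad for j in range(n_rep)]
    )
    mean = grads.mean(axis=0)
    norm_sq = float(np.dot(mean, mean))
    if norm_sq == 0.0:
        return VarianceReport(mean, 0.0, 0.0, n_rep, degenerate=True)
    dev = grads - mean
    v_tot_sq = float(np.sum(dev * dev) / (n_rep - 1)) / norm_sq
    v_par_sq = float(np.sum((dev @ mean) ** 2) / (n_rep - 1)) / norm_sq**2
    return VarianceReport(mean, v_tot_sq, v_par_sq, n_rep)


def norm_test(report: VarianceReport, gamma_tot: float) -> bool:
    """Pass iff V_tot^2 <= gamma_tot^2 (boundary passes)."""
    return report.v_tot_sq <= gamma_tot**2


def inner_product_test(report: VarianceReport, gamma_par: float) -> bool:
    """Pass iff V_par^2 <= gamma_par^2 (boundary passes)."""
    return report.v_par_sq <= gamma_par**2


def step_size(cfg: StrategyConfig, report: VarianceReport | None = None) -> float:
    """Step size alpha_n for the configured strategy (see module docstring)."""
    L = cfg.lipschitz_L
    if cfg.strategy_id == 1:
        return 1.0 / ((1.0 + cfg.gamma_tot**2) * L)
    if report is None:
        raise ValueError("strategies 2-3 need a variance report")
    if cfg.strategy_id == 2:
        return 1.0 / ((1.0 + report.v_tot_sq) * L)
    return 1.0 / ((1.0 + report.v_tot) * L)


def growth_factor(cfg: StrategyConfig, report: VarianceReport) -> float:
    """Sample-size factor kappa: 1 on a passing (or degenerate) test, else the
    strategy's overshoot ratio, clamped to >= 1."""
    if report.degenerate:
        return 1.0
    if cfg.strategy_id == 1:
        if norm_test(report, cfg.gamma_tot):
            return 1.0
        return max(report.v_tot_sq / cfg.gamma_tot**2, 1.0)
    if inner_product_test(report, cfg.gamma_par):
        return 1.0
    if cfg.strategy_id == 2:
        return max(report.v_par_sq / cfg.gamma_par**2, 1.0)
    return max(report.v_par / cfg.gamma_par, 1.0)


@dataclass
class DescentTrace:
    """Per-iteration record of the inversion."""

    rows: list = field(default_factory=list)
    status: str = "ok"

    def append(self, **kw) -> None:
        self.rows.append(kw)

    def __len__(self) -> int:
        return len(self.rows)

    _COLUMNS = [
        "n",
        "F_Sn",
        "S_n",
        "alpha_n",
        "cum_photons",
        "V_tot",
        "V_par",
        "test_pass",
        "kappa",
        "F_mua",
    ]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self._COLUMNS)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _round_up(n: float, granularity: int) -> int:
    m = int(math.ceil(n))
    r = m % granularity
    return m if r == 0 else m + granularity - r


def run_inversion(
    oracle,
    x0,
    cfg: StrategyConfig,
    s1: int,
    n_ph_budget: int,
    seed: int,
    truth=None,
    project_nonnegative: bool = True,
    f_stop: float | None = None,
) -> tuple:
    """Run the adaptive-sample-size descent until the photon budget is spent.

    Sample sizes are rounded up to the oracle's granularity (e.g. 2 for QPAT,
    4 for UMOT).  The loop terminates when the next iteration would exceed the
    budget (the final iteration is skipped, never truncated); with
    ``count_metric_photons`` the metric evaluations deplete the budget too.
    The update always uses a fresh gradient sample, never the metric mean.
    ``f_stop`` enables discrepancy-principle early stopping on the sampled
    cost.  Returns ``(x_final, trace)`` with ``x_final`` of the same type as
    ``x0``.
    """
    granularity = int(getattr(oracle, "sample_granularity", 1))
    as_field = isinstance(x0, AbsorptionField)
    grid = x0.grid if as_field else None
    x = np.array(x0.mu_a if as_field else x0, dtype=float)
    truth_arr = None
    if truth is not None:
        truth_arr = np.asarray(truth.mu_a if isinstance(truth, AbsorptionField) else truth, float)

    trace = DescentTrace()
    S = _round_up(max(s1, getattr(oracle, "min_sample", 1)), granularity)
    budget = int(n_ph_budget)
    if S > budget:
        trace.status = "budget_too_small"
        return (x0, trace)

    alpha = step_size(cfg) if cfg.strategy_id == 1 else None
    used = 0
    n = 0
    S_next = S
    while used + S <= budget:
        n += 1
        v_tot = v_par = kappa = math.nan
        test_pass = None
        if cfg.test_every is not None and (n - 1) % cfg.test_every == 0:
            report = estimate_variance(oracle, x, S, cfg.n_rep, child_seed(seed, 1, n))
            alpha = step_size(cfg, report)
            kappa = growth_factor(cfg, report)
            if cfg.strategy_id == 1:
                test_pass = norm_test(report, cfg.gamma_tot)
            else:
                test_pass = inner_product_test(report, cfg.gamma_par)
            if report.degenerate:
                test_pass = True
            v_tot, v_par = report.v_tot, report.v_par
            S_next = S if test_pass else _round_up(kappa * S, granularity)
            if cfg.count_metric_photons:
                used += cfg.n_rep * S
                if used + S > budget:
                    trace.status = "budget_exhausted_by_metrics"
                    break

        gs: GradientSample = oracle(x, S, child_seed(seed, 2, n))
        x = x - alpha * gs.grad
        if project_nonnegative:
            np.clip(x, 0.0, None, out=x)
        used += S
        trace.append(
            n=n,
            F_Sn=gs.cost,
            S_n=S,
            alpha_n=alpha,
            cum_photons=used,
            V_tot=v_tot,
            V_par=v_par,
            test_pass=test_pass,
            kappa=kappa,
            F_mua=(
                0.5 * float(np.sum((truth_arr - x) ** 2)) * grid.dz
                if truth_arr is not None and grid is not None
                else math.nan
            ),
        )
        S = S_next
        if f_stop is not None and gs.cost <= f_stop:
            trace.status = "discrepancy_stop"
            break

    x_final = AbsorptionField(grid, x) if as_field else x
    return (x_final, trace)


class GaussianQuadraticOracle:
    """Closed-form test oracle: F(x) = 1/2 ||x - x*||^2 with isotropic
    Gaussian gradient noise of covariance (sigma^2 / n) I.

    The exact noise moments make controller behaviour predictable:
    E[V_tot^2] = d sigma^2 / (n ||gradF||^2), E[V_par^2] = sigma^2 /
    (n ||gradF||^2), and fixed-sample SGD stalls at a computable cost floor.
    "Photons" are abstract sample units (granularity 1).
    """

    sample_granularity = 1
    min_sample = 1

    def __init__(self, x_star: np.ndarray, sigma: float):
        self.x_star = np.asarray(x_star, dtype=float)
        self.sigma = float(sigma)

    def true_cost(self, x) -> float:
        d = np.asarray(x, float) - self.x_star
        return 0.5 * float(np.dot(d, d))

    def true_gradient(self, x) -> np.ndarray:
        return np.asarray(x, float) - self.x_star

    def noise_floor_cost(self, alpha: float, n: int) -> float:
        """Stationary E[F] of fixed-step, fixed-sample SGD on this oracle."""
        d = self.x_star.size
        msd = alpha**2 * d * self.sigma**2 / n / (1.0 - (1.0 - alpha) ** 2)
        return 0.5 * msd

    def __call__(self, x, n: int, seed: int) -> GradientSample:
        rng = np.random.default_rng(seed)
        scale = self.sigma / math.sqrt(n)
        grad = self.true_gradient(x) + scale * rng.standard_normal(self.x_star.size)
        cost = self.true_cost(x) + scale * rng.standard_normal()
        return GradientSample(grad=grad, cost=cost, sample_size=int(n), seed=seed)
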
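"""Stochastic first-order oracles for QPAT and UMOT absorption estimation.

Each oracle call runs a small number of Monte Carlo transport simulations and
returns an unbiased sample of the data-fit cost and of its gradient with
respect to the per-layer absorption coefficient.

QPAT: the data are the absorbed energy density h = mu_a * Phi.  One forward
run gives Phi and h; the adjoint run is driven by the isotropic internal
source Q_adj = mu_a * (h_obs - h) (signed, simulated as two non-negative
parts) and yields the adjoint fluence Phi*.  Under the isotropic-radiance
(fluence) approximation the gradient is

    dF/dmu_a = -Phi * (h_obs - h) + Phi* * Phi.

UMOT: the data are b = eta * Phi_q * Phi_m, the product of the fluence from
the physical source at z=0 and from a virtual source at z=d reciprocal to the
detector, weighted by the ultrasound focus eta.  Two adjoint runs driven by
Q1 = eta * Phi_q * (b_obs - b) and Q2 = eta * Phi_m * (b_obs - b) give

    dF/dmu_a = Phi*1 * Phi_m + Phi*2 * Phi_q.

Both costs are F = 1/2 * sum_i (obs_i - model_i)^2 * dz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import child_seed
from .slab import AbsorptionField, DepthGrid, LayeredSlab
from .transport import (
    FluenceProfile,
    SurfaceSource,
    TransportConfig,
    simulate,
    simulate_signed,
)

__all__ = [
    "GradientSample",
    "QpatProblem",
    "UmotProblem",
    "qpat_forward",
    "qpat_cost",
    "qpat_gradient_sample",
    "umot_forward",
    "umot_gradient_sample",
    "synthesize_observed",
    "QpatOracle",
    "UmotOracle",
]


@dataclass(frozen=True)
class GradientSample:
    """One stochastic oracle call: sampled gradient, sampled cost, photon cost."""

    grad: np.ndarray
    cost: float
    sample_size: int
    seed: int


def _as_mu_a(x, grid: DepthGrid) -> np.ndarray:
    arr = x.mu_a if isinstance(x, AbsorptionField) else np.asarray(x, dtype=float)
    if arr.shape != (grid.n_layers,):
        raise ValueError("mu_a does not match the problem grid")
    return arr


@dataclass(frozen=True)
class QpatProblem:
    """QPAT setup: slab, collimated source at z=0, observed absorbed energy h_obs."""

    slab: LayeredSlab
    h_obs: np.ndarray
    source: SurfaceSource = SurfaceSource("front")

    def __post_init__(self) -> None:
        h = np.asarray(self.h_obs, dtype=float)
        if h.shape != (self.slab.grid.n_layers,):
            raise ValueError("h_obs length must equal the number of layers")
        if np.any(h < 0):
            raise ValueError("h_obs must be >= 0")
        object.__setattr__(self, "h_obs", h)


@dataclass(frozen=True)
class UmotProblem:
    """UMOT transmission setup: source at z=0, virtual detector source at z=d.

    ``eta`` is the per-layer ultrasound focus weight; the default 1 everywhere
    models an ideal delta focus scanned over every grid depth.
    """

    slab: LayeredSlab
    b_obs: np.ndarray
    eta: np.ndarray | None = None
    source_q: SurfaceSource = SurfaceSource("front")
    detector_virtual_source_m: SurfaceSource = SurfaceSource("back")

    def __post_init__(self) -> None:
        n = self.slab.grid.n_layers
        b = np.asarray(self.b_obs, dtype=float)
        if b.shape != (n,):
            raise ValueError("b_obs length must equal the number of layers")
        eta = np.ones(n) if self.eta is None else np.asarray(self.eta, dtype=float)
        if eta.shape != (n,) or np.any(eta < 0):
            raise ValueError("eta must be a non-negative per-layer vector")
        object.__setattr__(self, "b_obs", b)
        object.__setattr__(self, "eta", eta)


def _cost(obs: np.ndarray, model: np.ndarray, grid: DepthGrid) -> float:
    if obs.shape != model.shape:
        raise ValueError("observed and modeled data lengths differ")
    r = obs - model
    return 0.5 * float(np.sum(r * r)) * grid.dz


def qpat_forward(
    problem: QpatProblem, mu_a, n_photons: int, seed: int
) -> tuple[np.ndarray, FluenceProfile]:
    """Forward QPAT model: h[i] = mu_a[i] * Phi[i] from one transport run."""
    grid = problem.slab.grid
    mu = _as_mu_a(mu_a, grid)
    prof = simulate(problem.slab, mu, problem.source, n_photons, TransportConfig(seed=seed))
    return mu * prof.phi, prof


def qpat_cost(h_obs: np.ndarray, h: np.ndarray, grid: DepthGrid) -> float:
    """Data-fit cost 1/2 * sum (h_obs - h)^2 * dz."""
    return _cost(np.asarray(h_obs, float), np.asarray(h, float), grid)


def qpat_gradient_sample(
    problem: QpatProblem, mu_a, n_photons: int, seed: int
) -> GradientSample:
    """Sampled QPAT cost and absorption gradient using ``n_photons`` packets.

    The budget is split floor(n/2) forward / remainder adjoint.  A perfect fit
    on this sample (zero residual) gives a zero adjoint source and the
    gradient collapses to zero.
    """
    if n_photons < 2:
        raise ValueError("QPAT oracle needs n_photons >= 2")
    grid = problem.slab.grid
    mu = _as_mu_a(mu_a, grid)
    n_fwd = n_photons // 2
    n_adj = n_photons - n_fwd

    h, prof = qpat_forward(problem, mu, n_fwd, child_seed(seed, 0))
    residual = problem.h_obs - h
    cost = _cost(problem.h_obs, h, grid)

    q_adj = mu * residual
    phi_star = simulate_signed(
        problem.slab,
        mu,
        np.clip(q_adj, 0.0, None),
        np.clip(-q_adj, 0.0, None),
        n_adj,
        TransportConfig(seed=child_seed(seed, 1)),
    )
    grad = -prof.phi * residual + phi_star.phi * prof.phi
    return GradientSample(grad=grad, cost=cost, sample_size=n_fwd + n_adj, seed=seed)


def umot_forward(
    problem: UmotProblem, mu_a, n_photons: int, seed: int
) -> tuple[np.ndarray, FluenceProfile, FluenceProfile]:
    """Forward UMOT model: b[i] = eta[i] * Phi_q[i] * Phi_m[i].

    Half the packets launch from the physical source at z=0, half from the
    detector-reciprocal virtual source at z=d.
    """
    if n_photons < 2:
        raise ValueError("UMOT forward needs n_photons >= 2")
    grid = problem.slab.grid
    mu = _as_mu_a(mu_a, grid)
    n_q = n_photons // 2
    n_m = n_photons - n_q
    prof_q = simulate(
        problem.slab, mu, problem.source_q, n_q, TransportConfig(seed=child_seed(seed, 0))
    )
    prof_m = simulate(
        problem.slab,
        mu,
        problem.detector_virtual_source_m,
        n_m,
        TransportConfig(seed=child_seed(seed, 1)),
    )
    b = problem.eta * prof_q.phi * prof_m.phi
    return b, prof_q, prof_m


def umot_gradient_sample(
    problem: UmotProblem, mu_a, n_photons: int, seed: int
) -> GradientSample:
    """Sampled UMOT cost and absorption gradient using ``n_photons`` packets.

    The budget is quartered across forward q, forward m and the two adjoint
    runs; the integer remainder goes to the first adjoint run.
    """
    if n_photons < 4:
        raise ValueError("UMOT oracle needs n_photons >= 4")
    grid = problem.slab.grid
    mu = _as_mu_a(mu_a, grid)
    n4 = n_photons // 4
    n_adj1 = n_photons - 3 * n4

    prof_q = simulate(
        problem.slab, mu, problem.source_q, n4, TransportConfig(seed=child_seed(seed, 0))
    )
    prof_m = simulate(
        problem.slab,
        mu,
        problem.detector_virtual_source_m,
        n4,
        TransportConfig(seed=child_seed(seed, 1)),
    )
    b = problem.eta * prof_q.phi * prof_m.phi
    residual = problem.b_obs - b
    cost = _cost(problem.b_obs, b, grid)

    q1 = problem.eta * prof_q.phi * residual
    q2 = problem.eta * prof_m.phi * residual
    phi_star1 = simulate_signed(
        problem.slab,
        mu,
        np.clip(q1, 0.0, None),
        np.clip(-q1, 0.0, None),
        n_adj1,
        TransportConfig(seed=child_seed(seed, 2)),
    )
    phi_star2 = simulate_signed(
        problem.slab,
        mu,
        np.clip(q2, 0.0, None),
        np.clip(-q2, 0.0, None),
        n4,
        TransportConfig(seed=child_seed(seed, 3)),
    )
    grad = phi_star1.phi * prof_m.phi + phi_star2.phi * prof_q.phi
    return GradientSample(grad=grad, cost=cost, sample_size=3 * n4 + n_adj1, seed=seed)


def synthesize_observed(
    modality: str,
    slab: LayeredSlab,
    mu_a_true: AbsorptionField | np.ndarray,
    n_photons_obs: int,
    seed: int,
    eta: np.ndarray | None = None,
) -> np.ndarray:
    """Generate "observed" data by a high-photon-count forward run at the truth.

    Emulates acquiring noise-free measurements: with a large photon count the
    sampled forward data approach the deterministic RTE solution.
    """
    if n_photons_obs < 1:
        raise ValueError("n_photons_obs must be >= 1")
    mu = _as_mu_a(mu_a_true, slab.grid)
    if modality == "qpat":
        problem = QpatProblem(slab, np.zeros(slab.grid.n_layers))
        h, _ = qpat_forward(problem, mu, n_photons_obs, seed)
        return h
    if modality == "umot":
        problem = UmotProblem(slab, np.zeros(slab.grid.n_layers), eta=eta)
        b, _, _ = umot_forward(problem, mu, n_photons_obs, seed)
        return b
    raise ValueError(f"unknown modality {modality!r} (expected 'qpat' or 'umot')")


class QpatOracle:
    """Callable adapter exposing the QPAT oracle to the descent loop."""

    sample_granularity = 2
    min_sample = 2

    def __init__(self, problem: QpatProblem):
        self.problem = problem

    @property
    def dz(self) -> float:
        return self.problem.slab.grid.dz

    def __call__(self, x, n_photons: int, seed: int) -> GradientSample:
        return qpat_gradient_sample(self.problem, x, n_photons, seed)

    def cost(self, x, n_photons: int, seed: int) -> float:
        """Forward-only sampled cost (used for finite-difference validation)."""
        h, _ = qpat_forward(self.problem, x, n_photons, seed)
        return _cost(self.problem.h_obs, h, self.problem.slab.grid)


class UmotOracle:
    """Callable adapter exposing the UMOT oracle to the descent loop."""

    sample_granularity = 4
    min_sample = 4

    def __init__(self, problem: UmotProblem):
        self.problem = problem

    @property
    def dz(self) -> float:
        return self.problem.slab.grid.dz

    def __call__(self, x, n_photons: int, seed: int) -> GradientSample:
        return umot_gradient_sample(self.problem, x, n_photons, seed)

    def cost(self, x, n_photons: int, seed: int) -> float:
        b, _, _ = umot_forward(self.problem, x, n_photons, seed)
        return _cost(self.problem.b_obs, b, self.problem.slab.grid)
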
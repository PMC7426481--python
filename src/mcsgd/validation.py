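"""Gradient correctness checks against finite differences.

Because photon trajectories depend only on mu_s and g (absorption is handled
by continuous weight attenuation), re-running the forward model with the same
seed but perturbed mu_a re-uses identical trajectories.  Central differences
of the sampled cost under such common random numbers therefore differentiate
the *sampled* cost almost exactly, giving a low-variance independent reference
for the adjoint-based oracle gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import child_seed

__all__ = ["GradientValidationReport", "validate_gradient"]


@dataclass(frozen=True)
class GradientValidationReport:
    grad_oracle: np.ndarray
    grad_fd: np.ndarray
    rel_l2: float
    per_layer_abs_diff: np.ndarray
    n_photons: int
    delta: float

    def summary(self) -> str:
        lines = [
            f"photons per evaluation: {self.n_photons}",
            f"finite-difference step: {self.delta} 1/cm",
            f"relative L2 discrepancy: {self.rel_l2:.4%}",
            "layer  oracle_grad    fd_grad        abs_diff",
        ]
        for i, (a, b, d) in enumerate(
            zip(self.grad_oracle, self.grad_fd, self.per_layer_abs_diff)
        ):
            lines.append(f"{i:5d}  {a:+.6e}  {b:+.6e}  {d:.3e}")
        return "\n".join(lines)


def validate_gradient(
    oracle,
    mu_a: np.ndarray,
    n_photons: int,
    seed: int,
    delta: float = 0.01,
    n_avg: int = 4,
) -> GradientValidationReport:
    """Compare the oracle gradient with central finite differences of the cost.

    ``oracle`` must expose ``__call__(x, n, seed) -> GradientSample`` and
    ``cost(x, n, seed)``.  The oracle gradient is averaged over ``n_avg``
    independent calls of ``n_photons`` packets each; the finite differences
    use one common seed for every +/- evaluation.

    The oracle gradient is a per-depth density, whereas a partial derivative
    with respect to one layer's value integrates that density over the layer;
    the finite differences are therefore divided by the layer thickness
    (``oracle.dz``) to compare in density units.
    """
    x = np.asarray(mu_a, dtype=float)
    d = x.size
    dz = float(getattr(oracle, "dz", 1.0))

    grads = [
        np.asarray(oracle(x, n_photons, child_seed(seed, 100 + j)).grad)
        for j in range(n_avg)
    ]
    grad_oracle = np.mean(grads, axis=0)

    fd_seed = child_seed(seed, 7)
    grad_fd = np.empty(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = delta
        lo = np.clip(x - e, 0.0, None)
        hi = x + e
        c_hi = oracle.cost(hi, n_photons, fd_seed)
        c_lo = oracle.cost(lo, n_photons, fd_seed)
        grad_fd[i] = (c_hi - c_lo) / (hi[i] - lo[i]) / dz

    denom = float(np.linalg.norm(grad_fd))
    rel = float(np.linalg.norm(grad_oracle - grad_fd)) / denom if denom > 0 else 0.0
    return GradientValidationReport(
        grad_oracle=grad_oracle,
        grad_fd=grad_fd,
        rel_l2=rel,
        per_layer_abs_diff=np.abs(grad_oracle - grad_fd),
        n_photons=int(n_photons),
        delta=float(delta),
    )
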
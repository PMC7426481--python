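"""Photon-packet Monte Carlo transport in a layered slab.

Forward and adjoint problems share one engine; they differ only in the source:
collimated surface sources at either face, or an internal isotropic source
with a per-layer (possibly signed, via :func:`simulate_signed`) emission
density.  The returned fluence is the track-length estimate of the
angle-integrated radiance, averaged over each layer and normalized per unit
source power, then scaled by the actual source power for internal sources.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._rng import child_seed
from .slab import AbsorptionField, LayeredSlab

__all__ = [
    "SurfaceSource",
    "InternalIsotropicSource",
    "TransportConfig",
    "FluenceProfile",
    "sample_step",
    "sample_hg",
    "simulate",
    "simulate_signed",
]


def sample_step(mu_t: float, u: float) -> float:
    """Exponential free path s = -ln(u)/mu_t for attenuation coefficient mu_t.

    mu_t = 0 gives an effectively infinite step (handled downstream by
    boundary crossing).
    """
    if mu_t < 0:
        raise ValueError("mu_t must be >= 0")
    if not (0.0 < u < 1.0):
        raise ValueError("u must lie in (0, 1)")
    if mu_t == 0.0:
        return math.inf
    return -math.log(u) / mu_t


def sample_hg(g: float, u: float) -> float:
    """Henyey-Greenstein deflection cosine via inverse-CDF sampling.

    g = 0 reduces to the isotropic case cos(theta) = 2u - 1.  The azimuth is
    sampled uniformly by the caller.
    """
    if not (-1.0 < g < 1.0):
        raise ValueError("anisotropy g must satisfy -1 < g < 1")
    if not (0.0 <= u <= 1.0):
        raise ValueError("u must lie in [0, 1]")
    return float(_kernels._hg_cos(g, u))


@dataclass(frozen=True)
class SurfaceSource:
    """Collimated, normally incident source at the front (z=0) or back (z=d) face."""

    face: str = "front"

    def __post_init__(self) -> None:
        if self.face not in ("front", "back"):
            raise ValueError(f"face must be 'front' or 'back', got {self.face!r}")

    @property
    def total_power(self) -> float:
        return 1.0


@dataclass(frozen=True)
class InternalIsotropicSource:
    """Isotropic volumetric source with non-negative per-layer density (per cm).

    Emission position: layer sampled proportional to density[i]*dz, uniform
    within the layer; direction uniform on the sphere.
    """

    density: np.ndarray
    dz: float

    def __post_init__(self) -> None:
        dens = np.asarray(self.density, dtype=float)
        if np.any(dens < 0):
            raise ValueError("internal source density must be >= 0")
        object.__setattr__(self, "density", dens)

    @property
    def total_power(self) -> float:
        return float(np.sum(self.density) * self.dz)


@dataclass(frozen=True)
class TransportConfig:
    """Roulette parameters and RNG seed.

    Defaults follow the MCML convention: packets dropping below weight 1e-4
    survive roulette with probability 0.1 (weight boosted 10x) or terminate.
    """

    weight_threshold: float = 1e-4
    survival_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.survival_prob <= 1.0):
            raise ValueError("survival_prob must lie in (0, 1]")
        if not (0.0 <= self.weight_threshold < 1.0):
            raise ValueError("weight_threshold must lie in [0, 1)")


@dataclass
class FluenceProfile:
    """Grid-resolved fluence estimate with Monte Carlo uncertainty and tallies.

    ``phi`` is normalized per unit source power and scaled by the source's
    total power; ``reflected``/``transmitted``/``absorbed`` are weight
    fractions per launched packet (their expectation sums to 1 under roulette).
    """

    phi: np.ndarray
    phi_se: np.ndarray
    n_photons: int
    reflected: float
    transmitted: float
    absorbed: float
    reflected_se: float = 0.0
    transmitted_se: float = 0.0
    absorbed_se: float = 0.0
    seed: int = 0
    status: str = "ok"


def _run_kernel(slab, mu_a, src_kind, src_cdf, power, n_photons, cfg, seed):
    n_layers = slab.grid.n_layers
    phi_sum = np.zeros(n_layers)
    phi_sqsum = np.zeros(n_layers)
    scalars = np.zeros(6)
    _kernels.propagate(
        np.ascontiguousarray(mu_a, dtype=np.float64),
        np.ascontiguousarray(slab.mu_s, dtype=np.float64),
        np.ascontiguousarray(slab.g, dtype=np.float64),
        slab.grid.dz,
        src_kind,
        src_cdf,
        n_photons,
        cfg.weight_threshold,
        cfg.survival_prob,
        np.uint64(seed & 0xFFFFFFFFFFFFFFFF),
        phi_sum,
        phi_sqsum,
        scalars,
    )
    n = float(n_photons)
    phi = phi_sum / n
    var = np.maximum(phi_sqsum / n - phi * phi, 0.0) / n
    phi_se = np.sqrt(var)
    r, t, a = scalars[0] / n, scalars[1] / n, scalars[2] / n
    ses = [
        math.sqrt(max(scalars[3 + k] / n - m * m, 0.0) / n)
        for k, m in enumerate((r, t, a))
    ]
    return FluenceProfile(
        phi=phi * power,
        phi_se=phi_se * power,
        n_photons=n_photons,
        reflected=r,
        transmitted=t,
        absorbed=a,
        reflected_se=ses[0],
        transmitted_se=ses[1],
        absorbed_se=ses[2],
        seed=seed,
    )


def simulate(
    slab: LayeredSlab,
    mu_a: AbsorptionField | np.ndarray,
    source: SurfaceSource | InternalIsotropicSource,
    n_photons: int,
    cfg: TransportConfig = TransportConfig(),
) -> FluenceProfile:
    """Estimate the layer-averaged fluence produced by ``source``.

    The estimator is unbiased: E[phi[i]] converges to the RTE fluence averaged
    over layer i as n_photons grows.  Identical (inputs, seed) give
    bit-identical output.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    mu_a_arr = mu_a.mu_a if isinstance(mu_a, AbsorptionField) else np.asarray(mu_a, float)
    if mu_a_arr.shape != (slab.grid.n_layers,):
        raise ValueError("mu_a does not match the slab grid")
    if np.any(mu_a_arr < 0):
        raise ValueError("mu_a must be >= 0")

    empty = np.zeros(0)
    if isinstance(source, SurfaceSource):
        kind = _kernels.SRC_FRONT if source.face == "front" else _kernels.SRC_BACK
        return _run_kernel(slab, mu_a_arr, kind, empty, 1.0, int(n_photons), cfg, cfg.seed)

    power = source.total_power
    if power <= 0.0:
        warnings.warn("zero-power internal source: returning all-zero fluence")
        nl = slab.grid.n_layers
        return FluenceProfile(
            phi=np.zeros(nl),
            phi_se=np.zeros(nl),
            n_photons=0,
            reflected=0.0,
            transmitted=0.0,
            absorbed=0.0,
            seed=cfg.seed,
            status="zero_power",
        )
    pmf = source.density * slab.grid.dz
    cdf = np.cumsum(pmf / pmf.sum())
    cdf[-1] = 1.0
    return _run_kernel(slab, mu_a_arr, _kernels.SRC_INTERNAL, cdf, power, int(n_photons), cfg, cfg.seed)


def simulate_signed(
    slab: LayeredSlab,
    mu_a: AbsorptionField | np.ndarray,
    density_pos: np.ndarray,
    density_neg: np.ndarray,
    n_photons: int,
    cfg: TransportConfig = TransportConfig(),
) -> FluenceProfile:
    """Fluence of a signed internal source, via two non-negative sub-runs.

    The photon budget is split between the positive and negative parts
    proportionally to their integrated powers (each nonzero part gets at least
    one packet) and the power-scaled results are subtracted; the profile may
    be negative.  Both densities zero returns a flagged all-zero profile.
    """
    dz = slab.grid.dz
    pos = InternalIsotropicSource(density_pos, dz)
    neg = InternalIsotropicSource(density_neg, dz)
    p_pos, p_neg = pos.total_power, neg.total_power
    nl = slab.grid.n_layers

    if p_pos <= 0.0 and p_neg <= 0.0:
        return FluenceProfile(
            phi=np.zeros(nl),
            phi_se=np.zeros(nl),
            n_photons=0,
            reflected=0.0,
            transmitted=0.0,
            absorbed=0.0,
            seed=cfg.seed,
            status="zero_power",
        )
    if p_neg <= 0.0:
        return simulate(slab, mu_a, pos, n_photons, cfg)
    if p_pos <= 0.0:
        prof = simulate(slab, mu_a, neg, n_photons, cfg)
        prof.phi = -prof.phi
        return prof

    if n_photons < 2:
        raise ValueError("n_photons must be >= 2 when both signed parts are nonzero")
    n_pos = int(round(n_photons * p_pos / (p_pos + p_neg)))
    n_pos = min(max(n_pos, 1), n_photons - 1)
    n_neg = n_photons - n_pos
    cfg_pos = TransportConfig(cfg.weight_threshold, cfg.survival_prob, child_seed(cfg.seed, 1))
    cfg_neg = TransportConfig(cfg.weight_threshold, cfg.survival_prob, child_seed(cfg.seed, 2))
    prof_pos = simulate(slab, mu_a, pos, n_pos, cfg_pos)
    prof_neg = simulate(slab, mu_a, neg, n_neg, cfg_neg)
    return FluenceProfile(
        phi=prof_pos.phi - prof_neg.phi,
        phi_se=np.hypot(prof_pos.phi_se, prof_neg.phi_se),
        n_photons=n_photons,
        reflected=prof_pos.reflected + prof_neg.reflected,
        transmitted=prof_pos.transmitted + prof_neg.transmitted,
        absorbed=prof_pos.absorbed + prof_neg.absorbed,
        seed=cfg.seed,
    )
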
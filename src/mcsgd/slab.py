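"""Layered-slab geometry, optical properties, phantoms and the truth error metric.

The medium is a 1D stack of ``n_layers`` uniform layers of thickness ``dz``
(cm), infinite and homogeneous in x and y.  Scattering coefficient, scattering
anisotropy and refractive index are known per layer; the per-layer absorption
coefficient is the unknown being estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DepthGrid",
    "LayeredSlab",
    "AbsorptionField",
    "PhantomSpec",
    "make_grid",
    "realize_phantom",
    "absorption_error",
]


@dataclass(frozen=True)
class DepthGrid:
    """Uniform depth grid: layer i occupies [i*dz, (i+1)*dz), 0-based."""

    n_layers: int
    dz: float

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError(f"n_layers must be >= 1, got {self.n_layers}")
        if not self.dz > 0:
            raise ValueError(f"dz must be > 0, got {self.dz}")

    @property
    def thickness(self) -> float:
        """Total slab thickness d = n_layers * dz in cm."""
        return self.n_layers * self.dz

    @property
    def centers(self) -> np.ndarray:
        """Layer-center depths z_i = (i + 1/2) * dz in cm."""
        return (np.arange(self.n_layers) + 0.5) * self.dz

    def layer_of(self, z: float) -> int:
        """Index of the layer containing depth z, for 0 <= z < thickness."""
        if not (0.0 <= z < self.thickness):
            raise ValueError(f"z={z} outside [0, {self.thickness})")
        return min(int(z / self.dz), self.n_layers - 1)


def make_grid(n_layers: int, dz: float) -> DepthGrid:
    """Create a uniform depth grid of ``n_layers`` layers of thickness ``dz`` cm."""
    return DepthGrid(int(n_layers), float(dz))


def _per_layer(value, grid: DepthGrid, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(grid.n_layers, float(arr))
    if arr.shape != (grid.n_layers,):
        raise ValueError(f"{name} must be scalar or length {grid.n_layers}, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class LayeredSlab:
    """Known optical environment: grid plus per-layer mu_s (cm^-1), g, n_rel.

    Refractive indices default to matched (n_rel = 1 everywhere, ambient 1):
    no specular or Fresnel reflection is modelled.
    """

    grid: DepthGrid
    mu_s: np.ndarray
    g: np.ndarray
    n_rel: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu_s", _per_layer(self.mu_s, self.grid, "mu_s"))
        object.__setattr__(self, "g", _per_layer(self.g, self.grid, "g"))
        object.__setattr__(self, "n_rel", _per_layer(self.n_rel, self.grid, "n_rel"))
        if np.any(self.mu_s < 0):
            raise ValueError("mu_s must be >= 0 in every layer")
        if np.any(np.abs(self.g) >= 1):
            raise ValueError("anisotropy g must satisfy -1 < g < 1")
        if np.any(self.n_rel < 1):
            raise ValueError("n_rel must be >= 1")

    @classmethod
    def uniform(cls, grid: DepthGrid, mu_s: float, g: float, n_rel: float = 1.0) -> "LayeredSlab":
        return cls(grid, mu_s, g, n_rel)


@dataclass(frozen=True)
class AbsorptionField:
    """Per-layer absorption coefficient mu_a (cm^-1); the iterate of the inversion."""

    grid: DepthGrid
    mu_a: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu_a", _per_layer(self.mu_a, self.grid, "mu_a"))
        if np.any(self.mu_a < 0):
            raise ValueError("mu_a must be >= 0 in every layer")

    @classmethod
    def uniform(cls, grid: DepthGrid, mu_a: float) -> "AbsorptionField":
        return cls(grid, mu_a)


@dataclass(frozen=True)
class PhantomSpec:
    """Piecewise-constant ground-truth absorption: a background level plus
    localized rectangular features (center_cm, width_cm, amplitude_per_cm)."""

    background_mu_a: float
    features: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_mu_a < 0:
            raise ValueError("background_mu_a must be >= 0")
        object.__setattr__(self, "features", tuple(tuple(map(float, f)) for f in self.features))


def realize_phantom(spec: PhantomSpec, grid: DepthGrid) -> AbsorptionField:
    """Materialize a phantom spec on a grid.

    Each feature adds its amplitude to every layer whose center lies within
    width/2 of the feature center.  Negative excursions clamp at 0 (mu_a is
    physical).  Deterministic given (spec, grid).
    """
    d = grid.thickness
    mu_a = np.full(grid.n_layers, spec.background_mu_a)
    centers = grid.centers
    for center, width, amplitude in spec.features:
        if not (0.0 <= center < d):
            raise ValueError(f"feature center {center} outside [0, {d})")
        mask = np.abs(centers - center) < width / 2.0
        mu_a[mask] += amplitude
    return AbsorptionField(grid, np.clip(mu_a, 0.0, None))


def absorption_error(mu_a: AbsorptionField, mu_a_true: AbsorptionField) -> float:
    """Truth-referenced error F_mua = 1/2 * sum_i (mu_a_true - mu_a)^2 * dz.

    Discrete L2 with dz quadrature weight, so the value approximates the
    depth integral of the squared residual and is comparable across grid
    resolutions.  Zero iff the two fields are identical.
    """
    if mu_a.grid != mu_a_true.grid:
        raise ValueError("absorption fields live on different grids")
    r = mu_a_true.mu_a - mu_a.mu_a
    return 0.5 * float(np.sum(r * r)) * mu_a.grid.dz
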
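"""Run configuration: YAML schema, validation and assembly of run objects.

One master seed deterministically derives every sub-seed (observed data,
per-iteration oracle calls, metric evaluations), so a config file fully
reproduces a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from ._rng import child_seed
from .oracles import QpatOracle, QpatProblem, UmotOracle, UmotProblem, synthesize_observed
from .sgd import StrategyConfig
from .slab import AbsorptionField, LayeredSlab, PhantomSpec, make_grid, realize_phantom

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration; message names the offending key."""


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"{context}.{key}: required key is missing")
    return mapping[key]


@dataclass(frozen=True)
class RunConfig:
    """Validated end-to-end experiment description."""

    modality: str
    n_layers: int
    dz: float
    mu_s: object
    g: object
    n_rel: object
    phantom: PhantomSpec
    x0_mu_a: float
    strategy: StrategyConfig
    s1: int
    n_ph_budget: int
    n_photons_obs: int
    seed: int
    out_dir: str = "."

    def grid(self):
        return make_grid(self.n_layers, self.dz)

    def slab(self) -> LayeredSlab:
        return LayeredSlab(self.grid(), self.mu_s, self.g, self.n_rel)

    def truth(self) -> AbsorptionField:
        return realize_phantom(self.phantom, self.grid())

    def x0(self) -> AbsorptionField:
        return AbsorptionField.uniform(self.grid(), self.x0_mu_a)

    def observed_seed(self) -> int:
        return child_seed(self.seed, 101)

    def inversion_seed(self) -> int:
        return child_seed(self.seed, 102)

    def synthesize(self) -> np.ndarray:
        return synthesize_observed(
            self.modality, self.slab(), self.truth(), self.n_photons_obs, self.observed_seed()
        )

    def build_oracle(self, observed: np.ndarray):
        slab = self.slab()
        if self.modality == "qpat":
            return QpatOracle(QpatProblem(slab, observed))
        return UmotOracle(UmotProblem(slab, observed))

    def to_dict(self) -> dict:
        s = self.strategy
        return {
            "modality": self.modality,
            "grid": {"n_layers": self.n_layers, "dz_cm": self.dz},
            "slab": {
                "mu_s": np.asarray(self.mu_s).tolist(),
                "g": np.asarray(self.g).tolist(),
                "n_rel": np.asarray(self.n_rel).tolist(),
            },
            "phantom": {
                "background_mu_a": self.phantom.background_mu_a,
                "features": [list(f) for f in self.phantom.features],
                "seed": self.phantom.seed,
            },
            "x0_mu_a": self.x0_mu_a,
            "strategy": {
                "id": s.strategy_id,
                "gamma_tot": s.gamma_tot,
                "gamma_par": s.gamma_par,
                "lipschitz_L": s.lipschitz_L,
                "test_every": s.test_every,
                "n_rep": s.n_rep,
                "count_metric_photons": s.count_metric_photons,
            },
            "s1": self.s1,
            "n_ph_budget": self.n_ph_budget,
            "n_photons_obs": self.n_photons_obs,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }


def _parse(raw: dict) -> RunConfig:
    modality = _require(raw, "modality", "config")
    if modality not in ("qpat", "umot"):
        raise ConfigError(f"modality: must be 'qpat' or 'umot', got {modality!r}")

    grid = _require(raw, "grid", "config")
    n_layers = int(_require(grid, "n_layers", "grid"))
    dz = float(_require(grid, "dz_cm", "grid"))
    if n_layers < 1 or dz <= 0:
        raise ConfigError("grid: n_layers must be >= 1 and dz_cm > 0")

    slab = _require(raw, "slab", "config")
    mu_s = _require(slab, "mu_s", "slab")
    g = _require(slab, "g", "slab")
    n_rel = slab.get("n_rel", 1.0)

    ph = _require(raw, "phantom", "config")
    phantom = PhantomSpec(
        background_mu_a=float(_require(ph, "background_mu_a", "phantom")),
        features=tuple(tuple(f) for f in ph.get("features", [])),
        seed=int(ph.get("seed", 0)),
    )

    st = _require(raw, "strategy", "config")
    sid = int(_require(st, "id", "strategy"))
    try:
        strategy = StrategyConfig(
            strategy_id=sid,
            lipschitz_L=float(_require(st, "lipschitz_L", "strategy")),
            gamma_tot=(float(st["gamma_tot"]) if st.get("gamma_tot") is not None else None),
            gamma_par=(float(st["gamma_par"]) if st.get("gamma_par") is not None else None),
            test_every=(int(st["test_every"]) if st.get("test_every") is not None else None),
            n_rep=int(st.get("n_rep", 100)),
            count_metric_photons=bool(st.get("count_metric_photons", False)),
        )
    except ValueError as exc:
        raise ConfigError(f"strategy: {exc}") from exc

    s1 = int(_require(raw, "s1", "config"))
    n_ph_budget = int(_require(raw, "n_ph_budget", "config"))
    n_photons_obs = int(_require(raw, "n_photons_obs", "config"))
    if s1 < 1 or n_ph_budget < s1:
        raise ConfigError("s1 must be >= 1 and n_ph_budget >= s1")

    cfg = RunConfig(
        modality=modality,
        n_layers=n_layers,
        dz=dz,
        mu_s=mu_s,
        g=g,
        n_rel=n_rel,
        phantom=phantom,
        x0_mu_a=float(_require(raw, "x0_mu_a", "config")),
        strategy=strategy,
        s1=s1,
        n_ph_budget=n_ph_budget,
        n_photons_obs=n_photons_obs,
        seed=int(_require(raw, "seed", "config")),
        out_dir=str(raw.get("out_dir", ".")),
    )
    # materialize once so geometry/property errors surface before any simulation
    cfg.slab()
    cfg.truth()
    return cfg


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a run configuration from YAML (path) or a dict."""
    if isinstance(path_or_dict, dict):
        return _parse(path_or_dict)
    raw = yaml.safe_load(Path(path_or_dict).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a YAML mapping")
    return _parse(raw)
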
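"""Simulation configuration: every model parameter with units and defaults.

Unit system: length in mm, time in days, stress in Pa.  Derived units are
carried consistently (force = Pa*mm^2, mass = Pa*mm*day^2, energy = Pa*mm^3);
only ratios of energies are ever reported, so the absolute mass scale is a
numerical device (mass scaling), not a physical density.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration values."""


@dataclass
class SimulationConfig:
    """Parameters of the coupled folding / pathfinding model.

    Geometry
    --------
    w, h, t_c : mm
        Width of the slice, white-matter depth, cortical-plate thickness.
    elem_size : mm
        Structured quad element edge length.

    Growth
    ------
    G_ctx : 1/day
        Cortical (tangential, area) growth rate; the dimensionless simulation
        time is T = G_ctx * t and a standard run spans T in [0, 1].
    growth_ratio : dimensionless
        Cortex-to-substrate growth-rate ratio G_ctx / G_sub (default 6).
    exponential_kinetics : bool
        If True the growth multipliers follow theta_dot = G * theta instead
        of the default linear law theta_dot = G.

    Materials
    ---------
    mu_s : Pa
        Shear modulus of the white-matter ECM (absolute scale; only ratios
        are reported by the paper-facing metrics).
    mu_c_over_mu_s, mu_f_over_mu_s : dimensionless
        Cortex / fiber shear-modulus ratios to the ECM.
    k_over_mu : dimensionless
        Bulk-to-shear modulus ratio per material (near-incompressibility).

    Axon agents
    -----------
    G_axn : mm/day           intrinsic tip-growth rate
    a : mm Pa^-1 day^-1      stress-induced (towed) elongation rate
    sigma_0 : Pa             target stress for towed growth (0: any tension grows)
    t_star : agent steps     reorientation relaxation parameter
    noise_std : rad          std of the Gaussian angle noise per agent step
    n_fibers : count         bundles seeded at t = 0
    seed_band : mm           y-extent [0, seed_band] of the seeding region
    reorientation_enabled, clamp_negative_growth : switches

    Solver
    ------
    agent_steps : count
        Agent updates per run (the cortex multiplier grows by
        G_ctx * t_end / agent_steps between updates; 500 by default so each
        step advances the multiplier by 0.002).
    substeps : count
        Explicit dynamic increments per agent step.  Mass scaling is derived
        from this: the nodal density is chosen so that the resulting time
        increment is stable for the stiffest material present.
    damping : 1/day
        Mass-proportional damping coefficient.
    dt_safety : dimensionless
        Fraction of the estimated stable increment actually used.
    """

    # geometry (mm)
    w: float = 60.0
    h: float = 30.0
    t_c: float = 1.5
    elem_size: float = 0.5

    # growth
    G_ctx: float = 0.02
    growth_ratio: float = 6.0
    exponential_kinetics: bool = False

    # materials
    mu_s: float = 100.0
    mu_c_over_mu_s: float = 2.0
    mu_f_over_mu_s: float = 2.0
    k_over_mu: float = 50.0

    # axon agents
    G_axn: float = 0.8
    a: float = 0.015
    sigma_0: float = 0.0
    t_star: float = 300.0
    noise_std: float = 0.025
    n_fibers: int = 100
    seed_band: float = 10.0
    reorientation_enabled: bool = True
    clamp_negative_growth: bool = True

    # solver
    agent_steps: int = 500
    substeps: int = 160
    damping: float = 20.0
    dt_safety: float = 0.9
    hourglass_coef: float = 0.2
    contact_enabled: bool = False
    node_perturbation: float = 0.0
    perturbation_modes: int = 6

    # ensembles / reproducibility
    n_replicates: int = 10
    seed: int = 0

    # output
    output_dir: str | None = None
    write_vtk: bool = False
    vtk_interval: int = 50

    def __post_init__(self) -> None:
        if min(self.w, self.h, self.t_c, self.elem_size) <= 0:
            raise ConfigError("geometry dimensions must be positive")
        if self.t_c < self.elem_size - 1e-12:
            raise ConfigError("cortex thickness must be at least one element")
        for name in ("G_ctx", "growth_ratio", "mu_s", "mu_c_over_mu_s",
                     "mu_f_over_mu_s", "k_over_mu", "G_axn", "a", "t_star",
                     "noise_std", "damping", "hourglass_coef"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.agent_steps < 1 or self.substeps < 1:
            raise ConfigError("agent_steps and substeps must be >= 1")

    # ------------------------------------------------------------------ #
    # derived quantities
    # ------------------------------------------------------------------ #
    @property
    def G_sub(self) -> float:
        """Substrate (ECM) isotropic growth rate, 1/day."""
        return self.G_ctx / self.growth_ratio if self.growth_ratio > 0 else 0.0

    @property
    def t_end(self) -> float:
        """Physical duration of a standard run (T = 1), days."""
        return 1.0 / self.G_ctx if self.G_ctx > 0 else 50.0

    @property
    def mu_c(self) -> float:
        return self.mu_c_over_mu_s * self.mu_s

    @property
    def mu_f(self) -> float:
        return self.mu_f_over_mu_s * self.mu_s

    @property
    def agent_dt(self) -> float:
        """Physical time per agent step, days."""
        return self.t_end / self.agent_steps

    # ------------------------------------------------------------------ #
    # (de)serialization
    # ------------------------------------------------------------------ #
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(json.loads(text))

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
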
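"""Run configuration: a strict, self-describing schema for coupled runs.

All physical quantities are SI (metres, seconds, Pa) except concentrations,
which follow the field convention of mg/ml; anti-FA concentrations quoted in
ng/ml must be converted by 1e-6.  Unknown keys are rejected so that a config
file always means what it says.  ``RunConfig.resolved()`` returns the full
key tree actually used by a run, suitable for auditing and exact replay.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "PhysicalBlock", "NumericsBlock", "DomainBlock", "ClotBlock",
    "StopBlock", "OutputBlock", "RunConfig", "load_config", "dump_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PhysicalBlock(_Strict):
    nu: float = Field(1e-6, gt=0, description="kinematic viscosity (m^2/s)")
    rho0: float = Field(1000.0, gt=0, description="fluid density (kg/m^3)")
    grad_P: float = Field(400.0, gt=0, description="pressure gradient across the clot (Pa/m)")
    D_antifa: float = Field(1e-13, ge=0, description="anti-FA diffusion coefficient (m^2/s)")
    Fstar: float = Field(0.2, gt=0, description="lysis threshold (mg/ml)")
    Fbar0: float = Field(2e-5, gt=0, description="inlet anti-FA concentration (mg/ml)")
    k1: float = Field(1400.0, gt=0, description="lysis reaction rate ((s mg/ml)^-1)")
    Rf0: float = Field(1.4e-7, gt=0, description="initial fiber radius (m)")
    k0: Optional[float] = Field(1e-13, gt=0, description="initial clot permeability (m^2)")
    ns0: Optional[float] = Field(None, gt=0, lt=0.5, description="initial solid fraction (overrides k0)")

    @model_validator(mode="after")
    def _one_of_k0_ns0(self):
        if self.k0 is None and self.ns0 is None:
            raise ValueError("give one of k0 or ns0")
        return self


class NumericsBlock(_Strict):
    dx: float = Field(2e-5, gt=0, description="lattice spacing (m)")
    dt_lb: float = Field(2e-4, gt=0, description="LB time step (s)")
    lattice: Literal["D2Q9"] = "D2Q9"
    steady_tol: float = Field(1e-4, gt=0, description="initial steady-solve tolerance")
    steady_check_every: int = Field(50, ge=1)
    steady_tol_resolve: float = Field(
        3e-4, gt=0, description="tolerance for warm in-run flow re-solves")
    steady_check_every_resolve: int = Field(250, ge=1)
    max_lb_steps: int = Field(300_000, ge=1)
    max_lb_steps_resolve: int = Field(
        5000, ge=1,
        description="step budget per in-run re-solve; stiff pressure "
                    "re-equilibration beyond this is carried to later solves")
    resistance_retrigger: float = Field(
        0.075, gt=0,
        description="re-solve the flow when the clot resistance proxy "
                    "sum(gamma/(1-gamma)) changed by this relative amount")
    max_steps_between_solves: int = Field(200, ge=1)
    dt_reaction_max: float = Field(5.0, gt=0, description="reaction step ceiling (s)")
    cfl_safety: float = Field(0.6, gt=0, le=1)
    max_reaction_steps: int = Field(2_000_000, ge=1)


class DomainBlock(_Strict):
    ny: int = Field(30, ge=5, description="transverse nodes incl. wall rows")
    nx: int = Field(50, ge=5, description="axial nodes")
    inlet_lumen: int = Field(5, ge=1, description="open nodes upstream of the clot")
    clot_len: int = Field(25, ge=1, description="clot length in nodes")

    @model_validator(mode="after")
    def _fits(self):
        if self.inlet_lumen + self.clot_len >= self.nx:
            raise ValueError("inlet_lumen + clot_len must leave outlet lumen nodes")
        return self


class ClotBlock(_Strict):
    kind: Literal["homogeneous", "type1", "type2"] = "homogeneous"
    F_mean: float = Field(2.0, gt=0, description="target mean fibrin (mg/ml)")
    dispersion_pct: float = Field(100.0, ge=0, le=100)
    F_disk: float = Field(3.5, gt=0)
    n_disks: int = Field(25, ge=1)
    disk_radius_vox: float = Field(2.4, gt=0, description="disk radius in voxels (default ~8.6% of channel width, the reference disk-to-tube ratio)")


class StopBlock(_Strict):
    mass_frac_stop: float = Field(0.01, gt=0, lt=1)
    t_max_s: float = Field(2e5, gt=0)


class OutputBlock(_Strict):
    sample_period_s: float = Field(20.0, gt=0)
    snapshot_period_s: Optional[float] = Field(None, gt=0)
    outdir: Optional[str] = None


class RunConfig(_Strict):
    physical: PhysicalBlock = Field(default_factory=PhysicalBlock)
    numerics: NumericsBlock = Field(default_factory=NumericsBlock)
    domain: DomainBlock = Field(default_factory=DomainBlock)
    clot: ClotBlock = Field(default_factory=ClotBlock)
    stop: StopBlock = Field(default_factory=StopBlock)
    outputs: OutputBlock = Field(default_factory=OutputBlock)
    seed: int = 0

    def resolved(self) -> dict:
        return self.model_dump()


def load_config(path) -> RunConfig:
    """Load and strictly validate a YAML config file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.resolved(), fh, sort_keys=True)
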
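"""Run configuration: schema, YAML round trip, hashing, desk presets.

A run is described by one human-readable YAML tree with four sections —
geometry, regime, solver, analysis — plus a seed.  All physical
quantities are SI (metres, m^2/s); solver quantities are lattice units.
Every defaulted field is materialized on serialization, so a config file
re-parses to an identical run plan and its hash identifies the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .geometry import LayoutSpec, SpongeSpec
from .lbm import SimParams, tau_from_nu
from .units import FlowRegime, UnitScaling, scaling_for_regime

__all__ = ["RunConfig", "SolverConfig", "AnalysisConfig", "desk_config"]

#: above this Reynolds number a desk-resolution BGK run is under-resolved
#: and must be requested explicitly
RE_DESK_LIMIT = 300.0


@dataclass(frozen=True)
class SolverConfig:
    """Lattice-side solver choices (the regime fixes only physical values)."""

    u_in_lattice: float = 0.07      # along +x; <= 0.1 for low-Mach safety
    n_steps: int = 2600
    steady_window: int = 600
    steady_tol: float = 1e-4
    force_cadence: int = 10
    check_every: int = 100
    backend: str = "numba"
    allow_under_resolved: bool = False


@dataclass(frozen=True)
class AnalysisConfig:
    seeds_per_cavity: int = 1000
    pathline_ds: float = 0.25        # voxels per integrator step
    pathline_max_steps: int = 6000
    speed_floor_rel: float = 1e-6    # of u_in
    flux_refine: int = 2
    flux_wall_clearance: float = 1.0  # voxels between cylinder and wall
    window_fraction: float = 0.5     # trailing force-averaging window


@dataclass(frozen=True)
class RunConfig:
    sponge: SpongeSpec = field(default_factory=SpongeSpec)
    layout: LayoutSpec = field(default_factory=LayoutSpec)
    spacing: float = 2e-4            # voxel size, m
    regime: FlowRegime = field(default_factory=lambda: FlowRegime(Re=100.0))
    solver: SolverConfig = field(default_factory=SolverConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    #: explicit grid dimensions; None sizes the domain automatically.
    #: Matched cross-run comparisons (isolated vs paired) should share one
    #: explicit domain so blockage and outlet distance are identical.
    domain: tuple[int, int, int] | None = None
    seed: int = 0

    def validate(self) -> None:
        self.sponge.validate()
        self.layout.validate(self.sponge.D)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.regime.Re > RE_DESK_LIMIT and not self.solver.allow_under_resolved:
            raise ValueError(
                f"Re={self.regime.Re} is under-resolved at desk resolution; "
                "set solver.allow_under_resolved to proceed"
            )
        self.sim_params()  # raises on invalid tau / u_in

    # -- derived lattice quantities ---------------------------------------
    @property
    def d_lattice(self) -> float:
        """Cavity diameter in lattice nodes."""
        return self.sponge.D / self.spacing

    @property
    def nu_lattice(self) -> float:
        return self.solver.u_in_lattice * self.d_lattice / self.regime.Re

    @property
    def tau_f(self) -> float:
        return tau_from_nu(self.nu_lattice)

    def sim_params(self) -> SimParams:
        return SimParams(
            tau_f=self.tau_f,
            u_in_lattice=(self.solver.u_in_lattice, 0.0, 0.0),
            n_steps=self.solver.n_steps,
            steady_window=self.solver.steady_window,
            steady_tol=self.solver.steady_tol,
            force_cadence=self.solver.force_cadence,
            check_every=self.solver.check_every,
            seed=self.seed,
        )

    def unit_scaling(self) -> UnitScaling:
        return scaling_for_regime(
            self.regime, self.d_lattice, self.solver.u_in_lattice
        )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("domain") is not None:
            d["domain"] = tuple(d["domain"])
        return cls(
            sponge=SpongeSpec(**d.pop("sponge", {})),
            layout=LayoutSpec(**d.pop("layout", {})),
            regime=FlowRegime(**d.pop("regime", {})),
            solver=SolverConfig(**d.pop("solver", {})),
            analysis=AnalysisConfig(**d.pop("analysis", {})),
            **d,
        )

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def desk_config(
    mode: str = "isolated",
    lambda_over_D: float = 1.0,
    Re: float = 100.0,
    d_voxels: int = 14,
    seed: int = 0,
    n_steps: int = 2600,
    seeds_per_cavity: int = 150,
) -> RunConfig:
    """Desk-scale preset: full sponge morphology at coarse resolution.

    The cavity diameter spans ``d_voxels`` nodes and the strut lattice
    pitch is widened to four voxels so the wall pores stay resolved;
    sub-voxel struts and diagonals inflate to one voxel.  Reynolds
    similarity (not geometric strut fidelity) carries the physics at
    this scale.
    """
    D = 0.040
    spacing = D / d_voxels
    sponge = SpongeSpec(lattice_pitch=4 * spacing)
    layout = LayoutSpec(
        mode=mode, lambda_=lambda_over_D * D, lambda_convention="surface"
    )
    return RunConfig(
        sponge=sponge,
        layout=layout,
        spacing=spacing,
        regime=FlowRegime(Re=Re, D_phys=D),
        solver=SolverConfig(n_steps=n_steps),
        analysis=AnalysisConfig(
            seeds_per_cavity=seeds_per_cavity, pathline_max_steps=4000
        ),
        seed=seed,
    )
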
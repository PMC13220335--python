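"""End-to-end orchestration: geometry -> solve -> forces/pathlines/fluxes.

`run_case` executes one configured run and returns a `CaseResult` whose
`summary()` collects the per-body observables of interest: time-averaged
drag and lift (with coefficients on the projected-silhouette reference
area), cavity residence-time medians, and cavity inflow in litres/hour.
`write_artifacts` dumps the standard-format files for a run directory.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np

from . import __version__
from .config import RunConfig
from .fluxes import all_fluxes, build_partition, cavity_inflow_rate, flux_closure
from .forces import drag_lift_coefficients, ForceRecord, silhouette_area
from .geometry import VoxelGeometry, build_sponge, place_layout
from .lbm import RunResult, run_to_steady
from .pathlines import (
    cavity_seed_grid,
    clip_to_region,
    residence_stats,
    trace_pathlines,
)
from .units import UnitScaling

log = logging.getLogger(__name__)

__all__ = ["CaseResult", "build_case_geometry", "run_case", "write_artifacts"]


def auto_domain(sponge: VoxelGeometry, cfg: RunConfig) -> tuple[int, int, int]:
    """Domain dimensions giving >= D clearance around the bodies.

    Upstream margin comes from the layout, the wake gets three diameters
    before the zero-gradient outlet, sides and top get one diameter.
    """
    from .geometry import effective_separation_vox

    bx, by, bz = sponge.occupancy.shape
    d = int(np.ceil(cfg.d_lattice))
    lam = effective_separation_vox(sponge, cfg.layout)
    x0 = int(round(cfg.layout.upstream_margin * cfg.d_lattice))
    nx = x0 + bx + 3 * d
    ny = by + 2 * d
    nz = 1 + bz + d
    if cfg.layout.mode == "IL":
        nx += lam
    elif cfg.layout.mode == "SBS":
        ny += lam
    return nx, ny, nz


def build_case_geometry(cfg: RunConfig) -> VoxelGeometry:
    sponge = build_sponge(cfg.sponge, cfg.spacing)
    domain = cfg.domain if cfg.domain is not None else auto_domain(sponge, cfg)
    return place_layout(sponge, cfg.layout, domain)


def matched_desk_configs(Re: float = 100.0, seed: int = 0,
                         lambda_over_D: float = 1.0,
                         n_steps: int = 2600) -> dict[str, RunConfig]:
    """Desk-scale isolated / IL / SBS configs sharing one explicit domain.

    The common grid is the elementwise maximum of the three auto-sized
    domains, so blockage ratio, body-1 position, and outlet distance are
    identical across the layouts being compared.
    """
    from dataclasses import replace

    from .config import desk_config

    cfgs = {
        mode: desk_config(mode=mode, lambda_over_D=lambda_over_D, Re=Re,
                          seed=seed, n_steps=n_steps)
        for mode in ("isolated", "IL", "SBS")
    }
    sponge = build_sponge(cfgs["isolated"].sponge, cfgs["isolated"].spacing)
    dims = np.array([auto_domain(sponge, c) for c in cfgs.values()])
    common = tuple(int(v) for v in dims.max(axis=0))
    return {m: replace(c, domain=common) for m, c in cfgs.items()}


@dataclass
class CaseResult:
    """One finished run: geometry, solver output, unit scaling, config."""

    config: RunConfig
    geometry: VoxelGeometry
    run: RunResult
    scaling: UnitScaling

    def body_forces(self):
        """Time-averaged lattice force per body over the trailing window."""
        return self.run.mean_forces(self.config.analysis.window_fraction)

    def body_records(self) -> list[ForceRecord]:
        means = self.body_forces()
        out = []
        u_in = self.config.solver.u_in_lattice
        for body, row in means.iterrows():
            rec = ForceRecord(
                body=int(body),
                F_total=row[["Fx", "Fy", "Fz"]].to_numpy(),
                Fd=float(row["Fx"]),
                Fl=float(row["Fy"]),
            )
            A = silhouette_area(self.geometry, int(body))
            drag_lift_coefficients(rec, rho=1.0, u_in=u_in, A=A)
            out.append(rec)
        return out

    def cavity_pathlines(self, body: int):
        """Traced pathlines clipped to one body's cavity, plus statistics."""
        cfg = self.config
        mask = self.geometry.cavity_masks[body - 1]
        seeds = cavity_seed_grid(
            mask, cfg.analysis.seeds_per_cavity, seed=cfg.seed + body
        )
        paths = trace_pathlines(
            self.run.macro,
            seeds,
            ds=cfg.analysis.pathline_ds,
            u_ref=cfg.solver.u_in_lattice,
            speed_floor_rel=cfg.analysis.speed_floor_rel,
            max_steps=cfg.analysis.pathline_max_steps,
            region=mask,
        )
        clipped = clip_to_region(paths, mask)
        t_cross_lat = self.scaling.time_to_lattice(self.config.regime.t_cross)
        dist = residence_stats(clipped, t_cross=t_cross_lat)
        return clipped, dist

    def cavity_fluxes(self, body: int) -> dict[str, float]:
        part = build_partition(
            self.geometry, body,
            refine=self.config.analysis.flux_refine,
            wall_clearance=self.config.analysis.flux_wall_clearance,
        )
        return all_fluxes(self.run.macro, part)

    def summary(self) -> dict:
        """Per-body observables plus run-level diagnostics."""
        bodies = []
        for rec in self.body_records():
            b = rec.body
            fluxes = self.cavity_fluxes(b)
            entry = {
                "body": b,
                "Fd_lattice": rec.Fd,
                "Fl_lattice": rec.Fl,
                "Fd_phys_N": self.scaling.force(rec.Fd),
                "Cd": rec.Cd,
                "Cl": rec.Cl,
                "A_lattice": rec.A,
                "inflow_L_h": cavity_inflow_rate(fluxes, self.scaling),
                "flux_closure": flux_closure(fluxes),
            }
            try:
                _, dist = self.cavity_pathlines(b)
                entry["t_res_median_s"] = self.scaling.time(dist.median)
                entry["t_res_q90_s"] = self.scaling.time(dist.quantile(0.9))
                entry["n_pathlines"] = int(len(dist.samples))
            except ValueError:
                entry["t_res_median_s"] = float("nan")
                entry["n_pathlines"] = 0
            bodies.append(entry)
        return {
            "mode": self.config.layout.mode,
            "lambda_over_D": self.config.layout.lambda_ / self.config.sponge.D,
            "Re": self.config.regime.Re,
            "t_cross_s": self.config.regime.t_cross,
            "converged": self.run.converged,
            "low_mach_violated": self.run.low_mach_violated,
            "config_hash": self.config.config_hash(),
            "bodies": bodies,
        }


def run_case(cfg: RunConfig, geometry: VoxelGeometry | None = None) -> CaseResult:
    """Validate, build geometry if needed, and solve to steady state."""
    cfg.validate()
    if geometry is None:
        geometry = build_case_geometry(cfg)
    log.info(
        "run %s: mode=%s lambda/D=%.1f Re=%g grid=%s tau=%.4f",
        cfg.config_hash(), cfg.layout.mode,
        cfg.layout.lambda_ / cfg.sponge.D if cfg.layout.mode != "isolated" else 0,
        cfg.regime.Re, geometry.shape, cfg.tau_f,
    )
    result = run_to_steady(geometry, cfg.sim_params(),
                           backend=cfg.solver.backend)
    return CaseResult(config=cfg, geometry=geometry, run=result,
                      scaling=cfg.unit_scaling())


def write_artifacts(case: CaseResult, outdir: str) -> dict:
    """Write the standard output files for one run; returns the manifest."""
    import pandas as pd

    from .vtkio import write_vti

    os.makedirs(outdir, exist_ok=True)
    cfg = case.config
    header = cfg.unit_scaling().header_lines()

    write_vti(
        os.path.join(outdir, "fields.vti"),
        {
            "rho": case.run.macro.rho,
            "node_type": case.geometry.labels.astype(float),
            "u": case.run.macro.u,
        },
        spacing=cfg.spacing,
        comments=header,
    )
    forces = case.run.forces_frame()
    fpath = os.path.join(outdir, "forces.csv")
    with open(fpath, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        forces.to_csv(fh, index=False)

    flux_rows = []
    for b in range(1, len(case.geometry.cavities) + 1):
        fx = case.cavity_fluxes(b)
        for name, q in fx.items():
            flux_rows.append(
                {"body": b, "surface": name, "Q_lattice": q,
                 "Q_m3_s": case.scaling.volume_rate(q)}
            )
    pd.DataFrame(flux_rows).to_csv(os.path.join(outdir, "fluxes.csv"), index=False)

    summary = case.summary()
    manifest = {
        "config_hash": cfg.config_hash(),
        "spongeflow_version": __version__,
        "config": cfg.to_dict(),
        "summary": summary,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    cfg.to_yaml(os.path.join(outdir, "config.yaml"))
    return manifest
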
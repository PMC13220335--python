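"""D3Q19 single-relaxation-time (BGK) lattice Boltzmann solver.

The update is the standard two-stage cycle: local BGK collision toward
the second-order truncated Maxwellian equilibrium, then streaming of the
19 populations along the stencil links, with kinematic viscosity
``nu = cs2 * (tau - dt/2)``.  Five boundary conditions close the domain:

* inlet: fixed-velocity equilibrium populations at the upstream x plane,
* outlet: zero-gradient copy of density and velocity at the downstream
  x plane (equilibrium populations),
* periodic side boundaries (y),
* halfway bounce-back (no-slip) on the bottom plane and at every
  solid-fluid link,
* specular free-slip at the top plane.

Double precision throughout; collision conserves mass and momentum
nodewise to machine precision, which the test suite asserts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import VoxelGeometry
from .stencil import C, CS2, MIRROR_Z, OPP, W

log = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "MacroFields",
    "StabilityError",
    "equilibrium",
    "macro_moments",
    "collide_bgk",
    "stream_periodic",
    "Simulation",
    "run_to_steady",
    "nu_from_tau",
    "tau_from_nu",
]


class StabilityError(RuntimeError):
    """Raised when populations blow up (NaN or strongly negative)."""


def nu_from_tau(tau: float, dt: float = 1.0) -> float:
    """Lattice kinematic viscosity nu = cs2 * (tau - dt/2)."""
    return CS2 * (tau - dt / 2.0)


def tau_from_nu(nu: float, dt: float = 1.0) -> float:
    return nu / CS2 + dt / 2.0


@dataclass(frozen=True)
class SimParams:
    """Solver parameters in lattice units (dx = dt = 1).

    ``tau_f`` must exceed dt/2 for positive viscosity, and the inlet speed
    is kept at or below 0.1 lattice units as a low-Mach guard.
    """

    tau_f: float
    u_in_lattice: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_steps: int = 1000
    dt: float = 1.0
    dx: float = 1.0
    body_force: tuple[float, float, float] = (0.0, 0.0, 0.0)
    force_cadence: int = 10
    check_every: int = 100
    steady_window: int = 1000
    steady_tol: float = 1e-4
    low_mach_warn: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_f <= self.dt / 2.0:
            raise ValueError(
                f"tau_f={self.tau_f} must exceed dt/2={self.dt / 2} "
                "(positive viscosity)"
            )
        if float(np.linalg.norm(self.u_in_lattice)) > 0.1 + 1e-12:
            raise ValueError("|u_in_lattice| must be <= 0.1 (low-Mach guard)")

    @property
    def nu_lattice(self) -> float:
        return nu_from_tau(self.tau_f, self.dt)


@dataclass
class MacroFields:
    """Macroscopic density and velocity moments of the populations."""

    rho: np.ndarray           # (nx, ny, nz)
    u: np.ndarray             # (3, nx, ny, nz)
    solid: np.ndarray         # (nx, ny, nz) bool

    @property
    def speed(self) -> np.ndarray:
        return np.sqrt((self.u**2).sum(axis=0))


def equilibrium(rho: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Second-order truncated Maxwellian equilibrium populations.

    f_eq_i = w_i rho (1 + c.u/cs2 + (c.u)^2/(2 cs2^2) - u^2/(2 cs2)),
    which recovers the zeroth and first moments exactly.

    Parameters
    ----------
    rho : array, shape S
    u : array, shape (3, *S)
    """
    rho = np.asarray(rho, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    cu = np.tensordot(C.astype(np.float64), u, axes=(1, 0))   # (19, *S)
    usq = (u**2).sum(axis=0)
    shape = (19,) + (1,) * rho.ndim
    w = W.reshape(shape)
    return w * rho * (1.0 + 3.0 * cu + 4.5 * cu**2 - 1.5 * usq)


def macro_moments(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Density rho = sum_i f_i and velocity u = sum_i f_i c_i / rho."""
    rho = f.sum(axis=0)
    mom = np.tensordot(C.astype(np.float64), f, axes=(0, 0))
    return rho, mom / rho


def collide_bgk(f: np.ndarray, tau_f: float, dt: float = 1.0) -> np.ndarray:
    """Relax populations toward local equilibrium by a factor dt/tau_f."""
    if tau_f <= dt / 2.0:
        raise ValueError("tau_f must exceed dt/2")
    rho, u = macro_moments(f)
    feq = equilibrium(rho, u)
    return f + (dt / tau_f) * (feq - f)


def stream_periodic(f: np.ndarray) -> np.ndarray:
    """Stream each population one link along c_i with periodic wrap."""
    out = np.empty_like(f)
    for i in range(19):
        out[i] = np.roll(f[i], shift=tuple(C[i]), axis=(0, 1, 2))
    return out


class Simulation:
    """One LBM run: geometry, parameters, state, and the step cycle.

    ``open_x`` switches the x direction from periodic to inlet/outlet;
    ``bottom_wall`` adds a solid no-slip floor plane at z=0 (bodies rest
    on it); ``top_freeslip`` closes the top with specular reflection,
    otherwise z is periodic.
    """

    def __init__(
        self,
        geometry: VoxelGeometry | np.ndarray,
        params: SimParams,
        open_x: bool = True,
        bottom_wall: bool = True,
        top_freeslip: bool = True,
        backend: str = "numba",
    ):
        occ = geometry.occupancy if isinstance(geometry, VoxelGeometry) else geometry
        self.geometry = geometry if isinstance(geometry, VoxelGeometry) else None
        self.params = params
        self.open_x = open_x
        self.bottom_wall = bottom_wall
        self.top_freeslip = top_freeslip
        if backend not in ("numba", "numpy"):
            raise ValueError(f"unknown backend {backend!r}")
        self.backend = backend

        self.solid = np.ascontiguousarray(occ.copy())
        if bottom_wall:
            self.solid[:, :, 0] = True
        if self.solid.all():
            raise ValueError("domain contains no fluid")
        self.labels = (
            self.geometry.labels.copy()
            if self.geometry is not None
            else self.solid.astype(np.uint8)
        )
        self.shape = self.solid.shape
        u_in = np.asarray(params.u_in_lattice, dtype=np.float64)
        self._feq_in = equilibrium(np.float64(1.0), u_in)  # (19,)
        self.step_count = 0
        self.init_state()

    # ------------------------------------------------------------------
    def init_state(self, rho: float = 1.0, u: np.ndarray | None = None) -> None:
        """Initialize populations at equilibrium (default: inlet velocity)."""
        nx, ny, nz = self.shape
        if u is None:
            u = np.zeros((3, nx, ny, nz))
            if self.open_x:
                u += np.asarray(self.params.u_in_lattice).reshape(3, 1, 1, 1)
        rho_field = np.full(self.shape, float(rho))
        self.f = np.ascontiguousarray(equilibrium(rho_field, u))
        self.f[:, self.solid] = W[:, None]
        self._scratch = self.f.copy()
        self.step_count = 0

    # ------------------------------------------------------------------
    def _apply_inlet_outlet(self, f: np.ndarray) -> None:
        fl_in = ~self.solid[0]
        f[:, 0, fl_in] = self._feq_in[:, None]
        # zero-gradient outlet: copy macroscopic state of last interior plane
        rho, u = macro_moments(f[:, -2])
        feq = equilibrium(rho, u)
        fl_out = ~self.solid[-1]
        f[:, -1, fl_out] = feq[:, fl_out]

    def step(self) -> None:
        """One stream-then-collide cycle; self.f ends post-collision."""
        if self.backend == "numba":
            self._step_numba()
        else:
            self._step_numpy()
        if self.open_x:
            self._apply_inlet_outlet(self.f)
        self.step_count += 1

    @property
    def fpost(self) -> np.ndarray:
        """Post-collision populations of the last completed step."""
        return self.f

    def _step_numba(self) -> None:
        from ._kernels import fused_step

        g = self.params.body_force
        fused_step(self.f, self._scratch, self.solid, self.params.tau_f,
                   g[0], g[1], g[2],
                   not (self.bottom_wall or self.top_freeslip),
                   self.top_freeslip)
        self.f, self._scratch = self._scratch, self.f

    def _step_numpy(self) -> None:
        """Readable reference step; bit-compatible with the numba kernel."""
        tau = self.params.tau_f
        g = np.asarray(self.params.body_force)
        fluid = ~self.solid

        # gather: pull streaming with halfway bounce-back / specular top
        f = self.f
        fstr = np.empty_like(f)
        for i in range(19):
            fstr[i] = np.roll(f[i], shift=tuple(C[i]), axis=(0, 1, 2))
            src_solid = np.roll(self.solid, shift=tuple(C[i]), axis=(0, 1, 2))
            m = fluid & src_solid
            fstr[i][m] = f[OPP[i]][m]
        if self.top_freeslip:
            for i in range(19):
                if C[i, 2] == -1:
                    j = MIRROR_Z[i]
                    plane = np.roll(f[j][:, :, -1],
                                    shift=(C[i, 0], C[i, 1]), axis=(0, 1))
                    fl = fluid[:, :, -1]
                    fstr[i][:, :, -1][fl] = plane[fl]
                elif C[i, 2] == 1 and not self.bottom_wall:
                    # floorless channel: specular bottom plane
                    j = MIRROR_Z[i]
                    plane = np.roll(f[j][:, :, 0],
                                    shift=(C[i, 0], C[i, 1]), axis=(0, 1))
                    fl = fluid[:, :, 0]
                    fstr[i][:, :, 0][fl] = plane[fl]

        # BGK collision with Guo forcing on the streamed state
        rho = fstr.sum(axis=0)
        mom = np.tensordot(C.astype(np.float64), fstr, axes=(0, 0))
        rho_safe = np.where(fluid, rho, 1.0)
        u = (mom + 0.5 * g.reshape(3, 1, 1, 1)) / rho_safe
        feq = equilibrium(rho, u)
        omega = 1.0 / tau
        fnew = fstr + omega * (feq - fstr)
        if np.any(g != 0.0):
            cu = np.tensordot(C.astype(np.float64), u, axes=(1, 0))
            cg = (C.astype(np.float64) @ g).reshape(19, 1, 1, 1)
            ug = np.tensordot(g, u, axes=(0, 0))
            fnew += (1.0 - 0.5 * omega) * W.reshape(19, 1, 1, 1) * (
                3.0 * (cg - ug) + 9.0 * cu * cg
            )
        fnew[:, self.solid] = W[:, None]
        self.f[...] = fnew

    # ------------------------------------------------------------------
    def macro(self) -> MacroFields:
        rho, u = macro_moments(self.f)
        rho = np.where(self.solid, 1.0, rho)
        u[:, self.solid] = 0.0
        return MacroFields(rho=rho, u=u, solid=self.solid)

    def kinetic_energy(self) -> float:
        m = self.macro()
        return float(0.5 * (m.rho * (m.u**2).sum(axis=0))[~self.solid].sum())

    def check_stability(self) -> None:
        if not np.isfinite(self.f).all():
            raise StabilityError(
                f"populations lost finiteness at step {self.step_count}; "
                "reduce u_in_lattice or increase resolution (larger tau_f)"
            )


def run_to_steady(
    geometry: VoxelGeometry,
    params: SimParams,
    backend: str = "numba",
    open_x: bool = True,
    bottom_wall: bool = True,
    top_freeslip: bool = True,
    record_forces: bool = True,
):
    """Advance collide-stream-boundaries to a statistical steady state.

    Runs at most ``params.n_steps`` steps; stops earlier once the windowed
    relative change of both total kinetic energy and per-body drag falls
    below ``params.steady_tol``.  Returns a :class:`RunResult` holding the
    final fields, the force time series per body, and a convergence trace.
    """
    from .forces import momentum_exchange_totals

    sim = Simulation(geometry, params, open_x=open_x, bottom_wall=bottom_wall,
                     top_freeslip=top_freeslip, backend=backend)
    n_bodies = int(sim.labels.max())
    force_rows: list[tuple] = []
    trace: list[tuple] = []
    ke_hist: list[float] = []
    drag_hist: list[float] = []
    converged = False
    low_mach_violated = False

    for _ in range(params.n_steps):
        sim.step()
        s = sim.step_count
        if record_forces and n_bodies and s % params.force_cadence == 0:
            totals = momentum_exchange_totals(sim.fpost, sim.solid, sim.labels,
                                              n_bodies)
            for b in range(n_bodies):
                fx, fy, fz = totals[b]
                force_rows.append((s, b + 1, fx, fy, fz))
            drag_hist.append(float(totals[:, 0].sum()))
        if s % params.check_every == 0:
            sim.check_stability()
            ke = sim.kinetic_energy()
            umax = float(sim.macro().speed.max())
            if umax > params.low_mach_warn and not low_mach_violated:
                low_mach_violated = True
                log.warning("max |u|=%.3f exceeds low-Mach guard %.2f at step %d",
                            umax, params.low_mach_warn, s)
            ke_hist.append(ke)
            trace.append((s, ke, umax))
            w = max(2, params.steady_window // params.check_every)
            if len(ke_hist) >= 2 * w:
                a = np.mean(ke_hist[-2 * w:-w])
                b_ = np.mean(ke_hist[-w:])
                d_ok = True
                if drag_hist:
                    wd = max(2, params.steady_window // params.force_cadence)
                    if len(drag_hist) >= 2 * wd:
                        da = np.mean(drag_hist[-2 * wd:-wd])
                        db = np.mean(drag_hist[-wd:])
                        d_ok = abs(db - da) <= params.steady_tol * max(abs(da), 1e-30)
                    else:
                        d_ok = False
                if abs(b_ - a) <= params.steady_tol * max(abs(a), 1e-30) and d_ok:
                    converged = True
                    break
    sim.check_stability()
    return RunResult(sim=sim, macro=sim.macro(), force_rows=force_rows,
                     trace=trace, converged=converged,
                     low_mach_violated=low_mach_violated)


@dataclass
class RunResult:
    """Final state of a run plus its force and convergence time series."""

    sim: Simulation
    macro: MacroFields
    force_rows: list
    trace: list
    converged: bool
    low_mach_violated: bool

    def forces_frame(self):
        import pandas as pd

        return pd.DataFrame(self.force_rows,
                            columns=["step", "body", "Fx", "Fy", "Fz"])

    def mean_forces(self, window_fraction: float = 0.5):
        """Time-averaged force per body over the trailing window."""
        df = self.forces_frame()
        if df.empty:
            return df
        cut = df["step"].max() - window_fraction * (
            df["step"].max() - df["step"].min()
        )
        return df[df["step"] >= cut].groupby("body")[["Fx", "Fy", "Fz"]].mean()
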
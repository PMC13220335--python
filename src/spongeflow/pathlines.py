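"""Pathline tracing and cavity residence-time statistics.

Pathlines are integrated through the converged time-averaged velocity
field (where pathlines and streamlines coincide) with fourth-order
Runge-Kutta on a trilinear interpolant, by default a quarter-voxel per
step, both forward and backward from each seed.  For each line the
length and residence time are the discrete sums

    l     = sum_s ||x(s) - x(s-1)||
    t_res = sum_s ||x(s) - x(s-1)|| / (||u(s) + u(s-1)|| / 2),

i.e. segment length over the trapezoidal segment speed.  Residence-time
samples of all retained lines of one cavity form the distribution
psi-tilde, reported against the ballistic cross time t_cross = D/u_in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .lbm import MacroFields

log = logging.getLogger(__name__)

__all__ = [
    "Pathline",
    "PathlineSet",
    "ResidenceDistribution",
    "trace_pathlines",
    "filter_cavity_contained",
    "clip_to_region",
    "residence_stats",
    "cavity_seed_grid",
]


@dataclass
class Pathline:
    """One traced pathline: ordered points and sampled velocities."""

    points: np.ndarray            # (n, 3), lattice coordinates
    velocities: np.ndarray        # (n, 3), lattice units
    seed_index: int               # index of the seed point within `points`
    termination: str              # exit | solid | stall | cap

    @property
    def n(self) -> int:
        return len(self.points)

    def length(self) -> float:
        if self.n < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class PathlineSet:
    """A bundle of pathlines traced in one field."""

    lines: list[Pathline]
    rejected_seeds: int = 0
    stalled: int = 0

    def __len__(self) -> int:
        return len(self.lines)


@dataclass
class ResidenceDistribution:
    """Residence-time samples of one cavity and their density estimate."""

    samples: np.ndarray           # t_res per retained pathline, > 0
    lengths: np.ndarray           # matching pathline lengths
    t_cross: float | None = None
    bin_edges: np.ndarray | None = None
    density: np.ndarray | None = None

    @property
    def median(self) -> float:
        return float(np.median(self.samples))

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.samples, q))


def _make_interp(field: MacroFields) -> RegularGridInterpolator:
    nx, ny, nz = field.rho.shape
    axes = (np.arange(nx), np.arange(ny), np.arange(nz))
    # components last for one vectorized interpolant
    vals = np.moveaxis(field.u, 0, -1)
    return RegularGridInterpolator(axes, vals, bounds_error=False, fill_value=None)


def cavity_seed_grid(
    mask: np.ndarray, n_target: int, seed: int = 0, jitter: bool = True
) -> np.ndarray:
    """Roughly ``n_target`` seed points on a uniform grid inside a mask.

    Points landing outside the mask are dropped; a sub-voxel jitter drawn
    from the run seed decorrelates seeds from the voxel lattice while
    keeping the set reproducible.
    """
    if not mask.any():
        raise ValueError("empty seeding mask")
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    span = np.maximum(hi - lo, 1)
    per_axis = np.maximum(
        1, np.round((n_target * span.prod() ** -1.0) ** (1 / 3) * span).astype(int)
    )
    axes = [lo[a] + (np.arange(per_axis[a]) + 0.5) / per_axis[a] * span[a]
            for a in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if jitter:
        rng = np.random.default_rng(seed)
        pts = pts + rng.uniform(-0.25, 0.25, size=pts.shape)
    vox = np.round(pts).astype(int)
    for a in range(3):
        vox[:, a] = np.clip(vox[:, a], 0, mask.shape[a] - 1)
    keep = mask[vox[:, 0], vox[:, 1], vox[:, 2]]
    return pts[keep]


def _trace_batch(
    interp: RegularGridInterpolator,
    solid: np.ndarray,
    seeds: np.ndarray,
    direction: float,
    ds: float,
    speed_floor: float,
    max_steps: int,
    region: np.ndarray | None,
) -> tuple[list[list[np.ndarray]], list[list[np.ndarray]], list[str]]:
    """Integrate all seeds simultaneously (one interpolant call per stage)."""
    n = len(seeds)
    shape = np.array(solid.shape, dtype=float)
    x = seeds.astype(float).copy()
    active = np.ones(n, dtype=bool)
    term = ["cap"] * n
    pts: list[list[np.ndarray]] = [[] for _ in range(n)]
    vels: list[list[np.ndarray]] = [[] for _ in range(n)]

    def eval_u(pos: np.ndarray) -> np.ndarray:
        p = np.clip(pos, 0.0, shape - 1.0)
        return interp(p)

    for _ in range(max_steps):
        if not active.any():
            break
        ia = np.flatnonzero(active)
        xa = x[ia]
        u = eval_u(xa)
        speed = np.linalg.norm(u, axis=1)
        bad = ~np.isfinite(speed)
        stalled = np.isfinite(speed) & (speed < speed_floor)
        for j, k in enumerate(ia):
            if bad[j]:
                term[k] = "exit"
                active[k] = False
            elif stalled[j]:
                term[k] = "stall"
                active[k] = False
            else:
                pts[k].append(xa[j].copy())
                vels[k].append(direction * u[j])
        go = ~(bad | stalled)
        if not go.any():
            continue
        ig = ia[go]
        xg = xa[go]
        dt = (ds / speed[go])[:, None]
        k1 = direction * u[go]
        k2 = direction * eval_u(xg + 0.5 * dt * k1)
        k3 = direction * eval_u(xg + 0.5 * dt * k2)
        k4 = direction * eval_u(xg + dt * k3)
        xn = xg + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

        out = np.any(xn < 0, axis=1) | np.any(xn > shape - 1, axis=1)
        vox = np.round(np.clip(xn, 0, shape - 1)).astype(int)
        hit = solid[vox[:, 0], vox[:, 1], vox[:, 2]]
        left = (
            ~region[vox[:, 0], vox[:, 1], vox[:, 2]]
            if region is not None
            else np.zeros(len(xn), dtype=bool)
        )
        u_end = eval_u(xn)
        for j, k in enumerate(ig):
            if out[j]:
                term[k] = "exit"
                active[k] = False
            elif hit[j]:
                term[k] = "solid"
                active[k] = False
            elif left[j]:
                # record the first point past the region edge, then stop
                pts[k].append(xn[j].copy())
                vels[k].append(direction * u_end[j])
                term[k] = "exit"
                active[k] = False
            else:
                x[k] = xn[j]
    return pts, vels, term


def trace_pathlines(
    field: MacroFields,
    seeds: np.ndarray,
    ds: float = 0.25,
    speed_floor_abs: float | None = None,
    u_ref: float = 1.0,
    speed_floor_rel: float = 1e-6,
    max_steps: int = 4000,
    bidirectional: bool = True,
    region: np.ndarray | None = None,
) -> PathlineSet:
    """Trace pathlines from seed points through a steady velocity field.

    Each seed is integrated forward and (by default) backward and the two
    halves concatenated, so containment tests see the full transit.  A
    line stops when it exits the domain (or the optional ``region``),
    enters a solid voxel, stalls below the speed floor
    (``speed_floor_rel * u_ref`` unless an absolute floor is given), or
    reaches the step cap.  Seeds inside solid are rejected and logged.
    """
    interp = _make_interp(field)
    solid = field.solid
    floor = speed_floor_abs if speed_floor_abs is not None else speed_floor_rel * u_ref
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    vox = np.clip(np.round(seeds).astype(int), 0, np.array(solid.shape) - 1)
    ok = ~solid[vox[:, 0], vox[:, 1], vox[:, 2]]
    rejected = int((~ok).sum())
    if rejected:
        log.info("%d seeds rejected (inside solid)", rejected)
    seeds = seeds[ok]

    fp, fv, fterm = _trace_batch(interp, solid, seeds, +1.0, ds, floor,
                                 max_steps, region)
    if bidirectional:
        bp, bv, bterm = _trace_batch(interp, solid, seeds, -1.0, ds, floor,
                                     max_steps, region)
    else:
        bp = [[] for _ in seeds]
        bv = [[] for _ in seeds]
        bterm = ["exit"] * len(seeds)

    lines: list[Pathline] = []
    stalled = 0
    for k in range(len(seeds)):
        # backward half reversed + forward half (seed point not duplicated)
        pts_b = bp[k][1:][::-1]
        vel_b = [-v for v in bv[k][1:]][::-1]
        points = np.array(pts_b + fp[k]) if (pts_b or fp[k]) else np.zeros((0, 3))
        vels = np.array(vel_b + fv[k]) if (vel_b or fv[k]) else np.zeros((0, 3))
        is_stalled = "stall" in (fterm[k], bterm[k])
        if is_stalled:
            stalled += 1
        if len(points) < 2:
            continue
        term = "stall" if is_stalled else (
            fterm[k] if fterm[k] != "cap" else bterm[k]
        )
        lines.append(
            Pathline(points=points, velocities=vels,
                     seed_index=len(pts_b), termination=term)
        )
    return PathlineSet(lines=lines, rejected_seeds=rejected, stalled=stalled)


def _in_mask(points: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vox = np.round(points).astype(int)
    ok = np.all((vox >= 0) & (vox < np.array(mask.shape)), axis=1)
    out = np.zeros(len(points), dtype=bool)
    if ok.any():
        v = vox[ok]
        out[ok] = mask[v[:, 0], v[:, 1], v[:, 2]]
    return out


def filter_cavity_contained(paths: PathlineSet, cavity_mask: np.ndarray) -> PathlineSet:
    """Retain exactly the pathlines whose every point lies in the mask."""
    if not cavity_mask.any():
        raise ValueError("empty cavity mask")
    kept = [p for p in paths.lines
            if p.n > 0 and bool(_in_mask(p.points, cavity_mask).all())]
    return PathlineSet(lines=kept, rejected_seeds=paths.rejected_seeds,
                       stalled=paths.stalled)


def clip_to_region(paths: PathlineSet, mask: np.ndarray) -> PathlineSet:
    """Clip each line to its maximal in-mask run containing the seed.

    The residence time inside a cavity is the time a particle takes to
    enter and leave it, so the in-cavity segment of a transiting pathline
    is the relevant piece; lines whose seed point left the mask are
    dropped.
    """
    if not mask.any():
        raise ValueError("empty region mask")
    kept: list[Pathline] = []
    for p in paths.lines:
        inside = _in_mask(p.points, mask)
        s = p.seed_index
        if s >= len(inside) or not inside[s]:
            continue
        a = s
        while a > 0 and inside[a - 1]:
            a -= 1
        b = s
        while b < len(inside) - 1 and inside[b + 1]:
            b += 1
        if b - a + 1 < 2:
            continue
        kept.append(
            Pathline(points=p.points[a:b + 1], velocities=p.velocities[a:b + 1],
                     seed_index=s - a, termination=p.termination)
        )
    return PathlineSet(lines=kept, rejected_seeds=paths.rejected_seeds,
                       stalled=paths.stalled)


def pathline_stats(line: Pathline) -> tuple[float, float]:
    """(length, residence time) of one line by the discrete sums."""
    d = np.linalg.norm(np.diff(line.points, axis=0), axis=1)
    sp = np.linalg.norm(line.velocities, axis=1)
    seg_speed = 0.5 * (sp[1:] + sp[:-1])
    ok = seg_speed > 0
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} zero-speed segments skipped in residence sum",
            stacklevel=2,
        )
    return float(d.sum()), float((d[ok] / seg_speed[ok]).sum())


def residence_stats(
    paths: PathlineSet, t_cross: float | None = None
) -> ResidenceDistribution:
    """Aggregate per-line length and residence time into psi-tilde.

    The density estimate uses Freedman-Diaconis bins on log-scaled
    residence times; raw samples are kept alongside so the estimate stays
    auditable.
    """
    if len(paths) == 0:
        raise ValueError("no retained pathlines")
    ls, ts = zip(*(pathline_stats(p) for p in paths.lines))
    samples = np.array(ts)
    lengths = np.array(ls)
    pos = samples > 0
    samples, lengths = samples[pos], lengths[pos]
    dist = ResidenceDistribution(samples=samples, lengths=lengths, t_cross=t_cross)
    if len(samples) >= 4:
        logt = np.log10(samples)
        q75, q25 = np.percentile(logt, [75, 25])
        iqr = q75 - q25
        width = 2 * iqr / len(logt) ** (1 / 3) if iqr > 0 else 0.0
        n_bins = (
            max(1, int(np.ceil((logt.max() - logt.min()) / width)))
            if width > 0 else 1
        )
        hist, edges = np.histogram(logt, bins=min(n_bins, 200), density=True)
        dist.bin_edges = 10.0**edges
        dist.density = hist
    return dist
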
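"""Procedural voxel skeletons of *Euplectella aspergillum* and pair layouts.

The generator emulates the sponge's tubular siliceous skeleton: a hollow
cylindrical body cavity whose wall is a checkerboard lattice of orthogonal
struts reinforced by double diagonals, decorated on the outside by helical
ridges, capped by an apical sieve plate (osculum) and attached to the
seafloor by a short solid base plug standing in for the anchoring bulb.

Conventions
-----------
* z is the vertical (body) axis; the sponge stands on the z=low side.
* A voxel is solid iff its **center** lies inside the analytic solid.
* Members thinner than one voxel are inflated to one voxel (logged), so
  coarse desk-scale grids still produce a connected skeleton.
* Ridges come in alternating handedness with half-slot phase offsets, which
  makes a single sponge mirror-symmetric about the x-z plane through its
  axis — and therefore a side-by-side pair mirror-symmetric about the
  mid-plane between the two bodies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "SpongeSpec",
    "LayoutSpec",
    "CavityCylinder",
    "VoxelGeometry",
    "build_sponge",
    "place_layout",
    "export_stl",
    "voxelize_stl",
]


@dataclass(frozen=True)
class SpongeSpec:
    """Dimensions of one sponge skeleton, in metres (full-scale defaults)."""

    H: float = 0.154              # total height, bulb base to osculum
    D: float = 0.040              # body-cavity inner diameter
    h: float = 0.100              # body-cavity height
    strut_thickness: float = 5e-4
    diagonal_thickness: float = 2e-4
    ridge_thickness: float = 5e-3
    lattice_pitch: float = 5e-3   # checkerboard strut spacing
    n_ridges: int = 8             # even count, alternating handedness
    ridge_pitch: float = 0.100    # axial advance per full helical turn
    include_osculum: bool = True
    include_base_plug: bool = True

    def validate(self) -> None:
        bad = []
        if not (0 < self.h < self.H):
            bad.append(f"h={self.h} must satisfy 0 < h < H={self.H}")
        if self.D <= 0:
            bad.append(f"D={self.D} must be > 0")
        for name in ("strut_thickness", "diagonal_thickness", "ridge_thickness"):
            v = getattr(self, name)
            if not (0 < v < self.D):
                bad.append(f"{name}={v} must be in (0, D)")
        for name in ("lattice_pitch", "ridge_pitch"):
            if getattr(self, name) <= 0:
                bad.append(f"{name} must be > 0")
        if self.n_ridges < 0:
            bad.append("n_ridges must be >= 0")
        if bad:
            raise ValueError("invalid SpongeSpec: " + "; ".join(bad))


@dataclass(frozen=True)
class LayoutSpec:
    """Placement of one or two sponges in the flow domain.

    ``mode`` is ``isolated``, ``IL`` (in-line, second body downstream along
    the flow axis) or ``SBS`` (side-by-side, second body transverse to the
    flow).  ``lambda_`` is the center-axis to center-axis separation in
    metres; the paired sweep of interest is lambda in {D, 3D, 5D}.
    """

    mode: str = "isolated"
    lambda_: float = 0.0
    flow_axis: str = "x"
    upstream_margin: float = 2.0   # clearance ahead of first body, in D
    #: "center": lambda_ is the raw axis-to-axis distance.  "surface":
    #: lambda_=D corresponds to the outer envelopes just touching, i.e.
    #: axis distance = lambda_ + (envelope width - D).  The tightest case
    #: lambda_=D is only realizable under "surface", since the wall shells
    #: of two cavities of inner diameter D would interpenetrate at an axis
    #: distance of D.
    lambda_convention: str = "center"

    def validate(self, D: float) -> None:
        if self.mode not in ("isolated", "IL", "SBS"):
            raise ValueError(f"unknown layout mode {self.mode!r}")
        if self.flow_axis != "x":
            raise ValueError("only flow along +x is supported")
        if self.lambda_convention not in ("center", "surface"):
            raise ValueError(
                f"unknown lambda_convention {self.lambda_convention!r}"
            )
        if self.mode != "isolated" and self.lambda_ < D:
            raise ValueError(
                f"paired layouts need lambda_ >= D (non-overlap); got "
                f"lambda_={self.lambda_}, D={D}"
            )


@dataclass(frozen=True)
class CavityCylinder:
    """Inscribed cylinder of one body cavity, in physical coordinates."""

    center_x: float
    center_y: float
    radius: float
    z0: float
    z1: float

    @property
    def height(self) -> float:
        return self.z1 - self.z0


@dataclass
class VoxelGeometry:
    """Boolean solid-occupancy grid plus per-body cavity metadata.

    ``occupancy[i, j, k]`` is True where voxel centers fall inside solid.
    ``labels`` assigns each solid voxel to a body (1-based; 0 = not solid).
    ``cavities[b]`` is the inscribed cavity cylinder of body ``b+1`` and
    ``cavity_masks[b]`` the corresponding fluid-region mask.
    """

    occupancy: np.ndarray
    spacing: float
    origin: np.ndarray
    labels: np.ndarray
    cavities: list[CavityCylinder]
    cavity_masks: list[np.ndarray]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def solid_fraction(self) -> float:
        return float(self.occupancy.mean())

    def solid_volume(self) -> float:
        """Physical solid volume in m^3."""
        return float(self.occupancy.sum()) * self.spacing**3

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.occupancy.shape[axis]
        return self.origin[axis] + self.spacing * np.arange(n)


def _band(value: np.ndarray, pitch: float, half_width: float) -> np.ndarray:
    """True where `value` lies within half_width of the nearest pitch line."""
    frac = np.mod(value, pitch)
    return np.minimum(frac, pitch - frac) <= half_width


def _analytic_solid(
    spec: SpongeSpec,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    spacing: float,
) -> np.ndarray:
    """Evaluate the analytic sponge solid on broadcastable coordinate arrays.

    Coordinates are relative to the body axis (x=y=0) with z=0 at the base.
    """
    # inflate sub-voxel members so they survive center-sampling
    t_s = max(spec.strut_thickness, spacing)
    t_d = max(spec.diagonal_thickness, spacing)
    t_r = max(spec.ridge_thickness, spacing)
    if t_s > spec.strut_thickness or t_d > spec.diagonal_thickness:
        log.info(
            "thin members inflated to one voxel (spacing=%g): strut %g->%g, "
            "diagonal %g->%g", spacing, spec.strut_thickness, t_s,
            spec.diagonal_thickness, t_d,
        )

    R = spec.D / 2.0
    t_wall = t_s
    t_sieve = t_s if spec.include_osculum else 0.0
    z_cav0 = spec.H - spec.h - t_sieve   # cavity floor
    z_cav1 = z_cav0 + spec.h             # cavity top (under osculum)
    wall_top = spec.H if spec.include_osculum else z_cav1

    r = np.hypot(x, y)
    theta = np.arctan2(y, x)

    solid = np.zeros(np.broadcast_shapes(x.shape, y.shape, z.shape), dtype=bool)

    # base plug: solid cylinder standing in for bulb + curved section
    if spec.include_base_plug and z_cav0 > 0:
        solid |= (z < z_cav0) & (z >= 0) & (r <= R + t_wall)

    # tubular wall shell with checkerboard strut lattice + double diagonals
    in_shell = (z >= z_cav0) & (z < wall_top) & (r >= R) & (r < R + t_wall)
    if np.any(in_shell):
        R_mid = R + 0.5 * t_wall
        circumference = 2.0 * np.pi * R_mid
        n_circ = max(1, round(circumference / spec.lattice_pitch))
        pitch_c = circumference / n_circ      # seamless around the tube
        pitch_z = spec.lattice_pitch
        arc = (theta + np.pi) * R_mid
        zeta = z - z_cav0
        struts = _band(arc, pitch_c, t_s / 2) | _band(zeta, pitch_z, t_s / 2)
        # double diagonals across each cell; perpendicular width /sqrt(2)
        diag = _band(arc + zeta, pitch_c, t_d / np.sqrt(2) / 2) | _band(
            arc - zeta, pitch_c, t_d / np.sqrt(2) / 2
        )
        solid |= in_shell & (struts | diag)

    # apical sieve plate: perforated disc capping the cavity
    if spec.include_osculum:
        in_cap = (z >= z_cav1) & (z < spec.H) & (r <= R + t_wall)
        rim = r >= R - t_s
        grid = _band(x, spec.lattice_pitch, t_s / 2) | _band(
            y, spec.lattice_pitch, t_s / 2
        )
        solid |= in_cap & (rim | grid)

    # helical ridges on the outside of the wall
    if spec.n_ridges > 0:
        # ridge band starts inside the wall band so ridges root on the wall
        in_ridge_shell = (
            (z >= z_cav0) & (z < z_cav1) & (r >= R) & (r < R + t_wall + t_r)
        )
        if np.any(in_ridge_shell):
            zeta = z - z_cav0
            hit = np.zeros_like(solid)
            n = spec.n_ridges
            for k in range(n):
                phase = 2.0 * np.pi * (k + 0.5) / n
                hand = 1.0 if k % 2 == 0 else -1.0
                th_r = phase + hand * 2.0 * np.pi * zeta / spec.ridge_pitch
                d = np.mod(theta - th_r + np.pi, 2.0 * np.pi) - np.pi
                hit |= np.abs(d) * np.maximum(r, 1e-300) <= t_r / 2
            solid |= in_ridge_shell & hit
    return solid


def build_sponge(spec: SpongeSpec, spacing: float) -> VoxelGeometry:
    """Voxelize one sponge skeleton on a grid of the given spacing (m).

    The grid tightly bounds the solid with one empty voxel layer on each
    side; the body axis sits midway between the lateral voxel centers so
    the voxelization is exactly mirror-symmetric.  Deterministic for a
    fixed spec and spacing.
    """
    spec.validate()
    if spacing <= 0:
        raise ValueError("spacing must be > 0")

    t_r = max(spec.ridge_thickness, spacing)
    r_out = spec.D / 2 + max(spec.strut_thickness, spacing) + t_r
    nx = ny = int(np.ceil(2 * r_out / spacing)) + 3
    nz = int(np.ceil(spec.H / spacing)) + 2
    # axis midway between centers => symmetric center sampling
    cx = cy = spacing * (nx - 1) / 2.0

    ix = np.arange(nx)[:, None, None] * spacing - cx
    iy = np.arange(ny)[None, :, None] * spacing - cy
    iz = np.arange(nz)[None, None, :] * spacing + spacing / 2.0  # base at z=0

    occ = _analytic_solid(spec, ix, iy, iz, spacing)
    if not occ.any():
        raise ValueError("spec produced an empty solid at this spacing")

    t_sieve = max(spec.strut_thickness, spacing) if spec.include_osculum else 0.0
    z_cav0 = spec.H - spec.h - t_sieve
    cav = CavityCylinder(
        center_x=cx, center_y=cy, radius=spec.D / 2, z0=z_cav0, z1=z_cav0 + spec.h
    )
    r = np.hypot(ix, iy)
    region = (r < cav.radius) & (iz >= cav.z0) & (iz < cav.z1)
    mask = region & ~occ

    labels = occ.astype(np.uint8)
    return VoxelGeometry(
        occupancy=occ,
        spacing=spacing,
        origin=np.zeros(3),
        labels=labels,
        cavities=[cav],
        cavity_masks=[mask],
    )


def effective_separation_vox(geom: VoxelGeometry, layout: LayoutSpec) -> int:
    """Axis-to-axis body separation in voxels under the layout convention."""
    sp = geom.spacing
    if layout.mode == "isolated":
        return 0
    lam_vox = int(round(layout.lambda_ / sp))
    if layout.lambda_convention == "surface":
        D = 2 * geom.cavities[0].radius
        axis = 0 if layout.mode == "IL" else 1
        proj = geom.occupancy.any(axis=tuple(a for a in range(3) if a != axis))
        extent = int(np.flatnonzero(proj)[-1] - np.flatnonzero(proj)[0] + 1)
        lam_vox = lam_vox + extent - int(round(D / sp))
        # keep at least one voxel of clear water between the envelopes
        lam_vox = max(lam_vox, extent + 1)
    return lam_vox


def place_layout(
    geom: VoxelGeometry,
    layout: LayoutSpec,
    domain: tuple[int, int, int],
) -> VoxelGeometry:
    """Place one or two copies of a voxel sponge into a flow domain.

    Flow runs along +x; bodies stand on the z=0 side (the solver adds the
    bottom wall plane).  IL duplicates the body downstream along x at
    separation ``lambda_``; SBS duplicates it transverse (along y); both
    copies are voxel-exact translations, so an SBS pair is mirror-symmetric
    about the mid-plane.  Raises on overlap or insufficient clearance.
    """
    D = 2 * geom.cavities[0].radius
    layout.validate(D)
    nx, ny, nz = domain
    bx, by, bz = geom.occupancy.shape
    sp = geom.spacing
    d_vox = D / sp
    lam_vox = effective_separation_vox(geom, layout)

    # body footprint centers (voxel indices, may be half-integer)
    bcx = (bx - 1) / 2.0
    bcy = (by - 1) / 2.0
    x0 = int(round(layout.upstream_margin * d_vox))   # first-body leading edge
    if layout.mode == "IL":
        positions = [(x0, (ny - by) // 2), (x0 + lam_vox, (ny - by) // 2)]
    elif layout.mode == "SBS":
        oy = (ny - by - lam_vox) // 2
        positions = [(x0, oy), (x0, oy + lam_vox)]
    else:
        positions = [(x0, (ny - by) // 2)]

    occ = np.zeros(domain, dtype=bool)
    labels = np.zeros(domain, dtype=np.uint8)
    masks: list[np.ndarray] = []
    cavities: list[CavityCylinder] = []
    clear_vox = d_vox  # required clearance on all sides, in voxels

    for b, (ox, oy) in enumerate(positions):
        if ox < 0 or oy < 0 or ox + bx > nx or oy + by > ny or bz + 1 > nz:
            raise ValueError(
                f"body {b + 1} at offset ({ox},{oy}) does not fit domain {domain}"
            )
        if ox < clear_vox - bx / 2 or nx - (ox + bx) < 0 or nz - bz < 1:
            raise ValueError("insufficient clearance around body")
        sl = (slice(ox, ox + bx), slice(oy, oy + by), slice(1, 1 + bz))
        if (occ[sl] & geom.occupancy).any():
            raise ValueError("bodies overlap at this separation")
        occ[sl] |= geom.occupancy
        labels[sl][geom.occupancy] = b + 1
        m = np.zeros(domain, dtype=bool)
        m[sl] = geom.cavity_masks[0]
        masks.append(m)
        c0 = geom.cavities[0]
        cavities.append(
            CavityCylinder(
                center_x=c0.center_x + ox * sp,
                center_y=c0.center_y + oy * sp,
                radius=c0.radius,
                z0=c0.z0 + 1 * sp,
                z1=c0.z1 + 1 * sp,
            )
        )

    # paired bodies must be disjoint before floor attachment
    if len(positions) == 2:
        n_comp = ndimage.label(occ)[1]
        if n_comp < 2:
            raise ValueError("paired bodies are in contact (not disjoint)")

    return VoxelGeometry(
        occupancy=occ,
        spacing=sp,
        origin=np.zeros(3),
        labels=labels,
        cavities=cavities,
        cavity_masks=masks,
    )


def export_stl(geom: VoxelGeometry, path: str) -> "trimesh.Trimesh":
    """Write a watertight triangulated isosurface of the occupancy as STL."""
    import trimesh
    from skimage import measure

    if not geom.occupancy.any():
        raise ValueError("cannot export an empty solid")
    vol = np.pad(geom.occupancy.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.5)
    verts = (verts - 1.0) * geom.spacing + geom.origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    mesh.export(path)
    return mesh


def _ray_parity_fill(
    verts: np.ndarray,
    faces: np.ndarray,
    lo: np.ndarray,
    spacing: float,
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Point-in-mesh by vertical ray parity, per voxel-center column.

    For every (x, y) column of voxel centers, z-crossings with the
    triangle soup are collected; centers below an odd number of crossings
    are inside.  Columns are offset by a tiny epsilon so rays do not pass
    exactly through triangle edges.
    """
    nx, ny, nz = shape
    eps = 1e-6 * spacing
    xs = lo[0] + spacing * np.arange(nx) + eps
    ys = lo[1] + spacing * np.arange(ny) + eps
    zs = lo[2] + spacing * np.arange(nz)
    crossings: list[list[float]] = [[] for _ in range(nx * ny)]
    tri = verts[faces]                     # (n_tri, 3, 3)
    for t in tri:
        x0, x1 = t[:, 0].min(), t[:, 0].max()
        y0, y1 = t[:, 1].min(), t[:, 1].max()
        i0, i1 = np.searchsorted(xs, [x0, x1])
        j0, j1 = np.searchsorted(ys, [y0, y1])
        if i0 == i1 or j0 == j1:
            continue
        gx, gy = np.meshgrid(xs[i0:i1], ys[j0:j1], indexing="ij")
        # barycentric coordinates in the (x, y) projection
        d = (t[1, 1] - t[2, 1]) * (t[0, 0] - t[2, 0]) + (
            t[2, 0] - t[1, 0]
        ) * (t[0, 1] - t[2, 1])
        if abs(d) < 1e-30:
            continue
        a = ((t[1, 1] - t[2, 1]) * (gx - t[2, 0])
             + (t[2, 0] - t[1, 0]) * (gy - t[2, 1])) / d
        b = ((t[2, 1] - t[0, 1]) * (gx - t[2, 0])
             + (t[0, 0] - t[2, 0]) * (gy - t[2, 1])) / d
        c = 1.0 - a - b
        hit = (a >= 0) & (b >= 0) & (c >= 0)
        if not hit.any():
            continue
        zhit = a * t[0, 2] + b * t[1, 2] + c * t[2, 2]
        for di, dj in zip(*np.nonzero(hit)):
            crossings[(i0 + di) * ny + (j0 + dj)].append(zhit[di, dj])
    out = np.zeros(shape, dtype=bool)
    for i in range(nx):
        for j in range(ny):
            cz = sorted(crossings[i * ny + j])
            if not cz:
                continue
            counts = np.searchsorted(cz, zs, side="left")
            out[i, j] = (counts % 2) == 1
    return out


def voxelize_stl(
    path: str, spacing: float, origin: np.ndarray | None = None
) -> VoxelGeometry:
    """Voxelize an STL surface on a grid of the given spacing.

    A voxel is solid iff its center lies inside the watertight surface.
    Passing the ``origin`` of a source voxel grid aligns the
    reconstruction with it (sub-voxel misalignment otherwise erodes
    members only one or two voxels thick).  Cavity metadata is not
    reconstructed.
    """
    import trimesh

    mesh = trimesh.load(path, force="mesh")
    lo, hi = mesh.bounds
    if origin is not None:
        # snap the grid onto the source lattice
        lo = origin + np.floor((lo - origin) / spacing) * spacing
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    inside = _ray_parity_fill(
        mesh.vertices.view(np.ndarray), mesh.faces.view(np.ndarray),
        lo, spacing, tuple(shape),
    )
    return VoxelGeometry(
        occupancy=inside,
        spacing=spacing,
        origin=np.asarray(lo, dtype=float),
        labels=inside.astype(np.uint8),
        cavities=[],
        cavity_masks=[],
    )
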
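"""Numba-compiled hot loop for the D3Q19 BGK solver.

One fused pass per step: gather (pull streaming with halfway bounce-back
and optional specular top), compute moments, BGK collision with optional
Guo forcing, write.  The numpy implementation in :mod:`spongeflow.lbm`
performs the same operations in the same per-node order and is asserted
bit-compatible in the tests; this kernel exists for single-core speed.
"""

from __future__ import annotations

import numba as nb
import numpy as np

from .stencil import C, MIRROR_Z, OPP, W

_CX = np.ascontiguousarray(C[:, 0])
_CY = np.ascontiguousarray(C[:, 1])
_CZ = np.ascontiguousarray(C[:, 2])
_W = np.ascontiguousarray(W)
_OPP = np.ascontiguousarray(OPP)
_MIRZ = np.ascontiguousarray(MIRROR_Z)


@nb.njit(cache=True, fastmath=False)
def fused_step(f, fnew, solid, tau, gx, gy, gz, periodic_z, top_freeslip):
    """Stream-then-collide: fnew = collide(stream(f)).

    ``f`` holds the post-collision populations of the previous step; after
    the call ``fnew`` holds those of this step.  y (and x) wrap
    periodically — open-channel inlet/outlet planes are overwritten by the
    caller; z wraps when ``periodic_z``, else the bottom is reached only
    through solid voxels (bounce-back) and the top reflects specularly
    when ``top_freeslip``.
    """
    nx, ny, nz = solid.shape
    omega = 1.0 / tau
    forced = gx != 0.0 or gy != 0.0 or gz != 0.0
    t = np.empty(19)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if solid[x, y, z]:
                    continue
                # gather: pull streaming with boundary rules
                for i in range(19):
                    xs = x - _CX[i]
                    if xs < 0:
                        xs += nx
                    elif xs >= nx:
                        xs -= nx
                    ys = y - _CY[i]
                    if ys < 0:
                        ys += ny
                    elif ys >= ny:
                        ys -= ny
                    zs = z - _CZ[i]
                    if zs >= nz:
                        if top_freeslip:
                            # halfway specular reflection at z = nz - 1/2
                            t[i] = f[_MIRZ[i], xs, ys, z]
                            continue
                        zs -= nz
                    elif zs < 0:
                        if periodic_z:
                            zs += nz
                        else:
                            # floorless channel: specular bottom (a solid
                            # floor plane never reaches this branch)
                            t[i] = f[_MIRZ[i], xs, ys, z]
                            continue
                    if solid[xs, ys, zs]:
                        # halfway bounce-back off the solid link
                        t[i] = f[_OPP[i], x, y, z]
                    else:
                        t[i] = f[i, xs, ys, zs]
                # moments
                rho = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(19):
                    fi = t[i]
                    rho += fi
                    mx += fi * _CX[i]
                    my += fi * _CY[i]
                    mz += fi * _CZ[i]
                ux = (mx + 0.5 * gx) / rho
                uy = (my + 0.5 * gy) / rho
                uz = (mz + 0.5 * gz) / rho
                usq = ux * ux + uy * uy + uz * uz
                ug = ux * gx + uy * gy + uz * gz
                # BGK collision (+ Guo forcing)
                for i in range(19):
                    cu = _CX[i] * ux + _CY[i] * uy + _CZ[i] * uz
                    feq = _W[i] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)
                    val = t[i] + omega * (feq - t[i])
                    if forced:
                        cg = _CX[i] * gx + _CY[i] * gy + _CZ[i] * gz
                        val += (1.0 - 0.5 * omega) * _W[i] * (
                            3.0 * (cg - ug) + 9.0 * cu * cg
                        )
                    fnew[i, x, y, z] = val
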
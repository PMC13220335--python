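"""Minimal ASCII VTK XML writers (ImageData .vti, PolyData .vtp).

Only the subset needed by this package: scalar/vector point data on a
uniform grid, and polyline point clouds with per-point scalars.  Files
open directly in ParaView.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_vti", "write_vtp_polylines", "write_vtp_points"]


def _data_array(name: str, arr: np.ndarray, n_comp: int) -> list[str]:
    flat = np.asarray(arr, dtype=np.float64).reshape(-1)
    body = " ".join(f"{v:.9g}" for v in flat)
    return [
        f'<DataArray type="Float64" Name="{name}" '
        f'NumberOfComponents="{n_comp}" format="ascii">',
        body,
        "</DataArray>",
    ]


def write_vti(
    path: str,
    fields: dict[str, np.ndarray],
    spacing: float = 1.0,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    comments: list[str] | None = None,
) -> None:
    """Write point-data fields on a uniform grid as VTK ImageData.

    Scalar fields have shape (nx, ny, nz); vector fields (3, nx, ny, nz).
    ``comments`` (e.g. unit-scaling header lines) are embedded as XML
    comments so downstream analysis is unit-unambiguous.
    """
    shapes = {
        k: (v.shape if v.ndim == 3 else v.shape[1:]) for k, v in fields.items()
    }
    if len(set(shapes.values())) != 1:
        raise ValueError(f"inconsistent field shapes: {shapes}")
    nx, ny, nz = next(iter(shapes.values()))
    lines = ['<?xml version="1.0"?>']
    for c in comments or []:
        lines.append(f"<!-- {c} -->")
    ext = f"0 {nx - 1} 0 {ny - 1} 0 {nz - 1}"
    lines += [
        '<VTKFile type="ImageData" version="0.1" byte_order="LittleEndian">',
        f'<ImageData WholeExtent="{ext}" Origin="{origin[0]} {origin[1]} '
        f'{origin[2]}" Spacing="{spacing} {spacing} {spacing}">',
        f'<Piece Extent="{ext}">',
        "<PointData>",
    ]
    for name, arr in fields.items():
        if arr.ndim == 3:
            # VTK expects x fastest; our arrays are (x, y, z) C-order
            lines += _data_array(name, np.transpose(arr, (2, 1, 0)), 1)
        else:
            lines += _data_array(
                name, np.transpose(arr, (3, 2, 1, 0)).reshape(-1, 3), 3
            )
    lines += ["</PointData>", "</Piece>", "</ImageData>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def _vtp(path: str, points: np.ndarray, point_data: dict[str, np.ndarray],
         lines_xml: list[str], n_lines: int, comments: list[str] | None) -> None:
    out = ['<?xml version="1.0"?>']
    for c in comments or []:
        out.append(f"<!-- {c} -->")
    out += [
        '<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">',
        "<PolyData>",
        f'<Piece NumberOfPoints="{len(points)}" NumberOfVerts="0" '
        f'NumberOfLines="{n_lines}" NumberOfStrips="0" NumberOfPolys="0">',
        "<Points>",
    ]
    out += _data_array("Points", points, 3)
    out += ["</Points>", "<PointData>"]
    for name, arr in point_data.items():
        out += _data_array(name, arr, 1 if arr.ndim == 1 else arr.shape[1])
    out += ["</PointData>"] + lines_xml + ["</Piece>", "</PolyData>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(out))


def write_vtp_polylines(
    path: str,
    polylines: list[np.ndarray],
    point_data: dict[str, list[np.ndarray]] | None = None,
    comments: list[str] | None = None,
) -> None:
    """Write a list of (n_i, 3) polylines as VTK PolyData."""
    pts = np.vstack(polylines)
    offsets = np.cumsum([len(p) for p in polylines])
    conn = " ".join(str(i) for i in range(len(pts)))
    offs = " ".join(str(o) for o in offsets)
    lines_xml = [
        "<Lines>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        conn,
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        offs,
        "</DataArray>",
        "</Lines>",
    ]
    pd = {}
    for name, chunks in (point_data or {}).items():
        pd[name] = np.concatenate([np.asarray(c) for c in chunks])
    _vtp(path, pts, pd, lines_xml, len(polylines), comments)


def write_vtp_points(
    path: str,
    points: np.ndarray,
    point_data: dict[str, np.ndarray] | None = None,
    comments: list[str] | None = None,
) -> None:
    """Write a point cloud (e.g. wall tractions) as VTK PolyData."""
    _vtp(path, np.asarray(points, dtype=float), dict(point_data or {}),
         [], 0, comments)
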
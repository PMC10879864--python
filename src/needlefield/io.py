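"""Surface mesh file I/O (OFF / STL / PLY) and VTK legacy scalar-field export.

Mesh reading and writing is delegated to :mod:`trimesh`; all formats are
written in plain text (ASCII) variants so artifacts stay inspectable, except
STL which may also be read in binary form.  The VTK legacy writer produces
version 3.0 ASCII POLYDATA files with one ``POINT_DATA`` SCALARS block, the
format used for field maps on the brain surface.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import trimesh

from .surfaces import TriSurface

__all__ = [
    "read_surface",
    "write_surface",
    "export_scalar_field",
    "read_scalar_field",
    "SUPPORTED_FORMATS",
]

SUPPORTED_FORMATS = ("off", "stl", "ply")


def _format_from_path(path: os.PathLike | str, fmt: str | None) -> str:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(
            f"unsupported mesh format {fmt!r}; expected one of {SUPPORTED_FORMATS}"
        )
    return fmt


def read_surface(path: os.PathLike | str, format: str | None = None) -> TriSurface:
    """Read a closed triangle mesh from an OFF, STL or PLY file."""
    fmt = _format_from_path(path, format)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        mesh = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # normalise loader errors
        raise ValueError(f"malformed {fmt.upper()} file {path}: {exc}") from exc
    faces = np.asarray(mesh.faces)
    if faces.size == 0:
        raise ValueError(f"malformed {fmt.upper()} file {path}: no faces parsed")
    if faces.shape[1] != 3:
        raise ValueError(f"{path}: only triangle meshes are supported")
    return TriSurface(np.asarray(mesh.vertices), faces, name=path.stem)


def write_surface(
    surface: TriSurface, path: os.PathLike | str, format: str | None = None
) -> None:
    """Write a surface as OFF, ASCII STL or ASCII PLY."""
    fmt = _format_from_path(path, format)
    mesh = trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.triangles, process=False
    )
    if fmt == "ply":
        data = mesh.export(file_type="ply", encoding="ascii")
    else:
        data = mesh.export(file_type=fmt)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def export_scalar_field(
    surface: TriSurface,
    field: np.ndarray,
    path: os.PathLike | str,
    name: str = "field",
) -> None:
    """Write a per-vertex scalar field as a VTK legacy ASCII POLYDATA file."""
    field = np.asarray(field, dtype=np.float64).ravel()
    if len(field) != surface.n_vertices:
        raise ValueError(
            f"field length {len(field)} != vertex count {surface.n_vertices}"
        )
    t = surface.triangles
    lines = [
        "# vtk DataFile Version 3.0",
        f"needlefield scalar field: {name}",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {surface.n_vertices} float",
    ]
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in surface.vertices]
    lines.append(f"POLYGONS {surface.n_triangles} {4 * surface.n_triangles}")
    lines += [f"3 {a} {b} {c}" for a, b, c in t]
    lines += [
        f"POINT_DATA {surface.n_vertices}",
        f"SCALARS {name} float 1",
        "LOOKUP_TABLE default",
    ]
    lines += [f"{v:.9g}" for v in field]
    Path(path).write_text("\n".join(lines) + "\n")


def read_scalar_field(path: os.PathLike | str) -> tuple[TriSurface, np.ndarray]:
    """Parse a VTK legacy ASCII file written by :func:`export_scalar_field`."""
    tokens_lines = Path(path).read_text().splitlines()
    i = 0

    def expect(prefix: str) -> str:
        nonlocal i
        while i < len(tokens_lines) and not tokens_lines[i].strip():
            i += 1
        if i >= len(tokens_lines) or not tokens_lines[i].startswith(prefix):
            raise ValueError(f"{path}: expected {prefix!r} at line {i + 1}")
        line = tokens_lines[i]
        i += 1
        return line

    expect("# vtk DataFile")
    i += 1  # title line
    expect("ASCII")
    expect("DATASET POLYDATA")
    n_pts = int(expect("POINTS").split()[1])
    verts = np.array(
        [tokens_lines[i + k].split() for k in range(n_pts)], dtype=np.float64
    )
    i += n_pts
    n_poly = int(expect("POLYGONS").split()[1])
    faces = np.array(
        [tokens_lines[i + k].split()[1:] for k in range(n_poly)], dtype=np.int64
    )
    i += n_poly
    expect("POINT_DATA")
    name = expect("SCALARS").split()[1]
    expect("LOOKUP_TABLE")
    field = np.array(tokens_lines[i : i + n_pts], dtype=np.float64)
    return TriSurface(verts, faces, name=name), field
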
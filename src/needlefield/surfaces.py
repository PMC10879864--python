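"""Triangulated compartment surfaces and their validity diagnostics.

A :class:`TriSurface` is a closed, outward-oriented triangle mesh bounding one
head compartment, with coordinates in millimetres.  Everything downstream
(electrode placement, the boundary-element solver, geodesic focality metrics)
assumes the invariants checked by :func:`validate_surface`:

* every edge is shared by exactly two triangles (closed 2-manifold),
* the two triangles traverse each shared edge in opposite directions
  (consistent winding),
* the enclosed signed volume is positive (outward orientation),
* no degenerate (zero-area) triangles,
* Euler characteristic ``V - E + F == 2`` (topological sphere).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "TriSurface",
    "SurfaceReport",
    "validate_surface",
    "triangle_areas",
    "triangle_normals",
    "vertex_normals",
    "vertex_areas",
    "signed_volume",
    "edge_lengths",
    "surface_area",
    "vertex_adjacency",
]

_MIN_TRIANGLE_AREA = 1e-12  # mm^2


@dataclass
class TriSurface:
    """Closed triangle mesh of one compartment boundary (mm coordinates)."""

    vertices: np.ndarray  # (n_vertices, 3) float64, mm
    triangles: np.ndarray  # (n_triangles, 3) int64, 0-based
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be an (m, 3) array")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def copy(self) -> "TriSurface":
        return TriSurface(self.vertices.copy(), self.triangles.copy(), self.name)


@dataclass
class SurfaceReport:
    """Deterministic diagnostic report from :func:`validate_surface`."""

    ok: bool
    violations: list[str] = field(default_factory=list)
    #: offending simplices per violation category (edge tuples or triangle ids)
    offenders: dict[str, list] = field(default_factory=dict)

    def __bool__(self) -> bool:  # truthy iff the surface is valid
        return self.ok


def triangle_areas(surface: TriSurface) -> np.ndarray:
    v = surface.vertices
    t = surface.triangles
    cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def triangle_normals(surface: TriSurface, normalized: bool = True) -> np.ndarray:
    v = surface.vertices
    t = surface.triangles
    cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    if normalized:
        norms = np.linalg.norm(cross, axis=1, keepdims=True)
        norms[norms == 0.0] = 1.0
        return cross / norms
    return cross


def vertex_normals(surface: TriSurface) -> np.ndarray:
    """Area-weighted outward vertex normals (unit length)."""
    n = np.zeros_like(surface.vertices)
    face_n = triangle_normals(surface, normalized=False)  # area-weighted
    for k in range(3):
        np.add.at(n, surface.triangles[:, k], face_n)
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return n / norms


def vertex_areas(surface: TriSurface) -> np.ndarray:
    """Barycentric vertex areas (1/3 of each incident triangle), mm^2."""
    areas = triangle_areas(surface)
    out = np.zeros(surface.n_vertices)
    for k in range(3):
        np.add.at(out, surface.triangles[:, k], areas / 3.0)
    return out


def surface_area(surface: TriSurface) -> float:
    return float(triangle_areas(surface).sum())


def signed_volume(surface: TriSurface) -> float:
    """Signed enclosed volume (positive for outward-oriented surfaces), mm^3."""
    v = surface.vertices
    t = surface.triangles
    return float(
        np.einsum("ij,ij->i", v[t[:, 0]], np.cross(v[t[:, 1]], v[t[:, 2]])).sum() / 6.0
    )


def edge_lengths(surface: TriSurface) -> np.ndarray:
    """Lengths of the unique undirected edges, mm."""
    t = surface.triangles
    e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    return np.linalg.norm(surface.vertices[e[:, 0]] - surface.vertices[e[:, 1]], axis=1)


def vertex_adjacency(surface: TriSurface) -> list[np.ndarray]:
    """One-ring vertex neighbours for each vertex."""
    t = surface.triangles
    pairs = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    pairs = np.unique(np.sort(pairs, axis=1), axis=0)
    neighbours: list[list[int]] = [[] for _ in range(surface.n_vertices)]
    for a, b in pairs:
        neighbours[a].append(b)
        neighbours[b].append(a)
    return [np.asarray(sorted(n), dtype=np.int64) for n in neighbours]


def _directed_edges(triangles: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
    )


def validate_surface(surface: TriSurface) -> SurfaceReport:
    """Check all TriSurface invariants; violations name the offending simplices."""
    if surface.n_triangles == 0:
        raise ValueError("cannot validate an empty mesh")

    violations: list[str] = []
    offenders: dict[str, list] = {}

    directed = _directed_edges(surface.triangles)
    und = np.sort(directed, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)

    bad_count = uniq[counts != 2]
    if len(bad_count):
        violations.append("non-manifold or boundary edges (edge not shared by exactly 2 triangles)")
        offenders["edges"] = [tuple(int(i) for i in e) for e in bad_count[:20]]

    # Consistent winding: each undirected edge appears once in each direction.
    d_uniq, d_counts = np.unique(directed, axis=0, return_counts=True)
    dup_directed = d_uniq[d_counts > 1]
    if len(dup_directed):
        violations.append("inconsistent winding (edge traversed twice in the same direction)")
        offenders.setdefault("winding_edges", []).extend(
            tuple(int(i) for i in e) for e in dup_directed[:20]
        )

    areas = triangle_areas(surface)
    degenerate = np.flatnonzero(areas <= _MIN_TRIANGLE_AREA)
    if len(degenerate):
        violations.append("zero-area triangles")
        offenders["triangles"] = [int(i) for i in degenerate[:20]]

    n_edges = len(uniq)
    euler = surface.n_vertices - n_edges + surface.n_triangles
    if euler != 2:
        violations.append(f"Euler characteristic V-E+F = {euler}, expected 2")

    # Orientation is only meaningful for a closed, consistently wound surface.
    if not len(bad_count) and not len(dup_directed):
        if signed_volume(surface) <= 0.0:
            violations.append("inward orientation (signed volume <= 0)")

    return SurfaceReport(ok=not violations, violations=violations, offenders=offenders)


def require_valid(surface: TriSurface) -> None:
    """Raise ``ValueError`` with the diagnostic list if the surface is invalid."""
    report = validate_surface(surface)
    if not report.ok:
        raise ValueError(
            f"invalid surface {surface.name!r}: " + "; ".join(report.violations)
        )


def points_inside(surface: TriSurface, points: Iterable) -> np.ndarray:
    """Boolean mask of points strictly inside a closed surface (winding number)."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    total = np.zeros(len(pts))
    v = surface.vertices
    # Solid angle of each triangle seen from each point; inside iff sum ~ 4*pi.
    from .bem import triangle_solid_angles  # local import to avoid cycle at import time

    for tri in surface.triangles:
        total += triangle_solid_angles(v[tri[0]], v[tri[1]], v[tri[2]], pts)
    return total > 2.0 * np.pi  # inside: 4*pi, outside: 0
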
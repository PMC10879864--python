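"""Discrete boundary-integral operator blocks.

Single-layer (S), double-layer (D) and their principal-value variants over
triangulated surfaces, with vertex collocation and triangle-mean (1/3 vertex
lumping) densities.  Double layers use the analytically exact van Oosterom &
Strackee solid angles (see :mod:`.bem`); single layers use subdivided-triangle
quadrature with an exact closed form for the singular own-vertex integrals.
All operators include the 1/(4 pi) factor; lengths in mm.
"""

from __future__ import annotations

import numpy as np

from .surfaces import TriSurface, triangle_areas

__all__ = [
    "double_layer_pv",
    "double_layer",
    "single_layer_rows",
    "subdivide_triangles",
]


def double_layer_pv(surf: TriSurface) -> np.ndarray:
    """PV double-layer matrix (1/4pi) PV int V dOmega on the surface's own
    vertices, closed with the auto-solid-angle identity (row sums = 1/2)."""
    from .bem import solid_angle_block

    pts = surf.vertices
    n = surf.n_vertices
    tris = surf.triangles
    tri_xyz = pts[tris]
    M = np.zeros((n, n))
    omega_total = np.zeros(n)
    block = max(1, int(4.0e5 / n))
    for start in range(0, len(tris), block):
        om = solid_angle_block(tri_xyz[start : start + block], pts)
        omega_total += om.sum(axis=0)
        for k in range(3):
            np.add.at(M.T, tris[start : start + block, k], om / 3.0)
    idx = np.arange(n)
    M[idx, idx] += 2.0 * np.pi - omega_total
    return M / (4.0 * np.pi)


def double_layer(surf: TriSurface, points: np.ndarray) -> np.ndarray:
    """Smooth double-layer matrix (1/4pi) int V dOmega at off-surface points."""
    from .bem import solid_angle_block

    tris = surf.triangles
    tri_xyz = surf.vertices[tris]
    M = np.zeros((len(points), surf.n_vertices))
    block = max(1, int(4.0e5 / max(len(points), 1)))
    for start in range(0, len(tris), block):
        om = solid_angle_block(tri_xyz[start : start + block], points)
        for k in range(3):
            np.add.at(M.T, tris[start : start + block, k], om / 3.0)
    return M / (4.0 * np.pi)


def subdivide_triangles(tri_xyz: np.ndarray, levels: int) -> np.ndarray:
    """Split each triangle into 4^levels subtriangles; (T, 3, 3) -> (T*4^l, 3, 3)."""
    out = tri_xyz
    for _ in range(levels):
        a, b, c = out[:, 0], out[:, 1], out[:, 2]
        ab, bc, ca = (a + b) / 2, (b + c) / 2, (c + a) / 2
        # children stay contiguous per parent triangle
        out = np.stack(
            [
                np.stack([a, ab, ca], axis=1),
                np.stack([ab, b, bc], axis=1),
                np.stack([ca, bc, c], axis=1),
                np.stack([ab, bc, ca], axis=1),
            ],
            axis=1,
        ).reshape(-1, 3, 3)
    return out


def _vertex_singular_integral(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Exact integral of 1/|r' - p| over the triangle (p, a, b)."""
    ab = b - a
    lab = np.linalg.norm(ab)
    if lab < 1e-300:
        return 0.0
    t = -(a - p) @ ab / lab**2
    foot = a + t * ab
    d = np.linalg.norm(foot - p)
    if d < 1e-14 * max(np.linalg.norm(a - p), np.linalg.norm(b - p)):
        return 0.0  # degenerate sliver
    phi_a = np.arctan2(-t * lab, d)
    phi_b = np.arctan2((1 - t) * lab, d)
    # polar integration around p: int R(phi) dphi with R = d / cos(phi)
    return float(d * (np.arcsinh(np.tan(phi_b)) - np.arcsinh(np.tan(phi_a))))


def single_layer_rows(
    src: TriSurface,
    points: np.ndarray,
    own_vertex_indices: np.ndarray | None = None,
    quad_levels: int = 1,
    near_levels: int = 3,
    near_factor: float = 2.0,
) -> np.ndarray:
    """Matrix (P, n_src) mapping vertex densities eta to (1/4pi) int eta / d.

    Quadrature uses 4^quad_levels sub-centroids, refined to 4^near_levels
    when the target lies within two triangle diameters; when
    ``own_vertex_indices[i]`` names the source vertex coinciding with
    collocation point i, incident triangles use the exact vertex integral.
    """
    tris = src.triangles
    verts = src.vertices
    tri_xyz = verts[tris]
    P = len(points)
    T = len(tris)
    contrib = np.zeros((T, P))  # int_T 1/d dS' per (triangle, point)
    areas = triangle_areas(src)
    diam = np.max(
        np.linalg.norm(tri_xyz - np.roll(tri_xyz, 1, axis=1), axis=2), axis=1
    )

    # far field: blocked sub-centroid quadrature over all pairs
    n_sub = 4**quad_levels
    block = max(1, int(4.0e5 / max(P * n_sub, 1)) or 1)
    centroids = tri_xyz.mean(axis=1)
    for start in range(0, T, max(block, 1)):
        stop = min(start + max(block, 1), T)
        sub = subdivide_triangles(tri_xyz[start:stop], quad_levels)
        sc = sub.mean(axis=1).reshape(stop - start, n_sub, 3)
        d = np.linalg.norm(sc[:, :, None, :] - points[None, None, :, :], axis=3)
        contrib[start:stop] = (1.0 / d).sum(axis=1) * (
            areas[start:stop, None] / n_sub
        )

    # near field: refine pairs closer than near_factor triangle diameters
    d0 = np.linalg.norm(centroids[:, None, :] - points[None, :, :], axis=2)
    near_t, near_p = np.nonzero(d0 < near_factor * diam[:, None])
    own = own_vertex_indices
    incident = None
    if own is not None:
        incident = [set() for _ in range(src.n_vertices)]
        for t, tri in enumerate(tris):
            for v in tri:
                incident[v].add(t)
    for t in np.unique(near_t):
        idx = near_p[near_t == t]
        sub = subdivide_triangles(tri_xyz[t : t + 1], near_levels)
        sc = sub.mean(axis=1)
        sa = areas[t] / len(sub)
        d = np.linalg.norm(points[idx][:, None, :] - sc[None, :, :], axis=2)
        vals = sa * (1.0 / d).sum(axis=1)
        if own is not None:
            for kk, i in enumerate(idx):
                vi = own[i]
                if vi >= 0 and t in incident[vi]:
                    tri = tris[t]
                    k = int(np.flatnonzero(tri == vi)[0])
                    vals[kk] = _vertex_singular_integral(
                        verts[tri[k]], verts[tri[(k + 1) % 3]], verts[tri[(k + 2) % 3]]
                    )
        contrib[t, idx] = vals

    out = np.zeros((P, src.n_vertices))
    w = contrib.T / (4.0 * np.pi) / 3.0
    for k in range(3):
        np.add.at(out.T, tris[:, k], w.T)
    return out
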
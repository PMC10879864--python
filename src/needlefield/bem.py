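"""Boundary-element solver for quasi-static volume conduction.

The head is a piecewise-homogeneous conductor with nested compartment
boundaries; injected currents are impressed point sources (patch centroids and
needle tips).  The potential satisfies Laplace's equation in each compartment
with continuity of V and of normal current across interfaces, which the
Geselowitz surface-integral identity turns into a second-kind equation on the
interfaces:

    (sigma_k^- + sigma_k^+)/2 * V(r)
        = g(r) + 1/(4 pi) * sum_l (sigma_l^- - sigma_l^+)
                 int_{S_l} V(r') dOmega_r(r'),

where g(r) = sum_s I_s / (4 pi |r - r_s|) is the impressed-source term and
dOmega is the (signed) solid angle seen from the collocation point.

Discretisation: collocation at mesh vertices; the potential is piecewise
linear and each triangle's analytically exact solid angle (van Oosterom &
Strackee) is lumped in thirds onto its vertices; the own-vertex singular
contribution is closed with the auto-solid-angle identity (the row sum over
the collocation point's own surface must equal 2 pi), which makes the
constant vector an exact nullvector of the operator.  The nullspace is
removed by rank-one deflation and the system solved by dense LU; the
reported potentials use a zero-mean gauge over all interface vertices.

Units: geometry in mm, currents in uA, conductivities in S/m, potentials in
volts, E in V/m, current density in A/m^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .electrodes import SourceTerms
from .head import HeadModel
from .surfaces import (
    TriSurface,
    vertex_adjacency,
    vertex_areas,
    vertex_normals,
)

__all__ = [
    "BemSystem",
    "FieldSolution",
    "assemble_system",
    "solve",
    "surface_fields",
    "triangle_solid_angles",
    "solid_angle_block",
    "solid_angle_gradient_block",
    "evaluate_interior_potential",
    "evaluate_interior_gradient",
    "interface_net_flux",
    "DEFAULT_VERTEX_BUDGET",
]

_NET_CURRENT_TOL = 1e-9  # uA
DEFAULT_VERTEX_BUDGET = 20_000  # total interface vertices for the dense solve

_UA_MM_TO_V = 1e-3  # (uA/mm) / (S/m) -> volts


def triangle_solid_angles(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Signed solid angle of one triangle seen from each point.

    Positive when the outward (right-handed winding) face is seen from
    behind, i.e. the angles of a closed outward surface sum to 4 pi at
    interior points and 0 at exterior points.
    """
    pts = np.atleast_2d(points)
    v1 = p0 - pts
    v2 = p1 - pts
    v3 = p2 - pts
    l1 = np.linalg.norm(v1, axis=1)
    l2 = np.linalg.norm(v2, axis=1)
    l3 = np.linalg.norm(v3, axis=1)
    num = np.einsum("ij,ij->i", v1, np.cross(v2, v3))
    den = (
        l1 * l2 * l3
        + np.einsum("ij,ij->i", v1, v2) * l3
        + np.einsum("ij,ij->i", v1, v3) * l2
        + np.einsum("ij,ij->i", v2, v3) * l1
    )
    return 2.0 * np.arctan2(num, den)


def solid_angle_block(tri_xyz: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Solid angles of a block of triangles (T, 3, 3) at points (P, 3) -> (T, P)."""
    v1 = tri_xyz[:, None, 0, :] - points[None, :, :]
    v2 = tri_xyz[:, None, 1, :] - points[None, :, :]
    v3 = tri_xyz[:, None, 2, :] - points[None, :, :]
    l1 = np.linalg.norm(v1, axis=2)
    l2 = np.linalg.norm(v2, axis=2)
    l3 = np.linalg.norm(v3, axis=2)
    num = np.einsum("tpi,tpi->tp", v1, np.cross(v2, v3))
    den = (
        l1 * l2 * l3
        + np.einsum("tpi,tpi->tp", v1, v2) * l3
        + np.einsum("tpi,tpi->tp", v1, v3) * l2
        + np.einsum("tpi,tpi->tp", v2, v3) * l1
    )
    return 2.0 * np.arctan2(num, den)


def _segment_integral(a: np.ndarray, b: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Closed form of the line integral int_a^b dl' x (r - r') / |r - r'|^3
    for each point r (the Biot-Savart segment kernel), shape (P, 3)."""
    A = a[None, :] - points
    B = b[None, :] - points
    la = np.linalg.norm(A, axis=1)
    lb = np.linalg.norm(B, axis=1)
    cross = np.cross(A, B)
    den = la * lb * (la * lb + np.einsum("ij,ij->i", A, B))
    den = np.where(np.abs(den) < 1e-300, np.inf, den)
    return cross * ((la + lb) / den)[:, None]


def solid_angle_gradient_block(tri_xyz: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Gradient (w.r.t. the observation point) of each triangle's solid angle,
    shape (T, P, 3); exact per-edge closed forms."""
    T = len(tri_xyz)
    P = len(points)
    out = np.zeros((T, P, 3))
    for t in range(T):
        g = np.zeros((P, 3))
        for k in range(3):
            a = tri_xyz[t, k]
            b = tri_xyz[t, (k + 1) % 3]
            g += _segment_integral(a, b, points)
        out[t] = g
    return out


@dataclass
class BemSystem:
    """Assembled boundary operator(s) with LU factorisation.

    In ``direct`` mode ``matrix`` is the deflated dense second-kind
    transmission operator over all interface vertices.  In ``multidomain``
    mode (auto-selected when an interface conductivity contrast exceeds the
    threshold, e.g. the skull) ``interior`` holds the coupled explicit-flux
    system of :class:`~needlefield.multidomain.MultiDomainSystem` and
    ``matrix`` is its operator.
    """

    head: HeadModel
    matrix: np.ndarray  # deflated operator of the active formulation
    lu: tuple = field(repr=False, default=None)
    offsets: list[int] = field(default_factory=list)
    half_sigma: np.ndarray = None  # (sigma^- + sigma^+)/2 per vertex
    sigma_jump: np.ndarray = None  # (sigma^- - sigma^+) per vertex
    points: np.ndarray = None  # all interface vertices, mm
    deflated: bool = True
    mode: str = "direct"  # direct | multidomain
    interior: object = field(default=None, repr=False)

    @property
    def n_total(self) -> int:
        return len(self.points)

    def surface_slice(self, index: int) -> slice:
        return slice(self.offsets[index], self.offsets[index + 1])


@dataclass
class FieldSolution:
    """Interface potentials and derived brain-surface fields for one montage."""

    system: BemSystem = field(repr=False)
    potentials: np.ndarray  # (n_total,) volts, zero-mean gauge
    brain_E: np.ndarray  # (n_brain, 3) V/m, tangential
    brain_J_mag: np.ndarray  # (n_brain,) A/m^2
    sources: object = None  # SourceTerms or (positions, currents)
    #: multidomain mode: normal derivative dV/dn (V/mm) per interior interface
    interface_flux: list = None

    def surface_potential(self, index: int) -> np.ndarray:
        return self.potentials[self.system.surface_slice(index)]

    @property
    def brain_potential(self) -> np.ndarray:
        return self.surface_potential(len(self.system.head.compartments) - 1)


def _interface_sigmas(head: HeadModel) -> list[tuple[float, float]]:
    """(sigma_inside, sigma_outside) per surface, outside-in."""
    out = []
    for l, (_, sigma_in) in enumerate(head.compartments):
        sigma_out = head.compartments[l - 1][1] if l > 0 else 0.0
        out.append((sigma_in, sigma_out))
    return out


def _assemble_operator(
    surfaces: list[TriSurface], sig: list[tuple[float, float]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int], np.ndarray]:
    """Dense deflated transmission operator for surfaces with given
    (sigma_inside, sigma_outside) pairs; returns (matrix, half, jump,
    offsets, points)."""
    n_per = [s.n_vertices for s in surfaces]
    n_total = sum(n_per)
    offsets = [0]
    for n in n_per:
        offsets.append(offsets[-1] + n)
    points = np.concatenate([s.vertices for s in surfaces])

    half = np.concatenate(
        [np.full(n, (si + so) / 2.0) for n, (si, so) in zip(n_per, sig)]
    )
    jump = np.concatenate([np.full(n, si - so) for n, (si, so) in zip(n_per, sig)])

    # AT[j, i] accumulates the operator transposed (column scatter is cheap).
    AT = np.zeros((n_total, n_total))
    block = max(1, int(4.0e5 / max(n_total, 1)))
    for l, surf in enumerate(surfaces):
        off = offsets[l]
        tris = surf.triangles
        tri_xyz = surf.vertices[tris]
        c_l = sig[l][0] - sig[l][1]
        scale = -c_l / (4.0 * np.pi) / 3.0
        omega_total = np.zeros(n_total)
        for start in range(0, len(tris), block):
            tb = tris[start : start + block]
            om = solid_angle_block(tri_xyz[start : start + block], points)
            omega_total += om.sum(axis=0)
            for k in range(3):
                np.add.at(AT, off + tb[:, k], scale * om)
        # Auto-solid-angle closure: own-surface row sums must equal 2 pi.
        deficit = 2.0 * np.pi - omega_total[offsets[l] : offsets[l + 1]]
        idx = np.arange(offsets[l], offsets[l + 1])
        AT[idx, idx] += -c_l / (4.0 * np.pi) * deficit

    idx = np.arange(n_total)
    AT[idx, idx] += half

    beta = float(half.mean())
    AT += beta / n_total  # rank-one deflation of the constant nullvector
    return AT.T, half, jump, offsets, points


def assemble_system(
    head: HeadModel,
    validate: bool = True,
    vertex_budget: int = DEFAULT_VERTEX_BUDGET,
    factorize: bool = True,
    mode: str = "auto",
) -> BemSystem:
    """Assemble (and LU-factorise) the boundary operator(s).

    ``mode='auto'`` selects the explicit-flux multi-domain scheme whenever an
    interface conductivity ratio exceeds the contrast threshold (the skull
    case); ``'direct'`` and ``'multidomain'`` force either scheme.
    """
    from .multidomain import MultiDomainSystem, needs_multidomain

    if validate:
        head.validate()
    surfaces = head.surfaces
    n_total = sum(s.n_vertices for s in surfaces)
    if n_total > vertex_budget:
        raise ResourceWarning(
            f"{n_total} interface vertices exceed the dense-solve budget "
            f"of {vertex_budget}"
        )
    sig = _interface_sigmas(head)

    if mode not in ("auto", "direct", "multidomain"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "multidomain" if needs_multidomain(head.conductivities) else "direct"

    if mode == "direct":
        matrix, half, jump, offs, pts = _assemble_operator(surfaces, sig)
        lu = lu_factor(matrix, overwrite_a=False) if factorize else None
        return BemSystem(
            head=head,
            matrix=matrix,
            lu=lu,
            offsets=offs,
            half_sigma=half,
            sigma_jump=jump,
            points=pts,
            mode="direct",
        )

    md = MultiDomainSystem.assemble(head, factorize=factorize)
    offsets = [0]
    for s in surfaces:
        offsets.append(offsets[-1] + s.n_vertices)
    points = np.concatenate([s.vertices for s in surfaces])
    half = np.concatenate(
        [np.full(s.n_vertices, (si + so) / 2.0) for s, (si, so) in zip(surfaces, sig)]
    )
    jump = np.concatenate(
        [np.full(s.n_vertices, si - so) for s, (si, so) in zip(surfaces, sig)]
    )
    return BemSystem(
        head=head,
        matrix=md.matrix,
        lu=None,
        offsets=offsets,
        half_sigma=half,
        sigma_jump=jump,
        points=points,
        mode="multidomain",
        interior=md,
    )


def _source_arrays(sources) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(sources, SourceTerms):
        return sources.point_sources()
    pos, cur = sources
    return np.atleast_2d(np.asarray(pos, float)), np.atleast_1d(np.asarray(cur, float))


def _free_term(points: np.ndarray, pos: np.ndarray, cur: np.ndarray) -> np.ndarray:
    """g(r) = sum_s I_s / (4 pi |r - r_s|), in uA/mm."""
    g = np.zeros(len(points))
    for p, I in zip(pos, cur):
        d = np.linalg.norm(points - p, axis=1)
        if (d < 1e-12).any():
            raise ValueError("impressed point source coincides with a mesh vertex")
        g += I / (4.0 * np.pi * d)
    return g


def solve(system: BemSystem, sources) -> FieldSolution:
    """Solve for interface potentials and brain-surface fields.

    ``sources`` is a :class:`~needlefield.electrodes.SourceTerms` bundle or a
    ``(positions_mm, currents_uA)`` pair.  The net impressed current must be
    zero (solvability of the interior Neumann problem).
    """
    pos, cur = _source_arrays(sources)
    net = float(cur.sum()) if len(cur) else 0.0
    if abs(net) > _NET_CURRENT_TOL:
        raise ValueError(f"net impressed current {net} uA violates solvability")
    if system.mode == "direct" and system.lu is None:
        raise ValueError("system was assembled with factorize=False")

    n_brain = system.head.brain.n_vertices
    if len(cur) == 0 or np.all(cur == 0.0):
        V = np.zeros(system.n_total)
        return FieldSolution(
            system=system,
            potentials=V,
            brain_E=np.zeros((n_brain, 3)),
            brain_J_mag=np.zeros(n_brain),
            sources=sources,
        )

    if system.mode == "direct":
        g = _free_term(system.points, pos, cur) * _UA_MM_TO_V
        V = lu_solve(system.lu, g)
        phi = None
    else:
        V_list, phi = system.interior.solve_potentials(sources)
        V = np.concatenate(V_list)
    V = V - V.mean()  # zero-mean gauge

    brain = system.head.brain
    Vb = V[system.surface_slice(len(system.head.compartments) - 1)]
    E, Jmag = surface_fields(brain, Vb, system.head.brain_conductivity)
    return FieldSolution(
        system=system,
        potentials=V,
        brain_E=E,
        brain_J_mag=Jmag,
        sources=sources,
        interface_flux=phi,
    )


def surface_fields(
    surface: TriSurface, V: np.ndarray, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex tangential E (V/m) and |J| = sigma |E| (A/m^2) from V (volts).

    E is the negative tangent-plane gradient of a linear least-squares fit of
    V over each vertex one-ring.
    """
    V = np.asarray(V, dtype=np.float64)
    if len(V) != surface.n_vertices:
        raise ValueError("potential length does not match vertex count")
    normals = vertex_normals(surface)
    neighbours = vertex_adjacency(surface)
    verts_m = surface.vertices * 1e-3  # mm -> m
    E = np.zeros((surface.n_vertices, 3))
    for i, nbrs in enumerate(neighbours):
        if len(nbrs) < 2:
            raise ValueError(f"vertex {i} has no usable one-ring")
        n = normals[i]
        D = verts_m[nbrs] - verts_m[i]
        D_t = D - np.outer(D @ n, n)
        # orthonormal tangent basis
        t1 = D_t[np.argmax(np.linalg.norm(D_t, axis=1))]
        norm_t1 = np.linalg.norm(t1)
        if norm_t1 < 1e-15:
            raise ValueError(f"degenerate tangent plane at vertex {i}")
        t1 = t1 / norm_t1
        t2 = np.cross(n, t1)
        a = D_t @ t1
        b = D_t @ t2
        dv = V[nbrs] - V[i]
        m11 = a @ a
        m12 = a @ b
        m22 = b @ b
        det = m11 * m22 - m12 * m12
        if det <= 1e-30 * max(m11 * m22, 1e-300):
            raise ValueError(f"rank-deficient one-ring at vertex {i}")
        r1 = a @ dv
        r2 = b @ dv
        g1 = (m22 * r1 - m12 * r2) / det
        g2 = (m11 * r2 - m12 * r1) / det
        E[i] = -(g1 * t1 + g2 * t2)
    Jmag = sigma * np.linalg.norm(E, axis=1)
    return E, Jmag


# ---------------------------------------------------------------------------
# interior evaluation and conservation diagnostics


def _compartment_sigma(system: BemSystem, compartment: int) -> float:
    return system.head.compartments[compartment][1]


def evaluate_interior_potential(
    system: BemSystem, solution: FieldSolution, points: np.ndarray, compartment: int
) -> np.ndarray:
    """Potential (volts) at points strictly inside the given compartment,
    via the discretised representation formula."""
    if system.mode != "direct":
        raise ValueError("interior evaluation requires a direct-mode system")
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    pos, cur = _source_arrays(solution.sources)
    acc = _free_term(pts, pos, cur) if len(cur) else np.zeros(len(pts))
    V = solution.potentials / _UA_MM_TO_V  # back to uA/mm operator scale
    sig = _interface_sigmas(system.head)
    block = max(1, int(4.0e5 / max(len(pts), 1)))
    for l, surf in enumerate(system.head.surfaces):
        c_l = sig[l][0] - sig[l][1]
        if c_l == 0.0:
            continue
        off = system.offsets[l]
        tris = surf.triangles
        tri_xyz = surf.vertices[tris]
        Vl = V[system.surface_slice(l)]
        for start in range(0, len(tris), block):
            tb = tris[start : start + block]
            om = solid_angle_block(tri_xyz[start : start + block], pts)
            w = Vl[tb].mean(axis=1)  # lumped linear density per triangle
            acc += c_l / (4.0 * np.pi) * (w @ om)
    sigma_k = _compartment_sigma(system, compartment)
    return acc / sigma_k * _UA_MM_TO_V


def evaluate_interior_gradient(
    system: BemSystem, solution: FieldSolution, points: np.ndarray, compartment: int
) -> np.ndarray:
    """grad V (V/m) at points strictly inside the given compartment."""
    if system.mode != "direct":
        raise ValueError("interior evaluation requires a direct-mode system")
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    pos, cur = _source_arrays(solution.sources)
    acc = np.zeros((len(pts), 3))
    for p, I in zip(pos, cur):
        d = pts - p
        r3 = np.linalg.norm(d, axis=1) ** 3
        acc += I / (4.0 * np.pi) * (-d) / r3[:, None]
    V = solution.potentials / _UA_MM_TO_V
    sig = _interface_sigmas(system.head)
    for l, surf in enumerate(system.head.surfaces):
        c_l = sig[l][0] - sig[l][1]
        if c_l == 0.0:
            continue
        tris = surf.triangles
        tri_xyz = surf.vertices[tris]
        Vl = V[system.surface_slice(l)]
        w = Vl[tris].mean(axis=1)
        block = 64
        for start in range(0, len(tris), block):
            grad = solid_angle_gradient_block(tri_xyz[start : start + block], pts)
            acc += c_l / (4.0 * np.pi) * np.einsum(
                "t,tpi->pi", w[start : start + block], grad
            )
    sigma_k = _compartment_sigma(system, compartment)
    return acc / sigma_k  # uA/mm^2 / (S/m) == V/m


def interface_net_flux(
    system: BemSystem,
    solution: FieldSolution,
    surface_index: int,
    eps_fraction: float = 0.2,
) -> float:
    """Net current (uA) through an interior interface, evaluated just inside.

    With all impressed sources outside the surface the exact net flux is
    zero; the returned value measures the discretisation defect.  In
    multidomain mode the flux unknowns are integrated directly; in direct
    mode the representation formula is differentiated just inside the
    interface.
    """
    surf = system.head.surfaces[surface_index]
    if system.mode == "multidomain":
        if solution.interface_flux is None:
            return 0.0  # zero-source solution
        phi = solution.interface_flux[surface_index - 1]  # V/mm
        sigma = _compartment_sigma(system, surface_index)
        # sigma * dV/dn integrated over the surface: (S/m)(V/mm)(mm^2) -> uA
        return float(sigma * (phi @ vertex_areas(surf)) * 1e3)
    normals = vertex_normals(surf)
    from .surfaces import edge_lengths

    eps = eps_fraction * float(np.median(edge_lengths(surf)))
    pts = surf.vertices - eps * normals
    grad = evaluate_interior_gradient(system, solution, pts, surface_index)
    areas_m2 = vertex_areas(surf) * 1e-6  # mm^2 -> m^2
    sigma = _compartment_sigma(system, surface_index)
    # J . n = -sigma dV/dn, integrated over the surface -> amperes -> uA
    flux_A = float(np.sum(-sigma * np.einsum("ij,ij->i", grad, normals) * areas_m2))
    return flux_A * 1e6
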
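"""Reference benchmark computations for solver and focality validation.

Self-contained routines that rebuild their geometry, run the solver and
measure errors against the independent closed forms (multilayer-sphere
Legendre series, great-circle distances, the Gaussian FWHM identity).  They
back both the validation test-suite and the reproduction script, so the
numbers those report are always recomputed from scratch.

All errors are max-abs errors relative to the peak |V| on the surface under
comparison.
"""

from __future__ import annotations

import numpy as np

from .analytic import analytic_sphere
from .bem import assemble_system, solve
from .electrodes import PatchTerm, SourceTerms
from .focality import fwhm
from .geodesics import geodesic_distances
from .head import BregmaFrame, HeadModel, icosphere
from .operators import subdivide_triangles
from .surfaces import triangle_areas

__all__ = [
    "sphere_head",
    "homogeneous_sphere_error",
    "two_shell_error",
    "three_shell_patch_errors",
    "three_shell_point_brain_error",
    "gaussian_fwhm_relative_error",
    "antipodal_geodesic_relative_error",
]

Z = np.array([0.0, 0.0, 1.0])


def sphere_head(radii, sigmas, subdiv) -> HeadModel:
    comps = [(icosphere(subdiv, r), s) for r, s in zip(radii, sigmas)]
    return HeadModel(comps, BregmaFrame(origin=np.array([0.0, 0.0, radii[0]])))


def _surface_error(model, solution_V, surface) -> float:
    va = model(surface.vertices * (1 - 1e-9))
    va = va - va.mean()
    vb = solution_V - solution_V.mean()
    return float(np.max(np.abs(va - vb)) / np.max(np.abs(va)))


def homogeneous_sphere_error(
    subdiv: int = 3, depth: float = 0.75, current: float = 30.0, order: int = 200
) -> float:
    """Max relative error of the solver vs the series for a homogeneous
    sphere (sigma = 0.3 S/m) with antipodal point injection."""
    head = sphere_head([10.0], [0.3], subdiv)
    system = assemble_system(head, validate=False, mode="direct")
    pos = np.array([Z * 10.0 * depth, -Z * 10.0 * depth])
    cur = np.array([current, -current])
    sol = solve(system, (pos, cur))
    model = analytic_sphere(
        [10.0], [0.3], [(Z, current, depth), (-Z, -current, depth)], order=order
    )
    return _surface_error(model, sol.surface_potential(0), head.surfaces[0])


def two_shell_error(
    subdiv: int = 3, depth: float = 0.97, current: float = 30.0, order: int = 300
) -> list[float]:
    """Per-surface errors for a scalp/brain two-shell sphere (0.465/0.3 S/m)."""
    radii, sigmas = [10.0, 9.3], [0.465, 0.3]
    head = sphere_head(radii, sigmas, subdiv)
    system = assemble_system(head, validate=False, mode="direct")
    pos = np.array([Z * 10.0 * depth, -Z * 10.0 * depth])
    cur = np.array([current, -current])
    sol = solve(system, (pos, cur))
    model = analytic_sphere(
        radii, sigmas, [(Z, current, depth), (-Z, -current, depth)], order=order
    )
    return [
        _surface_error(model, sol.surface_potential(l), head.surfaces[l])
        for l in range(2)
    ]


def _patch_sources(head: HeadModel, patch_radius: float, current: float) -> SourceTerms:
    scalp = head.scalp
    areas = triangle_areas(scalp)
    cents = scalp.vertices[scalp.triangles].mean(axis=1)
    R = np.linalg.norm(scalp.vertices, axis=1).max()
    patches = []
    for pole, sgn in ((Z * R, +1.0), (-Z * R, -1.0)):
        idx = np.flatnonzero(np.linalg.norm(cents - pole, axis=1) <= patch_radius)
        w = areas[idx] / areas[idx].sum()
        patches.append(PatchTerm(idx, cents[idx], sgn * current * w, sgn * current))
    return SourceTerms(patches=patches, monopoles=[])


def three_shell_patch_errors(
    subdiv: int = 3,
    patch_radius: float = 1.6,
    current: float = 33.8,
    order: int = 200,
) -> dict:
    """Scalp- and brain-surface errors for the three-shell sphere with the
    reference tissue conductivities (0.465 / 0.015 / 0.3 S/m) and two scalp
    patch electrodes.

    The analytic reference evaluates the exact potential of the same
    discrete impressed-current distribution the solver receives (triangle
    currents quadratured as surface injections at their true radii), so the
    reported number is pure solver discretisation error.
    """
    radii, sigmas = [10.0, 9.3, 8.6], [0.465, 0.015, 0.3]
    head = sphere_head(radii, sigmas, subdiv)
    system = assemble_system(head, validate=False)  # auto -> multidomain
    st = _patch_sources(head, patch_radius, current)
    sol = solve(system, st)

    scalp = head.scalp
    areas = triangle_areas(scalp)
    phi1 = system.interior._neumann_vertex_data(st)
    tri_phi = phi1[scalp.triangles].mean(axis=1)
    injections = []
    for t in np.flatnonzero(np.abs(tri_phi) > 1e-12 * np.abs(tri_phi).max()):
        sub = subdivide_triangles(scalp.vertices[scalp.triangles[t : t + 1]], 1)
        sc = sub.mean(axis=1)
        for p in sc:
            r = np.linalg.norm(p)
            injections.append(
                (p / r, sigmas[0] * tri_phi[t] * areas[t] / len(sc), r / radii[0])
            )
    model = analytic_sphere(radii, sigmas, injections, order=order)
    return {
        "mode": system.mode,
        "scalp": _surface_error(model, sol.surface_potential(0), head.surfaces[0]),
        "brain": _surface_error(model, sol.surface_potential(2), head.surfaces[2]),
    }


def three_shell_point_brain_error(
    subdiv: int, depth: float = 0.97, current: float = 30.0, order: int = 300
) -> float:
    """Brain-surface error for the three-shell sphere with point injection
    just below the scalp surface (refinement scans)."""
    radii, sigmas = [10.0, 9.3, 8.6], [0.465, 0.015, 0.3]
    head = sphere_head(radii, sigmas, subdiv)
    system = assemble_system(head, validate=False)
    pos = np.array([Z * 10.0 * depth, -Z * 10.0 * depth])
    cur = np.array([current, -current])
    sol = solve(system, (pos, cur))
    model = analytic_sphere(
        radii, sigmas, [(Z, current, depth), (-Z, -current, depth)], order=order
    )
    return _surface_error(model, sol.surface_potential(2), head.surfaces[2])


def gaussian_fwhm_relative_error(
    subdiv: int = 4, radius: float = 10.0, scale_mm: float = 2.0
) -> float:
    """Relative FWHM error for a Gaussian field exp(-d^2 / (2 s^2)) imposed
    on a sphere, against the closed form 2 sqrt(2 ln 2) s."""
    s = icosphere(subdiv, radius)
    cosg = np.clip(s.vertices @ s.vertices[0] / radius**2, -1, 1)
    d = radius * np.arccos(cosg)
    field = np.exp(-(d**2) / (2.0 * scale_mm**2))
    result = fwhm(s, field)
    true = 2.0 * np.sqrt(2.0 * np.log(2.0)) * scale_mm
    return abs(result.fwhm - true) / true


def antipodal_geodesic_relative_error(subdiv: int = 4, radius: float = 10.0) -> float:
    """Relative error of the fast-marching distance to the antipode vs pi R."""
    s = icosphere(subdiv, radius)
    d = geodesic_distances(s, 0)
    cosg = np.clip(s.vertices @ s.vertices[0] / radius**2, -1, 1)
    antipode = int(np.argmax(np.arccos(cosg)))
    return abs(d[antipode] - np.pi * radius) / (np.pi * radius)
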
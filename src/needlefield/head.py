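"""Synthetic layered head models at mouse scale.

The study geometry is a set of nested, closed compartment boundaries (scalp,
skull, optionally CSF, brain) with piecewise-constant conductivities and a
bregma-anchored stereotaxic frame (ML/AP/DV axes, mm).  Segmented imaging
meshes are not required anywhere downstream: :func:`make_nested_head` builds
nested ellipsoids by subdividing an icosahedron and scaling it per compartment,
with default dimensions of the order of an adult mouse head (brain
anterior-posterior extent ~13 mm) and the standard tissue conductivities
(scalp 0.465, skull 0.015, CSF 1.65, brain 0.3 S/m).

Axes convention: x = ML (right positive), y = AP (anterior positive),
z = DV (dorsal positive); vertex indices are 0-based; coordinates in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .surfaces import TriSurface, require_valid, validate_surface

__all__ = [
    "CONDUCTIVITY",
    "BregmaFrame",
    "HeadModel",
    "make_nested_head",
    "icosphere",
    "ellipsoid_surface",
    "DEFAULT_BRAIN_SEMI_AXES",
    "DEFAULT_SKULL_THICKNESS",
    "DEFAULT_SCALP_THICKNESS",
]

#: Tissue conductivities, S/m.
CONDUCTIVITY = {"scalp": 0.465, "skull": 0.015, "csf": 1.65, "brain": 0.3}

#: Default mouse brain semi-axes (ML, AP, DV), mm.
DEFAULT_BRAIN_SEMI_AXES = (5.5, 6.5, 4.0)
DEFAULT_SKULL_THICKNESS = 0.3  # mm
DEFAULT_SCALP_THICKNESS = 0.7  # mm

#: Per-surface vertex budget guarding the dense downstream solver.
DEFAULT_VERTEX_BUDGET = 50_000


@dataclass
class BregmaFrame:
    """Stereotaxic frame anchored at the bregma landmark on the scalp."""

    origin: np.ndarray  # (3,) point on the scalp dorsal midline, mm
    ml_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    ap_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    dv_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64)
        for name in ("ml_axis", "ap_axis", "dv_axis"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        R = np.stack([self.ml_axis, self.ap_axis, self.dv_axis])
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("bregma axes must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("bregma axes must be right-handed")

    def to_world(self, ap_mm: float, ml_mm: float) -> np.ndarray:
        """Map a stereotaxic (AP, ML) offset to a world-space point near the scalp."""
        return self.origin + ap_mm * self.ap_axis + ml_mm * self.ml_axis


@dataclass
class HeadModel:
    """Ordered outside-in nested compartments with conductivities (S/m)."""

    compartments: list[tuple[TriSurface, float]]
    bregma: BregmaFrame

    @property
    def surfaces(self) -> list[TriSurface]:
        return [s for s, _ in self.compartments]

    @property
    def conductivities(self) -> list[float]:
        return [c for _, c in self.compartments]

    @property
    def scalp(self) -> TriSurface:
        return self.compartments[0][0]

    @property
    def brain(self) -> TriSurface:
        return self.compartments[-1][0]

    @property
    def brain_conductivity(self) -> float:
        return self.compartments[-1][1]

    def validate(self) -> None:
        """Raise if any surface invariant or the strict-nesting invariant fails."""
        if not self.compartments:
            raise ValueError("head model has no compartments")
        for surf, sigma in self.compartments:
            if sigma <= 0.0:
                raise ValueError(f"non-positive conductivity for {surf.name!r}")
            require_valid(surf)
        from .surfaces import points_inside

        for (outer, _), (inner, _) in zip(self.compartments, self.compartments[1:]):
            inside = points_inside(outer, inner.vertices)
            if not inside.all():
                n_out = int((~inside).sum())
                raise ValueError(
                    f"nesting violated: {n_out} vertices of {inner.name!r} "
                    f"lie outside {outer.name!r}"
                )


def icosphere(subdivisions: int, radius: float = 1.0) -> TriSurface:
    """Deterministic subdivided icosahedron: V = 10*4^n + 2, F = 20*4^n."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriSurface(np.asarray(mesh.vertices), np.asarray(mesh.faces), "icosphere")


def ellipsoid_surface(
    semi_axes: tuple[float, float, float], subdivisions: int, name: str = "ellipsoid"
) -> TriSurface:
    """Ellipsoid built by anisotropic scaling of a unit icosphere."""
    ax = np.asarray(semi_axes, dtype=np.float64)
    if not (ax > 0).all():
        raise ValueError("semi-axes must be positive")
    base = icosphere(subdivisions)
    return TriSurface(base.vertices * ax, base.triangles, name)


def make_nested_head(
    brain_semi_axes: tuple[float, float, float] = DEFAULT_BRAIN_SEMI_AXES,
    skull_thickness: float = DEFAULT_SKULL_THICKNESS,
    scalp_thickness: float = DEFAULT_SCALP_THICKNESS,
    csf_thickness: float | None = None,
    subdivisions: int = 4,
    bregma_ap_fraction: float = 1.0 / 3.0,
    conductivities: dict[str, float] | None = None,
    vertex_budget: int = DEFAULT_VERTEX_BUDGET,
) -> HeadModel:
    """Build a nested ellipsoidal scalp/skull[/CSF]/brain model.

    Parameters
    ----------
    brain_semi_axes
        Brain ellipsoid semi-axes (ML, AP, DV) in mm.
    skull_thickness, scalp_thickness, csf_thickness
        Radial layer thicknesses in mm; ``csf_thickness=None`` builds the
        default three-compartment model.
    subdivisions
        Icosphere subdivision level; each surface has ``10*4^n + 2`` vertices.
    bregma_ap_fraction
        Bregma AP position as a fraction of the scalp AP extent measured from
        the anterior pole (default: anterior third), on the dorsal midline.
    conductivities
        Override of the default tissue conductivities (S/m).
    """
    ax = np.asarray(brain_semi_axes, dtype=np.float64)
    if ax.shape != (3,) or not (ax > 0).all():
        raise ValueError("brain_semi_axes must be three positive lengths (mm)")
    for label, t in (("skull", skull_thickness), ("scalp", scalp_thickness)):
        if t <= 0:
            raise ValueError(f"{label}_thickness must be positive")
    if csf_thickness is not None and csf_thickness <= 0:
        raise ValueError("csf_thickness must be positive")
    if subdivisions < 1:
        raise ValueError("subdivisions must be >= 1")
    n_vertices = 10 * 4**subdivisions + 2
    if n_vertices > vertex_budget:
        raise ResourceWarning(
            f"subdivisions={subdivisions} gives {n_vertices} vertices/surface, "
            f"over the budget of {vertex_budget}"
        )
    sigma = dict(CONDUCTIVITY)
    if conductivities:
        sigma.update(conductivities)

    layers: list[tuple[str, np.ndarray, float]] = [("brain", ax, sigma["brain"])]
    offset = 0.0
    if csf_thickness is not None:
        offset += csf_thickness
        layers.append(("csf", ax + offset, sigma["csf"]))
    offset += skull_thickness
    layers.append(("skull", ax + offset, sigma["skull"]))
    offset += scalp_thickness
    layers.append(("scalp", ax + offset, sigma["scalp"]))
    layers.reverse()  # outside-in

    compartments = [
        (ellipsoid_surface(tuple(semi), subdivisions, name), s)
        for name, semi, s in layers
    ]

    scalp_ax = layers[0][1]
    if not 0.0 < bregma_ap_fraction < 1.0:
        raise ValueError("bregma_ap_fraction must be in (0, 1)")
    # Dorsal midline point of the scalp ellipsoid at the requested AP station.
    y = scalp_ax[1] * (1.0 - 2.0 * bregma_ap_fraction)
    z = scalp_ax[2] * np.sqrt(max(0.0, 1.0 - (y / scalp_ax[1]) ** 2))
    bregma = BregmaFrame(origin=np.array([0.0, y, z]))

    head = HeadModel(compartments=compartments, bregma=bregma)
    for surf, _ in compartments:
        report = validate_surface(surf)
        if not report.ok:  # pragma: no cover - construction guarantees validity
            raise RuntimeError(f"generated surface {surf.name!r} invalid: {report.violations}")
    return head
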
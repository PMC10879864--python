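"""Electrode geometry, montage placement and stimulation dose.

Two cephalic electrode designs are modelled, both circular with the same
radius (0.5 mm by default):

* ``flat_disc`` — the conventional ring-based HD electrode; its contact area
  is the disc area pi*r^2 (0.785 mm^2 at r = 0.5 mm).
* ``needle_conjugated`` — an HD electrode with a short needle at its centre,
  raising the total conductive contact area (1 mm^2 in the reference design).
  The extra area fraction ``1 - pi*r^2/A`` is carried by the needle, whose
  tip sits a configurable depth inside the scalp and acts as a concentrated
  (monopole) current source at a sharp geometric gradient.

Current is prescribed as a density over the contact area (uA/mm^2), so the
needle electrode injects proportionally more total current at the same dose;
charge density (kC/m^2) is the density integrated over the stimulation time.

Montage presets follow motor-cortex coordinates relative to bregma
(AP +1.2 mm, ML +/-1.25 mm): ``cA`` is a single contralesional anode with a
distant return (modelled as a small caudal scalp patch standing in for an
extracephalic neck needle, which cannot exist on a closed synthetic head) and
``iC-cA`` is the bi-hemispheric anode-contralesional / cathode-ipsilesional
pair.  The contralesional side defaults to the right hemisphere (left-sided
arterial occlusion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .head import HeadModel
from .surfaces import TriSurface, triangle_areas, triangle_normals

__all__ = [
    "Electrode",
    "StimulationProtocol",
    "Montage",
    "PatchTerm",
    "MonopoleTerm",
    "SourceTerms",
    "make_electrode",
    "place_montage",
    "montage_source_terms",
    "charge_density",
    "total_current",
    "DEFAULT_PROTOCOL",
]

_AREA_TOL = 1e-3  # mm^2, flat-disc area consistency
_CURRENT_TOL = 1e-9  # uA, Kirchhoff closure

#: Motor-cortex placement relative to bregma (mm).
MOTOR_AP = 1.2
MOTOR_ML = 1.25

#: Fraction of the local scalp thickness at which the needle tip sits.
DEFAULT_TIP_DEPTH_FRACTION = 0.9


@dataclass
class StimulationProtocol:
    """Stimulation dose: current density (uA/mm^2), duration and ramp (s)."""

    current_density: float = 43.0
    duration: float = 1200.0
    ramp: float = 30.0

    def __post_init__(self) -> None:
        if self.current_density < 0:
            raise ValueError("current density must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


DEFAULT_PROTOCOL = StimulationProtocol()


@dataclass
class Electrode:
    kind: str  # flat_disc | needle_conjugated | needle_reference
    radius: float  # mm
    total_contact_area: float  # mm^2
    polarity: str  # anode | cathode
    needle_tip_depth: float | None = None  # mm, needle kinds only
    needle_area_fraction: float = 0.0
    #: (AP, ML) in the bregma frame, or None for the extracephalic reference.
    placement: tuple[float, float] | None = None

    @property
    def disc_area(self) -> float:
        return math.pi * self.radius**2


def make_electrode(
    kind: str,
    radius: float = 0.5,
    total_contact_area: float | None = None,
    needle_tip_depth: float | None = None,
    polarity: str = "anode",
) -> Electrode:
    """Construct an electrode, enforcing the geometric consistency rules."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if polarity not in ("anode", "cathode"):
        raise ValueError(f"unknown polarity {polarity!r}")
    disc = math.pi * radius**2
    if kind == "flat_disc":
        return Electrode(kind, radius, disc, polarity)
    if kind in ("needle_conjugated", "needle_reference"):
        if kind == "needle_conjugated":
            if total_contact_area is None:
                total_contact_area = 1.0  # mm^2, reference design
            if total_contact_area <= disc + _AREA_TOL:
                raise ValueError(
                    f"needle electrode area {total_contact_area} mm^2 must exceed "
                    f"the disc area {disc:.4f} mm^2"
                )
            fraction = 1.0 - disc / total_contact_area
        else:
            total_contact_area = total_contact_area or disc
            fraction = 0.0
        if needle_tip_depth is not None and needle_tip_depth <= 0:
            raise ValueError("needle tip depth must be positive")
        return Electrode(
            kind,
            radius,
            total_contact_area,
            polarity,
            needle_tip_depth=needle_tip_depth,
            needle_area_fraction=fraction,
        )
    raise ValueError(f"unknown electrode kind {kind!r}")


def total_current(electrode: Electrode, protocol: StimulationProtocol) -> float:
    """Injected current in uA: dose density times contact area."""
    return protocol.current_density * electrode.total_contact_area


def charge_density(protocol: StimulationProtocol) -> float:
    """Charge density in kC/m^2 (1 uA/mm^2 == 1 A/m^2)."""
    return protocol.current_density * protocol.duration / 1000.0


@dataclass
class PlacedElectrode:
    electrode: Electrode
    current: float  # signed, uA
    #: scalp triangles forming the contact patch
    patch_triangles: np.ndarray
    #: projected placement point on the scalp, mm
    contact_point: np.ndarray
    #: outward scalp normal at the contact point
    normal: np.ndarray
    #: local scalp thickness at the contact point, mm
    scalp_thickness: float


@dataclass
class Montage:
    electrodes: list[PlacedElectrode]
    protocol: StimulationProtocol
    preset: str = "custom"
    head: HeadModel | None = field(default=None, repr=False)

    def check_closure(self) -> None:
        net = sum(p.current for p in self.electrodes)
        if abs(net) > _CURRENT_TOL:
            raise ValueError(f"montage currents sum to {net} uA, not 0")
        polarities = {p.electrode.polarity for p in self.electrodes}
        if not {"anode", "cathode"} <= polarities:
            raise ValueError("montage needs at least one anode and one return")


def _closest_point_on_triangles(
    points: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """Closest point to ``p`` on each triangle (a, b, c) (Ericson's method)."""
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    v = vb / denom
    w = vc / denom
    result = a + v[:, None] * ab + w[:, None] * ac  # interior projection

    # Edge/vertex regions override the interior barycentric point.
    t_ab = np.clip(d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3), 0, 1)
    on_ab = a + t_ab[:, None] * ab
    t_ac = np.clip(d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6), 0, 1)
    on_ac = a + t_ac[:, None] * ac
    t_bc = np.clip(
        (d4 - d3) / np.where((d4 - d3) + (d5 - d6) == 0, 1.0, (d4 - d3) + (d5 - d6)),
        0,
        1,
    )
    on_bc = b + t_bc[:, None] * (c - b)

    outside = (vb < 0) | (vc < 0) | (va < 0)
    cand = np.stack([on_ab, on_ac, on_bc], axis=1)
    d_cand = np.linalg.norm(cand - p[:, None, :], axis=2)
    best = cand[np.arange(len(p)), d_cand.argmin(axis=1)]
    return np.where(outside[:, None], best, result)


def project_to_surface(surface: TriSurface, point: np.ndarray) -> tuple[np.ndarray, int]:
    """Closest point on the mesh and the index of the closest triangle."""
    t = surface.triangles
    v = surface.vertices
    p = np.broadcast_to(np.asarray(point, dtype=np.float64), (len(t), 3))
    closest = _closest_point_on_triangles(p, v[t[:, 0]], v[t[:, 1]], v[t[:, 2]], p)
    d = np.linalg.norm(closest - point, axis=1)
    i = int(d.argmin())
    return closest[i], i


def _local_scalp_thickness(head: HeadModel, point: np.ndarray) -> float:
    if len(head.compartments) < 2:
        return np.inf
    inner = head.compartments[1][0]
    q, _ = project_to_surface(inner, point)
    return float(np.linalg.norm(q - point))


def _contact_patch(
    scalp: TriSurface, point: np.ndarray, radius: float
) -> np.ndarray:
    centroids = scalp.vertices[scalp.triangles].mean(axis=1)
    idx = np.flatnonzero(np.linalg.norm(centroids - point, axis=1) <= radius)
    if len(idx) == 0:
        raise ValueError(
            f"empty contact patch: no triangle centroid within {radius} mm of the "
            "placement point; refine the scalp mesh"
        )
    return idx


def _place_one(
    head: HeadModel,
    electrode: Electrode,
    ap: float,
    ml: float,
    current: float,
) -> PlacedElectrode:
    target = head.bregma.to_world(ap, ml)
    scalp = head.scalp
    point, tri = project_to_surface(scalp, target)
    if np.linalg.norm(point - target) > 5.0 * electrode.radius + 2.0:
        raise ValueError("placement point projects far outside the scalp mesh")
    normal = triangle_normals(scalp)[tri]
    patch = _contact_patch(scalp, point, electrode.radius)
    thickness = _local_scalp_thickness(head, point)
    placed = PlacedElectrode(
        electrode=electrode,
        current=current,
        patch_triangles=patch,
        contact_point=point,
        normal=normal,
        scalp_thickness=thickness,
    )
    placed.electrode.placement = (ap, ml)
    return placed


def _place_reference(
    head: HeadModel, current: float, radius: float = 0.5
) -> PlacedElectrode:
    """Caudal-pole scalp patch standing in for the extracephalic neck needle."""
    scalp = head.scalp
    ap = scalp.vertices @ head.bregma.ap_axis
    pole = scalp.vertices[int(ap.argmin())]
    point, tri = project_to_surface(scalp, pole)
    ref = make_electrode("needle_reference", radius=0.125, polarity="cathode")
    patch_radius = max(radius, 1e-6)
    patch = _contact_patch(scalp, point, patch_radius)
    return PlacedElectrode(
        electrode=ref,
        current=current,
        patch_triangles=patch,
        contact_point=point,
        normal=triangle_normals(scalp)[tri],
        scalp_thickness=_local_scalp_thickness(head, point),
    )


def place_montage(
    head: HeadModel,
    preset: str = "cA",
    electrode_kind: str = "needle_conjugated",
    protocol: StimulationProtocol = DEFAULT_PROTOCOL,
    contralesional_ml: float = +MOTOR_ML,
    electrode_kwargs: dict | None = None,
) -> Montage:
    """Place a montage preset on the scalp by bregma coordinates.

    ``cA``: one anode over the contralesional motor cortex (AP +1.2,
    ML +/-1.25) returned through the caudal reference patch.  ``iC-cA``:
    anode contralesional, cathode mirrored on the ipsilesional side.
    """
    kwargs = dict(electrode_kwargs or {})
    anode = make_electrode(electrode_kind, polarity="anode", **kwargs)
    i_anode = total_current(anode, protocol)
    placed: list[PlacedElectrode] = []
    if preset == "cA":
        placed.append(_place_one(head, anode, MOTOR_AP, contralesional_ml, +i_anode))
        placed.append(_place_reference(head, -i_anode))
    elif preset == "iC-cA":
        cathode = make_electrode(electrode_kind, polarity="cathode", **kwargs)
        placed.append(_place_one(head, anode, MOTOR_AP, contralesional_ml, +i_anode))
        placed.append(
            _place_one(head, cathode, MOTOR_AP, -contralesional_ml, -i_anode)
        )
    else:
        raise ValueError(f"unknown montage preset {preset!r}")
    montage = Montage(electrodes=placed, protocol=protocol, preset=preset, head=head)
    montage.check_closure()
    return montage


@dataclass
class PatchTerm:
    """Uniform impressed normal current over a scalp contact patch."""

    triangle_indices: np.ndarray
    positions: np.ndarray  # (n, 3) triangle centroids, mm
    currents: np.ndarray  # (n,) uA, area-apportioned
    total: float  # uA


@dataclass
class MonopoleTerm:
    """Concentrated current source at the needle tip inside the scalp."""

    position: np.ndarray  # (3,) mm
    current: float  # uA


@dataclass
class SourceTerms:
    patches: list[PatchTerm]
    monopoles: list[MonopoleTerm]

    def point_sources(self) -> tuple[np.ndarray, np.ndarray]:
        """All impressed currents as point sources: (positions mm, currents uA)."""
        pos = [p.positions for p in self.patches] + [
            m.position[None, :] for m in self.monopoles
        ]
        cur = [p.currents for p in self.patches] + [
            np.array([m.current]) for m in self.monopoles
        ]
        if not pos:
            return np.zeros((0, 3)), np.zeros(0)
        return np.concatenate(pos), np.concatenate(cur)

    @property
    def net_current(self) -> float:
        _, cur = self.point_sources()
        return float(cur.sum())


def montage_source_terms(
    montage: Montage,
    head: HeadModel,
    tip_depth_fraction: float = DEFAULT_TIP_DEPTH_FRACTION,
) -> SourceTerms:
    """Resolve a placed montage into boundary patch and needle-tip source terms.

    A flat disc delivers its full current uniformly over the contact patch.
    A needle-conjugated electrode splits current by conductive-area fraction:
    the ring patch carries ``1 - f`` and a monopole at the needle tip (at
    ``tip_depth_fraction`` of the local scalp thickness along the inward
    normal) carries ``f``, where ``f`` is the needle area fraction.
    """
    if montage.head is not head:
        raise ValueError("montage was not placed on this head")
    scalp = head.scalp
    areas = triangle_areas(scalp)
    centroids = scalp.vertices[scalp.triangles].mean(axis=1)

    patches: list[PatchTerm] = []
    monopoles: list[MonopoleTerm] = []
    for placed in montage.electrodes:
        e = placed.electrode
        patch_current = placed.current
        if e.kind == "needle_conjugated" and e.needle_area_fraction > 0:
            depth = e.needle_tip_depth
            if depth is None:
                depth = tip_depth_fraction * placed.scalp_thickness
            if depth >= placed.scalp_thickness:
                raise ValueError(
                    f"needle tip depth {depth:.3f} mm >= local scalp thickness "
                    f"{placed.scalp_thickness:.3f} mm (tip would leave the scalp)"
                )
            tip = placed.contact_point - depth * placed.normal
            monopoles.append(
                MonopoleTerm(position=tip, current=e.needle_area_fraction * placed.current)
            )
            patch_current = (1.0 - e.needle_area_fraction) * placed.current
        idx = placed.patch_triangles
        w = areas[idx] / areas[idx].sum()
        patches.append(
            PatchTerm(
                triangle_indices=idx,
                positions=centroids[idx],
                currents=patch_current * w,
                total=patch_current,
            )
        )
    terms = SourceTerms(patches=patches, monopoles=monopoles)
    if abs(terms.net_current) > _CURRENT_TOL:
        raise ValueError(f"source terms sum to {terms.net_current} uA, not 0")
    return terms
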
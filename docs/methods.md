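# Methods

`needlefield` models the electric field that high-definition transcranial
direct-current stimulation (HD-tDCS) produces on the cortical surface of a
layered rodent head, and quantifies how focal that field is.  It was built
to compare a conventional flat ring-based HD electrode against a
needle-conjugated HD electrode (same 0.5 mm radius, but a larger conductive
contact area of 1 mm² vs 0.785 mm² with the extra area carried by a short
central needle), and to compare montage configurations (single
contralesional anode with a distant return, versus a bi-hemispheric
anode–cathode pair).

## Volume-conduction model

The head is a piecewise-homogeneous ohmic conductor: nested, closed
triangulated surfaces bound compartments of constant conductivity (scalp
0.465, skull 0.015, CSF 1.65, brain 0.3 S/m).  In the quasi-static regime
the potential satisfies Laplace's equation in each compartment with
continuity of potential and of normal current density across interfaces,
no-flux at the outer scalp/air boundary, and impressed currents from the
electrodes.  Capacitive, inductive and frequency-dependent effects are
neglected, as is tissue anisotropy.

Two boundary-element discretisations are provided, both collocating at mesh
vertices with triangle-lumped (1/3 per vertex) densities and analytically
exact van Oosterom–Strackee solid angles:

* **direct** — the classical second-kind (Geselowitz) double-layer
  transmission equation over all interfaces.  The own-surface singular term
  is closed with the auto-solid-angle identity, which makes the constant
  vector an exact nullvector; the nullspace is removed by rank-one
  deflation and the dense system solved by LU.  Accurate for moderate
  conductivity contrast.
* **multidomain** — Green's third identity written compartment by
  compartment, with both interface potentials and interface normal
  derivatives (fluxes) as unknowns, coupled through single- and
  double-layer operators.  Electrode patches enter as genuine Neumann data
  on the scalp; needle tips as interior monopoles.  Because the weak
  current transmitted through the skull is represented by its own unknown
  rather than as a cancellation of large terms, the scheme keeps its
  accuracy at arbitrary contrast.  It is selected automatically whenever an
  adjacent-compartment conductivity ratio exceeds 20 — in particular for
  the 31:1 scalp/skull pair.  (A truncated two-pass "insulated-core"
  scheme was evaluated first and rejected: with a 0.3–0.7 mm skull the
  neglected back-reaction scales like (σ_skull/σ_scalp)·(R/t) ≈ 0.4, far
  too large.)

Single-layer operators use subdivided-triangle quadrature (4 sub-centroids,
refined to 64 within two triangle diameters) with an exact closed form for
the singular own-vertex integrals.  Geometry is kept in mm, currents in µA,
conductivities in S/m; potentials come out in volts, current density in
A/m².  The reported potentials use a zero-mean gauge over all interface
vertices — only relative maps and peak comparisons are meaningful, matching
how such fields are usually reported (min–max normalised).

The cortical field is the tangent-plane least-squares gradient of the
brain-surface potential over each vertex one-ring, with |J| = σ_brain |E|.

**Validation.**  An independent analytic oracle solves the multilayer
concentric-sphere problem by per-degree Legendre transfer matrices, for
point injections on the outer sphere or at any radius inside the outermost
layer; it reduces to the homogeneous-sphere closed form at equal
conductivities to machine precision.  At 642 vertices/surface the solver
agrees with the oracle to ≤1% (homogeneous sphere, antipodal injection at
0.75 R) and ≤5% on the brain surface of the three-shell sphere with the
tissue conductivities above and two scalp patch electrodes; errors fall
with mesh refinement.  In the patch benchmark the oracle is fed the exact
discrete impressed-current distribution the solver receives, so the
reported number is pure discretisation error.  Net current through any
interior interface vanishes to round-off (each term of the representation
is exactly harmonic inside it), and linearity, superposition,
anode/cathode antisymmetry and mirror symmetry hold by construction and are
tested.

## Electrodes, montages and dose

Current is prescribed as a density over the conductive contact area
(default 43 µA/mm² for 20 min, i.e. a charge density of 51.6 kC/m²), so the
needle electrode injects 43 µA against the flat disc's 33.8 µA at the same
dose.  The contact patch is the set of scalp triangles whose centroids lie
within the electrode radius of the placement point; placements are
stereotaxic (AP, ML) offsets from a bregma landmark on the scalp dorsal
midline.  The needle-conjugated electrode splits its current by
conductive-area fraction: the ring patch carries 1 − f and a monopole at
the needle tip carries f = 1 − πr²/A (0.215 for the reference design), with
the tip at 90% of the local scalp depth by default — the needle penetrates
the scalp but never the skull.  The extracephalic neck return cannot exist
on a closed synthetic head; it is modelled as a small caudal-pole scalp
patch, preserving the far-return topology.  "Contralesional" defaults to
the right hemisphere (left-sided occlusion) and is configurable.

## Synthetic head geometry

Study-grade imaging meshes are replaced by nested ellipsoids built from a
subdivided icosahedron: brain semi-axes 5.5 × 6.5 × 4.0 mm (ML × AP × DV,
an adult-mouse scale with ~13 mm anterior–posterior brain extent), skull
thickness 0.3 mm, scalp 0.7 mm, optional CSF layer, at icosphere
subdivision 4 by default (2562 vertices per surface).  Bregma sits on the
dorsal midline at the anterior third of the scalp's AP extent.  Generation
is deterministic; every surface is validated as a closed, outward-oriented,
genus-0 2-manifold and strict nesting is checked by winding numbers.

What this geometry does *not* emulate: real skull topology (foramina,
sutures, thickness variation), cortical folding, tissue anisotropy, and the
true mouse head shape.  Benchmarks passing on spheres and ellipsoids
validate the solver and the statistics, not the anatomical accuracy of any
particular prediction; absolute field values on real heads will differ.
The needle-vs-flat and montage comparisons are therefore reported as
directions and ratios, not absolute reproductions.

## Focality statistics

Geodesic distances from the field peak are computed by fast marching
(Kimmel–Sethian eikonal updates with Dijkstra fallback at causality
violations).  The first-order source singularity is removed by initialising
a 4-ring neighbourhood of the seed with locally flat distances; on spheres
the antipodal distance is then accurate to <1% at subdivision 4, and on a
flat square to <1% against Euclidean distance.  This exact-flat
initialisation slightly underestimates distances in strongly curved seed
neighbourhoods (≲0.2% at the curvatures used here).

The field-vs-distance profile is the mean field per geodesic-distance bin
(default bin width: twice the median edge length — one sample per
resolvable length scale), with each bin plotted at the **mean distance of
its member vertices**; using bin centres instead biases the FWHM upward by
several percent at these resolutions.  The profile is regularised to be
non-increasing by a running minimum; the FWHM is twice the linearly
interpolated distance of the first crossing below half the peak (global
maximum vertex, ties to the lowest index).  A Gaussian field exp(−d²/2s²)
with s = 2 mm on a 10 mm sphere recovers 2√(2 ln 2)s within 1%.  The
half-max focal area counts triangles whose three vertices all reach half
the peak, so it under-counts by a boundary ring of one triangle — accurate
to a few percent once the focal radius spans ≳10 edges.

Montage comparisons report percent peak differences, 100(x_a − x_b)/x_b,
for peak potential and peak current density, and ratios 100·a/b for FWHM
and focal area.  All four are invariant to a common rescaling of the
fields.  FWHM values are reported in mm; the dimensionless ratio is the
quantity meant for cross-configuration comparison.

## Study metrics

The non-simulation formulas are implemented exactly as defined:
edema-corrected infarct volume Σ[contra − (ipsi − infarct)]·thickness;
qPCR relative expression 2^−ΔΔCt; recognition index 100·B/(B+A); event
percentages; differential-expression filtering with strict cutoffs (linear
fold change > 1.5 in magnitude, log2 normalised expression > 2, p < 0.05 —
the fold-change scale is an explicit parameter because both linear and
log2 conventions are common); and the cerebral-blood-flow inclusion rules
(≥80% drop at occlusion; a pre-reperfusion drop that has recovered to ≤30%
of baseline excludes the animal — this reading of the premature-reperfusion
rule is isolated in a single predicate).  A seeded toy-table generator
provides fixtures that exercise every rule on both sides.

## Numerical choices and problem sizes

* Dense LU with a 20 000-interface-vertex budget: deterministic,
  preconditioner-free; the default head (3 × 2562 vertices) assembles and
  factorises in a few minutes on one core.
* Benchmarks run at 642 vertices/surface (solver-vs-oracle) and 2562
  (focality closed forms, needle-vs-flat), sizes at which the documented
  tolerances hold with margin while a full validation pass stays in the
  minutes range.
* Montage presets fail loudly when the mesh is too coarse to resolve a
  0.5 mm contact patch (below ~2562 vertices/surface on the default
  scalp, placements can still resolve, but patch areas carry ~10% error).
* Ties, gauges and orderings (peak ties to lowest index, zero-mean
  potential gauge, outside-in compartment ordering, 0-based indices) are
  fixed so identical configurations reproduce byte-identical reports.

## Known limitations

* Vertex-collocation with lumped densities is first-order: near-electrode
  skull-surface errors reach ~5–10% at 642 vertices/surface (the brain
  surface, where the focality statistics live, is smoother and stays
  within 5%).
* The needle is a single monopole, not a resolved cylindrical conductor;
  field values within a millimetre of the tip are not meaningful.
* The extracephalic return approximation perturbs the caudal field; peak
  and FWHM statistics under the electrode are insensitive to it.
* FWHM on a closed surface saturates once the half-max cap approaches a
  hemisphere; metrics are meaningful for fields substantially more focal
  than that.
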
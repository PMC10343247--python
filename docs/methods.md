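# Methods

`braidfe` predicts the linear-elastic behaviour of a 3D-braided artificial
meniscus: a crescent-shaped wedge of polycarbonate polyurethane (PCU)
reinforced by a braided truss of Kevlar fiber bundles.  Three modelling
levels are chained: closed-form micromechanics for the matrix-impregnated
bundles, periodic finite-element homogenization of unit cells, and a
macro-scale compressive comparison of the reinforced implant against a
pure-matrix implant.  Internal units are N, mm and MPa; configuration files
and the CLI use GPa.

## Bridging micromechanics (`braidfe.bridging`)

A unidirectional bundle of fiber volume fraction `Vf` is homogenized by the
bridging model, which links the volume-averaged matrix stress to the
volume-averaged fiber stress through a bridging matrix `A`:

    sigma_m = A sigma_f,
    S = (Vf S_f + Vm S_m A)(Vf I + Vm A)^-1,   Vm = 1 - Vf.

The non-trivial entries of `A` are

    a11 = Em / E11f
    a22 = a33 = a44 = beta + (1 - beta) Em / E22f
    a55 = a66 = alpha + (1 - alpha) Gm / G12f

with two dimensionless bridging parameters `beta` (transverse modulus) and
`alpha` (axial shear), both conventionally in 0.3–0.6.

**Per-mode default evaluation.** The package's default evaluation applies
the bridging relation mode by mode — each Voigt compliance entry is
homogenized by its own diagonal entry of `A`, the axial Poisson ratio obeys
the rule of mixtures `v12 = Vf v12f + Vm vm` (an identity of the model),
and the transverse Poisson ratio follows from transverse isotropy,
`v23 = E22/(2 G23) - 1`.  This reproduces the classical closed-form
expressions for every engineering constant: the axial modulus is exactly
the rule of mixtures, and the transverse and shear moduli are
`a`-weighted Reuss-type means.  The full matrix product, including the
normal-coupling entry `a12`, is available via `bundle_compliance(...,
coupled=True)`; its coupling stiffens the transverse response by ~20% at
the extreme Kevlar/PCU contrast (axial-modulus ratio ≈ 2300), and it is not
the default because the per-mode forms are the ones the published
closed-form constants correspond to.

**Parameters.** The study tables never state `Vf`, `alpha` or `beta`.
`backsolve_params` inverts the model: `Vf` from the axial rule of mixtures,
then scalar root-finding for `beta` (transverse modulus) and `alpha` (axial
shear).  Applied to the published bundle row this yields `Vf = 0.700`,
`alpha = beta = 0.30`, which are the packaged defaults — back-solved
values, not the original authors' declared inputs.

**Kevlar transverse Poisson ratio.** The materials table lists equal
transverse modulus and transverse shear modulus (12.87 GPa), which together
with `G23 = E22/(2+2 v23)` forces `v23 = -0.5` for the fiber.  The
per-mode bundle constants are insensitive to this value; it is kept because
it is what the printed table implies.

## Embedded-fiber hexahedral kernel (`braidfe.hexfem`, `braidfe.embedded`)

The matrix phase uses standard 8-node trilinear hexahedra, engineering
Voigt order `(x, y, z, yz, zx, xy)`, full 2×2×2 Gauss quadrature (exact for
affine elements).  Fibers are polylines carrying only axial stiffness; a
fiber segment inside a host element contributes

    k_f = ∫ B'^T Ef B' A h dx',   B' = [l², m², n², mn, nl, lm] B,

where `(l, m, n)` are the segment's direction cosines and `h` its
half-length metric; the element stiffness is the superposition
`K_e = k_m + Σ k_f`.  No degrees of freedom are added.  The direction row
is the exact tensor rotation of engineering strain onto the fiber axis (a
fiber at 45° in the xy-plane under pure `γ_xy` sees `γ_xy/2`).

Fiber paths are split at element boundaries by host-marching: locate the
element containing the point just past the current parameter, bisect the
parameter at which the path exits it (50 bisections), emit the piece, and
continue.  This is robust to elements much thinner than the scan step.
Natural coordinates come from Newton inversion of the trilinear map
(residual 1e-12, 50 iterations).  Two numerical safeguards matter in
practice: candidate elements are found by a ball query over element
bounding boxes (nearest-centroid ranking misses thin slivers), and elements
that merely graze the path inside the inclusion tolerance band are excluded
and retried, because fibers routinely lie exactly on shared element faces.

**Overlap correction.** Embedded bars overlap matrix volume that is counted
twice.  With `mesh.overlap_correction` (default on) the bar modulus is
reduced to `E_fiber - E_matrix`, making the axial response of a
unidirectional cell exactly the rule of mixtures and keeping every
homogenized modulus at or below the Voigt bound.

## Periodic homogenization (`braidfe.homogenize`)

Effective stiffness of a unit cell is computed from six unit macroscopic
strain cases under periodic boundary conditions.  Opposite-face node pairs
are tied by master–slave elimination (`u_slave = u_master + ε·Δx`), which
satisfies the constraints exactly and keeps the pipeline deterministic;
one corner node is pinned to remove rigid translations and the reduced
system is factorized once (sparse LU) for all six cases.  Column `j` of the
effective stiffness is the volume-averaged stress (matrix quadrature plus
fiber line integrals) under unit strain `j`.  Every case is checked against
the Hill condition (macroscopic energy = volume-averaged microscopic
energy, 1e-6 relative); the resulting 6×6 stiffness must be symmetric to
1e-6 relative and positive definite, and engineering constants are read
from its inverse with L = x (fiber axis), T = y (vertical), Z = z.

**Unit cells.** The micro cell is a rectangular cell of aspect √3
(hexagonal packing: one full fiber at the center, four quarter fibers at
the corners), with the fibers realized as embedded bars whose summed
cross-section equals `Vf` times the transverse cell area.  Axial-only bars
reproduce the bundle's axial modulus (rule of mixtures, within 1% of the
published multi-scale value) but leave the transverse response
matrix-dominated — transverse bundle constants should be taken from the
bridging model, not from this cell.  For the same reason the literal Reuss
lower bound of the solid constituents does not apply to the transverse
moduli of embedded-bar cells; the meaningful bounds, and the ones the test
suite enforces, are the matrix modulus from below and the Voigt mixture
from above.

The meso cells derive from the braid dimensions (2 mm bundle width, 1 mm
height, 2 mm gaps → 4 mm in-plane period, 2 mm tall, two crossed bundle
layers).  `top` and `bottom` cells are mirror images (longitudinal bundle
above or below the transverse one); the `interior` cell adds the vertical
interlock loop (two legs of a 0.5 mm yarn).  The multi-scale chain
homogenizes the micro cell, feeds its axial modulus to the meso bundle
bars, and homogenizes the three meso cells.  The published meso-cell rows
cannot be matched bit-for-bit — their exact geometry is not recoverable —
so the package treats them as consistency references: the two pipelines
(bridging-fed vs micro-FE-fed) must agree within 5%, and the interior
cell's vertical modulus must dominate the top/bottom cells', which it does
(≈2.4 GPa vs ≈0.16 GPa against the published 2.19 vs 0.2 pattern).

## Braid geometry (`braidfe.geometry`)

The implant plan view is a crescent between two elliptical arcs sharing the
horn axis; the cross-section is a wedge tapering linearly from the full
11 mm height at the outer boundary to a 3 mm inner edge.  A mapped-block
parametrization `(u, v, w)` produces both the structured hexahedral mesh
and the fiber paths; fibers are evaluated through the *discretized* grid
map, so they lie inside the faceted solid by construction at any mesh
resolution.  A 4% trim near the horns keeps elements non-degenerate, and a
closed-form rescale makes the bounding box exactly length × width × height.

The lattice follows the published architecture: five layers in levels
(1, 1, 2, 2, 3) bottom-to-top; per level 6/4/2 transverse half-moon arcs
and 13/12/8 longitudinal fibers fanning inner-to-outer (the 13 fibers at
the stated ~15° spacing span the half-moon); per-level lengths shrink
according to the stated nominal lengths (45/40/35 mm transverse; 8 mm then
6 mm longitudinal shortening), applied as ratios of the generated arc
lengths since the generated model is smaller than the nominal fiber
lengths.  Because the wedge is thin at the inner edge, upper levels sit
toward the tall outer rim.  Vertical interlock loops (the braided-in
"Z" yarns, two 0.5 mm legs per loop) join adjacent layers at each
transverse/longitudinal crossing that fits inside the wedge.  Bundle
cross-sections are the stated 2×1 mm.

## Macro comparison (`braidfe.macro`)

Both implant models share one wedge mesh; the reinforced model embeds the
full lattice with the bridging bundle's axial modulus (overlap-corrected).
The bottom surface is fully fixed; the load is applied as uniform pressure
on the sloped top surface via consistent vertical nodal forces through
projected face areas, so the resultant equals the requested load exactly.
"Resistance to deformation" is the inverse of the maximum downward
displacement of the loaded surface at equal load, and the improvement is
`(u_matrix/u_reinforced - 1)·100`, constant across load cases in a linear
model (both the per-load values and their mean are reported).

**Tension-only fibers.** Textile yarns buckle or go slack under
compression.  Modelling the vertical interlock loops as bilateral bars
would let them act as rigid Kevlar columns and triples the apparent
stiffening; the macro solver therefore deactivates fiber segments whose
axial strain is compressive and re-solves until the active set is stable
(it is load-level independent, so one factorization sweep suffices).
Deactivation removes only positive-semidefinite contributions, so the
reinforced model can never be softer than the pure matrix.  Unit-cell
homogenization keeps bilateral fiber stiffness: elastic constants are
small-strain properties probed in all directions, matching how the
published cell tables report them.  With this treatment the improvement is
≈46% at the coarse test mesh (stable between 2.5 and 2.0 mm meshes),
consistent with the published ≈60% given that the exact macro geometry and
mesh of that comparison are not recoverable.

## Configuration, determinism and problem sizes

All defaults live in one validated YAML schema (unknown keys rejected):
materials (the published Kevlar/PCU constants), bridging parameters,
geometry, mesh resolutions and the 400–1400 N load set.  The pipeline
contains no randomness — direct sparse factorization, deterministic
orderings — except an optional interior-node mesh jitter
(`braidfe compare --perturb --seed`) for robustness checks; its amplitude
scales with the smallest element dimension so thin horn elements cannot
invert.  The default macro mesh is 1.5 mm (~2000 elements); the test suite
and the packaged acceptance checks run the macro comparison at 2.5–3.5 mm
and the unit cells at 5 divisions per axis, sizes chosen so the whole suite
completes in about a minute while the reported quantities are mesh-stable
at the 1–2% level.

## Known limitations

* Embedded bars carry axial stiffness only: no fiber bending or torsion,
  no fiber-matrix slip or debonding, and matrix-dominated transverse
  response of the micro cell (use the bridging model for transverse bundle
  constants).
* Linear elasticity throughout: no PCU viscoelasticity or plasticity, no
  strength or failure prediction, no contact with the femoral condyle or
  tibial plateau — the macro case is a fixed-base pressure load.
* The crescent outline, wedge taper and interlock loop geometry are
  parametric reconstructions from stated overall dimensions and photos;
  meso-cell and macro results are therefore consistency-level predictions,
  not replications of a specific mesh.
* The tension-only treatment is a linear-complementarity approximation of
  yarn slackening; true loop geometry (curvature, friction) is not modelled.
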
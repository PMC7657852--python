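# Methods

`septamech` regenerates a family of theoretical phragmocone models --
cylindrical stand-ins for the chambered part of an ammonoid shell -- and
asks how suture-line complexity, septal spacing and wall thickness change
the shell's elastic response to external water pressure.  This note records
the model, the numerical choices, and what the synthetic geometry does and
does not capture.

## Geometry

**Suture curves.**  A suture is a closed curve on the inner cylinder
(radius 9.11 mm by default).  Two parametric families are provided:

* *Lobate* curves: a short cosine series
  `y(x) = -sum_k w_k cos(2 pi k n x)`, rescaled to a target peak-to-peak
  amplitude, with weights `(1, 0.18, 0.03)` chosen so the curve has exactly
  `n` primary lobes, slight lobe/saddle asymmetry, and bilateral symmetry
  about every lobe and saddle axis.  The published drawings these imitate
  are not machine-readable; the parametric family trades exact shape for
  controllability.
* *Koch* curves: a four-segment bump generator applied 1-3 times per copy,
  four copies around the circumference.  The classic generator (60 degree
  flanks) overhangs in arc position from the second iteration onward, which
  would make the suture multivalued over the circumference; the default
  generator angle is therefore 25 degrees, which keeps three iterations
  single-valued while preserving the `4^n` segment-count law and the
  self-similar frilling.  Curves are smoothed with a periodic cubic spline
  through the generator vertices and rescaled to the target amplitude.

Suture amplitude is nowhere stated in the source experiments; the default is
0.2 x cylinder radius (1.82 mm peak-to-peak) for both families, so lobate and
Koch suites are geometrically comparable.

**Septa.**  A septum is the surface spanning its suture that minimises the
discrete thin-plate (biharmonic) energy `sum_c x_c' L M^-1 L x_c` on a
structured polar disc triangulation, with the boundary clamped in position
(rotation free) and the cotangent Laplacian rebuilt from the updated
geometry until the energy change is below 1e-8 (500 iteration cap; the
energy is monotone by construction since an increase terminates the
iteration at the previous iterate).  A planar boundary yields a flat disc to
machine precision, which is the analytic minimiser and the main oracle.
Inside the shell assembly only the axial coordinate is solved (the in-plane
polar layout stays fixed); this height-field variant is exact in one solve.

Septa are thickened by offsetting the midsurface half a thickness along the
vertex normals on both sides.  The feasible thickness is limited by
self-intersection of the offset suture: the limit is found by bisection with
a brute-force pairwise segment-intersection test on the unrolled cylinder.
At the default amplitude the third-iteration Koch suture admits at most
~0.14 mm -- which is why the Koch suite uses 0.04 mm septa while lobate
models use 0.4 mm.

**Shell assembly.**  A model is the annular wall between two cylinders,
closed by hemispherical caps of the same thickness, with N septa fused to
the inner wall at fixed spacing, centred on midlength.  Assembly is
constructive and conformal: the wall grid's axial levels are warped per
angular station so two levels coincide with each septum's lower and upper
faces along its suture, and the septal discs reuse those wall nodes as their
boundary rings.  The wall attachment band spans `t sec(slope)` axially where
the suture is steep -- the trace a slab of uniform normal thickness leaves on
a cylinder -- so frilled Koch septa keep their nominal thickness on the
flanks.  No boolean operations or mesh repair are involved, and watertightness
is checked structurally (every boundary edge shared by exactly two facets).

Cylinder length is `(N-1) * spacing + 2 * end_margin`.  The free end beyond
the outermost septum must be long enough for the shell's edge-bending
boundary layer, which decays as `exp(-x/lambda) cos(x/lambda)` with
`lambda = sqrt(r t) / (3(1-nu^2))^(1/4)` (~1.7 mm for the 0.5 mm wall, an
oscillation wavelength of ~10.6 mm).  The default margin is 20 mm, about two
wavelengths, so the validation band sits on a genuine membrane plateau
rather than on the first bending overshoot.

**Symmetry sectors.**  Every suite geometry has dihedral symmetry (mirror
planes through each lobe and saddle axis; every pi/4 for the four-copy Koch
curves).  By default only the fundamental sector is meshed and the FEM
imposes zero normal displacement on the two cut planes -- exact for the
symmetric geometry and load -- which shrinks each model by the symmetry
order (6-16x) and lets the whole suite run on one CPU in minutes.  Full
360-degree meshing is available (`sector=False`) and is used for the
benchmark fixtures with 3-2-1 point constraints.

## Meshing

Cells (hexahedra, wedges, degenerate pole cells) are tetrahedralised by
triangulating each face with the diagonal through its smallest global node
id -- a rule both sharing cells apply identically, guaranteeing conformity --
and fanning tetrahedra from the cell's smallest node; cells that are not
star-shaped from that node (detected by comparing fan and centroid
decomposition volumes) fall back to a centroid split.  Quadratic (10-node)
tetrahedra are the default; midside nodes on edges whose endpoints share a
cylindrical or spherical model surface are projected onto it, restoring
curved geometry to second order.  Projection is suppressed where the
chord-sagitta would approach the radial layer thickness (thin-wall caps),
where it would invert elements; the flat-facet area error this leaves on the
caps is below one percent and does not touch the mid-cylinder validation
band.

Mesh resolution is set at assembly: a nominal element size (1.2 mm coarse
tier, 0.6 mm fine), one quadratic element through the wall thickness, and
angular resolution raised for Koch sutures so the finest frills are sampled;
the three Koch iterations are meshed at the *same* angular resolution (that
of iteration 3) so cross-iteration comparisons are not confounded by mesh
density.  The problem sizes of the coarse tier (2-25k quadratic tets per
model) were chosen so the full 11-model suite solves in a few minutes on one
CPU; they are the package's working scale, and the source experiments'
element counts are unknown.

## Elasticity

Standard displacement FEM: isotropic linear elasticity (E = 70 GPa from
nanoindentation of *Nautilus* shell wall, nu = 0.3), mm-MPa-N units,
4-point Gauss quadrature for TET10 stiffness, pressure applied as a dead
traction `-P n` integrated isoparametrically over the curved external
facets, direct sparse LU factorisation (symmetric minimum-degree ordering)
with one factorisation per geometry reused across the pressure series
(each pressure's right-hand side is solved exactly; the model is linear, so
this is identical to independent runs).  Tension is positive.  Element
stresses are evaluated at element nodes from the displacement gradient and
volume-averaged to mesh nodes; evaluating at nodes rather than centroids is
what lets outer-surface hoop values reflect the surface rather than the
mid-wall state.  Strain energy is `f'u/2`.

Checks: a hydrostatically loaded cube reproduces `-P I` to 1e-6 (exact for
the elements); the Lame thick-walled cylinder (plane strain) matches the
closed-form hoop profile within 2%; a thin spherical shell matches
`P r / (2t)` within 3%; rigid-body reactions vanish to 1e-6 of the applied
traction for closed pressure loads.

## Validation protocol and reported quantities

The thin-wall formula `sigma_h = P r / t` (inner radius, per the reference
convention: 36.44 MPa for the 0.5 mm wall, 182.2 MPa for 0.1 mm) anchors the
validation: the relative deviation of mean sampled outer-wall hoop stress in
a band midway between the outermost septum and the cap.  Coarse-tier models
land at 0.5-2.7%, inside the 0.1-4% protocol window.  Note the window has a
physical floor: the formula uses the inner radius while the sampled surface
carries the Lame outer-wall value, a ~2.8% offset at t = 0.5 mm that no
refinement removes; at t = 0.1 mm the floor is ~0.55%, so the
mesh-convergence demonstration (error below 1%) uses the thin wall.

Region statistics (mean, sd, peak of maximum principal stress) are taken on
the external shell wall within one septal spacing of the middle septum and
over the middle septum itself -- the exterior septa see asymmetric local
loads and are poor proxies for a mid-phragmocone septum.  Line probes run
axially along the outer surface at a chosen angular station (default: a
primary lobe axis).  Septum centre displacement is the displacement
magnitude at the node nearest the septal disc apex.  The depth-equivalence
calculation fits ordinary least squares lines of mean shell-wall maximum
principal stress against pressure for two models and converts the pressure
at which one model's line reaches the other's reference stress into depth
via `dP / (rho g)` with rho = 1025 kg/m^3, g = 9.81 m/s^2 (~100 m per MPa).
Applied to the published Koch-suite stress table this reproduces the
printed equivalent pressures (2.25 and 2.38 MPa) and depth increments.

## What the models do and do not show

The synthetic suite isolates three morphological factors under strict
control, which real shells never offer.  It inherits the source design's
idealisations: straight cylinders rather than coiled whorls, no siphuncle,
homogeneous isotropic material (no nacre layering), dead pressure loading,
and no internal chamber pressure.  Passing tests therefore demonstrate the
*mechanics of the idealised geometry*, not of real shells.

Two desk-scale observations deserve flagging.  First, with length held equal
across the spacing suite (all three models span the same 20 mm septal band),
total strain energy *increases* with septal spacing -- more septa stiffen the
shell and reduce the work done by pressure.  Second, within the Koch suite
at the default (shallow, 0.2 r) amplitude, the *peak* septum stress rises
monotonically with iteration, but mean septum stress, mean wall stress and
septum-centre displacement move monotonically only from iteration 1 to 2 and
flatten or slightly reverse at iteration 3; displacement *grows* with
iteration, because normalising peak-to-peak amplitude across iterations
drains the primary (four-lobe) dome component as frill height accumulates,
leaving a flatter, more compliant interior.  Deeper flutes reverse this (at
~0.45 r amplitude the third iteration is stiffest), so these directions are
sensitive to the unreported amplitude of the original suture drawings.
Both observations are left visible in the acceptance suite rather than
calibrated away.

## Limitations

* Linear kinematics: no buckling, contact or failure criterion; stresses
  scale exactly with pressure.
* The height-field septum solver requires single-valued sutures; truly
  overhanging (classic 60-degree Koch at high iteration) frills are outside
  the meshable family, though the curve generator itself supports them.
* Structured meshing concentrates distorted elements where steep Koch
  frills warp the wall grid; quality is monitored (positive Jacobians
  enforced, fallback splits counted) but local stress extrema there carry
  more discretisation error than the global measures.
* Nodal stress recovery by volume averaging smooths interface
  discontinuities; septum/wall junction peaks are mesh-dependent, which is
  why cross-model comparisons use consistent tiers.
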
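# Methods

`stentrec` reconstructs the three-dimensional geometry of a deployed
coronary stent from two routinely available inputs: segmented intravascular
OCT pullback frames (lumen contour, stent contour, strut points, and an
orientation marker per frame) and a 3D vessel centerline derived from
biplane angiography. The pipeline has three stages — lumen reconstruction,
planar stent-wireframe reconstruction, and roll-back with volume sweeping —
followed by morphometric validation metrics. A synthetic phantom generator
with exact ground truth stands in for physical validation hardware.

## Coordinate conventions

All lengths are millimetres; coordinate systems are right-handed. The
centerline is an arc-length-parameterized polyline (linear interpolation
between vertices; a cubic spline is fitted first when the input is sparser
than 1 mm). Cross-section planes are spanned by rotation-minimizing frames
(RMF) computed with the double-reflection construction, which transports an
initial normal with zero twist and avoids the flips Frenet frames exhibit
at inflection points. The default initial normal is derived
deterministically from the first tangent, so repeated runs and the phantom
generator share one roll convention; absolute roll is then fixed per frame
by the imaged marker. The circumferential origin (angle 0) of every
cross-section is the transported normal direction.

## Lumen reconstruction

Each frame's station is `index x frame_distance` (frame distance 0.1 or
0.2 mm depending on pullback speed); no longitudinal motion compensation is
applied. Lumen contours are placed on the RMF frame at their station,
rotated in-plane by `-marker_angle` so the marker maps to the transported
reference direction (frames without a marker get linear angular
interpolation between the nearest marked frames, with boundary values
held), and lofted: every contour is resampled to `samples_per_contour`
points by arc length starting at the reference direction, and consecutive
rings are stitched with triangles. Anchoring the resampling at the
transported reference gives a twist-free ring correspondence.

## Unrolling

Stent contours and strut points are rotated by exactly the rotation applied
to the same frame's lumen contour, stacked on a straight axis at their
stations, and translated so the distal stent contour centroid is the axis
origin. Unrolling maps each strut to `x` = station minus distal station and
`y` = arc length along the frame's measured stent contour polygon, from the
reference direction to the strut's radial projection (ray from the contour
centroid). Frames with strut points but no segmented stent contour get a
convex contour fitted through the struts. Because the map walks the
measured polygon itself — no smoothing — unrolling and its inverse are
bit-exact mutual inverses per frame: the round trip on noiseless phantoms
reproduces strut positions to machine precision.

Struts farther than 1 mm from the stent contour are flagged malapposed and
unrolled on the arc at their own radius; every strut's radial gap to the
contour is stored and re-applied radially at roll-back, so malapposition
magnitude survives the round trip. A duplicate wrap band (default 2 mm) is
appended beyond `y = perimeter` to expose cross-seam continuity.

## Planar wireframe reconstruction

The builder implements the method's four connection rules — zig-zag
fragments join consecutive peaks and valleys; link locations follow the
stent template's numbered chart; wire-shadow gaps are bridged at the
template's expected crown phase; the pattern repeats across the seam — as
an algorithm. The published procedure performs this step manually; a
declarative edit list (`apply_manual_edits`) preserves the
operator-in-the-loop capability.

Numerical choices, in order of application:

- **Ring clustering.** Strut points are partitioned by nearest expected
  ring center, with the template pitch scaled to the observed axial extent.
- **Phase.** Each ring's zig-zag phase is found by a grid search fitting a
  triangle wave to `x(y)` — robust against link points lying in the
  inter-ring gaps and the quantization of `x` to frame stations.
- **Corner solve.** All legs of a ring share one |slope| by the template
  geometry, so the slope is estimated once per ring (median over per-leg
  fits) and each crown corner is solved with the slope held fixed, pooling
  both flanks (one-sided where the shadow hides a flank). Regressions are
  y-on-x throughout: the station `x` is exact while `y` carries
  segmentation jitter, and an x-on-y fit would attenuate the slope and bias
  every corner inward (errors-in-variables). Samples on the rounded crown
  arcs are excluded from the fits by a y-window (0.1-0.85 of the apex
  pitch) and an x-band (0.12 of the crown height).
- **Bridging.** Unobserved slots are synthesized at the slot phase, at the
  ring's consensus crown level (median of observed refined apexes), and
  marked `bridged`.
- **Crown numbering.** Crown numbers are anchored on a pooled,
  parity-corrected circumferential grid (ring phases alternate by one slot
  between neighbours); per-ring sorting by raw y would rotate the numbering
  whenever an apex sits within noise of the seam and mispair the links.
- **Link rotation.** The global rotation of the crown numbering relative to
  the template's link chart is unobservable from the zig-zag rows alone;
  the strut points falling between a ring's peak level and the next ring's
  valley level can only belong to links, and the rotation whose predicted
  link positions best match them is chosen — the algorithmic analogue of an
  operator aligning the CAD chart with the visible link points.

A linked crown pair is represented by one degree-4 junction node at the
link midpoint, with the two crown apexes absorbed into the incident edge
polylines; unlinked apexes are degree-2 nodes. This is the representation
under which "every link-junction has degree 4, every crown apex degree 2"
holds exactly.

Perimeter handling: when per-frame stent-contour perimeters vary by more
than 10% (tapered vessels), the builder works in normalized azimuth
(y scaled to the mean perimeter) and the roll-back rescales per station.

## Roll-back, crown rounding, volume sweep

Roll-back is the inverse of unrolling: edge polylines are densified
(default 0.05 mm), `x` selects the frame pair by bisection with a linear
blend of equal-arclength-resampled contours between frames, `y` is walked
as arc length along the blended contour, and the malapposition field —
median gap of at least 4 observed struts within 0.3 mm, with gaps below
0.1 mm treated as apposed so jitter is not re-applied — offsets samples
radially. At exact frame stations the frame's own measured polygon is
used, preserving the exact inverse. The resampled contours are smoothed
longitudinally with a triangular window (+-3 frames) before blending; the
window is symmetric, so linear axial trends (tapers) pass through
unchanged, while per-frame segmentation noise is damped by about a factor
of two. Real lumens with abrupt steps (e.g. at a side branch ostium) would
be blurred over ~0.5 mm by this window — the phantoms do not model such
steps, so passing tests bound only smooth-lumen behaviour.

Crown apexes are rounded with circular-arc fillets tangent to both legs
(default radius 1.5x the strut half-width; infeasible radii fall back
per-apex to the maximum feasible with a warning; near-parallel spike
corners, an artifact signature, are left sharp). The strut profile —
circular or rectangular per the template — is swept along each edge with
rotation-minimizing orientation; rectangular profiles align their wide face
tangent to the lumen surface via the radial direction from the centerline,
falling back to RMF orientation where no radial direction is defined (e.g.
strongly malapposed struts near the axis). Circular profiles are
area-corrected n-gons so swept volumes match closed forms. Per-segment
meshes are watertight (flat caps; tangent-continuous across filleted
degree-2 nodes); a boolean union at junctions is attempted only when a
boolean engine is available, otherwise segments are concatenated.

## Metrics

- **Stent length**: centerline arc length between the most distal and
  proximal strut material.
- **Mean stent diameter (MSD)**: serial cross-sections every 0.1 mm,
  cut perpendicular to the centerline; per slice, the area-equivalent
  diameter `2*sqrt(A/pi)` of the polygon through the strut intersections
  ordered by azimuth (min/max Feret widths are available behind a flag);
  slices with fewer than 3 intersections are skipped. Raw strut positions
  are used at malapposed sites.
- **Ellipse ratio**: furthest-pair distance X over the maximum point-pair
  separation perpendicular to X. Ratios are reported only for slices that
  sample the full circumference (no azimuthal gap over 90 deg and at least
  6 points): a cut grazing only inter-ring links does not define a stent
  shape, and the extremes-based ratio is meaningless there.
- **Malapposition**: signed distance from wireframe samples to the lumen
  surface, positive toward the lumen center (exact point-to-triangle
  distances against KD-tree candidate triangles).
- **Bland-Altman**: mean difference and mean +- 1.96 x sample SD of the
  paired differences. The published agreement intervals behave as limits of
  agreement, which is what is implemented and labelled.
- **TAWSS**: trapezoidal time integral of |tau_w| over one cardiac cycle,
  divided by the cycle duration, per surface element (at least 3 time
  points required).

Paired reconstruction-vs-truth comparisons slice both stents on one common
station grid (`paired_cross_sections`); per-series grids would silently
misalign for some frame distances.

## Synthetic phantoms

The generator replaces silicone casting and micro-CT. A parametric vessel
(straight, circular-arc, or helical centerline; constant, tapered, or
elliptic lumen) receives the template stent by purely geometric wrapping:
the planar pattern is mapped onto the wall preserving circumferential arc
length (scaled to the local lumen perimeter), as a metal scaffold conforms
to a non-circular lumen — and matching the isometric assumption of the
unrolling stage. Crowns are rounded in the planar pattern with the same
default fillet the reconstruction uses, because physical stents have
rounded crowns. Malapposition zones offset struts radially inward by a
prescribed gap. No mechanics are modelled; the reconstruction never models
mechanics either, so geometric wrapping is sufficient to validate it.

The virtual pullback cuts frames every `frame_distance` along the
centerline. Strut points are wireframe/plane intersections with i.i.d.
Gaussian jitter (default sd 0.03 mm, the scale of OCT axial resolution);
contours get smooth low-order Fourier radial noise of the same pointwise
sd, emulating operator tracing error, which is correlated along the contour
(i.i.d. vertex noise would produce self-intersecting polygons). A
guidewire-shadow sector (default 30 deg, optionally drifting) censors strut
points in catheter coordinates; per-frame catheter rotation (drift) is
encoded by the marker angle. The marker is defined relative to the shared
RMF roll convention, standing in for a physical marker of known absolute
orientation. The catheter is kept on the lumen axis; catheter eccentricity
is not simulated. Everything is driven by one seeded generator: equal seeds
give byte-identical frame files.

The six-phantom validation suite (`validation_suite`) spans deployment
diameters 2.5-4.0 mm, 16/18 mm templates with 6-10 crowns per ring, both
frame distances, and elliptic lumens up to ratio 1.5, all at 0.03 mm jitter
and 30 deg shadow.

What passing tests do *not* show: performance on lumens with focal
stenoses, side branches, or thrombus; strut-level segmentation errors
beyond Gaussian jitter (dropouts, duplicates); overlapping or double-stent
patterns; catheter eccentricity and NURD-type rotational artifacts beyond
smooth drift.

## Defaults and degenerate inputs

| parameter | default | rationale |
|---|---|---|
| frame field spacing | 0.05 mm | well below frame distance; RMF queries continuous |
| samples per lofted contour | 64 | sub-0.5% area error on 3 mm lumens |
| clustering radius | 0.15 mm | point-to-wireframe match radius |
| apex prominence | 0.25 x crown height | rejects mid-leg extrema |
| crown fillet radius | 1.5 x strut half-width | visually matches deployed stents; no published value |
| densification step | 0.05 mm | edges follow surface curvature |
| section spacing | 0.1 mm | serial cross-section spacing of the validation protocol |
| wrap band | 2 mm | seam-continuity band of the unrolled plane |
| gap-field radius / neighbours | 0.3 mm / >= 4 | median malapposition support |
| jitter sd (phantom) | 0.03 mm | OCT axial resolution scale |
| shadow width (phantom) | 30 deg | guidewire shadow |

Degenerate inputs raise typed errors: non-increasing stations, contours
with under 3 vertices or self-intersections, stations beyond the
centerline, single-contour lofts, missing markers, empty strut sets,
zero-length sweep edges (skipped with a warning), and WSS histories with
fewer than 3 time points.

## Known limitations

- The wireframe builder assumes a single zig-zag-and-link stent matching
  the supplied template; overlapping stents and template inference from
  points alone are out of scope.
- The RMF framing convention is a choice (the published procedure does not
  name its framing); it is shared between phantom and reconstruction, so
  the tests do not probe sensitivity to a mismatched roll convention.
- CFD itself is out of scope: the package exports CFD-ready surface meshes
  and post-processes solver WSS histories (TAWSS), nothing more.
- Junction meshing falls back to concatenated capped segments when no
  boolean engine is installed; the surface is then watertight per segment,
  not globally.
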
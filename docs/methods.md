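# Methods

`nasolab` quantifies residual upper-lip dysmorphology after unilateral
cleft-lip repair on 3D surface scans: per-axis bilateral asymmetry of the
landmark-bounded upper-lip region, the surface area of a manually traced
scar, and the reliability statistics that connect such objective
measurements to panel-based Likert ratings.  This note records the models,
conventions and numerical choices, and what the synthetic validation does
and does not establish.

## Anatomical frame and units

All coordinates are millimetres.  STL carries no unit metadata; files are
taken as stored (a `stl_scale` config/CLI override exists for scans
exported in other units).

Reported disparities are resolved in a landmark-derived anatomical frame:

* **X (mediolateral)** — the unit vector from the right to the left
  cheilion;
* **Y (vertical)** — the component of (subnasale − mid-cheilion)
  orthogonal to X, normalised;
* **Z (depth)** — X × Y;
* origin at the subnasale.

A landmark-derived frame makes the per-axis numbers invariant to scanner
pose, at the cost of depending on the digitized landmarks; the
repeat-digitization distances reported per case bound that dependency.

## Region extraction

The five named landmarks (right/left alare, subnasale, right/left
cheilion) and the ordered vermilion-border curve are snapped to the
surface by exact point-to-triangle projection (default tolerance 1 mm; a
farther landmark is an error naming it).  The upper-lip boundary is the
closed loop right cheilion → right alare → subnasale → left alare → left
cheilion → vermilion border (traversed left to right) → right cheilion,
with consecutive anchors linked by shortest paths on the mesh edge graph;
anchors are first inserted as mesh vertices by splitting their containing
faces.  Edge-graph paths overestimate the continuous geodesic by a bounded
grid-metric factor (≈8% worst case on regular grids), which is adequate for
region bounding; exact polyhedral geodesics were deliberately not used.

Regular scan meshes make shortest paths massively degenerate (many
equal-length staircases).  Ties are resolved deterministically: among the
edges of the true shortest-path DAG (per-edge slack 1e-9 mm), the path
minimising the integrated distance to the straight start–goal chord is
selected.  The chosen boundary is therefore reproducible, mirror-consistent
on symmetric meshes, and still exactly a Dijkstra optimum — its length
matches an independent Dijkstra implementation to 1e-9.

The enclosed region is flood-filled from a seed point over face adjacency,
with boundary edges acting as walls.  The default seed is the midpoint of
the on-surface path from the subnasale to the middle vermilion point — an
interior point for any lip-like geometry, where a naive 3D centroid can
project outside the region on strongly curved surfaces.  Faces are kept
whole (centroid rule, no clipping): region extraction feeds the asymmetry
integral, where sub-face accuracy is immaterial.  If the seed selects the
larger of the two sides a warning reports both areas (the seed was
probably outside).

## Mirror, registration, disparity

The extracted region is reflected through the plane holding the frame
origin with normal X (face winding reversed).  The mirror is then
superimposed on the original by **rigid** Procrustes surface registration:
scaling is excluded because the reported disparities are millimetre
quantities.  Two phases:

1. **Trimmed point-to-point ICP** — each iteration matches transformed
   mirror vertices to closest points on the original surface
   (point-to-triangle), keeps the best 90% (trimming reduces boundary and
   outlier bias on open regions), and solves the orthogonal Procrustes
   problem in closed form.  The recorded trimmed RMS is non-increasing;
   iteration stops at a trimmed-RMS change < 1e-9 mm or 100 iterations.
2. **Trimmed point-to-plane Gauss–Newton refinement** (up to 60 steps,
   stopping at an update norm < 1e-13).  Smooth facial surfaces constrain
   near-tangential slides only weakly; point-to-point steps move along
   such modes extremely slowly, whereas the point-to-plane linearisation
   converges in a handful of steps.  This is what makes the measurement
   invariant (to < 1e-6 relative) to where exactly the mirror plane was
   placed.

A registration is flagged failed when the median correspondence distance
exceeds 5 mm (configurable); failed cases are reported as such, never as
silent zeros.

The **displacement field** assigns each region vertex the vector to its
closest point on the registered mirror surface, expressed in the
anatomical frame.  Conventions, also echoed in every report header:

* disparity is the raw original-to-mirror distance — for an ideal
  mid-plane about twice the one-sided deviation from symmetry — and is
  unsigned;
* per-axis summaries are means of absolute components; `mean_total` and
  `max_total` summarise the Euclidean norms;
* means are area-weighted (barycentric vertex areas), so they estimate the
  surface-integral mean rather than the vertex-count mean; the two differ
  by a few percent through boundary over-counting.

## Scar area

The scar is outlined by four anatomical anchor points (most prominent
vermilion-border point on each side of the scar; most medial and lateral
points at the nasal floor) plus free polyline points.  Points are snapped
to the surface; consecutive points farther apart than 2.5 median edge
lengths are bridged by the same tie-broken shortest-path rule as region
boundaries; dense stretches are followed as straight segments walked
across adjacent faces (entry/exit points computed on shared edges).

The enclosed area is the **true 3D surface area**, not a projection: scar
relief is part of the quantity of interest.  Interior faces are summed
whole; triangles straddling the trace are cut along it: the per-face chain
polylines (2D in the face plane, slightly extended past the triangle
boundary) are subtracted as a hair-thin buffer (1e-7 of the face scale),
which separates the pieces robustly even when a crossing point misses the
boundary by float noise.  Pieces are classified by the signed side of the
nearest chain segment, with the side-to-inside orientation decided by a
global majority vote against flood-fill labels of adjacent whole faces;
each face's outside share is obtained by subtracting its inside pieces
from the face area, so clipped + complement partitions the parent area to
machine precision.  On planar test grids an off-grid rectangle is
recovered to ≈0.02% and a unit square aligned with mesh edges is exact.
A trace must enclose at least one whole face: a band narrower than the
local mesh resolution is rejected with an explicit error.  The pipeline
seeds the interior automatically (midpoints of chords between
loop-opposite trace points, projected to the surface, deepest-inside
candidate kept) and, because a scar patch is by definition the smaller
side of its outline, re-seeds from the complement if the heuristic picked
the larger side.

Known fragile configuration: a trace chord running for long stretches
*within float noise of, but not exactly on,* mesh edges (e.g. a synthetic
circle at exactly a uv-sphere latitude).  Exactly-on-edge stretches are
detected and treated as walls; hand-clicked clinical traces do not produce
the near-coincident case.

## Synthetic validation cases

No scan data are publicly available for this measurement task, so the
package ships a generator of nasolabial-like surfaces with analytically
known ground truth.  The base surface is a circular-arc "lip barrel"
(cylinder sheet, axis mediolateral, radius 24 mm, arc −115°…118°, width
64 mm) with a mirror-symmetric cosine relief (amplitude 0.8 mm,
wavelengths ≈13–15 mm) confined to the lip band below the nasal sill.
Design rationale:

* the barrel is developable, so geodesics are straight in the unrolled
  plane, the landmark-bounded region is an exact polygon there, and the
  scar band's flat area is exactly width × length;
* the default asymmetry-patch site (φ = 90°, the nasal-sill curl) has its
  surface normal aligned with the anatomical Y axis.  A displacement
  component tangent to a surface is invisible to surface-to-surface
  distance; aligning the normal with the injected direction is the only
  configuration in which closest-point disparity can recover the injected
  magnitude axis-pure.  The patch is wide (9 mm radius) and
  cosine-tapered (C¹) so its flanks stay gentle up to δ = 2 mm;
* the relief emulates philtrum/vermilion texture and removes the slide
  symmetry of a pure surface of revolution — a symmetry no real face has,
  and under which no surface registration could pin the tangential
  alignment.  It is windowed away from the patch so normal alignment is
  preserved where the displacement is injected.

Injected features with stored truth: the asymmetry patch (direction one of
the anatomical axes, magnitude `delta_mm`), a scar band (paramedian
vertical ridge raised along the surface normal inside a closed boundary
whose ground-truth trace lies on undisplaced surface; its 3D area is
computed by brute-force triangulation at 10× grid resolution), Gaussian
vertex noise, and a rigid pose perturbation.  Landmarks and scar traces
are carried through the pose perturbation (they are "digitized" on the
delivered scan) but not the noise (snapping absorbs it).  All randomness
derives from the spec seed; identical specs yield bit-identical meshes.

Defaults describe a mild residual deformity: δ = 1 mm vertical patch (the
order of reported residual asymmetries in repaired clefts), 0.3 mm scar
ridge over a 2 × 67 mm band, 0.05 mm vertex noise (the accuracy class of
intraoral scanners), grid n = 96 (≈9.4k vertices — landmark-region
measurements stabilise well below 1% discretisation error at this
resolution while a full case analyses in seconds).

The **asymmetry oracle** integrates the stored analytic displacement field
over the unrolled region polygon by dense quadrature (0.15 mm grid) — no
meshing, no registration.  Each patch contributes twice (once where the
original is displaced, once mirrored), so the oracle mean is
2·δ·∫b dA / A.  It is exactly linear in δ and axis-pure by construction.

What passing the synthetic suite shows: the pipeline's geometry and
statistics are internally correct and recover known truths at realistic
noise levels.  What it does not show: robustness to real scan pathologies
(holes, self-occlusions, texture-driven landmark ambiguity, non-rigid
expression differences between capture moments), nor anything about any
specific clinical cohort.

## Rater statistics

Ratings are five 1–5 Likert scores per case/rater/occasion (scar length
visibility, scar width / vermilion continuity, vermilion-border height
disparity, vertical asymmetry, depth asymmetry), two panels (professional,
lay), two occasions.  Composites: scar = length + width; asymmetry =
height disparity + vertical + depth; total = all five.  Conventions for
tie-heavy ordinal data:

* **Kendall correlation is tau-b** (tie corrections in both margins);
  tau-a would be biased toward zero on 1–5 data.  p-values: exact
  permutation enumeration for n ≤ 8 (valid under ties), tie-corrected
  normal approximation otherwise.
* **Wilcoxon signed-rank** drops zero differences and average-ranks tied
  |differences|; two-sided p by exact sign-flip enumeration (generating
  polynomial over doubled ranks) for effective n ≤ 25, else the tie- and
  continuity-corrected normal approximation.  The exact branch matches
  brute-force sign-flip enumeration exactly, including under ties (where
  other conventions — e.g. integer-rank permutation — give slightly
  different numbers).
* **Kruskal–Wallis** H with tie correction; p from chi-square (k−1 d.f.),
  optionally exact by enumeration of group labelings for total n ≤ 10.
* All-zero differences / fully tied margins / all-identical groups are
  degenerate: p = 1 with a note, or an error where the statistic is
  undefined (tau).
* Intra-rater tables pair occasion 1 vs 2 pooled over a panel's
  (rater, case) pairs; inter-panel tables compare the two panels'
  pooled scores (Kruskal–Wallis) and correlate per-case panel means
  (tau-b) — panels have different raters, so pairing exists only at case
  level.  Subjective–objective correlations use per-case mean composites
  (occasions pooled) against scar area and mean total disparity.
* No multiple-testing correction is applied; p-values are raw.

The rating simulator maps objective severities onto the 1–5 scale (higher
= more severe; the anchor direction is configurable in principle but this
convention is assumed throughout), adds per-rater bias and per-occasion
noise, and is used to exercise the tables where no human panel data exist.

## Degenerate inputs and edge behaviour

* Meshes: out-of-range face indices are hard errors; degenerate faces and
  unreferenced vertices are reported, not repaired.  Welding uses 1e-6 mm
  grid rounding (idempotent; below scanner precision).
* Coincident cheilions, subnasale on the cheilion line, coincident
  boundary anchors, open traces, empty regions: errors with the offending
  element named.
* Disjoint registration inputs: flagged failed, values still reported.
* STL attribute channels are dropped with a warning (no portable STL
  attribute standard); disparity color maps go to ASCII PLY instead, on a
  fixed blue–white–red scale over 0–2 mm so maps are comparable across
  cases (values beyond the range clamp to the end colors).

## Problem sizes used in the shipped verification

Synthetic cases run at grid n = 96 (9 409 vertices, 18 432 faces; region
≈6.7k vertices); the sphere oracle at a welded 100×100 uv-sphere; type-I
error simulations at 2 000 replicates of n = 15; the cohort check at three
cases (δ = 0, 1, 2 mm) with default noise.  These sizes hold all
discretisation terms comfortably below the tolerances they are tested
against while keeping a full verification run in minutes.
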
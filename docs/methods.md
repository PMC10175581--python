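# Methods

This note documents the models, conventions, and numerical choices behind the
package, and what the synthetic validation does and does not establish.

## Coordinate and intensity conventions

Cell centers and puncta live in continuous physical coordinates (μm);
rasterization happens only when a channel is rendered or a polygon is turned
into a pixel mask. The pixel grid has its origin at the top-left corner, and
pixel `(row, col)` has its center at `((col + 0.5)·p, (row + 0.5)·p)` for
pixel size `p` μm. Areas are pixel counts × `p²`. Rendering uses a fixed
linear intensity scale (1 arbitrary unit = 1 gray level, clipped to [0, 255]);
there is deliberately no per-image normalization, because the downstream
fixed thresholds (70 for the astrocyte marker, 30 for puncta) are only
meaningful on a stable scale.

## Point-process models

- **CSR / homogeneous Poisson** (`simulate_poisson_pattern`): count ~
  Poisson(λ·area), positions i.i.d. uniform. This is the wild-type-like null.
- **Thomas (Neyman–Scott)** (`simulate_thomas_pattern`): parents ~
  Poisson(κ·area) uniform; each parent emits Poisson(μ) offspring displaced
  by an isotropic Gaussian of scale σ. Offspring outside the window are
  discarded (no wrapping); a toroidal option exists only so intensity
  calibrations can be checked without edge loss. Parent assignments are kept
  as ground-truth cluster labels.

All randomness flows from a single integer seed through spawned child
generators (one per stochastic layer), so a scene spec is bit-reproducible
and layers do not perturb one another.

## NND and spacing index

For each point, the NND is the Euclidean distance to the closest other point
(kd-tree accelerated; validated exactly against the O(n²) computation). No
edge correction is applied by default — distances are measured on the raw
frame, as in the workflow being reproduced. The spacing index is
`mean(NND)² × density`. Under CSR, E[NND] = 1/(2√λ), so the index tends to
1/4; the test suite verifies 0.25 ± 0.02 under toroidal evaluation, which
removes the upward edge bias of finite frames. Clustered (Thomas) patterns
give strictly smaller values; a unit-spacing square lattice gives exactly 1.
The index is invariant under coordinate scaling and under density changes of
a CSR pattern, which is exactly why it is used: it separates "more cells"
from "cells arranged in clumps".

## Center dots vs. thresholded masks

The source workflow uses two different object reductions, and the package
mirrors the split:

- **Counting, NND and colocalization** operate on *center dots*. On real data
  these are manual dot annotations (importable via CSV); on rendered scenes
  `detect_cell_centers` places a dot at each local intensity maximum above
  the marker threshold after light smoothing (σ = 1 μm), with maxima closer
  than 4 μm merged. Peak detection, unlike connected-component centroids,
  still resolves two somata whose masks touch — the raster analogue of
  nucleus-guided manual dot placement.
- **Clustering** operates on the thresholded mask (≥ 70), as in the original
  enlarge-and-merge procedure.

## Perimeter-distance clustering

Each object mask is dilated by a Euclidean disk of radius 10 μm (exact
distance-transform threshold, not a square kernel — the criterion is an
isotropic distance in μm; a literal pixel radius is available for replicating
legacy fixed-pixel settings). Connected components (8-connectivity) of the
dilated union are candidate clusters: two somata join when their perimeter
gap is ≤ 20 μm, and membership is transitive along chains. Components with a
single object are removed (singleton rule) and logged. No minimum
cluster-area filter is applied. Because the original enlarge-then-measure
procedure is ambiguous about whether the dilation margin counts toward
cluster area, both metrics are reported: `area_um2` (merged dilated
component, margin included) and `core_area_um2` (union of member masks).

The implementation is validated against an exact geometric oracle
(boundary-to-boundary distances between shapely shapes, graph connected
components) on scenes of non-overlapping disks at 0.5 μm/px; agreement is
exact except for pairs whose gap lies within one pixel of the 20 μm
criterion, where rasterization legitimately rounds either way. Overlapping
disks are excluded from oracle scenes because they rasterize into a single
object — a different scene, not an operator discrepancy.

## Compartmentalized puncta

A punctum belongs to a compartment iff its centroid pixel lies on the
compartment mask (the analogue of clearing particles by location), so
inside + outside counts always conserve the total. Densities divide by the
compartment area and by frame − compartment area respectively; zero-area
compartments with nonzero counts are flagged and reported as NaN rather than
raising.

## Regions, intensity, fascicles

Quadrant subdivision clips the user-supplied striatum polygon with the four
boxes formed by the midpoints of its bounding extent. Because coronal
sections can be mounted either way, the medial side (`left`/`right`) must be
declared per image; dorsal is the small-y half under the image convention.
Integrated density is Σ(pixel values inside the polygon) × pixel area, and
intensity divides it by the measured (rasterized) region area, so a constant
region of value v has intensity exactly v regardless of size.

Fascicle size classes use the boundaries 1,000 and 5,000 μm² with both edges
assigned to "medium" (the printed ranges overlap at the boundaries; the
inclusive-medium convention is declared and tested). A fascicle is
marker-positive iff at least one cell centroid lies within its mask dilated
by a 10 μm halo — an explicit, configurable stand-in for visual scoring,
using the same distance scale as the clustering criterion.

## Statistics

Measurements are aggregated image → animal → group, never pooled across
animals; the animal is the unit of analysis. Normality testing is dispatched
on sample size (D'Agostino–Pearson for n ≥ 8, Shapiro–Wilk for 3 ≤ n < 8;
below 3 neither is defined). When normality fails, the parametric test is
still run and the failure is flagged in the result — matching the reporting
practice being reproduced — rather than silently switching to a
nonparametric test. Designs: unpaired two-tailed t; paired t keyed on animal
id (invariant to row order); one-way ANOVA with Tukey HSD; two-way ANOVA
(type-II) with Sidak-adjusted two-group contrasts within each level of the
second factor, computed on the pooled residual variance as GraphPad-style
workflows do. α = 0.05, configurable. Null calibration of the two-group t
(rejection rate 5% ± 1% over 2000 replicates) is part of the test suite.

## Synthetic scenes: defaults and fidelity limits

Scene defaults describe a 0.4 mm² analysis frame (632 × 632 μm at 1 μm/px):
~25 astrocytes per frame for the wild-type-like world, 35% dual-marker
fraction, an independent second-marker population at the same intensity,
puncta at 5×10⁻³/μm² in gray matter with a 10-fold depletion inside
exclusion zones (cluster territories of radius 30 μm around productive
Thomas parents, plus fascicles), and three elliptical fascicles spanning the
size classes. The disease-like world uses a Thomas process at 1.5× total
intensity with μ = 5 offspring per parent and σ = 10 μm dispersion.

Somata are rendered as Gaussian blobs with σ = 2.5 μm and amplitude 160 over
background 10 (noise σ = 4), so the fixed threshold 70 cuts an isolated soma
at ~7 μm diameter. The soma scale is a validity precondition of the
synthetic world, not a free dial: somata must remain resolvable at the
clustered process's typical sibling spacing, which is what nucleus-guided
manual annotation achieves on real tissue; blob renders carry no nucleus
channel, so resolvability has to live in the soma footprint itself. Even so,
~10–20% of clustered somata fuse at μ = 5, σ = 10, which attenuates (but
does not invert) the measured density contrast — the end-to-end validation
sizes its cohorts (8 animals × 8 images per genotype) so the group direction
is stable against this attenuation.

What a green synthetic run establishes: the operators implement their
definitions (oracle equivalence), the statistics hit their analytic limits
(CSR calibrations), planted structure is recovered (cluster counts, density
ratios), and the full pipeline wiring reproduces the qualitative group
contrasts it was built to detect. What it does not establish: performance on
real tissue — no astrocyte arborization (blobs approximate somata only), no
autofluorescence or uneven illumination, no true 3D structure (z-stacks are
max-projected), and no model of anatomical landmark identification (region
polygons are user input).

## Degenerate inputs and tie-breaks

Duplicate points yield NND 0 with a warning; patterns with fewer than two
points are rejected. Colocalization pairing is greedy in ascending distance
with lexicographic (a_id, b_id) tie-break, one-to-one, within 5 μm by
default (≈ one soma radius); on well-separated dual populations it coincides
with the optimal assignment (tested). Empty segmentations produce empty
cluster sets with a warning. Thomas scenes keep parent assignments even for
offspring-free parents (they simply have no members).
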
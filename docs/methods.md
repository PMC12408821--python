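# Methods

This note records the models, conventions and numerical choices behind
`vasctree`, and what the synthetic phantoms do and do not establish about
real imaging data.

## Data model and conventions

A vessel network is a spatial graph: nodes (3D junction/end locations),
segments (node-to-node polylines) and per-point radii, all in world-space µm.
Voxel indices appear only inside volume operations and convert through an
isotropic voxel size plus the µm position of voxel (0,0,0). The AmiraMesh
ASCII thickness channel is read as a **radius** by default
(`thickness_is_diameter=True` halves it); zero-arc-length segments are
rejected at load time because they break tortuosity and angle definitions.
Multifurcations are first-class; binary trees are a special case. Rooting is
breadth-first from a chosen node, or automatically from the degree-1 node
whose incident segment has the largest mean radius — the cut stump of the
feeding artery in an autopsy-derived network.

## Ordering and branching ratio

Truncated Strahler ordering assigns order 1 to every observed terminal
segment (the network is truncated above its true arteriolar endpoints);
at a junction the parent takes max(child orders), incremented by one when
that maximum is attained by at least two children — the standard
multifurcation generalisation of the pairwise rule. Topological generation
is centrifugal: root segment 1, +1 across every branching node. Degree-2
(pass-through) nodes are geometry, not topology: they never increment either
quantity, and both orderings are invariant under segment subdivision (a
property test enforces this).

The branching ratio is fitted by OLS of ln N on O; we use the operational
definition γ = e^(−slope) (equivalently N = N₀·γ^(−O)), which reproduces
γ = 2 exactly on a perfect binary tree. The natural log is used; base
changes cancel in γ. The fit range is configurable (`fit_range`), defaulting
to all orders; on the reference kidney's per-order counts all orders give
γ ≈ 2.83 and orders 2–9 give ≈ 2.99, bracketing the published whole-network
value. The missing-order estimate k = ln(N*/N₁)/ln γ assumes the branching
ratio persists below resolution; with non-terminal endpoints (glomeruli
sprouting from non-terminal arterioles) it is a lower-bound-flavoured
estimate, which is why it is reported as a fractional number of orders.

## Skeleton post-processing

**Smoothing.** Interior points of segments at or above the order threshold
(default 5) are relaxed for 15 iterations by a weighted average with
neighbour weight 0.8 and current-point weight 0.1. Those weights do not sum
to one; we split the neighbour weight symmetrically (0.4 each) and normalise
the triplet by 0.9, which makes the update a convex combination — endpoints
stay fixed, radii untouched, and the sum of squared deviations from the
chord is non-increasing per iteration (tested). Two-point segments pass
through unchanged.

**Collapse flagging.** Every segment of order ≥ 5 is a collapse candidate
(`auto_large`); smaller segments are flagged when their mean radius falls
below the 10th percentile of mean radii within their own order. (One source
stated "below the 90% percentile" and another "below the 10th percentile";
the 10th is adopted — a 90% threshold would flag nearly everything — and the
threshold is configurable.) Orders with a single segment get no percentile
flag. Confirmation is a batch decision map (segment id → confirm/clear), so
the pipeline is scriptable; an interactive prompt is deliberately absent.

**Cross-sections and radius correction.** At every centreline point of a
confirmed segment a plane normal to the local (central-difference) tangent
is sampled from the binary volume by trilinear interpolation, lightly
blurred in-plane (σ = 1 plane-pixel) to regularise the voxel staircase, and
thresholded at 0.5. Only the connected component containing the plane centre
is kept; its sub-pixel marching-squares contour length is the perimeter, and
the equivalent radius is perimeter/2π — the radius of the circle with the
same perimeter, which is robust to partially collapsed (non-convex) lumen
shapes. Plane half-width starts at 4× the segment's current mean radius
(floored at 4 voxels) and doubles while the section clips the window — the
skeleton radius of a collapsed vessel under-reads the lumen, so a fixed
multiple of it would crop the patent cross-section. Per segment, plane radii
outside the 5th–95th percentile window are discarded (residual-tortuosity
outliers and junction blobs); discarded or empty planes inherit the nearest
valid plane's radius along the polyline. Per-plane radii are written by
default; `per_segment_constant=True` assigns the median instead. Radius
correction never changes topology. On straight-tube phantoms the measured
equivalent radius is accurate to well under half a voxel at radius/voxel ≳ 8;
closed-loop correction of planted collapses recovers the true radii with
sub-1% median error at the phantom scales used in the tests.

**Short pinches.** Within a segment, point radii strictly below the
segment's own 5th percentile are replaced by the nearest non-outlier radius
along the polyline; positions untouched.

## Morphometry

Tortuosity is arc/chord (≥ 1, NaN for loop-backs). Branching angles use
chord vectors (start→end node, ignoring tortuosity): the default per-segment
`child_parent` angle is measured at the junction between the vector to the
parent's start node and the vector to the child's end node, so a straight
continuation scores 180°; `child_child` reports per-junction angles between
child chords (mean over pairs at multifurcations). Segment volume uses the
truncated-cone midpoint rule Σ π r̄² ℓ. Length:diameter is L/(2 r̄).
Midpoint inter-vessel distance takes the point at half arc length and the
nearest other segment's midpoint (self excluded, no adjacency exclusion,
exact ties broken toward the smaller id); the voxel estimator is the exact
Euclidean distance transform (scipy) of the vessel mask in µm, summarised
per compartment. Compartment assignment labels a segment by the unique
non-background label its points fall in; segments touching two or more
compartments are excluded — the per-zone tables report that excluded share
explicitly so the accounting is auditable.

## Radial scaling and cross-network comparison

Downstream endpoint counts N_d are computed by post-order summation (leaves
1, internal = Σ children). The scaling exponent *a* in R ∝ N_d^a is the SMA
slope of log₁₀R on log₁₀N_d — closed form sign(r)·SD(y)/SD(x), 95% CI
b·(√(B+1) ± √B) with B = F(0.95; 1, n−2)(1−r²)/(n−2). SMA is used because
both variables are measured with error; its axis-swap equivariance
(slope_xy·slope_yx = 1) and agreement with the geometric mean of the two OLS
slopes are verified in tests. All segments with N_d ≥ 1 enter the default
fit, using segment mean radii.

Murray tables report, per junction, parent radius^(1/a) against the child
sum (a = 1/3 by default, i.e. cubes) and the relative deviation
(Σr_c³ − r_p³)/r_p³. For a generator tree with a = 0.55 the deviation is
exactly 2·2^(−1.65) − 1 ≈ −0.363: children shed radius faster than the cube
law, so the child sum falls short.

Two networks' per-order radii are compared by OLS of log₁₀(radius) on order,
separately and pooled, with the extra-sum-of-squares F statistic
[(SS_pooled − SS_sep)/2]/[SS_sep/(n_a+n_b−4)] against F(2, n_a+n_b−4) — the
two constrained parameters being slope and intercept jointly. An
`anchor_order` normalises each table so that order's radius maps to 1 (the
cross-species plotting convention); because that is a per-table constant
shift in log space it leaves the separate fits unchanged, but anchoring by a
*measured* (noisy) anchor radius injects that measurement's noise into every
residual of the pooled fit and inflates the type-I error far above nominal
(~30% in simulation at σ = 0.05 dex). The F-test calibration experiment
therefore runs on unanchored tables, where simulation confirms the nominal
5% level; anchoring remains available for presentation. Degenerate
comparisons are resolved with a scale-aware tolerance: identical tables give
F = 0, p = 1; exact but different lines give F = ∞, p = 0.

## Validation metrics

Topological precision is the fraction of the predicted mask's 3D-thinned
skeleton lying inside the ground-truth mask; recall swaps the roles; clDICE
is their harmonic mean. Thinning uses scikit-image's 3D skeletonization;
when thinning annihilates a tiny object entirely (a known failure for small
even-width shapes) the mask's own voxels stand in so degenerate inputs stay
scoreable. Detection rate by radius counts a ground-truth segment (mean
radius above threshold) as detected when ≥ 50% of its centreline points fall
on predicted foreground.

The skeleton super-metric compares a candidate skeleton with its source
segmentation through five components: relative tube-reconstruction volume
discrepancy, |ΔCC|, |ΔEuler| (26-connectivity), centreline sensitivity
(fraction of skeleton points on mask foreground) and bifurcation DICE
(skeleton-graph branch nodes vs branch points of the thinned mask, greedily
matched closest-first within a capture radius, default 2 voxels). Branch
voxels of a thinned fat-tube mask cluster and sit up to a vessel radius away
from the true junction, so clusters are collapsed to centroids and the
capture radius should be set near the large-vessel radius when junctions are
fat relative to the voxel size. Weights default to 1; the combined score is
the weighted Euclidean norm with sensitivity and DICE entering as
(1 − value), hence zero iff all components agree perfectly and homogeneous
of degree 1 in the weights. Per-component values are always reported so a
ranking can be audited.

## Synthetic data: what it emulates, and what it does not

`TreeSpec` defaults are the measured whole-kidney structure: nine truncated
Strahler orders, branching ratio 2.9, root radius 2900 µm, radial scaling
exponent 0.55, per-order length:diameter targets derived from the reference
per-order mean lengths and radii (L/2r ranging from ~29 at order 1 to ~2 at
the root), branch angles drawn around a 35° deviation from the parent axis
(SD 12°), and centreline tortuosity noise of amplitude 200 µm (two smooth
perpendicular sinusoid components with random phase, zero at the endpoints,
capped at 10% of the chord so short segments stay sane).

Construction is top-down by order: each segment above order 1 branches into
m ≥ 2 children of the next order down, with m sampled from
{⌊γ⌋, ⌈γ⌉} (mean γ), so the constructed levels *are* the truncated Strahler
orders of the output and counts grow by γ per order in expectation. Child
radii follow r_c = r_p·m^(−a) exactly, which makes the junction scaling law
and Murray deviations exact ground truth by construction. Everything is
driven by one seeded generator; identical spec + seed gives bit-identical
output, and sub-µm radii raise an error.

Voxelization marks a voxel foreground iff its centre lies within the
locally interpolated radius of a subsegment, with spherical (capsule) joints
at interior polyline points — bridging the wedge voids where consecutive
chords bend — but flat faces at the two segment termini, so a straight tube
keeps its exact πr²L volume (within ~2% at 10 voxels per radius). A voxel
budget (default 512³) keeps phantoms desk-scale. Collapse injection scales
the graph radii of a seeded random segment fraction by a severity factor
while leaving the mask patent — exactly the artifact the correction stage
assumes — and returns the planted list for recovery scoring. Compartment
volumes are concentric ellipsoidal shells (hilum core, medulla shell crossed
by angular pillar wedges, cortex shell) with shell radii chosen analytically
so the volume fractions (cortex 63.7%, hilum 8.7%, pillars 4.1% by default)
hold exactly in the continuum limit; labels partition the organ ellipsoid
with no gaps.

What the phantoms do **not** emulate: real segmentation noise and contrast
artifacts, anatomically realistic space-filling (no constrained constructive
optimisation; generated branches may overlap in space), side-branching
(children are all one order below their parent, whereas real trees attach
low-order side twigs to high-order trunks), vessel taper within segments,
and actual skeletonization error. Passing the closed-loop tests therefore
establishes that the estimators are correct and well-calibrated under the
stated statistical structure — not that any given imaging pipeline meets
that structure. One visible finite-size effect: on the full nine-order
generator tree the SMA exponent lands near 0.57 for a generative a = 0.55,
because sibling-subtree size fluctuations add variance to log N_d that is
correlated with the radius cascade; at the five-order scale used for the
coverage experiment the 95% CI covers the generative value in ≥ 90% of
seeds.

## Numerical choices and degenerate inputs

- OLS fits use `numpy.polyfit`; percentiles use NumPy's linear-interpolation
  definition; distance transforms and interpolation come from
  `scipy.ndimage`; contours, labelling, Euler numbers and thinning from
  `scikit-image`.
- Midpoint-IVD ties break toward the smaller segment id (tolerance 1e-12);
  child lists are ordered by segment id, making every traversal
  deterministic.
- Graphs with cycles or multiple components refuse rooting with the
  offending cycles/component sizes in the message; duplicate parallel edges
  are reported as 2-cycles by the validator.
- Pipelines on degenerate networks (a single order, or no spread in tip
  counts) report `None` for the branching-ratio/scaling fits rather than
  failing; the report notes the missing panel.
- Problem sizes in the test suite and analysis scripts are chosen so the
  whole suite runs in well under a minute of compute on one CPU: oracle
  equivalence on 200 random trees of ≤ 64 segments, CI coverage over 100
  seeds of five-order trees, collapse recovery on a ~60-segment phantom at
  10 µm voxels, and 1000-replicate F-test calibration.

## Known limitations

- The AmiraMesh reader handles the ASCII `HxSpatialGraph` layout only (no
  binary AmiraMesh), by design.
- Cross-section extraction assumes the binary volume fully covers the
  flagged segments; sections clipped by the volume boundary are treated as
  window-clipped and retried at larger half-width, then dropped.
- The bifurcation-DICE component depends on the capture radius when
  junctions are fat relative to voxels; per-component reporting is the
  intended audit path.
- The missing-order estimate extrapolates a constant γ below resolution and
  ignores non-terminal endpoints beyond what the endpoint count encodes.
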
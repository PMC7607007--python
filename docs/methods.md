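# Methods

## Data model and conventions

A neuron is a rooted tree of traced 3D sample points in micrometres, read
from standard 7-column SWC. The node with `parent_id = -1` is the root and
is taken to be the soma; if several nodes carry SWC structure code 1, the
`parent_id = -1` node still wins, because SWC dialects disagree on soma
encoding. Radii are read and written (1.0 when absent) but used by no
metric — all metrics are centerline-based. Validation rejects duplicate
ids, unresolvable parents, multiple roots, cycles, and non-finite
coordinates.

Surface membership — `axial` (body wall), `fin_medial`, `fin_lateral` — is
carried in a sidecar TSV (`node_id`, `label`) rather than in SWC structure
codes, keeping the SWC files standard-compliant. Unlisted nodes are
`unlabeled`. Per-neuron scalars travel in a CSV: soma area (μm², measured
at a single-micron optical slice) and the signed anteroposterior soma
position (μm relative to the myomere 3/4 boundary; negative = hindbrain,
positive = spinal cord, where the labeled cells are Rohon-Beard neurons).

## Re-segmentation and the 13 parameters

A *critical node* is the soma, a branch point (≥2 children), or a terminal.
An *interbranch segment* is the maximal path between consecutive critical
nodes; a multifurcation of arity *a* starts *a* daughter segments but
counts as one branch point, so for a single-stem tree
`#segments = #terminals + #branch points`.

Restrictions: fin metrics are computed on the subtree induced by the
fin-labeled nodes *plus the processes leading from the soma to the fin*
(ancestor closure), so a process that branches before the fin contributes
its branch points, and path distance is measured from the soma. The plain
edge-labeled total (`restricted_length`) counts only edges whose child
carries the label; it is additive over a label partition of the tree and is
the quantity conserved by the octant split. The two totals differ by the
unbranched stem, deliberately.

The eleven tree parameters:

- **branch points** — nodes with ≥2 children in the restricted subtree.
- **maximum branch order** — branch points on the deepest root-to-terminal
  path, plus one.
- **Strahler number** — terminals are 1; a parent is `m+1` when at least
  two daughters attain the maximum `m`, else `m`. (The classical rule; for
  bifurcations it reduces to "increment on ties".)
- **mean partition asymmetry** — at each branch point, for every unordered
  daughter pair with subtree tip counts `(l, r)`, `|l−r|/(l+r−2)` when
  `l+r > 2`; `(1,1)` pairs are undefined and excluded; unweighted mean.
- **maximum path distance** — largest summed inter-node step length from
  the soma to any terminal.
- **mean contraction** — per-segment chord/arc ratio, averaged; zero-length
  segments are excluded with a warning.
- **branch / local / remote angles** — at each branch point, for each
  daughter pair, the amplitude between vectors from the branch point to:
  the immediate daughter nodes (branch angle); the nodes `local_offset`
  trace nodes into each daughter, clamped to the segment end (local angle,
  offset 10 by default); the daughters' next critical nodes (remote angle).
  The 10-node offset counts raw trace nodes — traces are not resampled, so
  the local angle is resolution-dependent by design; the offset is a
  parameter.
- **mean fractal dimension** — per segment, the slope of
  `log(cumulative path length)` against `log(chord length)` along the
  segment (exactly 1 for a straight segment, >1 for meandering); segments
  with fewer than 5 nodes are excluded; unweighted mean.
- **total length** — summed arc length of the restricted segments,
  including the stem to the fin.

Soma area and anteroposterior position pass through unchanged as parameters
12 and 13. Quantities undefined on a given neuron (asymmetry/angles of an
unbranched afferent) are NaN sentinels; the clustering stage mean-imputes
them per column with a warning. Neurons with zero branch points in the fin
are flagged not clusterable and excluded from classification.

The angle-metric family deserves a note: the immediate/10-node/endpoint
triple is the standard local-vs-remote bifurcation-amplitude family; the
"branch angle" is taken at the immediate daughter nodes so the three
metrics are distinct and coincide exactly on straight daughters (the
property the tests pin down).

## Fin geometry

Eighteen landmarks describe the fin: nine on the fin-body (FB) outer edge
(marked by the blood vessel) and nine on the fin-membrane (FM) edge; per
ring, two base points, one apex, three flanks per side. By convention the
`*_1` side is dorsal. The **plane** is total-least-squares through the 14
non-base points (smallest principal component); base points project but do
not influence the fit. The in-plane frame is anchored to the landmarks —
first axis along the FB base (side 1 → 2), second chosen so the FM apex has
a positive coordinate, normal = axis1 × axis2 — which makes every derived
quantity equivariant under rigid motion of the raw coordinates and gives
the signed distance a fixed sign convention (positive = medial under the
generator's chirality).

The **footprint** is the projected FM ring closed along the base; the
projected FB ring is the base/membrane boundary; the **dorsoventral
boundary** is the line through the midpoint between (FB-base midpoint) and
(FB apex), extended through the FM apex and clipped to the footprint. The
"midpoint of the proximal and distal points of the fin body" is read as the
midpoint of those two distinguished FB points — the only two landmarks that
qualify. Four quadrants (DM, DB, VB, VM) result; crossed with the
medial/lateral surface tags they give eight octants.

**Assignment** is per trace edge: the projected edge is cut at every
intersection with the three boundary curves (footprint ring, FB ring,
dorsoventral line; vectorized segment–segment intersection), and each piece
is classified by its midpoint (even-odd point-in-ring plus the side of the
boundary). Pieces carry their share of the edge's *3D arc length*, so the
eight octants sum to the fin-restricted total exactly — the conservation
property that makes results auditable; projected-2D lengths would not
conserve. Pieces whose midpoints fall outside the footprint (digitisation
noise, the fin-entry edge crossing the base line) are attributed to the
nearest region and counted in a warning. Boundary ties resolve
deterministically to the dorsal and membrane sides. Terminal counts use the
terminal's projected point, same rules.

The **model fin** is the mean of the cohort's projected FM outlines in a
canonical base frame (base midpoint at the origin, base along +x) — the
study's stereotyped outline is not published, so the cohort mean is the
package's own default. It is registered to each fish by rotation +
translation only (base midpoint onto base midpoint, base angle onto base
angle; the base angle is measured against the first in-plane axis, i.e.
the body axis). Axial innervation projected inside the placed outline is
reported as μm and as a percentage of total axial innervation — the skin
assumed contacted during fin adduction. Terminal counting "under the fin"
uses the fish's own footprint, a separate quantity from the model-fin
overlap.

## Classification and statistics

Features are standardized column-wise to mean 0 / s.d. 1 (n−1 denominator);
constant columns are an error naming the column. Clustering is Ward's
linkage on Euclidean distances. Two variants are exposed: the proper Ward
criterion (`ward.D2`, the default, via scipy) and the `ward.D` form — the
Lance–Williams recurrence applied to unsquared dissimilarities — as an
in-package implementation. Running that same recurrence on squared
distances reproduces scipy's criterion (heights squared), which the tests
use as a dual-route check. The cluster count scans k = 2..min(8, n−1) by
mean silhouette width (singletons score 0; ties go to the smaller k). A
leave-one-feature-out stability report (selected k, agreement with the
all-feature labels) is informational output, not a pass/fail test.

Cohort statistics: Pearson correlation of medial-surface fin terminal
counts against axial-under-fin terminal counts (two-sided t transform,
n−2 df); a single-predictor regression of total fin afferent length on
anteroposterior soma position, reported as the regression ANOVA F and
two-sided p with the slope sign (run with and without the Rohon-Beard
population — the regression trend form is the default reading of the
"ANOVA", with the grouped-factor alternative out of scope); and the
axial-vs-fin total length comparison, implemented as printed in the
original analysis — a chi-square goodness-of-fit of the two summed lengths
against equal expectation — which is statistically unusual for continuous
totals, so a paired Wilcoxon signed-rank test is always reported alongside,
both clearly labeled. No multiple-testing correction is applied (none was
described).

## Synthetic data

The generator emulates the study design, not neurite biophysics: a
stochastic branching walk suffices to exercise measurement code. Scene
conventions: fin base along the anteroposterior (x) axis centred 50 μm
anterior of the myomere 3/4 boundary; the footprint is a half-annulus fan
(FB radius 100 μm, FM band 60 μm); medial/lateral fin surfaces sit at
z = ±4 μm (tags and geometry agree by construction, so both assignment
paths are testable); the axial wall is the surrounding strip
(y ∈ [−120, 40] μm), which overlaps the fin base so "under-fin" axial
innervation exists. Landmarks get 4 μm in-plane and 2 μm out-of-plane
noise by default; zero out-of-plane noise gives exactly coplanar landmarks.

Each neuron: soma at its anteroposterior position 140 μm below the base
line; an unbranched stem (labeled axial) to the fin base; then concurrent
tip growth — 3 μm steps, heading noise of s.d. 0.25 rad, per-step
bifurcation probability, per-step retraction probability 0.02, daughter
separation 60° ± 15°; tips reflect toward the region centroid at
boundaries; if an arbor retracts completely with budget left, a new branch
sprouts from a random existing node (branching regimes only). Step counts
are Poisson around the regime mean (370 total steps, 60% fin), with a mild
anteroposterior coupling (5%) so anterior somas grow somewhat longer fin
arbors, emulating the reported organization. Ground truth (per-octant
lengths at sub-step resolution, terminal counts, totals, fin branch points,
Strahler) is bookkept during growth with the generator's own
point-in-polygon and side tests, independent of the measurement modules.

The default cohort mirrors the study's bookkeeping: 21 neurons — 14
"moderate", 5 "dense" (2.4× steps, 2.2× branching, larger fin share), 1
"sparse" (0.33× steps, 0.28× branching, straighter and narrower angles) —
plus one cell that never branches in the fin and is therefore excluded from
classification (20 clusterable rows). Soma areas are uniform in the
observed 48.9–178.6 μm² range; ~4 of 21 cells are spinal (Rohon-Beard,
positive soma position), the rest hindbrain. Soma area and position are
deliberately independent of morphology regime, as observed in the real
system.

**Cluster-recovery cohorts.** Recovery validation presupposes classes
separated by ≥4× the within-class spread in standardized feature space.
The default cohort cannot meet that premise — its two soma scalars carry no
class signal, and a tiny-arbor class has intrinsically noisy per-neuron
estimates of asymmetry/angles/fractal dimension — so `recovery_config`
builds a premise-satisfying cohort: three classes of sizes 9/7/4 (n = 20,
no singleton), larger arbors (740 steps, 8% branching, 8° angle jitter) so
per-neuron feature estimates are stable, contrasts spread over different
feature axes (branching density and length for one class; straightness and
narrow angles for another), and staggered soma-area/position subranges so
all 13 features carry signal. The `separation` knob interpolates all
contrasts from zero (identical classes) to the reference level; at zero the
mean silhouette stays below 0.3. What passing recovery shows is that the
clustering machinery recovers structure when the premise holds — not that
arbitrary real cohorts cluster cleanly.

## Numerical choices and limitations

- Merge heights, silhouette values and region polygons are deterministic;
  the whole pipeline is byte-reproducible under a fixed seed and config
  (manifests record config snapshots and input hashes; no timestamps).
- Edge splitting collects exact intersection parameters; interval sums
  equal the edge length by construction, so conservation holds to floating
  point rather than to a sampling tolerance. Collinear overlaps with a
  boundary contribute their endpoints as cut points; the midpoint rule then
  decides deterministically.
- Zero-arc segments are excluded from ratio averages with a warning;
  degenerate projections (edge perpendicular to the plane) fall back to
  point classification.
- The fin is modeled as a plane; strongly curved fins would need a curved
  parameterization (out of scope). Region quadrant/octant quantification
  assumes the landmark rings project to simple polygons and errors
  otherwise.
- The generator's ground-truth octant lengths agree with the measured
  assignment to 0.5% of fin length (boundary-granularity band) at zero
  landmark noise; with default noise the fitted plane differs slightly from
  the generator frame and agreement is correspondingly looser.
- Problem sizes in the shipped tests — cohorts of ~20 neurons of a few
  hundred nodes, 200 recovery replicates, 10⁴ null simulations — were
  chosen to pin each property down tightly while keeping the whole suite
  comfortably interactive.
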
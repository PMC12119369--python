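# Methods

This note documents the models and procedures colonnade implements, the
parameters that matter, what the synthetic-volume generator does and does
not emulate, and the numerical choices made where the underlying procedure
left the design open.

## Column coordinates

Columnar neurons of the optic lobe repeat once per ommatidium, so a hex
lattice of axial (p, q) addresses indexes retinotopic space across
neuropils.  Assignment is synapse-driven: every synapse is assigned the
column axis (straight proto-axis, or finished pin) minimizing the
point-to-polyline Euclidean distance — for a pin this is the minimum
distance to any of its pin points — and a neuron takes the mode of its
synapses' votes.  The historical workflow resolved modal ties and
disagreements between paired-connection votes by manual inspection; we
replace that with a deterministic rule (lowest (p, q) lexicographically)
plus an `ambiguous` flag, so downstream results are reproducible and the
cases a curator would review remain identifiable.  The staged bootstrap
(seed columns → straight proto-axes → prototype pins) is implemented as
one loop — assign, re-estimate axes per column by PCA, reassign — with a
configurable iteration count (default 3, matching the quick convergence we
observe on synthetic volumes).  The orientation of the (p, q) axes
relative to the eye's anatomical axes is a configuration convention (the
equator flag defaults to the q = 0 row); nothing downstream depends on it.

Proto-axes use the first principal component of a column's synapse cloud,
sign-fixed to point from the neuropil top to the bottom, with the centroid
as origin.  Fewer than three distinct points is an error: a line fit to a
degenerate cloud would be noise.

## Pins

A pin is an ordered list of `n_samp` 3D points modeling a column's curved
centre line.  Construction per column:

1. collect the synapse positions assigned to the column;
2. PCA; orient PC1 top→bottom;
3. drop lateral outliers with l_i > f_lat·σ_lat, where l_i is the distance
   from the centroid in the PC2–PC3 plane and σ_lat = sqrt(mean l_i²);
4. normalize the PC1 projection to t ∈ [−1, 1] using the axis'
   intersections with the bounding surfaces (−1 = top);
5. estimate r_top from a PCA of the top fraction (t < 0.1, else the N_PC
   smallest t) intersected with the top surface; r_bottom analogously
   (t > 0.2 / N_PC largest);
6. rank points by t, smooth each element with its N_avg neighbours
   (centred window, truncated at the ends), keep the endpoints exact;
7. take the shortest order-preserving sublist from r_top to r_bottom with
   consecutive gaps ≤ d_max = ‖r_top − r_bottom‖/N_tang, solved exactly by
   an O(n²) dynamic program (ties to the earliest indices);
8. resample to n_samp points uniformly in cumulative arc length with
   shape-preserving piecewise-cubic (PCHIP) interpolation per coordinate.

Presets (configuration data, used verbatim):

| neuropil     | f_lat | N_PC | N_avg | N_tang | N_samp | endpoint PCA | PCA points |
|--------------|-------|------|-------|--------|--------|--------------|------------|
| medulla      | 2.0   | 800  | 260   | 7      | 121    | top/bottom subsets | synapses |
| lobula       | 1.5   | 800  | 37    | 2      | 76     | single, r_top extrapolated to the median of the N_avg shallowest points | synapses |
| lobula plate | 1.0   | 800  | 56    | 2      | 51     | single | per-neuron means |

Thin neuropils admit a pin only when (i) at least N_avg points survive the
outlier trim, and (ii)/(iii) the centroids of the 5% shallowest/deepest
points lie within d_max of r_top/r_bottom; rejections carry their reason.
In the lobula plate the PCAs run on per-neuron mean positions because the
slab is thin enough that raw synapse spread along the column is comparable
to the lateral spread and would tilt PC1; the remaining steps still use
the full cloud.

Design choices worth stating explicitly:

- The outlier rule is drop-if-greater: points far from the axis belong to
  neighbouring columns.  σ_lat is the root-mean-square lateral distance.
- "Shortest sublist" is an order-preserving subsequence and is solved
  exactly, not greedily; a greedy scan can return longer chains.
- "Uniformly sample" is read as uniform in arc length, which is well
  defined on the unevenly spaced sublist; index-uniform sampling would
  compress geometry wherever the sublist is dense.
- The smoothing window is centred with half-width N_avg/2 and truncates at
  the list ends; the endpoints are never averaged.
- Bounding surfaces are analytic planes here (the synthetic slab);
  triangulated ROI surfaces would slot into the same intersection
  interface but are not implemented.

After construction, pins are regularized and missing columns filled in, an
iterative pass designed for the sparser thin-neuropil pin sets: each pin
is replaced by the per-station median of the offset-from-first-point
polylines of all pins within Chebyshev distance ≤ 2 in (p, q) (the
neighbourhood metric is our reading of "differs by at most 2"; the axial
Chebyshev ball is the simplest symmetric choice), re-anchored at its own
first point; a missing column is created from the per-station median of
its four axial ±1 neighbours, or of an opposite pair along one axis.  The
loop stops when an iteration fills nothing (2–3 iterations on our
lattices).  Columns with no qualifying neighbours stay missing and are
reported.

Depth of an arbitrary point is index/(N_samp − 1) of the globally nearest
pin point, giving every point exactly one (column, depth); ties go to the
lexicographically lowest column, then the shallower station.

## Layers

Marker-type depth distributions (counts over the N_samp stations,
optionally subsampled ×2 by merging adjacent station pairs) define layer
boundaries.  The threshold syn_thre is implicit: the largest level such
that the fraction of distribution mass in bins strictly above it is at
least frac_peaks (0.85 medulla, 0.80 lobula, 0.75 lobula plate).  Scanning
depths in ascending order, up-crossings are lower cut-offs and subsequent
down-crossings upper cut-offs; cut-offs closer than 3 depth points merge.
The separation is measured in the stations of the distribution as given
(subsampled stations when the distribution was subsampled).  Which cell
type, polarity, peak, and side defines each boundary is configuration —
those are biological choices that cannot be derived — and in
lobula-plate mode each boundary is the mean of two marker thresholds.
Boundary intervals are half-open, deeper-layer inclusive ([b_k, b_{k+1});
depth 1.0 falls to the last layer); the convention is ours, stated because
synapses do land exactly on station boundaries.  A perfectly uniform
distribution yields one peak spanning the whole depth range under the
implicit-threshold rule (the threshold falls below the distribution); only
an empty distribution yields no peaks.

## Cell typing

Connectivity features: per neuron, summed connection weights to every
named partner type, inputs and outputs separate, restricted to the
configured regions.  Partners typed `*_unclear` are excluded, `*_fragment`
bodies count under their parent type, and bilateral types are split by
side instance.  Clustering is Ward linkage on cosine distances
(scipy.cluster.hierarchy), cut with the maxclust criterion; zero rows are
excluded (cosine undefined) with a warning.  An L2-normalize + Euclidean
route is provided and co-clusters with cosine on separable data.

Morphology features: 244 = 4 × 61 values per neuron, medulla only, from
synapses with confidence ≥ 0.9 — presynapse counts per subsampled depth
station scaled by N_pre,size/N_pre,syn so the block sums to the
presynaptic innervated-column count, the same for postsynapses, then the
raw per-depth innervated-column counts for both polarities.  Clustered
with Euclidean Ward.

Confusion matrices order rows lexicographically and columns by a greedy
pass (per type, clusters by descending count until the remainder holds
≤ 5% of the type); each nonzero cell is exactly one of red (≥80% of the
type in the cluster and ≥80% of the cluster from the type), blue (≥80% /
<80%), green (10–80% / ≥80%), yellow (10–80% / 10–80%) or grey, plus
completeness and homogeneity (sklearn).

Top-n connection fingerprints are rank-ordered tuples of (partner,
direction), ties broken by partner name; ordered fingerprints have the
prefix property, which makes the uniqueness proportion non-decreasing in
n (set-valued fingerprints do not guarantee this).

Mosaic views project per-cell synapse centres of mass onto the first two
principal axes of a fixed reference synapse set per neuropil; we default
to the synapses of the columnar types, which standardizes the view across
candidate types.  The projection presumes the retinotopic extent dominates
depth, as in a real neuropil shell; on a volume as deep as it is wide the
leading component picks the depth axis instead.

## Anchor matching

Candidate neurons inherit coordinates from anchors by maximum-weight
bipartite matching on the row-normalized connection matrix
C̃_ij = C_ij/Σ_k C_ik (removing regional synapse-density bias), solved
with the Hungarian algorithm after a lexicographic pre-sort for
deterministic ties.  Matches are vetoed when the anchor's mean presynapse
position (toward the candidate class) and the candidate's mean postsynapse
position are farther apart than a threshold, configured in µm (default 8,
about one column spacing); the threshold is configuration, not
re-estimated per dataset.  An anchor group is valid when every candidate
class is matched and at least three matches survive the veto — our
disambiguation of a grammatically ambiguous rule, consistent with groups
of three or four classes both being usable — and the surviving candidates'
positions seed downstream pin construction.

## Coverage and trimming

Per neuron, columns are ranked by synapse count; the cumulative fraction
curve (padded with 1.0 past its last rank; padding handles unequal
lengths) is medianed across the cells of a type.  rank* is the knee of the
median curve (point (0, 0) prepended) under the kneedle algorithm for
concave increasing curves with sensitivity S = 1; kneed is not available
in this environment, so the algorithm is implemented here following its
published description, without pre-smoothing — the curves are coarse rank
series and already monotone.  If the median cumulative fraction at rank*
is below 0.775 the knee is deemed unreliable and rank* becomes the first
rank reaching 0.995, else the last rank attaining the curve maximum
(flagged).  Each neuron then keeps the columns whose count is at least the
count of its own rank-rank* column, so ties are retained together.

Cell size is the median trimmed column count; coverage factor the mean
number of cells contributing to an occupied column after trimming (these
two satisfy the exact identity coverage_factor × occupied = Σ trimmed
sizes); columnar completeness is untrimmed occupied columns over total
columns.  Column area is the convex hull of the occupied columns'
hexagonal footprints (centre + 6 corners at circumradius 1/√3 in
unit-spacing embedding), in units of one column's area √3/2 — hulling
footprints rather than bare centres keeps a dense convex patch from
under-counting its own columns.  Types whose hull badly misrepresents
their coverage can substitute the occupied-column count.

## Neurotransmitters

Calls aggregate per-synapse probability vectors over ACh, Glu, GABA, His,
Dop, OA, 5HT.  Confidence is the modal fraction of the per-synapse argmax
classes (the default; a synapse-probability-averaging variant is available
behind `method="mean_prob"` since the aggregation formula in the upstream
classifier is not restated anywhere we can implement from).  A cell is
called with its most frequent presynaptic transmitter at ≥ 50 presynapses
and confidence ≥ 0.5; a type at ≥ 100 pooled presynapses and ≥ 0.5.  A
modal tie cannot name a unique most-frequent class and yields unclear.
Consensus passes the type call through except that aminergic calls (Dop,
OA, 5HT) require experimental support — these classes are
under-represented in classifier training — and the support table may carry
several transmitters for co-transmitting types.  Raising either threshold
can only move calls toward unclear.  Fan-out is the per-cell ratio of
output connections to presynapses averaged over a type's cells; cells with
zero presynapses are excluded with a warning.

## Inter-region connectivity

contribution(A→C) = outputs[C] × inputs[A]/Σ inputs per neuron; group
matrices are element-wise sums.  Column sums therefore equal the group's
output totals per target region exactly, and aggregation is additive over
disjoint neuron subsets.  A connection's region is its postsynaptic site's
region on both sides of the scheme; connections in regions missing from
the region map accumulate under `unmapped` with a warning.  For display,
entries are ranked descending and kept up to a cumulative-share cut
(default 0.9375) with halving bands (50/75/87.5/93.75%) as bin labels.

## The synthetic generator

The generator emulates: a hex lattice with straight or circular-arc
planted axes spanning a slab (spacing 5 µm, depth 40 µm by default, the
scale of a medulla); per-type synapse clouds with piecewise-linear planted
depth profiles and isotropic Gaussian lateral jitter (σ = spacing/6, small
enough that nearest-axis assignment is almost always right — the premise
of column assignment); mosaics (one cell per column) and multicolumnar
territories (home plus nearest columns); Poisson partner-rule connection
counts preferring spatially nearby partners; synapse confidences with a
small low-confidence tail; and per-presynapse transmitter probability
vectors with a 10% argmax error rate.  The default study scenario plants
five types — four columnar mosaics with single-band depth profiles
spanning the full slab depth between them, and one five-column amacrine-
like type with a broad profile — with disjoint partner rules and five
different transmitters.  Depth coverage spanning the whole slab matters:
the pin algorithm presumes columns whose synapses reach both surfaces, and
the default per-cell synapse counts (120 pre / 180 post; 200/200 for the
multicolumnar type, roughly 1,600 synapses per column) keep the preset
smoothing window a small fraction of a column's points, as it is at real
column densities.

It does not emulate: neuron skeletons or arbor shapes, curved neuropil
shells (the slab is flat), reconstruction errors, fragments or unclear
annotations, synapse polyadicity (fan-out is exercised on constructed
counts instead), lamina/accessory-medulla compartments, or realistic
region maps for a central brain.  Tests passing on these volumes show the
procedures recover planted structure under the stated noise; they do not
show robustness to reconstruction artefacts or anatomical curvature.

## Problem sizes and determinism

The test suite and the acceptance script run on 7–37-column volumes
(~10,000–60,000 synapses), sizes chosen so the full preset parameters
operate in their intended regime while a complete run stays in the tens of
seconds.  All randomness flows from explicit integer seeds through
numpy Generators; no global random state is used, and a rerun with the
same seed is byte-identical, which the suite asserts.  The two
combinatorial solvers (shortest bounded sublist, maximum-weight
assignment) are verified against exhaustive enumeration on small random
instances.

## Known limitations

- Bounding surfaces are planes; real ROI meshes (and the ridged lobula
  top) are only approximated by the lobula's median-extrapolation rule.
- Voxelized column/layer ROIs and alpha-shape layer meshes are out of
  scope; assignment is direct nearest-pin.
- The equator flag is a convention passthrough, not derived from
  photoreceptor counts.
- Automatic distance-gap estimation for the matching veto is not
  implemented; the threshold is configuration.
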
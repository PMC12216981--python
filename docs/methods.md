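# Methods

This note documents the models, parameters and design choices behind
`topotrace`, and what the synthetic test suite does and does not show
about real AFM data.

## Image model and flattening

Inputs are calibrated 2D height grids in nm with an isotropic pixel size
(0.5–1 nm/pixel is the regime the tracer is designed for). Flattening
removes, in order: a best-fit plane, a quadratic bow, per-scanline median
offsets, single-row scar streaks (runs of ≥3 pixels deviating >1 nm from
both vertical neighbours, replaced by the neighbour mean), and finally
re-levels the background to mean 0 and applies a 1.1 px Gaussian filter
against high-gain noise. All fits are computed over a background mask
(pixels below one sigma of the height distribution); sigma is estimated
robustly as 1.4826 × MAD so bright molecules do not bias the background.
The fit/align cycle runs twice (crude mask, then refined), which makes
the levelling idempotent to well under 0.01 nm. A molecule that fills
entire scanlines is indistinguishable from a line offset by any per-row
statistic; the row alignment therefore assumes molecules never span a
full row, which holds for isolated molecules at typical coverages.

Grain masking thresholds the flattened image (default 0.75 nm absolute,
or k·sigma above background), labels 8-connected components, and drops
undersized (<60 px) and border-touching grains.

## Height-biased skeletonisation

Classical Zhang–Suen thinning deletes all simultaneously deletable
boundary pixels of a sub-iteration at once, so both flanks erode
symmetrically and the skeleton lands on the geometric centre. Here the
same deletability conditions feed a global priority queue ordered by
(height, exposure generation, raster position): the lowest currently
deletable boundary pixel is always removed first, and each deletion
re-exposes its neighbours. Low flanks therefore erode before the ridge,
and the surviving one-pixel trace follows the height maximum — at DNA
crossings this keeps the trace on the over-passing duplex. At constant
height the generation key restores the symmetric layer-by-layer peel, so
a flat bar still thins to its centreline. A post-pass removes redundant
staircase pixels (pixels whose neighbours remain mutually 8-connected
without them), which converts L-steps into diagonal steps.

Branch pruning repeats two rules to a fixpoint: terminating branches
shorter than 15% of the skeleton pixel count, and branches whose centre
pixel lies more than 0.85 nm (the depth of the DNA major groove) below
the mean skeleton height, are removed. The "centre height" is the height
of the branch's midpoint pixel (a literal reading; the mean over the
branch was the alternative). Both constants are configuration defaults.
In replication-intermediate mode the pipeline relaxes the relative-length
rule to 2% so genuine short fork arms (reversed forks) survive.

## Crossings and the FWHM order call

Skeleton pixels with three or more graph neighbours are junction
candidates; connected candidates form nodes. Nodes within 7 nm (about
twice the tip-convolved DNA width) are merged together with the
connecting path, and remaining odd-branch nodes are joined pairwise along
the shortest skeleton path — these are the two T-shaped halves of a
crossing that thinning pulled apart, common at shallow crossing angles.
The connection is limited to 40 nm and refused when the joining path runs
through a third node, so genuine replication forks (3-way junctions
separated by whole segments) are never welded into fake crossings.

Within a 20 nm crossing region (below the ~45 nm persistence length, so
duplexes are straight) each emanating branch gets a least-squares
propagation vector oriented away from the node; branches are paired by
exhaustive maximum-weight perfect matching with weight −cos(angle), i.e.
the most anti-parallel branches continue through each other.

For each pair, heights are sampled along the through-path (routed via the
node's summit pixel) and the full width at half maximum of the profile is
measured with the *profile minimum* as baseline and linear interpolation
at the half-maximum crossings. The flattened-image zero level cannot
serve as the baseline here: the through-trace never leaves the molecule,
so its minimum is the single-duplex height, not the substrate. The pair
with maximal FWHM is called over-passing and pseudo-heights are assigned
as ascending integer ranks (deepest under = 1). The average crossing
order reliability is the mean of 1 − min/max over all C(k,2) FWHM
pairings of the k duplexes in the node; for two duplexes with widths 0.2
and 0.5 this gives 0.6, and for {0.2, 0.5, 0.7} the three pairings give
(0.60, 0.71, 0.29), mean 0.53. The default threshold for a reliable call
is 0.263. Equal widths (e.g. crossings compressed to single-duplex
height by the tip) give reliability 0 and flag the node degenerate.

## Tracing and topology

The skeleton is partitioned into crossing regions and connecting
segments; traces start from an endpoint (linear molecules) or the
lexicographically first segment (closed), and follow the branch pairing
through every node until they close. Leftover segments seed further
molecules — this is what separates the circles of a catenane. The NXYZ
table (index, x, y, pseudo-height) is the interchange format; only the
relative pseudo-height order within a node matters.

The XY projection of a trace is a crossing diagram: per component, the
cyclic over/under sequence plus a sign per crossing from the 2D tangents
of over and under strands (right-handed = +1). Reidemeister I and II
reductions run to a fixpoint; the Kauffman bracket is then evaluated by
the exhaustive sum over all 2^n smoothings (refused above 14 crossings
rather than approximated) and writhe-normalised to the Jones polynomial.

Classification is lookup of the polynomial — over all relative component
orientations, since molecule orientation is arbitrary — against a table
generated at first use from rational (2-bridge) tangle closures: all
positive continued fractions with crossing sum ≤7 are enumerated, every
closure's Jones polynomial computed, and labels assigned through the
invariant triple (component count, Jones span, determinant), which is
collision-free in this range because the span of a reduced alternating
diagram equals the crossing number and determinants are distinct within
each crossing number. This covers every prime knot to 7 crossings and
the 2-component rational catenanes to 6 crossings; 7-crossing
2-component links are not tabulated and classify as "unclassified".

Chirality convention: the plain label denotes the right-handed
(positive-crossing) form — the convention in which the Xer product is the
right-handed 4-node catenane `4^2_1` and the positive-sign 5-crossing
torus knot is `5_1` — with `*` for the mirror; this is the mirror of the
sign convention some printed tables use. For links whose orientation-set
of Jones polynomials is mirror-symmetric (the Hopf link `2^2_1`, and the
det-10 6-crossing catenane), the polynomial cannot decide chirality and
the result is flagged ambiguous. `4_1` and `6_3` are amphichiral. The
two non-torus 6-crossing catenane labels follow determinant order, since
the printed table indexing for them is not nailed down by the invariants.

When crossing reliabilities are attached, the classification after
flipping the single least-reliable crossing is reported as
`alternate_rolfsen` — for a 4-node catenane this is the 2-node catenane,
the characteristic single-crossing failure mode.

The misclassification model flips every subset of crossings of a
diagram, classifies each result, and weights by p^(n−k)(1−p)^k with
per-crossing accuracy p (default 0.82, the hand-label benchmark value).
For the minimal trefoil diagram 6 of 8 assignments are unknots and 2 are
trefoils, so P(correct | 3-node) = 0.82³ + 0.18³ ≈ 56%; for 5-crossing
torus knots P = 0.82⁵ + 0.18⁵ ≈ 37% (counting the all-flipped mirror as
correct; without it the figure is 0.3707, which rounds identically).

Writhe and linking numbers of 3D curves use the exact per-segment-pair
solid-angle form of the discrete Gauss integral, so Lk quantises to
integers (within 0.05) even at coarse discretisation; twist
parallel-transports the ribbon vector along the axis, and Lk = Tw + Wr
holds to 1e-3 on parametric ribbons (White's theorem, used as the test
oracle).

## Morphometrics

Contour length sums Euclidean steps along the traced backbone after a
5-pixel circular moving-average smoothing of the pixel path. Raw
(1, √2) chain stepping systematically overestimates smooth curve length
by ~5–8% depending on orientation (a known property of digital chains);
the smoothing removes this, bringing rendered circles to within ~1% of
2πr. The raw digital rule remains available (`smooth_px=0`) and is what
the trace-length invariant is stated in. Expected lengths use 0.34 nm
per base pair (2260 bp → 768 nm); percentage error is
|predicted − true|/true × 100.

Replication intermediates are analysed by breaking the skeleton at
junction nodes: exactly three segments bounded by two 3-way forks
qualify as a theta structure, whose unreplicated arm is the segment most
dissimilar in length from the other two (the two replicated arms are
copies and should match; the shortest segment is reported as well since
both conventions coincide for most geometries, and the call is flagged
low-confidence when the dissimilarity falls below a 15% relative
margin). Reversed forks are 4-way junctions with exactly one short
(<50 nm) terminating arm; ordinary crossings have no terminating arms
and never trigger the rule.

Conformation classes for catenanes are a user-editable rule table on
(node count, branches per node): open = 4 well-separated 4-branch nodes;
clustered = any node with ≥6 branches (three or more duplexes in one
region); bow-tie = a single ≥8-branch node bridging exactly 2 lobes;
taut = 2–3 collinear nodes. These thresholds are heuristics chosen here
(the published rule table is supplementary material not reproduced), so
results depending on them are labelled accordingly. Data cleanup applies
the documented steps per analysis mode — (1) empty contour length,
(2) linear fragments, (3) clustered crossings, (4) unexpected molecule
count — with removal counts logged per step.

## Pseudo-AFM generation

The generator renders exact closed curves whose z coordinate only
encodes crossing order; contour lengths are in-plane lengths, since a
deposited molecule is flat. Tubes have a Gaussian cross-section with
FWHM = 2·(tip radius) + duplex width (defaults 5 nm and 2 nm → ~12 nm
apparent width, emulating tip dilation), ridge height 2 nm (DNA on mica),
a final 1 px Gaussian filter and i.i.d. Gaussian noise (default 0.1 nm;
the clean suite uses 0). At every projected crossing the over strand is
lifted by a smooth cos² bump of 15 nm half-length whose apex
interpolates from twice duplex height (compression 0) down to
single-duplex height (compression 1, the tip-compressed regime in which
crossing calls become unreliable). Each seed applies a random in-plane
rotation and sub-pixel offset, so every render digitises differently.

Topologies: circles; (2,q) torus knots; twist knots built geometrically
as a twisted band closed through one vertical and one final horizontal
twist (determinant 2n+1: n=2 → 4_1, 3 → 5_2, 4 → 6_1); the 4-node
catenane as two orthogonal ellipses (open conformation, steep
well-separated crossings) or as a circle threaded by a strongly squashed
ellipse (the taut conformation, whose near-tangential crossing pairs the
tracer must merge); theta structures as a circle plus bowed chord, with
an optional <50 nm radial stub for reversed forks; and figure-of-8
dimers as two circles sharing a junction. Every knot/catenane curve is
classified on its exact projection at generation time, so stored labels
are guaranteed consistent. Default contour lengths (768–1200 nm,
catenane circles ~500 nm) put crossings ≥25 nm apart at 1 nm/pixel —
the well-resolved regime the suite is meant to emulate.

What the suite does not emulate: surface-induced conformational
variability, molecule-molecule contacts, piezo drift and scar artefacts
(available but off by default), tip asymmetry, and helical substructure.
Passing the clean-suite recovery test therefore demonstrates the
correctness of the algorithmic chain under ideal deposition, not
instrument-grade robustness; the noisy and compressed variants probe the
degradation direction but not its real-data magnitude. A genuinely
bow-tie-folded catenane (all four crossings in one blob) renders as a
single 4-branch node at this tube width, so the bow-tie rule is
exercised on constructed node statistics rather than on renders.

## Problem sizes and numerics

The clean recovery suite runs 6 topologies × 10 distinct seeds; the
invariant engine is cross-checked against an independent recursive-skein
oracle on every rational closure with ≤6 crossings, and against frozen
literature polynomials for the common types. Bracket evaluation is exact
integer Laurent arithmetic throughout — there is no floating-point
tolerance anywhere in the topology chain. Geometric tolerances:
projected crossings need strand heights differing by >1e-12 nm
(guaranteed by construction in the generator); Gauss-integral
quantisation is asserted at 0.05 and White's theorem at 1e-3 for
500-vertex ribbons. Ties in thinning deletability are broken by raster
order; ties in branch matching by lexicographic branch index; FWHM ties
flag the node degenerate rather than guessing.
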
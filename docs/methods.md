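# Methods

This note records the modelling choices behind `wormtrack`: what each
stage assumes, the parameters that matter, what the synthetic fixtures
do and do not emulate, and the numerical conventions that make results
reproducible bit for bit.

## Imaging assumptions

The tracker is built for a controlled-backlight rig that keeps the dish
background above gray level 48 and worm bodies below 35 in every frame.
All segmentation is therefore fixed-threshold; there is deliberately no
adaptive (Otsu-style) thresholding, because the premise of the pipeline
is that the illumination makes intensities stationary.  Sequences are
short (nominally 30 frames at 1 Hz) and worms are small (tens of pixels
long, 3–5 px wide), which motivates the 3× upscaling during tracking:
at the native scale a worm's width quantizes to 1–2 px and widths,
colors and skeleton topology become unstable.

## Segmentation

* **ROI.** Per-frame masks above the background threshold are ANDed
  across the sequence, hole-filled, and the largest connected component
  is kept.  A pixel ever covered by a worm fails the AND, so moving
  worms only punch interior holes, which the fill removes — the ROI is
  invariant to worm motion (asserted by test).
* **Worm tracks.** Components below `levels[0]` (= 35) inside the ROI
  are kept as worm tracks if they pass three filters: area ≥ `min_area`
  (default 40 px²), a dark core below `levels[-1]` (= 20; this is how
  the multi-level threshold sweep is realized — a stable worm is dark at
  its core, faint debris is not), and thinning-skeleton length ≥
  `min_skeleton_length` (default 20 px).  Components that pass the area
  filter but fail the others are returned as *plate noise* and feed the
  noise criterion.
* **Track matrix.** Components are linked frame-to-frame by any-pixel
  overlap (the weakest sufficient rule at 1 Hz); the matrix stores the
  per-frame component count of each linked track.  The start frame *k*
  maximizes the minimum pairwise boundary distance among frames where
  every track is at its maximal count and every component's skeleton has
  exactly two endpoints and no branch points.  Eligibility is judged at
  the native scale; if the 3× skeleton of a chosen frame turns out
  branched (rare), the next-ranked frame is used.

## Skeletons

Classical skeletons come from topology-preserving thinning, condensed
into a graph of endpoints, branch clusters, and pixel chains.  Two
cleanups deal with thinning artifacts at 3–5 px widths: terminal spurs
up to 3 px (scaled with resolution) are pruned, and tiny interior loops
plus two-edge branch clumps are collapsed back into plain chains.

The width-constrained variant targets aggregations.  Overlap zones are
the regions where the Euclidean distance transform exceeds `width_max`,
the largest half-width of any active worm model: deeper than that, two
bodies must be stacked.  The mask outside the zones is thinned normally;
around each zone, the endpoint stubs within reach are reconnected
pairwise by Dijkstra paths through the zone, with a small penalty for
pixels shallower than `width_min` so routes prefer the ridge.  For a
mask whose distance transform never exceeds `width_max` the classical
skeleton is returned unchanged, which pins the two methods together on
isolated worms.  An earlier draft marked zones at `width_max / 1.5`;
that floods the normal body interior (a worm's own ridge depth is about
one half-width) and destroyed the stub geometry exactly in aggregation
frames, so the threshold is `width_max` itself.  The tracker adds a
1.2× margin (`overlap_width_factor`) on top of the measured model
widths so that ordinary frame-to-frame width fluctuation of an isolated
worm does not trigger zone carving.

## Worm models and reconstructions

A model is sampled once per worm at frame *k*: half-widths from the
distance transform and gray levels from the raw frame, both along the
skeleton, ordered head first (the head is the darker end, judged by the
mean gray of the outer five skeleton pixels; the tail of *C. elegans*
carries more light pixels).  The color model is frozen afterwards; only
the length model is a running mean, and it advances only while the worm
is separate, because lengths measured inside an aggregation are
unreliable.

Bodies are rebuilt from any candidate path by stamping disks of the
model half-widths (linearly resampled over normalized arclength) along
the path.  Disk membership is strict (`distance < r`): the radius is a
distance-to-background value, so a `≤` disk would overshoot the body by
one pixel all around — this convention is what makes model → body →
model a fixed point within ±0.5 px.  Body colors are carried by nearest
path pixel, with ties resolved by the distance transform's
deterministic feature selection.

## Candidates and optimization

Candidates grow by depth-first traversal of the skeleton graph from
every node inside the worm's previous body dilated by 3 px (scaled with
resolution), without repeating nodes or edges.  A branch is cut and
kept when it reaches the model length; a branch ending at a graph
endpoint is kept if it reaches at least half the model length (the
window is [0.5, 1.5]·L&#x2097; — aggregations genuinely stretch and
shrink apparent lengths).  Duplicate pixel sets are removed and the
list is capped at 12 candidates per worm, keeping those overlapping the
previous body the most, which bounds the optimizer's product.
Candidates are oriented head-first by proximity to the previous head
before costs are evaluated.

Five criteria are additive over worms and are precomputed per
candidate: length (scaled by the model's mean squared width so a pixel
of length error weighs like a pixel of area error), previous-body
overlap (symmetric difference), smoothness (windowed mean turning
angle, degrees, window ±3 — unstated in the source method; 3 smooths
8-connectivity quantization at these widths), noise intersection, and
color mismatch above U = 1 gray level.  Completeness is deliberately
*not* per-worm: it is the symmetric difference between the component's
segmentation and the **union** of all reconstructions in the
combination.  The per-worm alternative is nearly constant across
candidates (every full-length in-mask body differs from AS by about the
same amount) and permits the degenerate optimum where all worms pile
onto one body; the union form is the reading under which the criterion
actually "prevents the segmentation from being incomplete", matches the
criterion's documented behavior (identity swaps tie; uncovered
extremities score high), and in our crossing experiments raised identity
preservation from 7/10 to 10/10 seeds.  Because of this coupling the
optimizer scans the full Cartesian product (separable parts cached,
union part evaluated per combination on the component's bounding box);
ties break to the lexicographically smallest index tuple, which makes
the argmin deterministic.

## Tracking

Models are built at frame *k*; the forward pass covers *k*+1 … end and
the backward pass *k*−1 … start.  Both start from an identical snapshot
of the frame-*k* state (models are deep-copied per pass), which is what
makes the backward pass equal the forward pass over the reversed
sequence — a property asserted by test.  After each frame the winning
reconstructions become the previous bodies for the next frame.  Worms
are grouped into segmentation components by maximal previous-body
overlap; a worm whose body overlaps no component is marked `lost` for
the frame and keeps its last state, so it can re-acquire later.  Gray
frames are upscaled bilinearly (preserving the intensity ramps the
color criterion needs) and masks nearest-neighbor; output paths are
divided by 3 and rounded, with rounding-induced duplicate pixels and
loops collapsed.

## Synthetic fixtures

The generator renders what the imaging assumptions promise: a bright
dish interior (gray 120) in a dark surround, worms as smooth undulating
tubes 38–50 px long and 3.2–4.6 px wide with a linear head→tail gray
ramp (head 12–18, tail 9–13 levels lighter, all below 35), optional
static dark blobs as plate noise, and 1 Hz motion of about 2.2 px per
frame with smooth heading and phase perturbation.  Contact events (end
contact, partial overlap, parallel bodies, crossing) are scripted into
the middle of the sequence so the first and last frames always show
every worm separated.  The crossing uses seeded perpendicular and
timing offsets: a perfectly concentric, simultaneous crossing is a
measure-zero configuration whose identity assignment is genuinely
ambiguous.  Parallel bodies are pressed to 0.6× the sum of their
half-widths so that plain thinning cannot separate them — the situation
that event exists to pose.  Everything is a deterministic function of
the scenario seed.

What the fixtures do **not** emulate: self-coiling and omega turns,
condensation and vignetting, intensity flicker, worms near or on the
dish wall, more than two worms in simultaneous contact, and the
contact-induced slowdown of real worms.  A green fixture suite
therefore establishes the pipeline's mechanics (segmentation, skeleton
separation, cost discrimination, determinism), not field performance on
laboratory plates.

## Numerical conventions

Coordinates are 0-based (row, col); masks are boolean; paths are
8-connected and free of repeated pixels.  All randomness lives in the
fixture seed — the tracker itself has none.  Angles are degrees.  The
evaluation disk has radius 2 with inclusive membership (13 pixels), per
the scoring protocol's definition; IoU of two empty masks is defined as
0.  Identity matching between tracker output and ground truth is fixed
at frame *k* by best IoU and never re-matched, so identity swaps show
up as zero-IoU poses instead of being silently absorbed.

## Known limitations

* Aggregations lasting much longer than a body length of travel still
  erode the previous-body anchor; with contact windows near 20 frames,
  about one crossing in ten loses an identity (the acceptance suite
  measures 18/20 preserved under `OCpCl`, 8–10/20 under overlap alone).
* The exhaustive product over per-worm candidates is exponential in the
  number of worms sharing one component; the per-worm cap of 12 keeps
  pairs and triples cheap, but large multi-worm clumps would need
  component-level partitioning.
* The color model is frozen at frame *k*; slow photobleaching or focus
  drift over much longer sequences would require model refresh.
* Pose orientation relies on the tail-lighter-than-head contrast; a
  worm whose ends are optically symmetric can be tracked with a
  consistent but arbitrary head assignment.
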
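# Methods

## Detection model

The pipeline assumes widefield 2-D fluorescence images in which cilia
(acetylated α-tubulin) and basal bodies (pericentrin) occupy separate
channels, background is darker than signal, and a global intensity
threshold separates the two.  Segmentation is deliberately minimal —
threshold, connected components, size window — so that every downstream
number is a deterministic function of three interpretable parameters
per channel.  Pixels strictly greater than the threshold are
foreground; the strictness matters only at exact threshold equality and
is fixed so results are reproducible across implementations.
Connectivity defaults to 8, which keeps diagonally oriented, 1–2 px
wide cilia in one piece; 4-connectivity is available and can only split
objects, never merge them.

Coordinates are 0-based `(row, col)` with pixel centers on the integer
grid.  Object boundaries are ordered Moore-neighbor traces through
pixel centers (clockwise, Jacob's stopping criterion); for a 1-px-wide
stretch the trace runs out and back, which is exactly what makes half
the boundary length a sensible proxy for the length of a thin object.

## Pairing rule

For each cilium candidate and each basal body, the distance is the
minimum Euclidean distance from the candidate's boundary pixels to the
basal body's area centroid.  A candidate is confirmed iff its nearest
basal body is strictly closer than `max_distance` (default 12 px) and
it is the *only* basal body strictly within `vicinity_distance`
(default = `max_distance`); with two or more puncta in the vicinity the
candidate is discarded as an artifact, the geometry produced by
overlapping cells.  Candidates are classified independently — no
one-to-one assignment — and a missing basal-body channel makes every
candidate "too far" (distance ∞), never an error.  The d = 12.0
boundary case is excluded (strict `<`).

The percentage ciliated is `100 · confirmed / all detected basal
bodies`.  The denominator counts every detected punctum, including
those inside artifacts and those with no cilium; an option
(`exclude_artifact_bbs`) removes artifact-involved puncta instead.  A
zero denominator yields an explicit undefined value (empty CSV cell),
never 0.  Wells pool counts (`100 · Σcilia / Σbasal bodies`) so images
with more cells weigh more; the unweighted mean of image percentages is
reported alongside for comparison.

## Length estimation

Two estimators are computed per cilium, both in pixels:

- **half_perimeter** (headline): half the length of the closed boundary
  trace.  The cycle is split at the object's two most mutually distant
  boundary pixels (its tips) into two side paths; each side is measured
  and the two are averaged.
- **skeleton**: the arc length of the thinned skeleton path, extended
  from each skeleton endpoint to the nearer object tip.  Thinning
  (Zhang–Suen-class, directional subiterations) retracts endpoints by
  1–2 px; the tip extension restores that length.  For 1-px-wide
  objects the tips coincide with the skeleton endpoints and the
  extension is zero.

Digitized paths are measured by **chord resampling**: chords spanning 4
path steps (endpoints always included) rather than summing unit/√2
pixel steps.  Raw step sums overestimate digitized straight lines at
intermediate angles by up to ~8% (the staircase effect), which at a
60 px cilium is a 5 px bias; 4-step chords are exact for rectilinear
and 45° paths (a 1×10 line measures 9.0 under both estimators) and
recover smooth curves to sub-pixel accuracy.  Splitting the boundary
cycle at the tips prevents chords from short-cutting the fold the trace
makes around the end of a thin object.  Verified accuracy: both
estimators stay within ±2 px of truth for rendered cilia of length
10–60 px, widths 1–3, arbitrary orientation and curvature up to 0.18.

Lengths are exactly invariant under translation; the half-perimeter is
exactly invariant under 90° rotations, while the skeleton length can
shift by ≲1 px because directional thinning passes are not
rotation-equivariant.  Branched or looped skeletons (not expected for
cilia) fall back to the total edge weight of the skeleton's minimum
spanning tree.

## Screening statistics

Z-scores standardize each well against the population of all screened
wells, dividing by the **population** SD (ddof = 0) — the convention
when the library itself defines the null; `ddof` is switchable.  Hit
calling is one-sided above the mean because the screen seeks increased
ciliation: z ≥ 2 → `hit_2sd`, z ≥ 3 → `hit_3sd` (tiers nest by
construction).  A constant plate (σ = 0) is an error, not a silent
zero.  Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋| uses **sample** SDs within each
control arm (ddof = 1 default), is undefined for coincident control
means, and equals 1 only for zero-variance arms.

## Synthetic scenes

`SceneSpec` defaults describe the emulated assay geometry: 800×800 px
fields, 20 cells, 60% ciliated, cilium lengths 12–25 px at width 3
(about right for primary cilia at 60× on a ~0.2 µm/px camera), basal
bodies as radius-3 disks, the proximal cilium boundary 2–8 px from the
punctum center, curvature up to 0.12, ~4 distractor puncta per field, a
0.7 px Gaussian blur standing in for the PSF, and additive Gaussian
sensor noise (`noise_sigma`, in units of the signal amplitude 1.0).
One `numpy` Generator seeded from `spec.seed` drives all randomness;
identical specs render bit-identical images.

Cells are placed on a shuffled grid of tiles, each cell jittered within
its tile behind a guard margin wider than half the pairing radius, so
no structure of one cell can enter another cell's 12-px vicinity.  This
is what makes noise-free recovery *exact*: the planted ciliated count
is `round_half_even(fraction · n_cells)`, and the pipeline's percent
equals `100·(planted − artifacts)/(puncta)` identically.  The grid caps
capacity (~64 cells at default geometry); overflow raises rather than
silently overlapping.  Planted multi-basal-body cases add a second
punctum 8 px from the first, perpendicular to the cilium, with the gap
capped at 5 px so both puncta stay strictly inside the vicinity.
Distractor puncta go in the cilia channel, below the cilia min-size and
≥20 px from real objects; none are planted in the basal-body channel by
default because every detected punctum enters the denominator and would
change the planted truth.

A planted cilium's **true length** is the tip-to-tip extent of the
rendered structure: the centerline arc length plus the dilation radius
protruding past each endpoint (dilating a polyline physically lengthens
the object).  Default segmentation parameters
(`DEFAULT_CILIA_PARAMS`: threshold 0.5, min 8 px;
`DEFAULT_BB_PARAMS`: threshold 0.5, min 5 px, max 500 px) are
calibrated to this renderer — amplitude 1, blur 0.7 — and are starting
points for real data, not screen-derived values: the assay's original
thresholds are not published.

What the generator does **not** emulate: uneven illumination,
autofluorescent background texture, out-of-focus light, touching or
overlapping cells, photobleaching, and cilia seen end-on (foreshortened
to puncta).  Passing the synthetic suite therefore demonstrates the
correctness of the algorithm, not the adequacy of a global threshold on
any particular microscope's output; real deployments should tune the
per-channel thresholds and size windows on control wells.

Synthetic plates draw sample wells i.i.d. normal(μ, σ) (defaults 20%,
4 points); a "+z SD spike" sets its well to μ + zσ, a compound of known
displacement, so spike recall is a sharp property rather than a
distributional one.

## Problem sizes

The verification suite exercises: 200 random pairing scenes against a
pure-python exhaustive oracle; 20 seeded scenes of 10–50 cells spanning
planted fractions 0–100%, noise-free (exact recovery) and at noise
σ = 20% of signal (±5 points); 45 length fixtures (10–60 px, widths
1–3, straight and curved); 100 null 384-well plates for false-hit
calibration plus 25 spiked plates; and byte-level CLI determinism on
two-scene runs.  The full suite runs in well under a minute on one
core; `scripts/acceptance.py` recomputes the same quantities from
scratch in ~15 s.

## Known limitations

- Global thresholding only; no illumination correction or adaptive
  thresholds (by design — the method is the reproducible baseline).
- 2-D only: no z-stacks, no 3-D length correction; foreshortened cilia
  are under-measured.
- No per-cell assignment via nuclei — the denominator is basal bodies,
  and the DAPI channel is display-only.
- No one-to-one cilium/basal-body matching: a single punctum can
  confirm several candidates within its radius (faithful to the
  per-candidate rule, but worth knowing on dense fields).
- The skeleton length inherits a ≲1 px orientation dependence from
  directional thinning.
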
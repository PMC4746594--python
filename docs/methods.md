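# Methods

This note documents the models behind `cellpick`, the defaults they carry,
the choices that were genuinely open, and what the synthetic experiments do
and do not demonstrate about the physical instrument.

## Coordinate conventions

All positions live in a single stage frame in micrometers: x increases to
the right (image columns), y downward (image rows). Pixel indices are
0-based and a pixel coordinate refers to the pixel center, so stage and
pixel frames are related by the affine map
`x = col·pixel_size + offset_x` (and likewise for y). Keeping one
convention everywhere removes the half-pixel bugs that otherwise plague
mosaic stitching; the round trip is exact to 10⁻⁹ µm.

## Synthetic imaging

Populations are placed uniformly at random inside the arena, optionally
with a hard-core minimum separation enforced by dart throwing (retry budget
100 attempts per cell; an infeasible packing — fraction ≥ 0.5 — is rejected
up front). Arenas default to 5 × 5 mm² squares with a 97 µm medium layer,
so the medium volume is area × height = 2,425 nl.

A fluorescent cell is rendered as an isotropic Gaussian spot on a constant
background with i.i.d. Gaussian read noise, clipped to the bit range. The
spot width defaults to σ = size/4 so the apparent blob diameter tracks the
nominal cell size; the amplitude is the cell's own brightness. This is the
simplest point-spread-like model whose centroid, peak and translation
behavior have closed forms the tests can check exactly. Unlabeled cells are
invisible in the fluorescent channel and appear only as low-contrast rings
in phase renders. No optical realism is attempted: no vignetting, shading
or photobleaching kinetics.

Mosaics tile the arena bounding box with a configurable overlap; tiles
advance by `extent × (1 − overlap)`, each records its stage offset, and a
cell in an overlap strip is rendered in every covering tile. The camera
geometry (default 640 × 640 px at 2 µm/px) is freely configurable since no
fixed pixel scale is assumed for the 10× optics.

## Detection

Segmentation follows the local-variance principle: a cell against a flat
background is a patch of high intensity variance. The variance map over a
(2r+1)² window (r = 2 by default, reflected borders) is thresholded at

    t = noise_level² × sensitivity

so that sensitivity = 1 means "variance equal to the noise floor"; the
default sensitivity 4 sits far above the ~10σ tail of the windowed noise
variance. Components use 8-connectivity with hole filling so ring-shaped
fluorescent cells stay single objects; touching cells are deliberately not
split (no watershed) — the sorting strategy avoids dense fluorescent
clusters rather than resolving them. Per component we report the
intensity-weighted centroid (weights are the image minus its component
minimum, so constant offsets cancel), the equivalent-circle diameter of the
component area as "size", and the raw mean intensity as brightness.
Whether the original instrument thresholds variance or standard deviation,
and at which window size, is not published; both knobs are exposed.

Mosaic detection runs per tile, maps centroids to stage coordinates, and
merges cross-tile duplicates closer than the dedup radius (20 µm default),
keeping the record whose centroid lies farthest from its own tile border —
the least-truncated view. External segmenters are supported through a CSV
dialect mapping (the ImageJ "Analyze Particles" results dialect is built
in, accepting XStart/YStart, X/Y or centroid columns, bounding boxes and
mean brightness, with pixel→stage conversion).

## Adaptive targeting

Closed-loop visual servoing is rejected by design (continuous fluorescent
exposure bleaches and damages cells), so each target is re-detected exactly
once, in a single 200 × 200 µm frame captured immediately before its pick.
The nearest fresh detection within the search radius wins (ties: larger
brightness, then smaller id); with none, the target is reported lost and
skipped — there is no retry of the retarget itself. The 50 µm default
search radius is a few minutes of thin-layer drift (5.4 µm/min) with
margin, still below typical inter-cell spacing in sparse cultures. The
fresh image reuses the same detection parameters as the survey scan.

## Scheduling and the valve protocol

The pick order is a greedy nearest-neighbor tour (ties to the smaller id).
It matches the visited-all-cells paths the instrument produces and is
trivial to audit; an exact brute-force tour serves as a test oracle for
n ≤ 7, where greedy is provably optimal on collinear instances.
Destinations are a row-major 500 µm grid, the 24 wells (2 × 2 mm²) of the
miniature plate at one cell per well, or numbered PCR tubes; exceeding the
plate capacity is an error. Each pick expands to exactly five timed
actions (move, descend to 5 µm, −100 Pa vacuum for 10 ms, ambient pressure
for 1 s, ascend) and each deposit to four (move, descend, +4,200 Pa for
1 s, ascend). Moves and z-travel are treated as instantaneous — motor
kinematics and settling are out of scope — so timestamps advance only by
the pulse durations.

## Suspension digital twin

**Motion.** Only floating *speeds* are reported for the instrument, not a
process, so the twin uses a persistent random walk: each cell draws a
constant speed once from Normal(mean, sd) truncated at zero, and a heading
that is redrawn uniformly with probability 1 − exp(−dt/τ) per step.
Presets carry the three measured regimes — open dish 39 ± 12 µm/min, oil
thin layer 5.4 ± 1.1, thin layer inside a miniature well 2.3 ± 0.6 — with
τ = 300 s by default, chosen so 120 s-interval speed estimates are close to
unbiased (the residual bias is ~8%; see below). Walls reflect specularly.
MSD grows quadratically while t ≪ τ and linearly for t ≫ τ, which the
tests verify. There is no z-motion, no division, no death, no fluid
dynamics.

**Capture.** A pick removes every cell within the capture radius of the
aim point and exactly 1.4 nl of medium (also on a failed pick — fluid is
drawn regardless); a deposit adds 147 nl and scatters the carried cells
uniformly within the deposit spread radius. Two radius presets exist and
are deliberately not reconciled: 34 µm is the measured sparse-suspension
resolution of the 30 µm pipette; 63 µm is the *effective* dense-regime
radius calibrated so that a 2,000 cells/mm² field yields ~25 bystanders
per pick (λ = d·π·R²). The published ±4 µm on the resolution is treated as
measurement uncertainty, not per-pick noise; per-pick radius jitter is
available (`radius_jitter_sd`) but defaults to zero. The 127 µm deposit
spread is likewise a calibration, not a measurement: it is the radius that
makes the pass-2/pass-1 bystander ratio equal (34/127)² ≈ 0.072, the
empirically observed thinning. (For two independent uniform points in a
disc the exact small-r ratio is ≈ 0.064; the simulated thinning lands
between the two.) Pick failure leaves the cell in place; the default
success probability in suspension is 1.

**Microwells.** Trapping is Bernoulli per well (at most one cell each) at
the measured fill efficiency — 0.25 for fibroblasts in 20 µm wells, 0.54
for monocytes in 15 µm wells, 100 µm pitch, 10,000 wells on 10 × 10 mm² —
with occupancy capped by the applied cell count. Cells not trapped are
washed away. Aspirating a trapped cell succeeds with probability 0.5
(cells adhere to the PDMS); a stuck cell stays in its well flagged at risk.
Spatially explicit settling is not modeled; only the aggregate
efficiencies are published.

## Workflows

**Sparse isolation** composes the full loop: synthesize 2,000 cells in a
5 × 5 mm² arena (80 /mm², hard-core 50 µm), render and detect a mosaic,
tour the detections, and per target advance motion by one 20 s cycle
(3 cells/min), capture a fresh frame, retarget adaptively, pick at 34 µm
and deposit into its own vessel. Success means exactly the intended cell,
alone, in its vessel. Three operational elements, all configurable, were
added because a fixed 50 µm search radius cannot survive a long route
otherwise (drift grows ~√t and passes 50 µm after ~10 minutes):

* a periodic ROI rescan every 15 picks refreshes pending target
  coordinates (modeled as idealized re-detection with 1 µm error — 130
  full mosaic re-renders would add nothing but runtime since the imaging
  path is already exercised by the survey scan and every fresh frame);
* each fresh frame opportunistically refreshes any other pending target
  it covers (the greedy tour keeps upcoming targets nearby);
* a purity gate defers a target (to the queue tail, at most twice) when
  the fresh frame shows a neighbor inside the capture disc or when the
  matched blob exceeds 34 µm apparent diameter — doublet exclusion, since
  cells closer than ~28 µm image as one blob at these optics.

Under these defaults the simulated recovery is ~0.95. The physical
instrument reports ~75%; the gap is the wet failure modes the twin does
not model (loss inside the pipette, adhesion, damage), which are not
separately published. Setting `pick_success_prob ≈ 0.79` reproduces the
printed figure by construction; the regression test asserts only the
published lower bound (> 0.75). Recovery is monotone non-increasing in
floating speed, and adaptive targeting strictly beats stale coordinates on
paired seeds — both asserted.

**Successive enrichment** starts from 50 labeled + 50,000 unlabeled cells
(1,000:1) and each pass picks every labeled cell still present and
redeposits it, with its bystanders, on a 500 µm grid in the next of four
arenas. Pass 1 uses the dense effective radius (63 µm); later passes use
the measured 34 µm, because the redeposited clusters are sparse by the
density criterion (~44 µm typical spacing inside a 127 µm cluster) — this
is also the regime in which the (34/127)² thinning ratio is defined.
Motion is off by default (a settled dense culture at ≤ 2.3 µm/min moves
negligibly per ~1 min cycle); detection is taken from the simulator state
rather than re-rendering a 50,050-cell mosaic each pass. Cell-count and
volume conservation are exact by construction and asserted per pass.

**Microwell comparison** loads the array, selects every filled well and
attempts each: with 300,000 cells applied, 98–99% are untrapped (closed
form 1 − wells·efficiency/applied agrees with simulation) and ~50% of the
selected trapped cells are recovered — the baseline the thin-layer method
is compared against. The recovery denominator is attempted (selected)
targets, not the initial population.

**Speed estimation** mirrors the time-lapse measurement: positions every
30 s for 1 h, per-cell speeds from non-overlapping 120 s displacement
intervals, averaged per cell then across cells. Averaging over 120 s
rather than 30 s suppresses tracking noise at the cost of a small downward
bias once headings decorrelate within the window: with τ = 300 s the
estimator reads ~8% low; with τ ≫ 120 s (as in the acceptance run,
τ = 1800 s) the bias is ~1–2%. A pure drift is recovered to 10⁻⁹ and a
fast-tumbling walk is strictly underestimated — both asserted.

## Numerical notes

* Variance maps use `uniform_filter` on E[x²] − E[x]²; scipy's "reflect"
  border equals numpy's "symmetric" padding, which the brute-force test
  oracle mirrors. Values are clipped at zero against cancellation error.
* Retarget ties break deterministically (distance, −brightness, id);
  route ties break on the smaller id; detections sort by (y, x).
* Problem sizes in the test suite (e.g. 1,000-pick Poisson checks, 60-seed
  enrichment averages, 250–2,000-target isolation runs) were chosen so the
  full suite completes in about a minute while keeping Monte-Carlo
  tolerances at 3σ.

## What passing tests do and do not show

The generator and twin reproduce the *published aggregate statistics* and
the geometry that links them; they do not model optics beyond a Gaussian
spot, cell-to-cell size/brightness heterogeneity beyond mild jitter,
convective (collective) drift as opposed to independent random walks,
adhesion, or any hardware timing. Conclusions about detection accuracy,
scheduling and the enrichment arithmetic transfer to real data only to the
extent those simplifications hold; the dense-regime capture radius and the
deposit spread are calibrated to the published outcomes and must not be
read as independent predictions of them.
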
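# Methods

`polarsig` quantifies the subcellular localization of fluorescently tagged
envelope proteins — type IVa pilus machine components such as the secretin
PilQ and its pilotin Tgl are the motivating case — in rod-shaped bacteria
imaged by epifluorescence microscopy. The package has two halves: an analysis
pipeline operating on single-channel images plus per-cell meshes, and a
synthetic-microscopy generator that produces images, meshes and ground truth
with the statistical structure the analysis assumes, so that every stage is
testable without access to raw microscopy data.

## Cell geometry and axial coordinates

A cell is represented as a **mesh**: an ordered sequence of axial segments,
each owning a disjoint set of image pixels, running from pole 0 to pole 1.
Segments target an axial extent of one pixel (0.065 µm at the default pixel
size, minimum 10 segments per cell) — the mesh step of the Oufti-style
meshes this emulates. Fine segmentation matters for the detection statistic:
a diffraction-limited focus must occupy a small fraction of segments even in
a 3 µm cell, otherwise a two-focus cell can never satisfy the narrow-peak
criterion below.

Relative axial position runs from 0 to 1. A segment sits at the midpoint of
its span of the cumulative axial extent, i.e. position `(i + 0.5)/n` for `n`
equal segments; unequal segments are weighted by their physical extent. Cell
length is the sum of segment extents times the pixel size; the population is
stratified into short (< 6.5 µm) and long (≥ 6.5 µm) cells.

Meshes are read from a structured-text format (one header line per cell, one
line per segment with its 0-based row-major pixel indices) or derived from
integer label images by projecting each label's pixels onto its principal
axis and slicing into equal axial bins. The label-image route assumes
straight cells; curved (banana-shaped) cells would need geodesic axial
coordinates and are a documented limitation.

## Signal conditioning and background correction

`background_correct` prepares a frame for detection: a mild Gaussian filter
(σ = 0.7 px by default, exposed as a parameter and set to 0 to disable)
followed by subtraction of the median intensity of all non-cell pixels, with
negative values clipped to zero. The filter exists because the detection
statistic below is built on per-segment *maxima*: on images with spatially
uncorrelated shot and read noise, single-pixel outliers follow extreme-value
statistics and would dominate the maxima, a pathology real (optically
band-limited) images do not show. The 0.7 px width suppresses single-pixel
outliers while leaving features at the diffraction scale (≥ 1.5 px)
essentially intact. An image with no background pixels (cells covering the
full frame) is rejected rather than silently miscorrected.

## Fluorescence profiles

For each cell, the per-segment statistic (mean by default; max and sum are
available — which statistic the published demograph-style panels used is not
documented, so it is exposed as a flag) is divided by the **maximum pixel
intensity within the cell**, giving a profile in [0, 1] with maximum 1.
Cells with zero signal receive an explicit zero-signal verdict rather than a
division by zero. Profiles are scale-invariant: multiplying the image by any
positive constant changes nothing downstream.

Profiles can be oriented before pooling:

* **brightest pole** — the profile is reversed if the terminal value at
  position 1 exceeds the terminal value at position 0; an exact tie keeps the
  input order (deterministic).
* **old pole** — position 0 is assigned to the pre-existing pole; this
  requires lineage information (from tracking or generator truth).

Population summaries interpolate each oriented profile linearly onto 100 bin
midpoints and report the per-bin mean and sample SD (n − 1 denominator)
across cells. Bins where all cells agree report exactly zero SD.

The **polar signal fraction** is the summed intensity of segments whose
midpoint lies within 0.1 relative length of either pole, divided by the
total cell intensity. For a uniform-intensity cell with equal segments this
equals the window share (0.2) up to one-segment discretization.

## Cluster detection: the narrow-peak criterion

Detection works on the vector of per-segment maximum pixel intensities,
normalized to the cell maximum. A cell is called cluster-positive when

> (number of entries strictly above 0.75) / (number of entries) < 0.10

with strict inequalities on both comparisons — i.e. the cell contains an
intense and *narrow* fluorescence peak rather than bright diffuse envelope
signal. A flat profile normalizes to all-ones (fraction 1, negative); a cell
whose only bright structure is one focus has a small supra-threshold
fraction (positive). The fraction denominator is all segments by default;
`denominator="nonzero"` restricts it to segments with signal (whether the
original analysis counted empty segments is not documented, so both are
available).

Cluster locations: each maximal run of consecutive supra-threshold segments
yields one cluster, positioned at the run's intensity-maximum segment. The
localization rule is this package's own; only the detection criterion itself
follows the published description.

Pattern classification: a cluster is polar if its position is < 0.1 or
> 0.9. Clusters at both ends give **bipolar**, at exactly one end
**unipolar**. The **mid-cell** flag is independent: any cluster inside
[0.40, 0.60]. A cell whose clusters are all non-polar is labeled
``midcell`` when the flag is set (and ``none`` otherwise, an edge case the
generator does not produce). Population summaries report unipolar, bipolar
and no-polar-cluster percentages summing to 100 — cells with only a mid-cell
cluster count under "none" there — with the mid-cell percentage reported
separately, matching the figure convention of the motivating study. The
polar and mid-cell windows quantify the qualitative visual assignment of
that study and are configurable.

## Time-lapse analysis

Cells are linked across frames by greedy maximal mask overlap (ties: larger
overlap, then smaller track id). A track whose mask resolves into two
successors has completed cytokinesis: the first frame with two disjoint
daughter masks is t = 0 for both daughters, each scored independently.

**Appearance.** "Clearly visible" is operationalized as the first run of at
least 2 consecutive cluster-positive frames (configurable). The appearance
offset is (run start frame − t0) × frame interval. Negative offsets are
real: mid-cell clusters can appear in the mother before division, so each
daughter's scored sequence prepends the mother's pre-division frames (scored
by the mid-cell flag, since that is where pre-division recruitment happens)
to the daughter's own cluster verdicts.

**Lifetime.** From the appearance-run start to the last positive frame
before a permanent all-negative tail, counting inclusive frames:
(last − first + 1) × frame interval. Single-frame dropouts inside the
positive span are flicker, not disappearance. A track still positive at its
final frame (movie end, or the daughter's own division) is **censored**:
counted, reported, and excluded from lifetime means. Summaries use the
sample SD (n − 1); a single value reports SD 0 with n = 1.

## The synthetic generator

The generator emulates the study conditions of slow-growing rod-shaped
bacteria (the motivating organism divides every 5–6 h; default generation
time 330 min) imaged at 0.065 µm/px every 10 min.

**Geometry.** Cells are straight horizontal spherocylinders, width 0.7 µm,
snapshot lengths log-normal (median ≈ 5.5 µm, log-sd 0.28) clipped to
3–12 µm. Patch heights are odd so the centerline and cap tips fall on pixel
centers. Meshes are emitted directly; segmentation error is not modeled.

**Signal.** Envelope signal is membrane-weighted
(`exp(−((r − d)/0.35 r)²)`, d = distance to the centerline), peaking at
100 a.u. at the membrane over a 100 a.u. diffuse background. Foci are
membrane complexes: Gaussian spots (axial σ 0.1 µm — diffraction-limited)
with a flat-top tangential profile (~2 px), centered on the envelope at the
requested axial position and realized at pixel centers (sub-pixel optics are
out of scope). The default amplitude, 122 a.u., equals 5× the per-pixel
noise SD on envelope signal, `sqrt(envelope + background + read_sd²)` — a
faint-cluster regime; the motivating study reports no cluster/envelope
intensity ratio ("very faint" clusters), so amplitude is a free parameter,
not a calibrated claim. Noise is Poisson on the composited signal plus
Gaussian read noise (SD 20), applied once per field after compositing.

**Snapshots.** Patterns are drawn i.i.d. from configurable probabilities
over {bipolar, unipolar, midcell, none}; polar foci sit within 0.04 relative
length of a pole, mid-cell foci within 0.46–0.54. Spot amplitudes jitter
±5% per spot: the detection rule normalizes to the cell maximum, so strong
inter-pole asymmetry would make the weak pole undetectable by construction.
Cells are shelf-packed without overlap; a fixed field that cannot hold all
cells is a placement error.

**Movies.** Founders start at a uniformly random cell-cycle phase with no
cluster; cells elongate exponentially and divide at twice their birth length
(hence exactly one generation after birth), with a sinusoidal septum
constriction over the final 30 min. Each division replaces the mother by two
daughters in an ordered lane chain that is re-laid out every frame around
the lane center, so masks never overlap while neighbours grow. The pole at
the division plane is the daughter's *new* pole; truth records old-pole
identity (the left daughter keeps end 0, the right keeps end 1).

Cluster kinetics model a transiently recruited protein (the pilotin case):
for each daughter, an appearance offset is drawn (default Normal(20, 15)
min, relative to completion of cytokinesis) and a lifetime (default
Normal(70, 20) min, truncated positive). Negative offsets place the spot at
the mother's septum before division. Events are realized on the imaging
grid: appearance times snap to the nearest frame and lifetimes to a whole
number of frame intervals (minimum one) — recorded truth is what a camera
sampling every 10 min would see, so recovery tests compare like with like.
A stable-cluster flag (the secretin case) makes foci permanent instead.
Cephalexin mode blocks division while growth and constriction continue, and
places a single mid-cell focus per cell timed relative to when division
would have completed.

**What passing tests do and do not show.** The generator reproduces the
*statistical* structure the analysis assumes — membrane-weighted signal,
faint narrow foci, multinomial pattern mixtures, division-anchored event
times — but not optical point-spread functions, segmentation errors, cell
curvature or movement, photobleaching, or focus intensity dynamics
(intensity ramps are not modeled; foci switch on and off). Tests passing on
synthetic data therefore validate the measurement logic at realistic
contrast and noise, not robustness to segmentation or optics artifacts.

## Numerical choices and degenerate inputs

* Strict `<`/`>` at both detection thresholds; a vector with exactly 10% of
  entries above 0.75 is negative.
* All verdicts and profiles are invariant to positive rescaling of the
  image (linear pipeline, normalization to the cell maximum).
* Zero-signal cells propagate an explicit verdict (pattern "none",
  `zero_signal` annotation) instead of raising mid-pipeline.
* Symmetric-profile orientation ties keep input order; overlap-tracking ties
  prefer the larger overlap, then the smaller track id.
* Degenerate geometry (length < 3× width) and non-positive lifetime laws are
  rejected with explicit errors.
* All randomness flows from a single integer seed; identical configuration
  and seed reproduce byte-identical outputs, including TSV metadata headers
  (package version, configuration hash, seed).

## Problem sizes

Default verification sizes — 500-cell snapshots for mixture recovery,
100-founder / 55-frame movies (≈ 390 scored daughters) for timing recovery,
2000 cells for multinomial convergence — were chosen so the complete suite
and the reproduction script each run in well under a minute of compute per
component on a single core while leaving the Monte-Carlo error of every
recovered quantity far inside its assertion tolerance.
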
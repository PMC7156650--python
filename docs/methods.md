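# Methods

This note documents the models, algorithms, parameter choices, and known
limitations behind `endoescape`. It is the reference for what each number
the package produces means and for the design decisions that were
genuinely open.

## Coordinate and measurement conventions

All images use 0-based indices with x → column, y → row; movies are 5D
arrays in (t, c, z, y, x) order, declared in the TIFF metadata together
with the frame interval (default 3 s), pixel size (0.1 µm) and z-step
(0.3 µm, 30 planes in a standard acquisition). Object measurements are
single-plane means over a circular mask of all pixels whose centers lie
within `mask_diameter_px / 2` (default diameter 6 px ≈ 600 nm; on an
unbounded grid this disk holds 29 pixels). Mask centers are integer pixel
positions; there is no sub-pixel refinement, matching the pixel-grid
measurements of the underlying assay. Masks or rings clipped at an image
border use the in-bounds pixels and set an explicit flag — never silently.

The local fluorescence background of a vesicle is the median over a ring
of pixels at distance mask-radius + 8 px (± 1 px radial half-width, i.e. a
2 px wide ring ~0.8 µm outside the object). The ring geometry is
configurable because "a circular area outside the object mask" admits both
a thin ring and a filled annulus; the thin ring was chosen so large
neighboring objects bias the estimate less, and the median adds further
robustness.

## Onset detection and 4D tracking

Detection is seed-driven: a user (or the simulator) supplies approximate
(x, y, t) of a candidate de novo galectin focus. The scan starts
`initial_lookback_frames` (25) before the seed frame, truncated and
flagged at frame 0. Each scanned frame contributes one measurement: the
maximum mask-mean over the complete z volume within ± 6 px of the seed in
x and y. Once at least `min_pre_measurements` (5) scan values exist, a
measurement strictly above θ = mean + `threshold_k` (5) × s.d. of all
prior scan values marks a candidate onset. The candidate is confirmed by
forward tracking for `confirm_frames` (5) consecutive frames, each
required to stay strictly above θ *frozen at candidate time* —
recomputing θ during confirmation would mix post-event signal into the
null. An all-equal history gives s.d. 0 and θ = mean, with the strict
inequality still applying. The s.d. here and everywhere in thresholds is
the population s.d. (ddof = 0).

Design points worth making explicit:

- The scan history is kept across rejected candidates (the alternative —
  restarting it — discards null information and makes results depend on
  rejection order). Because the scan measurements are window maxima that do
  not depend on `threshold_k`, raising `threshold_k` provably never
  increases the number of confirmed events.
- `min_pre_measurements` = 5 is the package's own floor for forming a
  threshold; no published value exists.
- Tracking fits the mask to the maximum mask-mean within ± 12 px (x, y)
  and ± 5 z-planes of the previous position. Ties are broken by smallest
  Euclidean displacement from the previous position, then lowest
  (z, y, x) — a fixed, documented rule so runs are deterministic.
- Pre-onset "static" measurements (20 frames) are taken at the frozen
  onset coordinates. For a mobile vesicle these under-estimate pre-onset
  intensity in occasional frames; this mirrors the assay's static
  pre-event measurement and is the main source of heavy-tailed outliers in
  noisy single-frame release read-outs (the median-based recovery targets
  are unaffected).

## Traces and release statistics

A trace is raw mask-mean minus an 11-frame centered rolling average of the
local background (shrinking windows at the series edges), aligned so the
onset frame maps to relative time 0. Cargo traces are normalized to their
mean over the pre-onset window 3–60 s before t₀; galectin traces to their
maximum. Second-to-frame conversions round to the nearest whole frame,
minimum 1.

The released fraction is 1 − post/pre from *single-frame* measurements at
the frames nearest −15 s and +45 s (per the assay's figure-level
definition; window means would be more precise but would not match it). A
noisy post measurement can dip below zero, so the fraction is capped at 1.
Cargo presence before damage ("hit-rate" numerator) is called when the
mean background-subtracted cargo intensity within 15 s before onset
exceeds `cargo_presence_k` (3) × the s.d. of the local background over the
same frames — the published criterion is visual, so this numeric stand-in
is deliberately configurable. Fold recruitment is the focus mean 90–105 s
after onset over the cell-background mean 10–25 s before, both after
image-background subtraction. Event rates are foci / cells / hours, and
95% CIs are 1.96 × s.d./√n with the population s.d.

## Marker classification

Marker-object pixels of a cell are those whose log₁₀ intensity strictly
exceeds the cell's log-mean + 1 log-s.d.; non-positive pixels are excluded
before the transform (the alternative +1 offset distorts the distribution
at low counts). The bleaching reference is a line through the
non-logarithmic object means at the first and last frame — single anchor
frames, since "beginning and end of the acquisition" is otherwise
unspecified — and it normalizes the vesicle's background-subtracted marker
trace frame by frame. For 30% total exponential bleaching the
linear-chord error is below 2%, well within the 5% envelope the tests
check. Cell pixels are sampled from the maximum z-projection of the marker
channel so objects at any depth contribute.

Cells whose marker-object SNR — (object mean − image background mean) /
background s.d. — is strictly below 50 are excluded; SNR exactly 50 is
retained, and zero background s.d. maps to +∞ (pass). The assessment
window keeps five consecutive measurements starting at the first frame
after onset (≈ 3–16 s at 3 s intervals; the count, not the seconds, is
what generalizes across intervals). Window mean strictly above 0.5 →
positive; a positive with trace s.d./mean > 1 over the ~64 s evaluation
horizon is reclassified negative and flagged, the published guard against
signal borrowed from adjacent positive vesicles.

## Per-cell and spheroid measurements

Foci are assigned to the cell containing their centroid (the relationship
is otherwise external to the published pipeline); centroids on background
are reported separately, never dropped silently. The dextran and siRNA
margins use a radius-5 disk structuring element (isotropic, unlike a
square). Background-subtracted intensities are clamped at zero before
colocalization sums so fractions stay in [0, 1]. The dextran vesicle
threshold is a required input, as the published value was "prespecified"
per experiment and never stated.

Spheroid sections are scaled (nearest neighbor) so the mask's equivalent
radius — √(area/π), robust to non-circular spheroids — is 200 px. Pixels
below background mean + 3 s.d. are excluded. Shell membership bins the
Euclidean distance transform of the scaled mask into 1 px bands from the
margin inward, so irregular margins are followed during measurement, while
the export maps per-shell ratios onto concentric shells of a perfect
200 px circle (the same EDT binning on a disk, so shell i lands on shell
i). Export rounding is half-away-from-zero; the 1/1000-log quantization
bounds round-trip error at ~0.12%.

## The synthetic-data generator

The simulator is first-class, tested code; it defines the conditions under
which the pipeline is validated. It emulates:

- vesicles as PSF-blurred point sources at integer voxel positions
  (sampled separable Gaussian, in-plane σ 1.3 px, axial σ 1.2 planes,
  kernel normalized to sum 1 — so noise-free total intensity decomposes
  exactly into background plus source integrals);
- 2D random-walk motion (default step s.d. 0.5 px/frame, well inside the
  tracking volume; mobility statistics are free parameters, not calibrated
  to any published value);
- abrupt galectin recruitment (0 → amplitude at the true onset), step-wise
  cargo loss by the planted release fraction with optional exponential
  residual decay (covering both rapid- and slow-release regimes), marker
  signal on marker-positive vesicles plus static decoy endosomes, with
  linear or exponential photobleaching on the marker channel;
- Poisson shot noise on expected counts plus additive Gaussian read noise
  (s.d. 2), digitized to non-negative integers; background 100 counts.

Decoy endosomes are placed clear of every event's path: a vesicle whose
measurement volume contains another object's marker signal is genuinely
marker-associated, so overlap would make a planted "negative" label wrong
rather than hard.

Planted-event SNR is defined as the expected mask-mean signal increase
divided by the per-pixel noise s.d.; `mask_gain_factor` converts a source
amplitude to the expected mask-mean gain so tests can plant exact SNRs.

What the simulator does *not* emulate — and hence what passing tests do
not show about real data: deconvolution artifacts, spectral bleed-through,
stage drift, clustered or touching vesicles, intensity-dependent motion,
spatially varying background, and cell segmentation errors (label images
are taken as given throughout).

## Problem sizes and numerical choices

The validation suites use scaled-down acquisitions chosen to cover every
analysis window: 48 × 48 px fields, 6 z-planes, 55 frames at 3 s for
detection/release (the latest onset still leaves −60 s … +45 s of trace),
80 × 80 px, 45 frames, 4 events + 8 decoys for marker classification, and
radius-120 px spheroids. Onset-recovery, false-positive, release, and
marker batches run 100 (or 50) independently seeded instances. Brute-force
oracle comparisons run on ≥ 50 random instances per operation with
integer-valued images, where correlation-based and enumeration-based
arithmetic agree exactly, making "equal" a meaningful assertion.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical parameters and seed reproduce
bit-identical movies, and the CLI pipeline's data outputs are byte-stable
across runs (the run manifest carries a wall-clock timestamp and is
excluded from byte comparisons).

## Known limitations

- Detection is seed-driven by design; there is no unseeded whole-movie
  event caller.
- The pre-onset static measurement under-tracks mobile vesicles (see
  above).
- The marker normalizer anchors on two single frames; acquisitions with
  strong frame-to-frame object turnover would need range anchors.
- Statistical comparisons between conditions (Mann–Whitney, Fisher) are
  out of scope; the package exports the per-event counts and values those
  tests consume.
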
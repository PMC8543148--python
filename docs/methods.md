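# Methods

This note records the models and procedures implemented in `embryotrace`,
the parameters that matter, and the choices made where the design was
genuinely open.

## The measurement problem

During nc14 the *Drosophila* blastoderm cellularizes: lateral membranes grow
in from the surface around the ~6000 cortical nuclei, slowly for the first
~35 min and rapidly thereafter, while the nuclei elongate apico-basally and
their surfaces wrinkle. Notch-dependent transcription in the mesectoderm — a
single-cell-wide stripe — switches on ~30 min into nc14 and is visualised
with the MS2/MCP system as bright intranuclear puncta. The pipeline turns
multichannel 3-D time-lapse movies of this process into per-nucleus
transcription traces, onsets and outputs, nuclear shape time courses,
membrane-front kinetics, and FRAP recovery curves. Times are minutes from
the end of the 13th syncytial division; coordinates are µm from the volume
corner; frames are 0-based.

## Nucleus segmentation and tracking

Each histone-channel frame is median-filtered (3 voxels), contrast-rescaled
so the 1st/99th intensity percentiles map to [0, 1], and band-pass filtered
in the frequency domain. The band-pass is a difference of Gaussians in
physical frequency units — σ_small = scale/12 suppresses single-voxel noise,
σ_large = 2·scale removes background and DC — with `scale` the expected
in-plane nucleus diameter (default 5 µm). A Laplacian-of-Gaussian was
evaluated for this role and rejected: its halo displaces the boundary
obtained by a global threshold by ~σ/2, which caps the achievable mask
overlap near IoU 0.88 on rendered test objects, whereas the
difference-of-Gaussians keeps the half-level boundary at the object edge
(IoU ≥ 0.9 at realistic noise).

Segmentation applies a fixed threshold at 0.40 of the enhanced dynamic
range (the underlying protocol treats this constant as empirically
determined; 0.25 of the DoG range sits barely above the zero-response level
and admits the halo), fills holes, removes objects outside 20–800 µm³,
splits fused nuclei with a marker-based watershed on the anisotropic
Euclidean distance transform (markers are per-component local maxima of the
lightly smoothed EDT, separated by at least half the object scale — maxima
are found per connected component so a taller peak in a neighbouring object
cannot suppress a genuine marker), filters by size again and optionally
applies a constrained thickening. Thickening defaults to off in this path:
the band-pass boundary needs no compensation, and an index-space dilation
would inflate the coarse z axis five-fold; when enabled, the dilation is
measured in physical distance and never merges labels.

Tracking links each object to the nearest centroid (physical µm) strictly
within a 6 µm gate, searching the previous frame first and then up to the
configured lookback (2 frames; the envelope tracker uses 4 µm and 5 frames).
No candidate → new track; two objects claiming the same predecessor → both
become new tracks and the contested track ends. Only track tails are
linkable, so a track holds one object per frame. Equidistant ties break
toward the shallower frame, then the lower label.

## Transcription traces

The spot proxy is the maximum MCP intensity over the nucleus mask (no
sub-voxel fitting). Classification is the two-pass procedure described in
the README; the ≥5 ON frames are counted in total, not necessarily
consecutively (switchable). The 1.2× threshold presumes background
fluctuations well below 20% of the baseline, which holds for max-over-mask
proxies because the extreme value of a few thousand voxels fluctuates far
less than a single voxel; the trace-table generator mirrors this with a
read noise of 0.1 AU on a 1 AU baseline.

Photobleaching normalization has three modes. The default (`mixed`)
subtracts the straight-line baseline fitted to the inactive-pool mean and
divides by the *empirical* inactive-pool decay ratio m(t)/m(0) — the most
literal reading of "removing the fitted baseline" plus "normalizing for the
percentage that the fluorescence in inactive nuclei decreased". `fit`
divides by the fitted-line ratio instead; `empirical` uses the pool mean for
both, which cancels any global multiplicative decay exactly in the
noiseless limit. Under the default exponential bleach (0.5%/min over
60 min) the residual non-flatness of a constant-amplitude spot is <1% in
`mixed` mode and exactly 0 under linear decay.

Onsets are the first ON frame at/after the search start; nuclei whose first
ON frame precedes nc14 are discarded as carry-over activity from earlier
cycles. Output classes split strictly above the cohort median (ties → low).

## Envelope interiors

After cubic resampling to isotropic voxels (clamped to the input range —
cubic overshoot otherwise corrupts range-fraction thresholds), smoothing
(σ = 1 voxel) and histogram matching to frame 0, the membrane seed is a 10%
-of-range threshold. The active-contour refinement is the curvature-free
Chan–Vese fixed point: voxels are reassigned at the threshold
(c_in + c_out)/2 until convergence, with c_in measured over the 2-voxel
eroded core of the membrane mask so its blurred skirt does not drag the
boundary into the interior. The full morphological Chan–Vese was evaluated
and rejected: its curvature smoothing destroys membranes only 2–3 voxels
thick. The refined boundary sits at the edge half-level, which is what makes
enclosed-interior volumes accurate. Interiors are the enclosed components of
the inverted mask (border-connected space removed); any object whose
footprint in one slice exceeds 25% of the slice area is removed as the
vitelline membrane; touching interiors are split by the same watershed; the
10–200 µm³ range is enforced last. Near the bottom of that range the
estimator reaches its resolution floor: a 15 µm³ interior (radius ~1.5 µm)
reads ~6–9% low at realistic noise (~12% low on a perfectly noiseless
hard-rendered phantom) from the curvature bias of the prescribed smoothing.

## Morphology

Volume is voxel count × voxel volume. Surface area comes from marching
cubes on a lightly smoothed (σ = 1 voxel) indicator at level 0.5, which
removes the ~9% staircase inflation of a digital sphere. Solidity divides
the voxel count by the voxel count of the convex hull rasterised at voxel
centres — counting both the same way makes a convex digital object read 1,
where mixing voxel counts with continuous hull volumes is 10–18% biased.
Principal-axis lengths are 2·√(5λ) for eigenvalues λ of the voxel-cloud
covariance in µm (exact for solid ellipsoids). Slice metrics use per-embryo
planes at the requested fractions of the 10th–90th-percentile apico-basal
foreground extent; eccentricity is that of the second-moment-equivalent
ellipse, √(1 − (b/a)²).

## Cellularization front and correlation

Sections are median-filtered (3 px) and Otsu-thresholded; the membrane
length is the vertical extent (last row − first row, × pixel size) of the
largest object, counting only rows supported by a few member pixels (3% of
the section width, minimum 2) so attached single-pixel noise cannot stretch
the height. When Otsu has no real bimodality to find it splits the
background noise; frames where the foreground mean stands less than 4
background standard deviations above the background are left missing for
manual curation, mirroring the original protocol's curation step. Landmark
times are first crossings of a 3-frame running median of the length series;
a landmark never reached is flagged arrested. Per-embryo first quartiles of
onset times use linear interpolation between order statistics; the
correlation is a pooled ordinary-least-squares fit with R² the squared
Pearson correlation.

## FRAP

Mean intensities over 20 px circles (pixel-centre membership) are divided
by their own pre-bleach average and by the same ratio for the mean of the
six control circles; this double normalization cancels any global per-frame
multiplicative factor identically. Zero-scaling maps the first post-bleach
value to 0 and the pre-bleach plateau to 1 (`rescale`, default), so the
plateau of the scaled curve is the mobile fraction; a pure offset mode is
provided because the protocol's wording admits either reading. The
auxiliary readout fits s(t) = m·(1 − 2^(−t/τ)).

## Synthetic data generator

The generator renders the study conditions the pipeline is tested under:

* **Geometry/calibration**: 5 × 5 nuclei, 6 µm pitch (blastoderm packing),
  voxels (1.25, 0.25, 0.25) µm — the 5:1:1 anisotropy of a confocal stack
  with ~1 µm z-steps; apical surface at 3 µm depth.
* **Nuclei**: ellipsoids with apico-basal semi-axis growing 3→6 µm linearly
  until 35 min (in-plane semi-axes 2.2 µm); wrinkling from 25 min as a
  radial perturbation of the in-plane outline combining a mode-2
  (elongating) and a higher corrugation mode with random phases — a pure
  single high mode would leave the second moments isotropic and hence the
  measured eccentricity unchanged. Optional bounded random-walk jitter
  (cumulative offset clipped at 0.7 µm) models crowding without collisions.
* **Transcription**: the mesectoderm-like stripe is the central grid
  column; onsets are truncated normal (mean 30, sd 3, floor 15 min);
  bursting is a two-state telegraph process sampled with the *exact*
  continuous-time transition probabilities over one frame, so the
  stationary ON fraction is k_on/(k_on + k_off) (defaults 2 and 1 min⁻¹);
  puncta are Gaussian blobs (σ = 0.4 µm, amplitude 1 AU) centred on a voxel
  so the rendered peak equals the nominal amplitude.
* **Front**: piecewise-linear f(t), 0.5 µm/min then 1.5 µm/min after the
  35 min breakpoint; membrane walls are rendered two pixels wide (a
  one-pixel sheet would be thinner than any imaged membrane) along with a
  two-row apical surface, and wall depth is truncated to whole voxels so the
  rendered front never exceeds f(t).
* **Photobleaching and noise**: a global multiplicative exponential
  (0.5%/min; linear available) applied to all channels, then Gaussian read
  noise (0.15 AU on voxels — histone SNR ≈ 6; 0.1 AU on trace tables — spot
  SNR 10) and optional Poisson shot noise, added last.
* **FRAP**: pre-bleach plateau, bleach ROIs dropping to r₀ and recovering
  as r(t) = 1 − (1−r₀)(φ + (1−φ)·2^(−t/τ)) (φ immobile fraction), control
  ROIs on a deterministic ring, global acquisition bleaching over the whole
  field.

All randomness flows through one `numpy` generator seeded from the spec, so
a fixed seed reproduces movies byte for byte.

What the generator does **not** emulate: optical point-spread blur (off by
default), mitosis and gastrulation movements, depth-dependent attenuation,
chromatic shifts, and the irregular packing and curvature of a real embryo
surface. Passing tests therefore demonstrate the correctness and internal
consistency of the measurement chain under controlled conditions, not
performance on real microscope data, where parameter defaults (thresholds,
scales, gates) would need the same empirical adjustment the original
protocol applied.

## Problem sizes and numerical choices

Validation movies use 9–25 nuclei, 20–30 frames and 96²–128² × 32–40 voxel
frames; trace cohorts use 200 nuclei over 120 frames; correlation checks
use 40 embryos × 100 replicate seeds — sizes chosen so the whole suite and
the acceptance script each run in minutes on one CPU while every stage is
exercised end to end. Degenerate inputs are defined, not fatal: constant
frames preprocess to zeros with a warning, empty thresholds yield 0-object
label volumes, embryos without onsets are excluded from correlations with a
warning, and an all-active first classification pass falls back to the
cohort baseline. The run manifest records config, input hash, seed, package
version, stage timings and warnings; because it contains wall-clock
timings, determinism is defined over the data products (CSV/JSON tables),
which are byte-identical across runs.
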
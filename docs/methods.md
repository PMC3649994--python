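# Methods

This note documents the models, parameters and design choices behind
`netrack`: the synthetic nuclear-envelope movie generator, the measurement
pipeline that runs on such movies, the movement statistics, and the
zone-based cytology statistics.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Motion model

Aggregates live on the surface of a sphere of radius *R* (the nuclear
envelope; default *R* = 2 µm, a conventional size for germline nuclei in
the pachytene-adjacent region, configurable).  Motion alternates between two
states:

* **run** — processive motion along a great circle at `run_speed_nm_s`
  (default 190 nm/s, the reported average speed of dynein-driven SUN-1/ZYG-12
  aggregate movement).  A run keeps its tangent direction; each new run picks
  a fresh uniform tangent.  Run durations are geometric with mean
  `run_persistence_s`.
* **pause** — isotropic surface diffusion with coefficient
  `diffusion_um2_s`: per step, a 2D Gaussian tangent displacement with
  per-axis variance `2 D dt`, re-projected to the sphere.

State dwell times are quantized to whole frames, and pause durations are
scaled so the stationary fraction of time paused equals `pause_fraction`.
Closed forms used as test oracles: a pure run of duration *T* covers
geodesic path `v·T` exactly; the mean per-step geodesic speed of the mixture
is `(1−p_pause)·v + p_pause·sqrt(π D / dt)` (Rayleigh mean of the diffusion
step), accurate to within the state-transition quantization (< 5% at the
default persistence).

**Fusion and splitting.**  Two aggregates within `fusion_radius_um` (3D)
merge; the survivor takes the combined volume
(`d³ = d₁³ + d₂³`).  Each aggregate splits at rate `split_rate_per_s` into
two equal-volume children, the new child offset just past the fusion gate;
a five-frame refractory window prevents immediate re-fusion of a fresh pair.
Every event is logged with frame and participant track ids.

## Presets

Three named movement regimes ship with the package.  Their parameter values
are this package's own calibration — chosen once so that the pipeline
reproduces the qualitative ordering seen in live imaging (wild type >
movement-impaired mutant > diffusion-only mutant in both arc coverage and
high-speed fraction) — and are not measured constants:

| preset      | aggregates | diameter (µm) | run speed | pause fraction | D (µm²/s) | fusion radius |
|-------------|-----------:|--------------:|----------:|---------------:|----------:|--------------:|
| `wt-like`   | 2–4        | 1.2–1.8       | 190 nm/s  | 0.35           | 2×10⁻⁴    | 0.45 µm       |
| `spd3-like` | 6–10       | 0.5–0.9       | 190 nm/s  | 0.80           | 2×10⁻⁴    | 0.20 µm       |
| `jf18-like` | 6–10       | 0.5–0.9       | —         | 1.0            | 5×10⁻⁵    | —             |

Notes on the calibration.  The mutant-like preset keeps the full motor
speed but spends only ~20% of intervals in runs, which puts its share of
moving intervals in the few-tens-of-percent range; the diffusion-only preset
has no runs and slower diffusion.  The diffusion-only optical scene (many
small foci) deliberately matches the mutant-like one: mean arc coverage is a
cumulative per-track statistic, so if one genotype's spots were easier to
track (longer tracks), the comparison would measure detectability rather
than motion.  Preset photon budgets (48 000 photons/frame for a 1 µm
reference aggregate, scaled by volume) keep localization noise well below
the per-step displacement of even the slow regimes.

## Rendering

Each aggregate is rendered per frame as a separable 3D Gaussian whose
lateral sigma is the object sigma (FWHM-equivalent diameter / 2.355)
convolved with the PSF sigma (default 0.2 µm lateral, 2.5× axially), at
total photons `photon_budget · (d/1 µm)³ · 2^(−t/bleach_halflife)` —
patches are brighter than foci in proportion to volume, and everything
bleaches exponentially (default half-life 900 s).  The expected image sits
on a uniform background (default 10 photons/voxel) and is corrupted by
Poisson shot noise plus Gaussian read noise (default σ = 2 counts), clipped
at zero.  `photon_budget_for_snr` inverts the closed-form center-voxel
amplitude to pin the initial peak SNR of a chosen diameter.

Acquisition geometry defaults reproduce the live-imaging setup the analyses
assume: 181 frames at 5 s, 1 µm z-spacing, 0.107 µm/px.  Each nucleus gets
its own square field just covering the projected sphere plus a margin
(64 px at the defaults); multi-nucleus configurations tile fields on a grid.
Per-nucleus fields rather than full-camera frames are the package's standard
problem size for simulation studies; nothing in the pipeline depends on the
field size.

Randomness: one root `SeedSequence` per movie, spawned into one child
stream per nucleus plus one for camera noise, so nuclei are independent,
reproducible, and parallel-safe.  Fixed seed ⇒ bit-identical movie and
ground truth.

## Movie pipeline

**Projection.**  Per-frame maximum-intensity projection over z; idempotent
on 2D input (identity with a warning).

**Background.**  A large-Gaussian background estimate (default σ = 2 µm,
roughly 10× the spot sigma of small foci) is subtracted and the result
clipped at zero.  Spot leakage into the estimate scales as
`(σ_spot/σ_bg)²`, a few percent at the defaults.

**Registration.**  Upsampled phase cross-correlation of every projected
frame against frame 0 (fixed reference, avoiding drift accumulation over
15 min movies), followed by resampling with the inverse shift; integer
shifts are applied by `roll` so they are exact.  Subpixel alignment is the
default and switchable via `upsample_factor=1`.

**Detection.**  Multiscale Laplacian-of-Gaussian over the expected diameter
range (scales padded by the PSF), thresholded at `threshold_snr/2` noise
sigmas in the scale-normalized response — a matched, scale-normalized LoG
responds with half the amplitude of a Gaussian blob, so this accepts blobs
at peak SNR ≥ `threshold_snr` (default 3, a standard blob-detection floor).
The frame's noise sigma is estimated from a quantile placed inside the
surviving noise mass after measuring the zero-clip fraction (background
subtraction clips a frame-dependent share of blank pixels to zero; a fixed
percentile is wrong whenever bright objects cover more than its complement
or clipping passes one half).  Candidates are refined by intensity-weighted
centroid and pruned by non-maximum suppression at two blob sigmas: shot
noise on the shoulders of bright aggregates otherwise sheds satellite
detections, because the global threshold only reflects background noise.

**Diameters.**  FWHM-equivalent: the equivalent-circle diameter of the
connected region above half the background-subtracted peak, which for a
Gaussian equals its FWHM and is invariant to intensity scaling.  Regions
touching the frame border are flagged but still sized.  Diameters are
measured on projections; fixed-image 3D sizing is out of scope, so the
focus/patch threshold applies to projected FWHM.

**Classification.**  `focus` below 1.1 µm diameter, `patch` at or above it.
The boundary itself goes to `patch` (half-open convention, documented here
once).

**Detection evaluation.**  Recall/precision against ground truth collapse
same-frame true positions closer than the blur FWHM into one expected
target (projection overlap leaves a single physical blob; counting it as
two misses would measure the optics, not the detector), match targets to
detections by optimal assignment with a 2 px gate widened by the cluster
extent, and count a detection as true when it lies within the gate of a raw
or merged target.

## Track linking

Per frame, open tracks and new detections are matched by an optimal
assignment minimizing total squared displacement, gated at `max_disp_um`
per frame of elapsed gap (default 1.5 µm per 5 s ≈ 300 nm/s, comfortably
above the 190 nm/s motor speed so the fast tail is not truncated), with a
fixed no-link alternative just above the squared gate so admissible links
are always preferred.  Unmatched detections start tracks; tracks unmatched
longer than `max_gap_frames` (default 2, covering transient dropouts) close.
Detections are sorted by (y, x) within each frame, making the result
invariant to input order; equal-cost assignments are resolved
deterministically by the solver.  The identical objective is brute-forced on
tiny instances as the correctness oracle.  The minimum-track-length filter
used by the summaries (default 10 frames) is a free parameter.

**Fusion/split annotation.**  A track that ends while another spans the
ending frame within `merge_dist_um` records a fusion; a track appearing
next to a pre-existing one records a split.  The partner distance is the
minimum over the partner's detections within ±2 frames of the event: at the
merge frame the single surviving detection may be linked to either
participant (leaving the other a gap exactly there), and during fast
approaches the last co-detection lies well apart while the merged centroid
is close.  The meaningful merge distance is the *optical* merging scale —
two spots blur into one blob near their joint FWHM, which is when the
tracker necessarily drops one of them — not the physical contact distance;
the default is 0.9 µm and analyses should scale it to their spot sizes.

## Kinematics

* **Projected speed**: Euclidean 2D displacement per linked interval over
  elapsed time, nm/s.  Gap-spanning intervals are excluded from threshold
  fractions by default (configurable: included with time-normalized
  displacement).  Headline fractions use strictly-above at 40 nm/s and
  at-or-above at 160 nm/s.  Fractions are over per-interval speeds by
  default; a per-track-mean option exists.
* **Arc coverage**: total projected path length over the track's whole
  lifetime, expressed as `path/(2πR)·360` degrees — the angle the distance
  would subtend if traveled along the nucleus circumference, monotone in
  distance traveled, additive under concatenation, and invariant to rigid
  rotation about the nucleus centre.  The nucleus circle comes from ground
  truth for synthetic data and from a supplied ROI for real movies;
  automatic nucleus fitting is out of scope.
* **Track overlap**: each track rasterizes the 1 px-wide polyline through
  its detections; the overlap fraction is pixels visited by ≥ 2 tracks over
  pixels visited by ≥ 1.

Geometry places a ceiling on speed recovery: for isotropic motion on a
sphere the projected instantaneous speed is the 3D speed times
`sqrt(1−u²)` with `u` uniform on (−1, 1), so even a perfect pipeline
recovers a median of `(√3/2)·v ≈ 0.87 v`; chord quantization of 5 s steps
and detection noise take a little more.  A run confined to the equatorial
plane projects losslessly and recovers the median to within a few percent.

## Cytology statistics

* **Zones**: equal-length bins of normalized gonad position, position 1.0
  in the last zone.  Two named five-zone schemes are registered
  (`pairing-5` for the pairing survey's zones 2–6; `rad51-5` for the
  equal-length recombination-marker scheme); positions are supplied
  normalized because absolute gonad landmarks are not computable from score
  tables.
* **Pairing**: one FISH focus per nucleus, or two foci with 3D separation
  ≤ 0.75 µm (inclusive; the threshold is configurable and documented here
  because it is a scoring convention, not a published number), scores
  *paired*; more than two signals flags the nucleus for exclusion.
  Genotypes are compared per zone by a two-tailed Fisher's exact test
  (scipy); p-values are reported raw, with no multiple-testing correction,
  matching how per-zone tests are conventionally reported.
* **Diakinesis accounting**: with 2n = 12, `bodies = bivalents + univalents`
  and `2·bivalents + univalents = 12` give `bivalents = 12 − bodies`; the
  map is linear, so it applies to group means directly.  The generator draws
  bivalents per oocyte as Binomial(6, chiasma probability).  Group
  comparisons use a two-tailed Mann-Whitney test: exact enumeration of all
  rank arrangements (ties shared via midranks; two-sided p = twice the
  smaller one-sided tail, capped at 1 — the standard permutation
  convention, which stays well defined when ties make the null distribution
  asymmetric) when both samples have ≤ 8 observations, and the
  tie-corrected normal approximation otherwise.  Body counts are
  small-integer-valued with heavy ties, which is exactly the regime where
  scipy's exact method is unavailable.
* **Count histograms**: per-zone percent-of-nuclei in configurable count
  bins (default {0, 1–2, 3–5, 6–10, > 10}); a boolean `*_stretch` column
  (elongated recombination-marker structures) is tallied as its own bin.
  Fractions sum to one in every non-empty zone.
* **HIM-8/SC association**: a signal associates with an SC stretch when
  within `assoc_dist_um` of its polyline (segment distance).  Classes:
  `single-SC-paired`, `both-on-different-SC`, `both-on-same-SC`,
  `one-on-SC`, `none-on-SC`.  The fifth class covers the geometry (two
  separated signals nearest the same stretch) that a four-way scheme leaves
  unmapped.
* **Respiration**: per-well rate = mean of the seven oxygen-consumption
  readings divided by the counted worms in that well; genotypes are
  compared by a two-sided two-sample t-test over well replicates
  (equal-variance Student form, matching the simple two-group design), with
  the SEM across wells reported per genotype.

## What the generator does and does not emulate

It emulates: the acquisition geometry; few-large vs many-small aggregate
scenes; run/diffusion mixtures at motor speed; volume-conserving fusion and
splitting; volume-proportional brightness; bleaching; shot and read noise;
projection loss from the 3D sphere.

It does not emulate: nucleus translation or rotation (whole-cell movement
is instead handled by the registration stage, tested on constructed
shifts), non-uniform backgrounds and autofluorescence, aberrated or
spatially varying PSFs, aggregate shape anisotropy, z-dependent attenuation,
or multiple nuclei sharing a crowded field.  Passing tests therefore show
that the measurement chain is correct under idealized-but-noisy imaging of
the assumed motion process; they do not certify performance on real movies
with structured backgrounds or deformable nuclei.

## Known limitations

* **Identity through merges.**  Nearest-neighbour linking cannot preserve
  aggregate identity through optical merges: when two spots blur into one
  blob for more than the gap window, one track ends, and identity at
  re-separation is a coin flip.  Track-level identity metrics are therefore
  only meaningful for scenes with rare encounters (the diffusion-only
  preset); for motile scenes the per-interval statistics (speeds,
  fractions) and pooled arcs remain valid, but per-aggregate lifetime
  statistics fragment.  Motion-model-assisted (Kalman) tracking, which
  could disambiguate some merges, is deliberately out of scope.
* **Fusion counting is resolution-limited.**  Fusion events between
  aggregates whose approach happens below the blur scale are invisible in
  projection; blind fusion counts are only comparable to ground truth when
  the simulated fusion gate sits at or above the optical merging scale.
* **Arc inflation for slow motion.**  Localization noise adds a positive
  bias to cumulative path length; arcs of near-static aggregates measure
  noise plus motion.  Comparisons across conditions are made with matched
  optical scenes so the bias cancels in the ordering.
* **Sphere-projection bias.**  Projected speeds are biased low by the
  `sqrt(1−u²)` factor; threshold fractions are therefore conservative for
  isotropically oriented runs.

## Problem sizes

Default study sizes, chosen as the package's standard desk-scale
configuration: single-nucleus 64 px fields at the full 181-frame geometry;
ten nuclei for detector/speed recovery; ten seeded replicates of two nuclei
per condition for the genotype-ordering comparison; 100-seed sweeps for the
statistical-magnitude properties; 200 nuclei per zone and the published
group sizes (52/31/51/30/52 oocytes) for the cytology tables.
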
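# Methods

`paintbench` implements a generative model of DNA-PAINT blinking data and the
estimators used to benchmark fluorescent dyes on DNA-origami and cellular
reference samples. This note documents the model, the estimators, the
numerical choices, and what the synthetic data can and cannot establish.

## Generative model

A docking site alternates between an unbound (dark) and an imager-bound
(bright) state. Dwell times are exponential: bright with mean τ_b, dark with
mean τ_d. The process starts unbound at t = 0 with a fresh dark draw.
Optional extensions:

- **Destruction**: each site is destroyed with probability
  `destroy_fraction`, at a time drawn uniformly over the measurement (or at
  t = 0 with `destroy_at_start`, used to emulate structures that never
  assembled or were lost before acquisition). No events occur after the
  destruction time.
- **On-rate decay**: the instantaneous binding rate is
  (1/τ_d)·exp(−k·t), emulating progressive photodamage of concatenated
  docking sequences that reduces the effective imager on-rate without
  destroying the site outright. Waiting times are sampled exactly by
  inverting the inhomogeneous-exponential survival function.

**Camera discretization.** Binding events rarely align with frame
boundaries. Each frame overlapped by an event collects a fraction
overlap/exposure of the full photon budget; photon counts are Poisson with
mean `photon_rate · (exposure/0.1 s) · fraction` (`photon_rate` is
referenced to a fully bound 100 ms, the convention dye photon outputs are
reported in). Frames below `min_photons` (default 100) produce no
localization — a stand-in for the spot-detection threshold, below which a
spot is indistinguishable from background at realistic background levels.
Two events whose dark gap leaves no empty frame are recorded as one
localization run, exactly as on a real camera.

**Localization noise.** Each localization is the site position plus
isotropic Gaussian jitter with σ from the Mortensen closed form (below) at
that frame's photon count and the configured per-pixel background. The
fitted background and PSF width columns are populated with their generative
values. Off-target "sticking" is modeled as single-frame localizations,
uniform in space and time, with a uniform sub-frame dwell fraction.

Defaults (all overridable): exposure 0.1 s, pixel 130 nm, PSF σ 0.85 px,
10,000 frames, τ_d = 5 s (roughly 1 nM imager at typical hybridization
on-rates). Kinetic and photometric defaults correspond to a well-behaved
green-absorbing dye (τ_b = 0.35 s, 23,195 photons per 100 ms).

**What the simulator omits**: camera gain/offset/read noise, dye
photophysics within a bound period (triplet blinking, partial bleaching),
3D/astigmatic PSFs, drift, and spatially varying illumination. Passing
parameter-recovery tests on this model therefore validates the estimator
logic and its camera-discretization handling — not robustness to those
real-data effects.

## Estimators

### Event linking and dwell-time fits

Localizations assigned to a site (nearest site within 0.75 px) are linked
into binding events: maximal runs of consecutive frames (`max_dark_frames`
defaults to 0). Bright durations are event lengths × exposure; dark
durations are the empty gaps between consecutive events (the lead-in before
the first event is discarded).

Per site, a single exponential CDF `F(t) = 1 − A·exp(−t/τ)` is fitted by
unweighted least squares to the empirical CDF evaluated at the sorted
durations. Three numerical choices matter:

1. **Free amplitude A.** On frame-quantized data the observed durations are
   whole frame counts k·e. For an exponential dwell the classes k ≥ 2 fall
   exactly on a single exponential with the true τ but amplitude
   c = (τ/e)(exp(e/τ) − 1) ≠ 1; a fixed-amplitude fit is biased by roughly
   +e (one frame time). On continuous data A fits to ≈ 1.
2. **The one-frame class is excluded** from the fitted abscissae (the ECDF
   itself uses all durations): it cannot lie on the exponential curve and
   would otherwise pull τ up by several percent.
3. **The top 5% of abscissae are excluded** as a robustness guard against
   rare camera-merged double events contaminating the tail; a trimmed CDF
   fit on a true exponential remains exact.

**Camera-merge correction.** A dark gap shorter than about two frames
leaves no empty frame, so the camera concatenates two binding events; the
observed bright time is inflated by a factor ≈ 1/(1 − p) plus the mean
invisible gap, where

    p = 1 − exp(−2e/τ_d) · (τ_d/e) · (exp(e/τ_d) − 1)

is the merge probability (e = exposure) and the mean invisible gap is 7e/9.
Each site's fitted bright time is corrected using its own fitted dark time:
τ_b = τ̂_b·(1 − p) − p·7e/9. At the defaults (τ_d = 5 s, e = 0.1 s),
p ≈ 3% and the correction moves a 0.35 s bright time from ≈ 0.363 back to
≈ 0.349. The measurement value is the unweighted mean of per-site fits;
sites with fewer than `min_events` (10) durations are excluded and logged.

### Center-frame photometry and SBR

The first and last frames of an event under-collect photons (the imager
binds or unbinds mid-frame), so the photon output is estimated from *center
frames* only: non-terminal frames of events at least three frames long,
scaled to 100 ms. The signal-to-background ratio per localization is the
fitted PSF (total mass N) integrated over a 1×1 px square centered at its
maximum — `N·erf(1/(2√2·sx))·erf(1/(2√2·sy))` — divided by the per-pixel
background offset; the measurement SBR averages center-frame localizations
with positive background.

### Stability

Localization counts per site per 20 s window, averaged over sites. The
localization drop is 100·(1 − last/first window), clamped to [0, 100] for
reporting with the raw value retained. The window length and the
first-versus-last definition are configuration choices; at least two full
windows are required.

### Docking-site destruction

Per site, r = t_end/τ_d, where t_end is the time from the end of the last
recorded event to the end of the measurement and τ_d is that site's fitted
mean dark time. Without destruction, r samples an exponential with mean 1
(the residual dark time at an arbitrary cutoff). The histogram of r (bin
width 0.25 over [0, max(10, max r)]) is fitted with a·exp(−r/μ) by least
squares over non-empty bins, **excluding the first bin**: sites still being
sampled at the cutoff (an imager bound at, or binding just before, the end
of the measurement — a duty-cycle-fraction of all sites) form a point mass
at r ≈ 0 that sits on top of the exponential and otherwise drags μ down by
~25%. The destroyed-site percentage is the share of sites with
r > 4μ minus the 1/e⁴ = 1.83% an exponential itself places there, floored
at zero.

Recovery of a 17% destroyed fraction is accurate to about −1.5 points under
the defaults: sites destroyed very early never accumulate the 10 events the
dwell fit needs (and are excluded), and sites destroyed within ≈ 4μ·τ_d of
the end are below the tail threshold. Both shrink with longer measurements.

### Localization precision

**Mortensen (per localization)**, for least-squares Gaussian fitting with
s_a² = s² + a²/12 (a = pixel size, b = background photons per pixel):

    σ² = (s_a²/N) · (16/9 + 8π·s_a²·b/(N·a²))

**NeNA (per measurement)**: for every localization, the distance to its
nearest neighbor in the following frame, capped at 1 px. Same-emitter pairs
follow the 2D distribution of the difference of two Gaussians of width σ
(Rayleigh-type with scale √2·σ); false pairs are absorbed by a linear term
2d/W² normalized over the window, weighted 1−A. The binned density is
fitted for (σ, A). The default bin width is 0.02 px; passing
`bin_width=None` adapts it to the observed distance scale (median/25),
which is required to resolve precisions around 2 nm = 0.015 px. The false-
pair term is isolated so an alternative correction model can be swapped in.

### Sites, structures, specificity

The density clusterer is DBSCAN-style: a localization with at least
`min_locs` (15) neighbors within `radius` (0.04 px) — itself included — is
a core point; clusters are connected components of core points plus their
in-radius neighbors. Determinism and order independence come from a
canonical (x, y) sort; a border point reachable from several clusters joins
the lowest cluster id. Crosshair origami are accepted only when a pick
contains exactly five clusters; the designated docking site is the cluster
nearest the pick center plus a configurable offset (center by default).

Relative specificity: signal density over background density, computed on
identical regions for the imaging and the reference round; the ratio of the
two cancels imager concentration and shared sample effects. Circular-pick
membership is strict (< radius, ties outside); overlapping picks assign to
the nearest center with a warning. Mask regions use the pixel under each
localization, with areas from pixel counts.

### Registration and cross-talk

Channel alignment is a least-squares 2×3 affine (dst = A·[x y 1]ᵀ) on at
least three non-collinear matched bead positions; bead matching across
channels is nearest-neighbor with a 1 px gate. Cross-talk divides the
localizations an incorrect channel records within a radius of the known
sites by the correct channel's count.

### Spot detection and fitting

Detection scores each pixel by the *net gradient*: over a box (7 px
default), the sum of the dot products of the local intensity gradient with
the unit vector toward the box center; candidates are local maxima above a
user threshold (thresholds are data-dependent and left as inputs), with
non-maximum suppression within one box. Fitting is least squares of a
pixel-integrated 2D Gaussian (error-function differences, not point
samples) plus a constant offset; photons are the integrated mass,
background the offset. Initialization: brightest pixel, PSF prior for σ,
box sum minus median·area for the mass. Non-converged fits are flagged and
dropped.

## Problem sizes

Validation experiments use 600-site fields at 5,000–10,000 frames
(500–1,000 s), which put per-site fits at roughly 95 events and
measurement-level estimates well inside the published uncertainties; the
destruction calibration uses 800 sites. These sizes were chosen so each
experiment completes in seconds while leaving Monte-Carlo noise comfortably
below the tolerances being tested.

## Known limitations

- The merge correction assumes exponential dark times and first-order merge
  probability; at duty cycles approaching 1 or τ_d within a few frame
  times it under-corrects.
- The NeNA false-pair term is linear in distance — adequate for sparse
  fields; dense fields with structured neighbor distances (e.g. 20-nm
  grids, where the nearest grid neighbor sits at 0.15 px) bias σ upward
  unless the window is narrowed.
- The destruction statistic requires per-site dark-time fits; sparse sites
  (few events) are excluded, which slightly undercounts early-destroyed
  sites.
- `localize_movie` is a straightforward per-frame loop intended for
  validation-scale movies, not high-throughput processing.
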
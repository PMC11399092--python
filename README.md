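# paintbench

Simulation and quantitative analysis of **DNA-PAINT dye performance**.

DNA-PAINT achieves single-molecule blinking through transient hybridization
of dye-labeled *imager* strands to target-bound *docking* strands. Which dye
is on the imager determines nearly everything that matters in the final
image: photon output and signal-to-background ratio (hence localization
precision), photo-induced damage to the docking strands (hence sampling
stability and outright site destruction), and off-target sticking (hence
specificity). Benchmarking dyes on DNA-origami and cellular reference
samples requires turning raw localization tables into a handful of
comparable numbers — this package implements that analysis as a tested,
reusable pipeline, together with a generative model of DNA-PAINT blinking
so every estimator can be validated by parameter recovery, without any
experimental data.

## The model and the metrics

A docking site alternates between dark and bright states with exponential
dwell times (means τ_d and τ_b). A frame overlapping a binding event
collects photons proportional to the overlap fraction. From localization
tables the pipeline estimates:

- **Binding kinetics** — runs of consecutive-frame localizations are linked
  into binding events; per site, a single-exponential CDF fit
  F(t) = 1 − A·exp(−t/τ) over the observed bright/dark durations yields
  τ_b and τ_d (with corrections for frame quantization and camera-merged
  events; see `docs/methods.md`).
- **Photons per 100 ms** — mean over *center frames* (non-terminal frames
  of ≥3-frame events), the only frames guaranteed to record a continuously
  bound imager.
- **SBR** — the fitted PSF integrated over one pixel at its maximum,
  N·erf(1/(2√2·s_x))·erf(1/(2√2·s_y)), divided by the per-pixel background.
- **Localization precision** — per localization via the Mortensen closed
  form σ² = (s_a²/N)(16/9 + 8π·s_a²·b/(N·a²)), s_a² = s² + a²/12; per
  measurement via NeNA (nearest-neighbor distances between adjacent
  frames).
- **Stability** — localizations per site per 20 s window and the
  first-to-last-window drop.
- **Destroyed docking sites** — per site r = t_end/τ_d (time from the last
  recorded event to the end of the measurement over the site's mean dark
  time); an exponential fit a·exp(−r/μ) to the r histogram calibrates the
  threshold, and the share of sites with r > 4μ, minus the 1/e⁴ = 1.83% an
  exponential places there, estimates the destroyed percentage.
- **Sites and structures** — a density clusterer (≥15 localizations within
  0.04 px) finds docking sites; crosshair origami are accepted only with
  exactly five clusters.
- **Specificity and registration** — signal/background density ratios over
  identical regions, referenced to an alignment round; affine channel
  registration from matched beads and cross-talk quantification.

## Worked example

Simulate a measurement of a bright green dye (τ_b = 0.35 s, 23,195 photons
per 100 ms, background 237 photons/px/frame) on 600 isolated docking sites
for 500 s, then run the full analysis:

```python
from paintbench.sim import SimConfig, SiteLayout
from paintbench.model import DyePerformanceModel

layout = SiteLayout.single_sites(600, fov=(140, 140))
config = SimConfig(tau_b=0.35, tau_d=5.0, photon_rate=23195.0, bg_rate=237.0,
                   n_frames=5000, width=140, height=140, layout=layout, seed=1)
results = DyePerformanceModel.from_simulation(config, nena_bin_width=None).fit()
print(results.summary())
```

```
DNA-PAINT dye performance
==============================================
Sites (used/total)               600/600
Localizations                    251445
Precision sigma_NeNA (nm)        1.19
Photons per 100 ms               23,015  (n=149252)
Mean bright time (s)             0.345 +/- 0.045 (site sd)
Mean dark time (s)               4.950 +/- 0.669 (site sd)
SBR                              19.11  (n=149252)
Localization drop (%)            1.7
Destroyed docking sites (%)      0.84
r-histogram fitted mu            1.050 (n=600 sites)
```

The estimators recover the generative inputs: bright time 0.345 s vs 0.35 s,
photon rate 23,015 vs 23,195, dark time 4.95 s vs 5 s. The NeNA precision
(1.19 nm) sits close to the photon-weighted Mortensen prediction; with no
simulated destruction or on-rate decay, the drop is ≈ 0, the destruction
calibration μ is ≈ 1, and the destroyed-site estimate is ≈ 0.
`results.to_frame()` returns the same six benchmark metrics as a one-row
DataFrame, and `paintbench.report.summarize([...])` aggregates repeats into
a mean ± sd summary row.

A command-line interface mirrors the library:

```bash
paintbench simulate --out run --n-sites 100 --n-frames 5000 --seed 1
paintbench analyze run.hdf5 --sites run_truth.json --out summary.json
```

## Layout

- `src/paintbench/sim.py` — generative model (event streams, frame
  discretization, localization emission, movie rendering)
- `src/paintbench/locio.py` — localization tables (HDF5/CSV + YAML
  sidecar, Picasso-compatible column names), picks, masks, region
  assignment
- `src/paintbench/kinetics.py` — event linking, dwell-time CDF fits,
  center-frame photometry, SBR, stability, destruction statistic
- `src/paintbench/precision.py` — Mortensen and NeNA precision
- `src/paintbench/sites.py` — density clustering, crosshair
  identification, relative specificity
- `src/paintbench/register.py` — affine channel registration, cross-talk
- `src/paintbench/spotfit.py` — net-gradient spot detection and
  pixel-integrated Gaussian fitting
- `src/paintbench/model.py`, `report.py` — `DyePerformanceModel` /
  `DyePerformanceResults`, rendering and summary rows
- `docs/methods.md` — model assumptions, estimator details, numerical
  choices, limitations
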
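# Methods

This note documents the models, defaults, and numerical choices behind
`nirspot`, and what the synthetic benchmark does and does not establish.

## Sensor transduction model

The nanosensor response is a one-site Langmuir (rectangular hyperbola),
ΔF/F₀(c) = ΔF_max·c/(c + K_d). A single dissociation constant with no
cooperativity is the reported behaviour of (GT)₆-SWCNT catecholamine
sensors; a Hill exponent is exposed (`SensorParams.hill`) but defaults to 1
and is intended for sensitivity analyses only. Defaults: K_d = 15 μM;
ΔF_max = 6.44, *derived* — not printed anywhere — by inverting the isotherm
through the published working point (ΔF/F₀ = 5.60 at 100 μM):
ΔF_max = 5.6·(100+15)/100. Note the 560 % figure is quoted at 1200 nm while
the solution-phase calibration reads the (9,4) peak at 1130 nm; the two are
not reconciled in the source data, so the spectral window is a parameter
(default 1100–1160 nm) of `peak_response`.

Fitting (`fit_isotherm`) is Levenberg–Marquardt least squares with positive
bounds, unweighted unless per-point replicate SDs are supplied (then
inverse-variance weighted). Initialisation: ΔF_max⁰ = max response, K_d⁰ =
the concentration whose response is nearest half of ΔF_max⁰. Degenerate
inputs (fewer than three distinct positive concentrations, non-positive
responses, a K_d driven an order of magnitude beyond the sampled range —
i.e. half-saturation not bracketed) return a failure report with a message
instead of raising.

## Baseline and ΔF/F₀

F₀ is computed per pixel by `n_rounds` (default 3) of: moving-average
smoothing (default 31 frames ≈ 6 s at 5 fps, longer than the 5-s stimulus;
nearest-sample edge padding so constants are fixed points), then clipping
samples that exceed the smoothed estimate. Two deliberate departures from
the plain smooth-and-clip recipe, both forced by its measurable biases:

- **Clip margin.** Clipping *at* the smoothed estimate shaves the upper half
  of symmetric photon noise and biases F₀ low by ≈ 0.4 σ (≈ +1.3 % on
  ΔF/F₀ at 1000-count baselines). Samples are therefore clipped only above
  `smoothed + 2 × MAD-σ` of the residual. The margin is exactly zero on
  noiseless data, so it never affects clean fixtures.
- **Median reduction.** The iterated clip flattens a transient into a low,
  wide plateau whose *mean* still carries residual mass (several percent of
  a large transient even after many rounds). The final F₀ is the temporal
  *median* of the clipped trace: exact whenever the transient occupies less
  than half the movie, and unbiased under symmetric noise.

Pixels with F₀ below 1 % of the median positive F₀ are masked invalid
(NaN, plus a boolean mask) — a relative floor rather than a percentile cut,
because a percentile cut would always mask 1 % of a uniformly lit field.
The sensor is non-photobleaching, so no bleach correction is applied; motion
and flat-field correction are out of scope.

## Hotspot detection

Stages (all deterministic; ties broken by descending score then (row, col)):

1. **Score.** Per pixel, ΔF/F₀ is smoothed with a 3-frame moving average,
   differenced (× frame rate), and the maximum derivative taken within the
   evaluation window (stimulus onset → last stimulus end + 2 s pad — the
   pad absorbs release/diffusion lag). The score map is box-smoothed 3×3
   spatially to merge noise-split maxima on one release site.
2. **Seeds.** 8-neighbour local maxima above `median + snr_min × MAD-σ` of
   the same statistic computed over a *length-matched* pre-stimulus window
   (matching the window length keeps the max-statistics comparable), and
   above an absolute amplitude floor (`min_peak_dff`, default 0.05) — the
   automated counterpart of excluding "low amplitude" noise signals, and
   necessary because an SNR cut alone admits a few percent of background
   pixels on a max-over-window (Gumbel-tailed) statistic. Greedy minimum
   separation: 8 px.
3. **ROIs.** 8-connected region ≥ `roi_growth_fraction` (default 0.5, i.e.
   half-max) × the seed's value, grown on the smoothed ΔF/F₀ *snapshot at
   the seed's peak frame* rather than on each pixel's own windowed maximum:
   the snapshot background is single-frame noise, whereas the max-over-window
   map's inflated background percolates across dense fields and merges all
   regions into one component. An absolute floor (median + snr_min × MAD-σ
   of pre-stimulus smoothed ΔF/F₀) guards faint seeds. Where grown regions
   of different seeds overlap, contested pixels go to the nearest seed
   (marker-based partition) so overlapping release fields are split, not
   double-counted. For a noiseless separable release field all of this
   reduces to the exact half-max region of the spatial profile.
4. **Traces.** Hotspot trace = raw (unsmoothed) ΔF/F₀ averaged over the
   ROI; peak = max within the evaluation window; temporal FWHM at half of
   (peak − pre-stimulus median) with linear interpolation, flagged
   one-sided when a crossing is missing.
5. **Filters.** (a) peak-height variation across stimulation repeats,
   100·(max−min)/min (the most permissive denominator reading), must stay
   below 500 %; applies only when a movie contains several repeats.
   (b) area ≥ 1.64 μm², inclusive, so exactly three 0.74-μm pixels pass.
   (c) noise: trace SNR ≥ 3 versus the pre-stimulus MAD, the trace's global
   maximum must fall inside the evaluation window, and at most half the
   spectral power may sit above 1 Hz. Every rejection is logged with its
   reason; accepted ∪ rejected conserves the candidates.

The ROI construction is a transparent reimplementation of the described
derivative-maxima + FWHM/amplitude procedure, not a port of the released
matrix-factorisation code; seeds are localised on per-pixel traces (the
alternative — the mean-image trace — is coarser and was not chosen).
Against an exhaustive pure-Python reference implementing the same rules,
the vectorised pipeline is exactly equivalent on 16×16 movies (tested).

## Synthetic movies

Each release site contributes an isotropic 2-D Gaussian concentration field
(simplest profile with an analytic half-max area, 2πσ²ln2) that rises
within one frame at onset — sensor binding is nanosecond-scale, hence
instantaneous at 5 fps — and decays as exp(−t/τ). Fields of overlapping
sites add in concentration space; fluorescence is
baseline · (1 + ΔF/F₀(c)) with optional Poisson shot noise and Gaussian
read noise (InGaAs-camera behaviour). Defaults: baseline 1000 counts, read
noise σ = 10 counts — photon-starved NIR-II imaging; chosen once as
realistic conditions, with shot noise the dominant term (σ/F ≈ 3 % per
frame). A seed fixes the movie bit-exactly.

Group presets reproduce the reported per-FOV statistics (counts 45.0 ± 12.6
and 55.8 ± 23.1 for control early/late, 17.0 ± 8.8 and 16.3 ± 8.1 for PD;
hotspot peak ΔF/F₀ 0.158/0.513/0.845/0.328; areas 26 ± 21 and 32 ± 21 →
11 ± 13 μm²). Counts are interpreted per field of view (the printed
"per 180 mm²" is dimensionally inconsistent with 0.74-μm pixels on a 640-px
sensor and treated as a typo); the reported control-late area of
170 ± 19 μm² is described as statistically indistinguishable from 26 ± 21
and is replaced by the early-stage value. Amplitudes and areas are sampled
from lognormals with the reported mean and SD (positive by construction,
so the generating means equal the reported values exactly); site centres
are placed with a 12-px minimum separation (random sequential placement
with a farthest-proposal fallback so crowded draws cannot stall); onsets
are uniform over the stimulation window.

Ground truth per site records the **center-pixel peak** ΔF/F₀ (the
closed-form response at the site's amplitude) and the **hotspot-level
peak** — the mean response over the discrete half-max pixel region, which
is what an ROI-averaged trace measures (0.5/ln2 ≈ 0.72 of the center for a
Gaussian). Preset amplitudes are calibrated by root-finding so the
hotspot-level truth hits the sampled target exactly; the published group
means are themselves ROI-level statistics, so this is the faithful
correspondence. Clearance τ defaults — control 2.0 s, PD 7.0 s — are
*conventions*: only their 3.5-fold ratio is empirically constrained.

## Clearance fitting and statistics

`fit_clearance` fits a·exp(−t/τ)+b from the trace peak (≥ 5 frames of tail
required), initialised by log-linear regression on the offset-subtracted
tail; the offset absorbs residual baseline and the reported τ is the
exponential constant alone. `converged` demands optimiser success, τ > 0,
a > 0, and R² ≥ 0.2 after the peak, so flat or white-noise traces fail
honestly instead of returning a spurious τ.

`compare_groups` implements the pooled-variance two-tailed Student's t
(named test of the protocol; Welch behind a flag) and one-way ANOVA with
Tukey HSD via the studentized-range distribution, with star coding at
0.05/0.01/0.005/0.001. Both routes are cross-checked against independent
reference implementations (scipy, statsmodels) to 1e-10 in tests.

## Problem sizes and what the benchmark shows

The synthetic benchmark uses 128 × 128-px FOVs with 150 frames (30 s) and
one 5-s stimulation epoch starting at 10 s — a field roughly 5× smaller in
area than a 640-px sensor, carrying the full per-FOV site count, i.e. a
*denser* and therefore harder detection problem than the real recordings.
At these conditions the detector operates at ≈ 0.93 precision and recall
with per-FOV count and mean-peak essentially unbiased (45.1 detected vs
45.6 planted; 0.161 vs 0.159 across validation seeds).

The generator emulates: stable non-bleaching baselines, stimulus-locked
sparse release with group-specific amplitude/size/count distributions,
Langmuir transduction, exponential clearance, shot + read noise. It does
not emulate: dopamine diffusion (no reaction–diffusion PDE; the Gaussian
spatial profile is static), quantal/vesicular release statistics, optics
(no PSF), focal drift or motion, autofluorescent structure, or correlated
camera artefacts. Passing the benchmark therefore demonstrates the
correctness of the computational pipeline under the stated statistical
structure — not robustness to every real-world artefact; on real data the
exposed parameters (baseline window, thresholds, SNR floors) are the
intended adjustment points.

## Known limitations

- The variation filter needs several stimulation epochs per movie; with the
  default single-epoch protocol it passes vacuously (repeat recordings of
  one FOV are separate movies here).
- Mean detected peak ΔF/F₀ inherits a small (+1–2 %) selection bias from
  amplitude-thresholded detection: the faintest sites are the ones missed.
- Sub-pixel localisation and cross-movie hotspot tracking are out of scope.
- With fewer than ~3 pre-stimulus seconds the noise thresholds cannot be
  estimated and detection requires an explicit window and floors.
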
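# nirspot

Quantification of electrically evoked dopamine (DA) release from NIR-II
nanosensor fluorescence movies.

(GT)₆-ssDNA-wrapped single-walled carbon nanotube nanosensors emit in the
second near-infrared window (900–1400 nm) and turn their fluorescence on
when extracellular dopamine binds their DNA corona. Coated over a culture of
dopaminergic neurons and imaged at 5 frames/s during electrical field
stimulation (20 Hz, 5 s), they report release events as transient, spatially
sparse fluorescence *hotspots*. `nirspot` is the analysis pipeline for such
recordings — aimed at labs comparing release statistics between conditions,
e.g. healthy versus *GBA1*-mutation Parkinson's disease (PD) patient-derived
neurons — together with a synthetic-movie generator that provides ground
truth for every stage.

## The model

**Sensor transduction.** The dose response follows a one-site Langmuir
isotherm

&nbsp;&nbsp;&nbsp;&nbsp;ΔF/F₀(c) = ΔF_max · c / (c + K_d),

with dissociation constant K_d = 15 μM and saturation amplitude
ΔF_max = 6.44 (derived from the printed working point of 560 % enhancement
at 100 μM). `sensor.fit_isotherm` recovers (K_d, ΔF_max) from dose-response
tables; `sensor.peak_response` reads ΔF/F₀ off emission spectra at the
(9,4)-chirality peak near 1130 nm.

**Movie analysis.** Per pixel, the baseline F₀ is estimated by repeated
rounds of moving-average smoothing with asymmetric clipping (transients are
flattened, drift is tracked), then ΔF/F₀ = (F − F₀)/F₀. Hotspots are
detected as local maxima of the stimulus-locked temporal derivative, grown
into 8-connected half-maximum ROIs, and refined with the analysis rules of
the recording convention: peak-height variation across repeated stimulations
< 500 %, area ≥ 1.64 μm² (three 0.74-μm pixels), and automated noise
exclusion (peak SNR, peak presence in the evaluation window, high-frequency
power fraction). Per-FOV summaries bin hotspot areas into small (< 9 μm²),
middle (9–36 μm²) and large (> 36 μm²).

**Kinetics and statistics.** Dopamine clearance after release is fitted as
a · exp(−t/τ) + b; the control-vs-PD ratio of fitted τ (impaired reuptake
slows clearance 3.5-fold) is the headline kinetic readout. Group
comparisons use the two-tailed pooled-variance Student's t-test (Welch
optional) or one-way ANOVA with Tukey's HSD.

## Worked example

```bash
nirspot simulate --preset control_early --out ctrl.tif --seed 1
nirspot analyze ctrl.tif --outdir ctrl_out --group control
```

prints

```
ctrl.tif: 49 sites, seed 1
47 hotspots accepted, 9 rejected
```

The generator planted 49 release sites drawn from the control-early preset
(45.0 ± 12.6 sites per FOV, hotspot peak ΔF/F₀ 0.158 ± 0.084, area
26 ± 21 μm²); the pipeline recovered 47 of them from the noisy movie and
rejected 9 candidate ROIs with logged reasons (size, SNR, high-frequency
noise). `ctrl_out/fov_summary.csv` holds the FOV aggregate:

```
n_hotspots            47
mean_peak_dff   0.166494
mean_area_um2  20.890357
frac_small      0.148936
frac_middle     0.680851
frac_large      0.170213
```

— a mean detected peak ΔF/F₀ of 0.166 against the generating 0.158, i.e.
the relative amount of dopamine released per hotspot, with most hotspots in
the middle size class. Calibration from a (noisy, 5 % CV) dose-response
table:

```bash
nirspot calibrate dose.csv --out fit.json
# Kd = 14.81 uM, dFmax = 6.47
```

recovering the generating K_d = 15 μM within sampling error. A
`nirspot compare` command runs the group test on two or more FOV-summary
tables and writes the t/ANOVA results as JSON.

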
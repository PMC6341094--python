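# Methods

## Stimulation protocols and sampling grid

Two block designs are built in: *short* (6 blocks of 20 s ON / 40 s
OFF, 360 volumes) and *long* (20 s ON / 160 s OFF, 720 volumes), both
at a 2 s effective volume interval (two-segment acquisition at TR
1000 ms), 20 Hz pulse trains with 5 ms pulses.  A 20 s block therefore
spans exactly 10 volumes.  The scans include a 60 s lead-in baseline
before the first block; the source acquisitions show a pre-block
baseline of unstated length, and 60 s guarantees ≥ 30 baseline volumes
for percent-change normalisation.

## Hemodynamic model

The response kernel is a single gamma density, peak-normalised, with
shape 6 and scale 0.6 s (time to peak 3 s, in the range reported for
contrast-agent CBV responses in rodents) and configurable (shape,
scale, onset delay).  Activity regressors are built at a 0.1 s grid as
boxcar ⊗ kernel, averaged into volumes, and peak-normalised so that a
unit regression coefficient equals 1 % signal change; the generator and
the fitter share this construction, so noiseless recovery is exact
unless a kernel mismatch is introduced deliberately.  Temporal
derivatives are first differences of the activity columns; drift terms
are Legendre polynomials (default order 2) explicitly demeaned on the
sampled grid so they are orthogonal to the constant.

## CBV preprocessing

Raw signals follow the intravascular-contrast convention (CBV increase
→ raw signal decrease) with a multiplicative clearance drift.  The
chain is: (1) linear detrend, slope fitted on non-stimulation volumes
(each block plus a 25 s hemodynamic tail — the kernel support — is
excluded) and removed with the pivot at the pre-stimulation baseline
window, so the level the percent change divides by is the baseline
level; (2) percent change to the mean of pre-first-block volumes;
(3) sign inversion for CBV (skipped in BOLD mode).  A subtractive
linear detrend under a *multiplicative* drift leaves a small (≈ 2 % of
the amplitude at 0.5 %/min drift) scale interaction with the response;
this is a property of the stated chain, shared by any linear-drift
treatment of a multiplicative decay, and is negligible at the drift
levels emulated.

## Synthetic-data generator

The cohort generator produces, per ROI, `baseline × (1 + drift·t) ×
(1 − r(t)) + noise`, where `r(t)` applies a per-block amplitude
schedule to the shared regressors, signed + for DRN-like and − for
projection-like ROIs.  Defaults are the study conditions: 0.3 %
per-volume Gaussian noise (AR(1) optional), 0.5 %/min clearance drift,
6-block schedules, three scans per session, conditions control /
restraint (all amplitudes × 0.5) / fluoxetine (post-injection scans
× 1.5 in prefrontal/cingulate, amygdala and striatal ROIs).  The
adaptation preset declines linearly 2.6 % → 1.7 % across blocks with
zero drift, matching its stated generating conditions.

The probe generator inserts biphasic template spikes (Poisson trains
with optional stimulus gain and a 2.5 ms refractory) into Gaussian
noise on 16-site-style multichannel traces, adds a delta-band
oscillation whose amplitude is multiplied by a suppression factor in
stimulation epochs shifted by a 5 s power lag, a small gamma component
and inhomogeneous-Poisson network bursts whose rate is reduced by the
burst suppression factor in the same lagged epochs.  Burst times carry
no refractory dead time: dead-time thinning would prune the denser
baseline epochs harder and bias the epoch rate ratio away from the
nominal suppression factor.

Atlas maps are generated by exact orthogonalised mixing: the centred
COPE map and an orthogonalised Gaussian map are combined at the ratio
that pins the *sample* correlation to ±√(r² target), then affinely
rescaled into expression-like units.  A projection map with target 0 is
always included.  The delta-coupling preset applies the same mixing
between the CBV series and the regressor the coupling stage itself
recomputes from the synthetic LFP (burn-in range excluded), so the
measured mean r equals the target by construction.  The matched-site
presets draw (fractional metric, COPE) pairs from a bivariate normal
whose population correlation is inflated by the first-order
small-sample term (1 − r²)/(2n), centring the sample Pearson r at
n = 15 on the calibrated value.

What the generator does **not** emulate: spatially correlated
physiological noise, motion, k-space/susceptibility artefacts,
biophysical neuron or balloon models, spike-waveform drift, 1/f LFP
background.  Passing tests therefore demonstrate the correctness and
calibration of the analysis chain under the stated statistical
structure, not robustness to every property of real recordings.

## Electrophysiology

Spikes are negative-going crossings of k·σ (default k = 5) with σ the
robust MAD estimate median(|x|)/0.6745 (plain SD inflates with spike
content); after each detection one snippet window (40 samples, 1.6 ms
at 25 kHz) is dead, and the trough is aligned on a 3-sample smoothed
copy to suppress one-sample jitter.  Metrics per event: trough and
peak amplitude, trough-to-peak delay, half-width, peak/trough ratio
(configurable); z-scored per column, constant columns dropped with a
logged warning.  Sorting over-clusters with k-means (k = min(20,
n/50)) and merges the closest centroid pair while distance < 2.5 in
z-space and the merged ISI-violation fraction (ISIs < 2 ms) stays ≤
0.5 % — an exact-zero criterion is untestable under chance coincidence.
Stereotrode events (adjacent channels within ±0.4 ms) are sorted before
residual single-channel events; clusters with strictly more than 50
spikes are flagged included.  Waveform types come from seeded k-means
on cluster-mean metrics; response differences use tie-corrected
Kruskal–Wallis with Dunn's pairwise z tests, Holm-adjusted (the
adjustment is unstated in the source procedure and documented here as
a package choice).

## LFP analysis

The stated acquisition chain is reproduced literally: MUA band-pass
0.3–3 kHz, LFP low-pass 1.9 kHz then every 8th sample (fs 3125 Hz).
The low-pass sits above the post-decimation Nyquist (1562.5 Hz), so
the 1562–1900 Hz remnant aliases; it is far above the analysed bands
(≤ 100 Hz) and irrelevant in practice.  Wavelet spectra use a complex
Morlet with ≈ 6 cycles under the envelope ("cmor4.5-1.0"), 40
log-spaced frequencies 0.5–100 Hz, with a per-scale normalisation such
that a unit-amplitude sinusoid reads amplitude 1 at its own frequency;
under this convention white-noise power is proportional to frequency,
and the flatness sanity check divides by the (frequency-proportional)
bandwidth.  Band edges default to delta 1–4 Hz and gamma 30–90 Hz.
Fractional band changes use power (amplitude² — the amplitude option
exists because the source is ambiguous), excluding the first 5 s of
each stimulation epoch and of each post-stimulation baseline epoch to
accommodate the ~5 s power lag.  Bursts are maximal runs of 100 ms
population-count bins above 3× the median baseline bin count (mean
fallback when the median is zero), merged across gaps < 200 ms.

## Group inference

Session contrasts: drug sessions use mean(scan 2, scan 3) − scan 1;
restraint sessions average all three scans.  The permutation test is
Freedman–Lane: nuisance columns (intercept, sex, scan order where
applicable) are fitted, their residuals permuted and the full model
refitted, vectorised over permutations.  Family-wise correction uses
the max-|t| distribution; cluster-extent correction forms clusters at
uncorrected p < 0.01 (configurable, reported in output) on a synthetic
ROI adjacency graph (group-wise chains, bridged; no claim to true
anatomical adjacency) and compares observed extents with the null
max-extent distribution.  p-values use the (1 + exceedances)/(n + 1)
estimator, so corrected ≥ uncorrected holds everywhere.  ROI-level
screens use Benjamini–Hochberg FDR.  DRN normalisation divides
projection COPEs by the DRN COPE and refuses |t| < 2 DRN responses
(ratio instability); it is invariant to global amplitude rescaling,
which encodes the blunting-without-connectivity-change phenotype as a
testable property.

## Coupling and structure–function

Band-power envelopes are computed at ≈ 10 Hz (zero-phase band-pass,
squared, bin-averaged), convolved with the shared kernel and
average-resampled onto the volume grid; one kernel length (25 s) of
burn-in is excluded from correlations.  Site records carry descriptive
two-sided Pearson p-values without site-level multiplicity correction.
Regional coupling joins strictly on (animal, ROI), warns about
unmatched sites and requires ≥ 3 pairs.  Structure–function
correlations harmonise labels by case-insensitive inner join, require
≥ 3 shared ROIs, and the receptor screen applies BH-FDR across the
screened maps, ranking by r² with label-stable tie order.  ROI-level
correlation is implemented; voxel-level screening would be an
extension.

## Numerical and design choices

- All randomness flows from per-call `numpy` seeded generators spawned
  from a single `SeedSequence`; identical configuration and seed give
  bit-identical outputs, and no global random state is touched.
- The ">50 spikes" inclusion rule is strict, as stated.
- The frame-wise displacement rotation radius is 5 mm (mouse brain);
  FD_t = Σ|Δtranslation| + r·Σ|Δrotation|.
- Volumetric smoothing interprets the stated "0.45 mm²" kernel as a
  0.45 mm FWHM (the area/width ambiguity is unresolvable from the
  text); FWHM below the voxel size passes through with a warning.
- Problem sizes in the validation tooling (e.g. 500 null datasets ×
  500 permutations for the family-wise calibration; 50–100 replicate
  seeds for the calibrated recoveries) were chosen to bound the Monte
  Carlo standard error of each checked quantity well below its
  tolerance.

## Known limitations

- The permutation scheme supports two-sample designs with
  exchangeable residuals; repeated-measures or nested exchangeability
  blocks are not implemented.
- The sorter handles waveform-stationary units; electrode drift and
  template matching are out of scope by design.
- Real-data statistics that depend on live-animal recordings (e.g. the
  reported Kruskal–Wallis values) are not reproduced — only the
  procedures that would compute them.
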
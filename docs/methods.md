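# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations behind `synapcount`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate and unit conventions

Images are 2-D arrays indexed `(row, col)`, 0-based. The physical pixel
pitch defaults to 50 nm/px (a 51.2 µm × 51.2 µm field at 1024 × 1024 px);
12-bit sources span [0, 4095]. Densities are always reported per 100 µm²
of dendritic area — the area of the *dilated* dendrite mask, since that is
the region on which colocalizations are counted.

## Image screening

Acquisitions where signal is indistinguishable from background are dropped
before analysis using an SNR estimate: pixels are split at the Otsu
threshold and `snr = (mean(above) − mean(below)) / std(below)`; images with
`snr < 0.5` fail. The estimator is parameter-free, deterministic and
invariant under positive intensity rescaling. Limitation: on an image that
is pure unstructured noise the Otsu split itself manufactures a
"signal/background" separation, so the screen primarily rejects flat or
near-flat fields; it is a coarse gate, not a quality metric.

## Puncta detection

The fixed chain per puncta channel is: rolling-ball background subtraction
(radius 4 px, protecting structures under 9 px across), 3×3 median filter,
threshold at the 45th percentile of the filtered pixel distribution, local
maxima above that threshold, and stamping of each maximum as a Euclidean
disc of radius 2 px (13 pixels, 5 px / 250 nm across).

Numerical choices:

* **"45% of the intensity distribution"** is the 45th percentile of the
  pixel histogram (rank `floor(0.45·N)` of the sorted pixels), not 45% of
  the maximum. A quantile is the natural counterpart of the mean-intensity
  thresholds it is contrasted with, and is robust to isolated hot pixels.
* **Local maximum** = pixel ≥ all 8 neighbours and > at least one;
  "exceeding the threshold" is strict (`>`). An equal-valued plateau
  contributes exactly one representative, its lowest row-major pixel —
  8-connected maximum candidates are provably equal-valued, so this is
  well defined and deterministic. Out-of-bounds neighbours never veto;
  maxima near the border are kept and their discs clipped, conserving
  counts.
* **Disc shape**: the Euclidean disc of radius 2 (13 px), matching a
  circular 250 nm object, rather than a 5×5 square.
* **Dendrite mask** = pixels above the channel mean, dilated by 2 px
  (configurable; 4 px is a documented protocol variant) to capture puncta
  lying on and immediately beside dendrites.

## Colocalization counting and noise correction

A synapse candidate is an 8-connected component of
`pre_mask AND post_mask AND dendrite_mask`. 8-connectivity is used because
two circular objects touching diagonally represent one merged detection.
The 250 nm centroid criterion is emergent: two radius-2 discs can only
produce AND pixels when their centroids are within 4 px.

Chance coincidences are estimated under complete spatial randomness (CSR)
of puncta over the full image and subtracted. Two independent estimators
are provided:

* **Randomization.** When detection ran on intensity images, the detected
  punctum centroids are redrawn i.i.d. uniform (discs re-stamped), the AND
  recounted, and the mean over `n_reps = 10` replicates (reported with its
  standard error) is the noise estimate. Ten replicates stabilize the mean
  at negligible cost. When the input is already a binary mask (the
  simulator's validation regime), individual discs are not enumerable once
  objects merge. Relocating whole merged objects is measurably biased low
  even on pure-CSR masks — repositioned clumps present less interaction
  cross-section than the underlying disc process — so the punctum count is
  instead recovered from the covered area fraction by the Boolean-model
  inversion `n = −N·ln(1−p)/a` (`a` = 13 px disc area) and that many discs
  are redrawn. On noise-only scenes this null is unbiased (verified by the
  noise-only acceptance test). A shape-preserving object-relocation null
  is retained in the API for comparison.
* **Spatial cross-correlation.** The post mask is translated along rows by
  0..50 px (toroidal wrap, conserving puncta counts at every shift) and
  the AND count profiled. True pairs cannot overlap beyond 4 px of
  relative displacement, so counts at shifts ≥ 10 px (twice the punctum
  diameter) are chance only; their mean is the noise estimate.

Corrected counts may be negative on pure-noise images; they are reported
as-is with a flag and never silently clamped, so that averages over images
remain unbiased.

Limitation (quantified by the validation harness): both nulls assume
spatial uniformity. Real and simulated scenes concentrate true puncta on
dendrites, which (a) enhances the chance-coincidence rate near dendrites
relative to a uniform null and (b) lets chance coincidences merge into
true-pair components, depleting the countable chance rate. These two
scene-level effects are what keeps measured sensitivity near, rather than
exactly at, 100%−noise. On scenes built from full-length straight dendrite
lines, the 1-D shift profile additionally retains a structural excess at
*every* shift (the line network has long-range orientation correlations),
so the cross-correlation asymptote exceeds the randomization estimate
there; the estimator-agreement harness therefore uses scenes in which
pairs and noise are uniform over the field, where both estimators provably
target the same random-overlap expectation.

## The scene simulator

Defaults define the study conditions: 1024 × 1024 px scenes; dendrites as
40 random full-length straight chords rendered 5 px wide (≈ 15–20% pixel
coverage, chosen so the chance-coincidence rates needed for the SNR grid
are reachable); 800 true pre/post pairs; noise puncta uniform over the
image, with overlaps allowed (the null hypothesis being tested is complete
spatial randomness).

* **True pairs.** The pre centroid is uniform over dendrite pixels; the
  post centroid is offset uniformly over the integer offsets of the disc
  of radius 4 px *whose two discs share at least one pixel* (41 of the 49
  offsets; the (±3,±2)/(±2,±3) family, norm ≈ 3.6, yields an empty pixel
  intersection and thus would not constitute a colocalization under the
  mask-overlap criterion at all). Pairs are resampled until their disc
  footprint is not 8-adjacent to any previously placed pair, so every true
  pair is an individually countable ground-truth component and a
  noise-free scene is recovered exactly. Placement fails loudly if the
  dendrite cannot host the requested pairs within the resampling cap.
* **SNR calibration.** SNR = n_true / expected chance colocalizations.
  The expectation is estimated by Monte-Carlo under CSR: stamp
  `n_true + n_noise` discs per channel uniformly, AND with the dilated
  dendrite, count components. The integer `n_noise` solving
  `E[chance] = n_true / SNR` is found by fixed-point iteration on the
  near-quadratic count model (30-replicate evaluations) and the final
  expectation refined with 100 replicates; `realized_snr` is reported from
  that refined value. The expected-count model is monotone in `n_noise`,
  so the iteration is stable; targets below the noise-free chance floor
  return zero noise.
* **Binary rendering** emits the three masks as 0/1 images — the published
  validation regime — and the pipeline takes such channels as masks
  directly (auto-detected, overridable).
* **Grayscale rendering** is an extension used for end-to-end threshold
  sweeps. Per-punctum peak amplitudes are lognormal (median 55 DN,
  σ_log = 1.2 — a broad, strictly positive brightness distribution typical
  of immunostained spots); each channel additionally carries 12 000 dim
  non-target granules (radius 2 px, exponential amplitudes, mean 22 DN)
  modelling spurious staining, which populate the middle of the intensity
  histogram and supply the spatially random background maxima that the
  percentile threshold and the noise correction are designed to handle.
  Optics are a 1 px Gaussian blur; Poisson noise is applied to the
  fluorescent signal, while the offset baseline (100 DN) is rendered flat,
  as in deconvolved images whose background noise has been regularized
  away. These values were fixed once so the synthetic images land in the
  qualitative regime reported for real data: the 45th-percentile threshold
  sits below the mean intensity, background maxima are present but
  correctable, corrected density is flat for thresholds up to ~0.65 and
  falls beyond ~0.75 as dim true puncta are lost. What passing the sweep
  shows is robustness of the *correction*, not realism of every optical
  detail: PSF anisotropy, photobleaching, bleed-through and
  autofluorescence structure correlated with cells are not modelled.

The validation harness (`run_validation`) generates scenes per SNR point,
runs the complete pipeline, and reports per-SNR means of total detections,
noise estimate, corrected count, sensitivity (= corrected / n_true) and the
uncorrected relative error. Problem sizes in the shipped harnesses —
5 scenes per SNR point, 20 scenes for the estimator-agreement and
noise-only checks, 2 scenes for the threshold sweep — were chosen as the
smallest replication at which the Monte-Carlo error is comfortably inside
the tolerances being tested.

## MEA activity analysis

Filtering is zero-phase (forward-backward second-order Butterworth,
300 Hz–1.5 kHz) so spike timing is preserved. Spikes are samples crossing
below −5·SD of the filtered trace; the SD is taken over the whole
recording (a running estimate is a possible refinement, not implemented).
Sub-threshold samples within a 1 ms refractory window collapse to a single
spike at the most negative sample. Detection is exactly invariant under
positive rescaling of the trace.

The leaky integrator is the exact exponential-Euler recursion
`y[t] = y[t−1]·exp(−Δt/τ) + spike[t]` with τ = 50 ms (close to the
membrane time constant of a hippocampal pyramidal cell); it is linear in
the raster, its impulse response reaches 1/e exactly at τ, and periodic
drive at interval τ converges to the geometric-series peak 1/(1−e⁻¹).
Integration runs at the raster's native rate (25 kHz default; the
recursion is a single IIR filter, so decimation is unnecessary).

Bursts are maximal intervals where the integrated activity exceeds
`mean + 4·SD`; the mean offset is used because the integrated signal is
strictly non-negative. While a burst ramps through the threshold the
integrator ripples at the spike scale, so supra-threshold intervals
separated by less than 10 ms — far below physiological inter-burst
intervals (seconds) but far above the ripple — are merged into one event.
Note the threshold is self-referential (the SD includes the bursts), so a
burst must lift the integrator well above the background level scaled by
the burst duty cycle; and in the shot-noise regime (rate·τ ≲ 0.1) a single
spike already exceeds mean + 4·SD, so the detector is meaningful only for
multi-unit rates where the integrated signal is near-Gaussian.

The trace simulator injects a biphasic template (~1.5 ms, unit-normalized
negative peak) at given times over Gaussian noise; burst schedules lay
down dense regular clusters. Recovery of injected activity is exact when
inter-burst gaps exceed a few τ and injected amplitudes clear the
filtered-noise floor by a comfortable margin.

## Batch processing and statistics

Each manifest entry gets a seed derived from the global seed and a CRC of
its `source_id`, so results are independent of processing order and a
rerun reproduces the table byte-for-byte. Per-entry failures are logged
and skipped, never fatal. Group comparisons use the two-sided Wilcoxon
rank-sum test — exact null distribution when both groups have n ≤ 20 and
no ties, normal approximation with tie correction otherwise — with
Bonferroni adjustment `p_adj = min(1, p·n_comparisons)` and significance
at adjusted p < 0.05; group summaries are mean ± SEM.

## Known limitations

* Deconvolution is assumed to have happened upstream; inputs are plain
  grayscale TIFF (vendor formats are out of scope).
* The colocalization count is component-based; very high punctum densities
  undercount through merging, and the randomization null cannot see the
  dendrite-clustering of true puncta (both effects are visible in the
  validation tables as the gap between sensitivity and 100%).
* Sub-pixel localization, spot-shape scoring, 3-D colocalization and
  intensity-correlation colocalization measures are deliberately not
  implemented; the cultures analysed are an essentially 2-D monolayer.
* The MEA module performs no spike sorting; rasters are multi-unit per
  electrode.
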
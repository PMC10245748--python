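# synapcount

Automated, threshold-robust quantification of synapses in multi-channel
confocal images of neuronal cultures, with a ground-truth simulator for
validating the detector and a multi-electrode-array (MEA) spike/burst
analysis chain.

## The problem

Counting synapses in immunofluorescence images means finding places where a
presynaptic punctum (e.g. vGluT1 or vGAT) and a postsynaptic punctum
(e.g. PSD-95 or gephyrin) coincide on a dendrite (MAP2). Both stainings are
imperfectly specific, so some coincidences are pure chance — and the chance
rate depends strongly on the intensity threshold used to call puncta. This
package implements an object-based colocalization pipeline whose output is
corrected for random-chance coincidences, which makes the final synaptic
density largely insensitive to the threshold choice:

1. **Mask building** — per puncta channel: rolling-ball background
   subtraction (radius 4 px; protected zone 9 px = 450 nm at 50 nm/px),
   3×3 median filter, intensity threshold at the 45th percentile of the
   pixel distribution, local-maxima detection, and expansion of each
   maximum into a 5-px-wide (250 nm) circular binary object. The dendrite
   channel is thresholded at its mean intensity and dilated by 2 px.
2. **Counting** — a binary AND of the three masks; synapse candidates are
   the 8-connected components of the AND mask.
3. **Noise correction** — the chance-coincidence rate is estimated under a
   spatial-randomness null by two independent procedures (relocating the
   puncta uniformly and re-counting; and shifting the masks relative to
   each other and reading the count profile's asymptote), and subtracted:

   `corrected = total − noise`, reported per 100 µm² of dendritic area.

The simulator generates 1024×1024 scenes that mirror the experimental
geometry — 5-px-wide dendrite lines, 800 true pre/post pairs with centroid
separation < 250 nm, plus noise puncta calibrated to a target
signal-to-noise ratio (SNR = true pairs / expected chance coincidences) —
with exact ground truth, so sensitivity and noise estimates can be scored
against a gold standard.

The MEA module band-passes extracellular traces (Butterworth, 2nd order,
300 Hz–1.5 kHz, zero-phase), detects spikes as negative deflections beyond
5 SD of the filtered signal, feeds the spike raster to a leaky integrator
(τ = 50 ms), and marks network bursts where the integrated activity exceeds
its mean + 4 SD; rates are summarized as spikes/sec and bursts/min.

## Worked example

Generate a synthetic scene with 800 true synapses at SNR 2 and quantify it:

```console
$ synapcount simulate --n-true 800 --snr 2 --seed 7 --out-dir scene7
scene seed=7: 800 true pairs, 5680/5680 noise puncta, realized SNR 2.00 -> scene7

$ synapcount detect --pre scene7/pre.tif --post scene7/post.tif \
      --dendrite scene7/dendrite.tif --seed 11
source_id,params_digest,total_count,noise_estimate,noise_estimate_crosscorr,corrected_count,dendritic_area_um2,density_per_100um2,negative,seed
pre,02910d5e6d,1100,406.6,,693.4,676.5475000000001,102.49095591957695,False,11
```

Reading the row: the AND mask holds 1100 components, of which the
randomization null attributes 406.6 to chance, leaving a corrected count of
693.4 true synapses (sensitivity 693.4/800 ≈ 87% at this low SNR) on
676.5 µm² of dendrite — a density of 102.5 synapses per 100 µm². The
`params_digest` pins the detection parameters used, and rerunning with the
same seed reproduces the row exactly.

Other subcommands: `batch` (manifest CSV → per-image table), `validate`
(sensitivity-versus-SNR harness), `mea` (trace CSV → spike/burst tables),
`compare` (Wilcoxon rank-sum with Bonferroni correction across groups),
all documented via `synapcount --help`.

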
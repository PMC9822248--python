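# Methods

## The hierarchical bootstrap

The statistic of interest is the control-normalized ratio of two knockout
lines, T = [mean(KO_A)/mean(control_A)] / [mean(KO_B)/mean(control_B)],
with null value 1. Group means are grand means over all sweep values pooled
within the group; a `level="cells"` option averages per-cell means instead
for designs where cells contribute unequal sweep counts and should weigh
equally.

Each bootstrap iteration resamples the four groups independently at three
nested levels. Within a group: batches are drawn with replacement (as many
as the original batch count); within each drawn batch, that batch's cells
are drawn with replacement (that batch's own cell count); within each drawn
cell, its sweeps (that cell's own sweep count). Unbalanced trees therefore
keep their unbalance — a drawn unit always carries its own size. Datasets
flagged `single_sweep` (one measurement per cell, e.g. sucrose-evoked
charge) skip the sweep level. Group identity is never mixed across the
resampling.

From `n_iter` replicates T* (default 100,000) the package reports the 95%
confidence interval by the percentile method with linear interpolation
between order statistics (the rule is recorded in the result), and the
directional null probability P_H0 as the fraction of replicates on the null
side of 1. Ties at exactly 1 count toward the null, following the ≤ / ≥
definition. P_H0 is a probability of the null hypothesis given the data,
not a classical p-value.

Numerical choices:

* One root seed feeds a single sequential PCG64 generator; iterations are
  drawn in fixed-size chunks (4096) so results are bit-reproducible for a
  given `(dataset, n_iter, seed)` regardless of internal batching. There is
  no internal parallelism.
* Balanced trees take a fully vectorized resampling path; unbalanced trees
  a per-iteration path. Both implement the identical sampling scheme.
* Iterations in which a resampled control mean is exactly zero would make
  T* infinite; such iterations are jointly re-drawn (all four groups) and
  the re-draw count is reported. A dataset on which no valid draw can be
  found within 100 rounds per chunk raises an error rather than returning
  infinities.

### What the calibration simulations show

With the default generator conditions (below), null datasets (all group
effects equal) are rejected at P_H0 < 0.05 in roughly 8% of runs — inside
the expected envelope for a hierarchical bootstrap with only three batches
per group, which slightly underestimates batch-level spread and is
therefore mildly anti-conservative. The 95% percentile CI covers the true T
in ≈ 90% of runs under the same conditions.

Power is bounded by the design, not the test: with three batches per group,
batch and cell SDs of 0.3 log units and independent batch draws per group,
the sampling SD of log T is ≈ 0.385, so a true T of 2 (log 2 ≈ 0.693) sits
only ~1.8 SD from the null. Even an oracle z-test knowing the true SD
detects it in ~56% of experiments; the bootstrap's measured power is ~0.61.
Detecting a 2-fold ratio reliably at these variance components requires
more batches, or batch effects shared between a line's control and knockout
(sister cultures), which the generator deliberately does not assume because
the resampling treats the four groups independently.

## Electrophysiology metrics

All evoked metrics share the baseline convention: a configurable artifact
blanking window (default 2 ms) after each stimulus is excluded, and the
baseline is the mean over a short window (default 1 ms) starting at the end
of blanking — i.e. immediately after the stimulus artifact, so that within
trains and paired pulses each response is measured against the residual
decay of the previous one. The peak is the polarity-signed extremum between
the end of blanking and the next stimulus (or 50 ms for a final/single
stimulus). Amplitudes are reported as non-negative magnitudes and are
invariant to constant offsets.

* **20–80% rise time**: first crossings of 20% and 80% of the peak
  amplitude, linearly interpolated between samples.
* **Paired-pulse ratio**: sweeps (typically three to four per cell) are
  averaged sample-wise and the ratio A2/A1 is computed on the mean trace;
  averaging per-sweep ratios first is exposed as `method="per_sweep"`, as
  the two conventions differ on noisy data.
* **Sucrose charge**: baseline mean and SD come from the pre-application
  segment; response onset is the first crossing of 3 baseline SDs sustained
  for 5 ms (an infinitesimal threshold when the baseline is noise-free);
  the charge is the trapezoidal integral of the baseline-subtracted current
  magnitude over the first 10 s from onset, in pC. A trace that never
  leaves baseline has zero charge. The metric is additive over disjoint
  sub-windows and linear in the current.
* **Miniature events**: a biexponential template (rise τ 0.5 ms, decay τ
  4 ms, duration 5 decay constants, unit peak) slides along the
  polarity-rectified trace; at each offset the optimal scale and offset are
  fit by least squares. An event must satisfy two criteria: scale / SE ≥
  `threshold` (default 4, in noise-SD-like units) and a waveform
  correlation between segment and template ≥ `min_correlation` (default
  0.6). The correlation criterion is what makes the search usable without
  manual confirmation: for a 100-sample template it corresponds to a
  ≈ 7.4 SD equivalent, holding the expected number of noise-triggered false
  events per 100-s, 5-kHz trace near 10⁻⁵, while genuine events at
  realistic signal-to-noise have correlations above 0.9. Local maxima of
  the criterion closer than the template duration are merged. Amplitude is
  the fitted scale; rise time is measured on the data; decay time is the
  time from peak to 37% of peak (a τ-equivalent).

## Side-view profile quantification

The PSD mask (drawn manually in practice; generated from ground truth in
the synthetic pipeline) is fit with an ellipse from intensity-weighted
image moments: center = weighted centroid, orientation = major-axis angle
of the second-moment matrix, reported in [0, 180°). A mask whose axis ratio
falls below 1.3 has no meaningful major axis and is rejected.

A 1200-nm-long, 200-nm-wide rectangle is placed perpendicular to and across
the center of the PSD band. Intensities are sampled at pixel-pitch steps by
bilinear interpolation and averaged across the width. The presynaptic
(negative) end of the axis is assigned toward the vesicle-channel centroid.
The PSD channel is smoothed with a centered 5-sample moving average
(shrinking at the edges); the peak of the smoothed signal — ties broken
toward the position nearest 0 — defines the origin, all channels (vesicle,
test protein, smoothed PSD) shift with it, and profiles are reported on
[−400, +200] nm. Peaks that land on the window edge are flagged. Per-profile
peak values are maxima over the reported axis, independent of position, and
are taken from the stored profiles (non-PSD channels unsmoothed). All
analysis runs on raw intensities; no background subtraction.

Extraction uses the full 1200 nm so that alignment shifts of tens of nm
never run out of data inside the reported window; positions a shifted
profile cannot cover are NaN and excluded from the per-position mean.

## Puncta segmentation

Objects are 8-connected components of pixels above median + k × robust SD
(scaled MAD) of the raw image, k = 4 by default, filtered to a minimum area
of 4 px (maximum optional). The affine-equivariant criterion makes the
pixel sets invariant to intensity rescaling. Density is reported per image,
with per-µm² as an auxiliary; intensity and area are per-object means on
raw intensities. All parameters are recorded in the result. The
colocalization filter keeps an object iff its fractional pixel overlap with
the union of the reference objects strictly exceeds the threshold; at the
0% default a single shared pixel suffices, and at 100% full containment is
required.

## Synthetic data: what it emulates, and what it does not

**Nested datasets.** Values are log-normal — positive and right-skewed, as
PSC amplitudes are — built as baseline × group effect × exp(batch effect) ×
exp(cell effect) × sweep noise, with batch and cell effects normal on the
log scale (SDs 0.3 by default) and sweep noise log-normal with mean 1 and
CV 0.3. Defaults: 3 batches × 6 cells × 3–4 sweeps per group; group effects
(1, 0.15, 1, 0.075), i.e. an 85% single-knockout reduction and a further
50% in the double knockout, true T = 2 — matching the effect sizes the
analysis is designed around, with batch/cell counts at the scale of a
typical culture experiment (~18 cells per group over 3 cultures). Batch
draws are independent between a line's control and knockout group,
mirroring the independent per-group resampling of the bootstrap. The
ground-truth record carries the true T and every realized random effect.

Because T is a ratio of means, its expectation exceeds the true ratio by a
first-order Jensen term of order T·ΣCV²; the generator's recovery check is
therefore run on log T, where the per-group bias terms cancel by the
symmetry of the variance structure across groups.

**Traces.** PSC waveforms are unit-peak biexponentials, so an inserted
amplitude is exactly the waveform's peak; stimulus artifacts are biphasic
0.4-ms spikes inside the default blanking window; noise is additive
Gaussian. Sucrose responses are rectangular plateaus whose ground-truth
charge equals the integrated noise-free trace. Default sampling is 5 kHz.

**Images.** The PSD is an anisotropic Gaussian ridge (FWHM 350 × 80 nm),
the vesicle cloud an isotropic Gaussian (σ 150 nm) centered 180 nm
presynaptic, and the test protein a band parallel to the PSD at a signed
trans-synaptic offset (default −45 nm, the midpoint of the −70 to −20 nm
range typical of active-zone proteins); noise is additive Gaussian at a
default pixel size of 11.4 nm. Rendered fields are 256 × 256 px (~2.9 µm),
large enough for the 1200-nm extraction rectangle at any orientation.
Puncta fields place Gaussian spots with a minimum center separation by
rejection sampling (bounded retries).

None of the generators simulate membrane biophysics, vesicle-pool dynamics,
optics (PSF, depletion geometry) or detector statistics; they reproduce
only the statistical structure the analyses assume. Passing tests therefore
demonstrate that the pipeline recovers known structure of the assumed form
— not that the assumed form captures every property of real recordings or
micrographs (e.g. correlated noise, overlapping events, irregular PSD
shapes, uneven background).

## Problem sizes used in validation

The calibration and coverage simulations use 500 generated experiments per
condition at 2,000 bootstrap iterations each; the enumeration cross-check
uses 100,000 iterations against all 256 joint resamples of a 2-batch
design; profile-recovery statistics use 100 rendered synapses; mini
detection uses 100-s traces at 5 kHz. The acceptance script repeats the
calibration at 200 experiments per condition and records every n alongside
the values.

## Known limitations

* The bootstrap is approximate with few batches: mildly anti-conservative
  type-I behavior and CI under-coverage of a few percent are expected and
  quantified above; it does not replace more batches.
* No BCa or studentized intervals; percentile only.
* Mini detection assumes a single stereotyped waveform; strongly
  overlapping events within one template length merge.
* The segmentation is a global robust threshold; dense fields with uneven
  background would need local criteria that are out of scope here.
* Profile alignment shifts by whole pixels (the peak is defined on the
  sampled grid); sub-pixel peak localization is not attempted.
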
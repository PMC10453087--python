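# Methods

This note documents the models, defaults, and design choices behind
`sersnet`: what the synthetic SERS generator simulates, how the three
lightweight 1D networks are built and trained, and how the evaluation
protocol and metrics are defined. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Spectra and preprocessing

A spectrum is an intensity series (arbitrary units) on a uniform wavenumber
grid. The default grid covers the 300–1800 cm⁻¹ acquisition range of a
portable 785 nm Raman spectrometer at 2 cm⁻¹ spacing (751 points); 2 cm⁻¹ is
typical for that instrument class, and the grid is configurable.

* `resample` — linear interpolation onto a target grid, clamping to edge
  values outside the source range; disjoint ranges are an error.
* `normalize` — per-spectrum `minmax` (to [0, 1]), `vector` (unit Euclidean
  norm), or `none`. Constant spectra are rejected as degenerate rather than
  silently mapped.
* `peak_intensity` — the raw (baseline-uncorrected) maximum within
  center ± half-width, default half-width 10 cm⁻¹. Peak intensities are
  reported without baseline correction because the stability statistic is
  defined on the raw signal.
* `rsd` — 100 × sample standard deviation (n−1 denominator, the standard
  convention for small replicate counts) / mean.

Network inputs are min-max normalized by default. The intensity scale of a
SERS acquisition varies replicate-to-replicate (hot-spot lottery), so an
identification model should see the band *pattern*, not the scale; min-max
removes the scale while preserving relative band heights. Vector
normalization is available as an alternative; neither smoothing nor baseline
correction is applied (a deliberately simple front end — the networks see
the background and must learn around it).

## The synthetic-data generator

The generator replaces the instrument dataset with draws from an explicit
generative model of PAH mixture spectra on a plasmonic substrate.

**Bands.** Each analyte contributes Lorentzian bands (unit peak height,
FWHM parameterisation) at its characteristic wavenumbers:

| analyte | bands (cm⁻¹ : relative amplitude) | scale |
|---|---|---|
| BaP | 524 : 0.55, **607 : 1.0**, 1231 : 0.5, 1376 : 0.65 | 1.0 |
| Nap | 505 : 0.55, **1372 : 1.0** | 0.6 |
| Pyr | **587 : 1.0**, 1233 : 0.5, 1399 : 0.7 | 1.0 |

Default FWHM is 10 cm⁻¹ (Raman bands are classically Lorentzian; a ~10 cm⁻¹
linewidth is typical of solid-phase PAH bands on a portable instrument).
Nap's global 0.6× scale encodes its weaker SERS response: its C–C modes are
less polarisable than the C–H bending modes that dominate BaP and Pyr.
Secondary-band amplitudes (0.5–0.7) are free choices within the qualitative
pattern that each analyte has one dominant band; only the strongest-band
identities matter to the downstream statistics.

**Concentration response.** Band amplitude follows a competitive-Langmuir
isotherm, the minimal model for analytes competing for host–guest binding
sites:

    amp_i = c_i / (K + c_i + Σ_j α_j c_j),   j ≠ i

with half-saturation K = 1 µg/mL and competition strengths α = 1 for all
pairs. Signals saturate at high concentration and are suppressed by
co-adsorbing competitors — the competitive-adsorption effect that makes
mixture identification harder than single-analyte detection.

**Background and noise.** On top of the band signal the generator adds a
broad Gaussian fluorescence hump (center 1300 cm⁻¹, FWHM 900 cm⁻¹, amplitude
10% of the spectrum's peak analyte signal) plus a slight linear tilt (2%,
high end at low wavenumber), i.i.d. Gaussian noise with sd 1% of the peak
analyte signal, and a per-spectrum log-normal replicate factor r (median 1,
log-sd 0.08) multiplying the analyte signal. Baseline and noise scale with
the spectrum's own peak signal (r included): on a SERS substrate both the
background and the shot noise ride on the same plasmonic enhancement as the
analyte bands, so their natural scale is the realized signal, not an
absolute unit. A blank (all concentrations zero) is therefore exactly zero.
Spectra are clipped at zero (detector counts are non-negative).

The replicate log-sd 0.08 puts the true peak-intensity RSD at 8.0%
(√(e^σ² − 1)), inside the 7–10% stability envelope expected of a good
substrate; the noise term contributes negligibly at the strongest band. Note
that the *sample* RSD of only 10 replicates scatters around that value with
≈1.9 percentage points of estimator noise — single-series RSD readings
between ~5% and ~12% are ordinary draws, which is why stability checks in
the acceptance script aggregate a median over independent series.

**Dataset design.** The default design is 4 mixture classes (BaP+Pyr,
BaP+Nap, Pyr+Nap, BaP+Pyr+Nap — single-analyte classes are deliberately
absent) × 20 samples × 5 replicates = 400 spectra, with concentrations from
the dilution ladder 10, 8, 5, 2.5, 1, 0.5, 0.1, 0.05 µg/mL. Each sample is
one co-diluted mixture: all constituents sit at the sample's dilution level,
and levels cycle through the ladder so every class covers the full range.
This mirrors how mixture standards are actually prepared — a mixed stock
diluted stepwise, every constituent sharing the dilution factor. An
`independent` design (each constituent's concentration drawn separately from
the ladder) is available as a config option; be aware that it produces
concentration ratios up to 200:1, whose minor constituent is physically
invisible at the default noise level — classes then overlap irreducibly and
no classifier, however good, can reach high accuracy on such a dataset.

**What the generator does not model.** Peel-to-peel chemical variation,
wavenumber miscalibration/drift, cosmic-ray spikes, band shifts or width
changes with concentration, non-Lorentzian lineshapes, and hot-spot
electromagnetics. Passing tests therefore demonstrate that the pipeline
recovers the structure this model encodes — band patterns under competitive
suppression, replicate scale noise — not that it would reach the same
accuracy on instrument data.

## The lightweight networks

All convolutions are 1D along the wavenumber axis ("3×1" = kernel 3).
Published layer tables for the 1D variants are not available, so widths are
the smallest consistent with each architecture's block inventory; everything
is overridable via `NetworkConfig`.

* **SqueezeNet-1D**: conv(16, k7, stride 2) → ReLU → maxpool(2) →
  fire(squeeze 16, expand 32 ∥ 32, concatenated → 64 channels) → flatten →
  dropout 0.5 → dense(4). Pooling is delayed relative to the fire module so
  a larger feature map is convolved. 50,644 parameters.
* **MobileNet-1D**: conv(16, k3) → ReLU → DSC(32) → DSC(64) → maxpool(2) →
  flatten → dense(64) → ReLU → dense(4), where DSC = depthwise conv(k3) →
  BN → ReLU → pointwise conv(1×1) → BN → ReLU (convolutions bias-free, as
  batch norm follows). 1,539,380 parameters (the flatten→dense(64) junction
  dominates).
* **ShuffleNet-1D**: conv(24, k3) → ReLU → maxpool(2) → 2 × shuffle
  unit(C=24, g=3) → flatten → dropout 0.5 → dense(64) → ReLU → dense(4).
  A shuffle unit is 1×1 group conv → ReLU → channel shuffle → depthwise
  conv(k3) → 1×1 group conv, residually added to the unit input. The channel
  shuffle sends output channel i to input channel (i mod g)(C/g) + (i div g)
  — the reshape–transpose–flatten permutation that lets stacked group
  convolutions exchange information. 577,476 parameters.

ReLU activations throughout; batch normalisation only inside DSC blocks
(where the architecture specifies it); softmax heads. Each network is
strictly smaller than a plain CNN of the same depth and channel widths built
from dense kernel-3 convolutions (verified block-by-block in the tests).
Weight initialisation is uniform fan-in scaling (±1/√fan_in) from a seeded
generator, biases zero — chosen for determinism, not performance.

The engine (convolution with groups/stride/'same' padding, batch norm, max
pool, dropout, dense, softmax cross-entropy, Adam) is implemented in NumPy
with explicit forward/backward passes; gradient correctness is enforced by
finite-difference tests over every architecture. Batch-norm backward
distinguishes training mode (batch-statistic coupling) from eval mode (fixed
affine map).

## Training and evaluation protocol

* Split: 30% of spectra to prediction, remainder 3:1 training:validation,
  stratified by class. Per-class subset sizes use largest-remainder
  apportionment (deterministic tie-break by class order) so global totals
  are exact — 120/210/70 for N = 400 — even where per-class proportions are
  non-integral (0.25 × 70 = 17.5). Splitting is at the spectrum level, so
  replicates of one sample may land in different subsets, exactly as a
  "randomly selected spectra" protocol implies; a group-by-sample mode is
  provided for leakage-free evaluation.
* Training: Adam (lr 10⁻³, β = 0.9/0.999), batch 32, softmax cross-entropy,
  ≤200 epochs with early stopping on validation accuracy (patience 30); the
  epoch with the best validation accuracy (first, on ties) is kept. All
  randomness (batch order, dropout masks, weight init) derives from seeds.
* Metrics: overall ACC = trace/total of the confusion matrix (rows = true,
  columns = predicted), per class one-vs-rest TP/TN/FP/FN with
  Precision = TP/(TP+FP), Recall = TP/(TP+FN), and the standard harmonic
  F1 = 2PR/(P+R). A metric whose denominator is zero is reported as
  undefined (`None`), never silently zero; P = R = 0 with nonzero
  denominators gives F1 = 0 (the harmonic-mean limit). Reports round to 2
  decimals at serialisation; full precision is kept internally.

On the default synthetic dataset the four class templates are well separated
at the default noise level, and all three architectures reach perfect
subset accuracies; the acceptance script measures ShuffleNet-1D's training
and prediction accuracy at the full 400-spectrum scale as the median over
three seeds. Raising `noise_sd` degrades accuracy; lowering
`samples_per_class` shrinks the dataset proportionally (the reduced-scale
test-suite runs use 4 classes × 4 samples × 3 replicates on a 376-point
grid).

## Numerical and edge-case conventions

* Max pooling drops a trailing remainder shorter than the pool; ties within
  a pool window route the gradient to the first maximum.
* 'Same' padding computes output length ⌈L/stride⌉ and splits the pad
  left/right as ⌊total/2⌋ / remainder.
* `peak_intensity` windows must lie inside the grid; RSD requires ≥2 values
  and nonzero mean; splits require every class to appear in all three
  subsets; empty evaluation subsets are errors.
* CSV round-trips preserve intensities to ≥9 significant digits
  (`%.9g`); file parse errors name the offending record.
* Checkpoints store weights, batch-norm running statistics, and the network
  config (`.npz` plus a JSON architecture audit of block shapes and
  parameter counts).

## Known limitations

* The NumPy training loop is single-threaded BLAS-bound; MobileNet-1D (full
  751-point input) trains in minutes, not seconds.
* Determinism is guaranteed per platform (identical wheels/BLAS), not
  bit-exact across BLAS implementations.
* The generator's separability at default settings means near-ceiling
  accuracies for all three architectures; relative architecture rankings on
  this synthetic task are not evidence about their ranking on instrument
  data.
* Single-analyte spectra can be generated but are not a classification
  class; the classifier head is fixed to the four mixture classes of the
  study design.
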
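# Methods

This note documents the models, algorithms and design choices behind
`eegattr`: what is computed, under which assumptions, and where the open
design decisions were resolved.

## 1. Model abstraction and reference networks

Every model is an ordered list of layers — temporal convolution (1-D along
time, shared across channels, zero-padded "same", odd kernel), spatial
convolution (full-height filter collapsing the channel axis), pointwise
linear mixing, batch normalization, elementwise nonlinearity (ReLU or ELU),
time pooling (mean or max; pool size 0 = global), flatten, and dense.  The
contract the attribution engine relies on is that every layer is a linear
map composed with at most an elementwise nonlinearity, so the backward pass
can replace the local derivative at each nonlinearity with a rule-specific
factor.

Two stock architectures exercise every engine branch:

```
relu-compact / elu-compact:
  conv-over-time (12 filters, kernel 33) -> conv-over-channels (12)
  -> batchnorm -> relu|elu -> global mean pool over time -> dense
```

They are deliberately compact analogues of the temporal-then-spatial
filter-bank design used by EEG CNNs (EEGNet-style); bit-faithful
replication of any published network is a non-goal.  Kernel 33 at 128 Hz
(~0.26 s) spans multiple alpha cycles, giving the filters enough frequency
resolution to separate ~10 Hz spindles from 25–45 Hz EMG.  Global mean
pooling over time matches the generative structure of the synthetic data
(the class evidence is a band-limited burst at a random position, so the
decision statistic is translation-invariant band power) and makes the
200-sample training problem generalize; local pooling variants overfit the
burst positions at this sample size.

**Training.**  Adam with the conventional defaults (η = 0.001, β₁ = 0.9,
β₂ = 0.999), batch size 50, weighted cross-entropy on the pre-softmax
activations (per-class weights for imbalanced data), up to 50 epochs, best
epoch chosen by lowest loss on a held-out 20% validation split.  With
batch 50 on 200 samples an epoch is only 4 optimizer steps, so the full
50-epoch budget is needed for convergence at η = 0.001.  Weight
initialization is He-style Gaussian, seeded.  Because roughly one random
initialization in ten stalls in a poor basin under these settings,
`train_with_restarts` trains from a few consecutive seeds and keeps the
restart with the lowest validation loss; the CLI and the acceptance script
use 3 restarts.  Everything is bitwise reproducible from the seeds.

**Batchnorm linearization.**  For attribution, batch statistics must be
constants: `freeze_batch_stats` captures mean/variance from one forward
pass of a reference batch, after which the layer is a fixed affine map and
a sample's attribution no longer depends on its batch companions.  When
only a single sample is available (CLI `attribute`/`report`), the model's
running statistics are used instead — they are equally constant, and
freezing on a one-sample "batch" would subtract the sample's own feature
activity and distort the prediction.

## 2. Attribution engine

All seven methods run through one backward pass with a per-rule factor g
at each elementwise nonlinearity (README table).  Choices the literature
leaves open, resolved as follows:

* **Saliency sign** — the signed derivative by default (the linear-case
  analysis relies on the sign); `saliency_absolute=True` gives the
  magnitude variant.
* **Deconvolution** — the classic deconvnet rule: the backward signal is
  passed through a ReLU (negatives zeroed), independent of the forward
  pre-activation.  Note this means an inactive ReLU can still pass a
  positive backward signal.
* **Guided backpropagation** — backward signal zeroed where either it or
  the forward pre-activation z is negative.
* **LRP-ε** — g = f(z)/(z + ε·sign z) with sign(0) = +1 and ε = 1e-9.
  The stabilizer introduces a relative error of order ε/z at each unit;
  1e-9 keeps the exact ReLU identity LRP-ε ≡ gradient × input below 1e-5
  relative even when pre-activations pass near zero, while still guarding
  the division.
* **DeepLIFT (rescale)** — g = (f(z) − f(z̄))/(z − z̄) with z̄ from a second
  forward pass on the baseline; where |z − z̄| < ε the rule is 0/0 and
  falls back to its limit f′(z).
* **Integrated gradients** — zero baseline, 100 steps by default,
  **midpoint quadrature**: gradients are evaluated at α = (k−½)/m.  The
  midpoint rule has O(1/m²) completeness error and keeps the
  summation-to-delta identity within ~1e-4 at 100 steps, where an
  endpoint Riemann sum leaves ~1% error on ELU networks.  The path is
  evaluated in chunks of 128 points to bound peak memory.
* **Baselines** — the all-zero sample (a flat signal is the natural
  "absence of evidence" reference for amplitude-coded EEG features).
* **Pooling adjoints** — max-pool routes to the argmax (first index on
  ties), mean-pool distributes uniformly.  Batchnorm attributes through
  its frozen affine map only, never through the statistics.

The channel contribution map is the temporal mean of the sample map,
R̄_c(i) = (1/T)·Σ_j R_c(i, j).

The engine is validated against a central finite-difference oracle
(agreement to 1e-7 on ELU networks) and against closed-form linear-model
expressions; the baseline-referenced methods are additionally checked for
summation-to-delta.

## 3. Faithfulness tests

**Patch sensitivity.**  Patch length n = ⌊fraction·T⌋ for fractions
{0.1, …, 0.5}; 100 perturbations per fraction; channel and start position
drawn uniformly with a fixed seed; patches never wrap or span channels;
fill value 0 µV.  The score delta uses the pre-softmax activation S_c
(the "output score" reading); a probability-based variant is available by
running the deletion machinery instead.  Pearson r is flagged *undefined*
(not NaN-propagated) if either vector has zero variance.  The channel-map
variant zeroes each channel once and reports a single r; with fewer than
3 channels it is flagged low-power.

**Deletion.**  Points ranked by map score descending, ties broken by
(channel, time) ascending for reproducibility; the top ⌈fraction·N·T⌉
points are cumulatively zeroed at fractions 1%…100% (channel mode: whole
channels at k/N in descending channel-score order, plus a one-at-a-time
variant for the report); the predicted-class softmax probability is
recorded and the AUC computed by trapezoid.  At fraction 1.0 the model is
evaluated on the all-fill sample exactly.

**Random baseline.**  Seeded i.i.d. uniform(−1, 1) maps; their channel
maps are their temporal means.  `benchmark` runs samples × methods ×
tests into a long-format table with median/quartile summary rows;
per-sample perturbation seeds are derived from the sample content
(CRC32), so summaries are invariant to sample order.

## 4. Report pipeline

Processing order is fixed: **normalize → threshold → smooth** (the API
rejects other orders).  Normalization is a global z-score — the default
cutoffs (2 for sample maps, 1 for channel maps) then read as
standard-score thresholds; this is an assumption, recorded in the report
metadata.  Thresholding keeps positive (evidence-for-class) scores only by
default; a signed mode (|v| ≥ threshold) is available.  Smoothing is a
centred moving average along time (window 5, odd), with boundary windows
shrinking to the valid overlap rather than inventing padding values.

The report runs the sensitivity test on the **original** map (best
achievable correlation) and deletion on the **processed** map (so the
numbers describe exactly what the overlay highlights): it records the new
probability after zeroing the surviving points, the deleted portion
(exact rational accounting), the top-3 channels by deleted-point count
(ties by channel index), and the new probability after removing the
supra-threshold channels.  A degenerate (constant) map skips deletion and
is flagged.  The recorded probability is guaranteed to equal re-running
the model on the explicitly deleted sample.

## 5. Synthetic EEG generator

The generator emulates the statistical structure of the EEG the tests are
meant for, with known ground truth:

* **background**: per-channel 1/f (pink) noise, rFFT shaping of white
  Gaussian noise, scaled to 10 µV RMS (typical scalp EEG amplitude);
* **alpha_spindle** (class 1 default): 9–11 Hz carrier under a Hann
  (waxing-and-waning) envelope — the classic drowsiness marker;
* **blink_pulse**: a large Gaussian low-frequency transient on designated
  frontal channels;
* **emg_noise** (class 0 default): a 25–45 Hz band-limited burst,
  mimicking scalp-muscle activity in wakeful EEG.

Defaults: 8 channels × 256 points at 128 Hz, feature channels {2, 5},
duration 0.5–1.5 s at a seeded random onset, amplitude ratio (feature peak
to background RMS) 2.0 — strong enough to be visible in single trials, as
real spindles and EMG bursts are.  The binary mask marks exactly the
feature support; the background is drawn from an independent seed
substream, so subtracting it isolates the feature, and snr = 0 reproduces
the background bitwise.  A 4-class mode rotates the spindle across channel
pairs, mimicking class-specific spatial topographies.

What the generator does **not** emulate: volume conduction and realistic
channel covariance, non-stationary artifact mixtures, inter-subject
variability, line noise.  Tests passing on this data show the pipeline is
correct and that the faithfulness metrics separate methods as expected on
a learnable EEG-like task; they do not certify performance on any real
recording.

`localization_score` quantifies ground-truth recovery: the fraction of the
top-k attribution points inside the mask divided by the mask's area
fraction (1 = chance).

## 6. Problem sizes and numerical choices

The shipped tests and the acceptance script use the 200-sample training
set, a 12-sample evaluation subset for the method-comparison suites, a
50-sample set for localization, 100 paired seeds for the deletion
comparison, and 100 perturbations per sensitivity test — sizes at which
every comparison is stable across seeds while the whole stack runs in
minutes on a single CPU.  Floating-point contracts: softmax probabilities
sum to 1 within 1e-9; channel means within 1e-12 of brute-force sums;
deletion-report probabilities within 1e-9 of direct re-evaluation; the
batchnorm epsilon is 1e-5; degenerate normalization (std < 1e-12) returns
an all-zero flagged map.

## 7. Known limitations

* Only feed-forward stacks of the listed layer kinds are supported — no
  recurrent layers, no residual connections (a capability error is raised).
* LRP is the ε-rule only; z⁺/αβ variants are out of scope.
* Perturbation-based attribution families (occlusion, RISE, masks) are out
  of scope; the random map is the only baseline.
* The deletion test's zero-fill, like all ablation metrics, evaluates the
  model slightly off-distribution; results are comparative, not absolute.
* Topographic scalp interpolation is not rendered; channel-level results
  are reported as named lists.
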
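# eegattr

Attribution methods, faithfulness tests, and sample-wise trust reports for
neural networks that classify EEG.

Deep networks are widely used to decode mental state from multichannel EEG
— motor imagery, error-related potentials, driver drowsiness — and their
decisions are routinely "explained" with heatmaps that assign each sampling
point of a channels × time input a contribution score.  Those heatmaps are
often taken at face value.  This package is for BCI researchers who want to
know **whether a given contribution map can be trusted before drawing
neurophysiological conclusions from it**.  It provides:

* seven backpropagation-based attribution methods in one modified-gradient
  engine — saliency, deconvolution, guided backpropagation,
  gradient × input, integrated gradients, LRP-ε, and DeepLIFT (rescale);
* two quantitative faithfulness tests — a local patch **sensitivity test**
  and a **deletion test** — plus a random-map chance baseline;
* a sample-wise **evaluation report** and overlay visualization
  (normalize → threshold → smooth) that pairs every displayed heatmap with
  the numbers needed to accept or reject it;
* a seeded **synthetic EEG generator** (1/f background, alpha-spindle /
  blink / EMG features with ground-truth masks) and compact reference CNNs,
  so the whole stack is verifiable offline.

## The model and the metrics

For a sample X ∈ ℝ^(N×T) (N channels, T time points) predicted as class c
with pre-softmax score S_c(x), each method produces a contribution map
R_c ∈ ℝ^(N×T).  All seven are implemented as a single backward pass in
which the local derivative f′(z) at each elementwise nonlinearity may be
replaced by a rule-specific factor g:

| method | R_c(i) | nonlinearity factor g |
|---|---|---|
| saliency | ∂S_c/∂x_i | f′(z) |
| deconvolution | ∂_g S_c/∂x_i | backward signal, negatives zeroed |
| guided backprop | ∂_g S_c/∂x_i | zeroed where backward signal or z < 0 |
| gradient × input | x_i · ∂S_c/∂x_i | f′(z) |
| integrated gradients | (x_i − x̄_i) · mean path gradient | f′(z) |
| LRP-ε | x_i · ∂_g S_c/∂x_i | f(z) / (z + ε·sign z) |
| DeepLIFT (rescale) | (x_i − x̄_i) · ∂_g S_c/∂x_i | (f(z) − f(z̄)) / (z − z̄) |

On a purely linear model the last four collapse to w_ji·x_i while the first
three return the input-independent w_ji — which is why they split into two
performance groups under both tests.

**Sensitivity test**: zero a random patch of length n = ⌊fraction·T⌋
(fractions 0.1–0.5) in one random channel, 100 times; report the Pearson
correlation r between the score drop S_c(x) − S_c(x_perturbed) and the
summed map scores inside the patch.  **Deletion test**: zero the
highest-scoring points cumulatively (1%, 2%, …) and record the predicted
class probability; a faithful map gives a sharply dropping curve, i.e. a
small area under it (AUC).

## Worked example

```bash
eegattr synth --n 200 --seed 11 --out data           # synthetic 2-class EEG
eegattr train-demo --data data --seed 11 --out model.ckpt
eegattr report --model model.ckpt --sample data/sample0031.csv \
        --method gradient_x_input --out report.json --fig fig.png
```

The trainer reports `best_epoch=49 val_acc=0.975`, and the report for a
correctly classified "alpha spindle" sample (class 1, p = 0.82) prints:

```
model: relu-compact | method: gradient_x_input | window: 5 | thresholds: 2/1
sensitivity r [0.1: 1.00, 0.2: 1.00, 0.3: 1.00, 0.4: 1.00, 0.5: 1.00] | channel r: 1.00
prob after deletion: 0.52 | portion deleted: 0.07 | top channels: CH5 (0.070), CH2 (0.002)
prob after channel deletion: 0.51 | channels: CH5
```

Line 1 echoes the model, method and processing settings.  Line 2: the map
correlates perfectly (r = 1.00) with the model's actual score changes at
every patch size — this interpretation can be trusted.  Line 3: deleting
only the highlighted 7% of the data drops the class probability from 0.82
to 0.52, and the deleted points concentrate on CH5 — one of the two
channels where the generator actually implanted the spindle.  Line 4:
removing the single supra-threshold channel has the same effect.  A report
with r near 0, or a deletion that leaves the probability unchanged, tells
you to reject the heatmap even if it looks plausible.

The same pipeline is available as library calls
(`compute_contribution`, `sensitivity_test`, `deletion_curve`,
`generate_report`, `benchmark`, …); see the module docstrings.

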
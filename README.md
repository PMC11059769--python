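# mbdetect

Anomaly detection of **Marchiafava–Bignami disease (MBD)** in 2-D
corpus-callosum MRI slices.

MBD is a rare neurodegenerative disorder — typically associated with
chronic alcoholism — marked by demyelination, necrosis and cystic
degeneration of the corpus callosum. Positives are far too scarce for
supervised training, so `mbdetect` frames detection as one-class anomaly
detection for researchers and method developers working on rare-disease
neuroimaging pipelines:

1. **DTCWT features** — each slice is decomposed with a dual-tree complex
   wavelet transform into a low-pass band `δ₁` and six oriented complex
   high-pass bands `β_{L,n}` per level (near ±15°, ±45°, ±75°); the
   shift-robust coefficient magnitudes form the feature vector `x`.
2. **Soft attention** — a learned score network yields
   `w = softmax(f_att(x))` (weights sum to 1) and the input is gated as
   `g = x ⊙ (F·w)`, so the model concentrates on informative sub-band
   coordinates.
3. **Variational autoencoder** — an encoder maps `g` to a diagonal
   Gaussian posterior `(μ, σ)` over a 50-d latent; a sample
   `z = μ + σ⊙ε` is decoded back to `ĝ`. Training on *healthy slices
   only* maximises the evidence lower bound,
   `ELB = E[log P_θ(x|v)] − KL(e_φ(v|x) ‖ P(v))`,
   implemented as `loss = 0.5·MSE + 0.5·KL` with Adam.
4. **Detection** — at inference the anomaly score is the mean
   attention-weighted squared residual `mean_i F·w_i·(g_i − ĝ_i)²`; a
   slice is called MBD when the score exceeds the 0.95 quantile of
   normal-image scores.

A seeded **phantom generator** renders midsagittal corpus-callosum slices
(normal and MBD phenotypes, with exact lesion masks) from published
morphometric ranges, so the whole pipeline is testable end to end with
known ground truth. A metrics module (accuracy, sensitivity, specificity,
F1, AUC-ROC, MSE, discrete KL, Dice) completes the evaluation loop.

## Worked example

```python
import numpy as np
from mbdetect import MBDDetector, generate_dataset
from mbdetect.metrics import (ConfusionMatrix, ScoredLabels, accuracy,
                              auc_roc, sensitivity, specificity)

train = generate_dataset(n_normal=200, n_mbd=0, image_size=64, rng_seed=0)
test = generate_dataset(n_normal=50, n_mbd=50, image_size=64, rng_seed=1)

det = MBDDetector(epochs=20, seed=0).fit(train.pixel_stack())
scores = det.score_samples(test.pixel_stack())
truths = (test.labels == "MBD").astype(int)
pred = (scores > det.threshold_).astype(int)

cm = ConfusionMatrix.from_predictions(truths, pred)
print(f"threshold   : {det.threshold_:.4f}")
print(f"normal score: {scores[truths == 0].mean():.4f} +/- {scores[truths == 0].std():.4f}")
print(f"MBD score   : {scores[truths == 1].mean():.4f} +/- {scores[truths == 1].std():.4f}")
print(f"AUC-ROC     : {auc_roc(ScoredLabels(scores=scores, truths=truths)):.3f}")
print(f"accuracy    : {accuracy(cm):.3f}")
print(f"sensitivity : {sensitivity(cm):.3f}")
print(f"specificity : {specificity(cm):.3f}")
```

Output:

```
threshold   : 1.9323
normal score: 1.7715 +/- 0.1097
MBD score   : 2.8302 +/- 0.8580
AUC-ROC     : 0.970
accuracy    : 0.930
sensitivity : 0.920
specificity : 0.940
```

Healthy slices reconstruct well (scores tightly clustered below the
calibrated threshold) while diseased slices — thinning, hyper-/hypo-
intense lesions, cysts, necrosis, enhancement rims — produce large
attention-weighted residuals. The threshold sits at the 0.95 quantile of
training-normal scores, anchoring specificity near 0.95; sensitivity
reflects how far the MBD score distribution separates.

## Command line

The same pipeline is scriptable as four stages (every command takes
`--seed` and `--config`; flags override config-file values):

```bash
mbdetect phantom --n-normal 200 --n-mbd 0  --seed 0 --out data/train
mbdetect phantom --n-normal 50  --n-mbd 50 --seed 1 --out data/test
mbdetect train  --data data/train --epochs 20 --out runs/model
mbdetect detect --model runs/model --images data/test --out runs/scores.csv
mbdetect evaluate --scores runs/scores.csv --truth data/test/labels.csv --out runs/report
```

`phantom` writes PNG slices, lesion masks and `specs.csv`/`labels.csv`;
`train` writes a checkpoint (`.npz` parameter archive + `.json` sidecar
with the configuration, feature layout and normalization scales) and a
training-history CSV; `detect` writes per-image scores and labels;
`evaluate` writes the metric report (CSV + JSON).

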
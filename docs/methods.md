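# Methods

`mbdetect` detects Marchiafava–Bignami disease (MBD) in 2-D corpus-callosum
MRI slices as a *one-class anomaly-detection* problem: a variational
autoencoder with soft feature attention is trained on healthy slices only,
and disease is flagged when a slice's attention-weighted reconstruction
error exceeds a calibrated threshold. This note records the model, the
numerical choices, and what the synthetic experiments do and do not show.

## Feature extraction: dual-tree complex wavelet transform

Each slice `I` is decomposed over `L` dyadic levels into a low-pass
approximation `δ₁` and six oriented complex high-pass sub-bands `β_{L,n}`
per level (orientations near ±15°, ±45°, ±75°). The dual-tree construction
runs four separable real wavelet transforms (every row/column combination
of two filter trees offset by half a sample) and recombines them unitarily
into complex coefficients whose magnitudes are approximately invariant to
small shifts — the property that makes the magnitudes usable as a
translation-robust lesion descriptor, and the reason for preferring the
DTCWT over a critically sampled DWT.

Filter choices:

* **Level 1**: the CDF 9/7 biorthogonal pair; the second tree applies the
  same filters to the input cyclically delayed by one sample (the standard
  first-level half-sample offset).
* **Levels ≥ 2**: an 18-tap orthonormal quarter-sample-delay ("q-shift")
  filter designed in-code. The filter is parametrised by nine
  paraunitary-lattice rotation angles, so the two-channel bank is
  orthonormal *by construction* (machine-precision perfect reconstruction,
  measured round-trip error ≈ 2·10⁻¹²). The angles were chosen once by
  minimising stopband energy subject to the analysis group delay staying
  within ~0.2 samples of `(L−1)/2 − 1/4`; the last angle is derived so the
  set sums to exactly π/4, which forces one vanishing moment (`H(π) = 0`),
  so constant images produce no detail response at any level. Tree *b*
  uses the time-reversed filter, giving the half-sample inter-tree delay
  at every deeper level.
* **Boundary handling** is periodized (circular). This keeps the
  forward/inverse pair exactly invertible for every admissible size;
  shift-invariance statements are correspondingly made for cyclic shifts.
  Phantom slices have near-constant borders, so wrap-around artefacts are
  negligible in practice.

The feature vector concatenates all high-pass magnitudes (phase is
discarded) and the absolute low-pass values in a fixed (level,
orientation, position) order; for a 64×64 slice at the default `L = 4`
this gives `F = 8224` non-negative features.

**Normalization.** The `DTCWTFeatureExtractor` divides every coefficient
by the 95th percentile of that coefficient's magnitudes over the training
corpus. An earlier design used one scale per sub-band; it was discarded
because a focal lesion lands in coordinates whose absolute magnitudes are
tiny compared with the band's largest coefficients, so its residual
contribution vanished from the mean score. Per-coordinate scaling makes
residuals commensurable across coordinates (approximately unit scale
everywhere), which is what lets a ~100-pixel lesion move a mean over 8224
features.

## The attention-gated VAE

With input `x ∈ R^F` (the normalized feature vector):

* **Soft attention**: a score network `f_att` (two hidden ReLU layers of
  width 256) emits one raw score per feature; `w = softmax(f_att(x))`
  gives weights in (0, 1) summing to one. The input is gated as
  `g = x ⊙ (F·w)`, scaled by `F` so *uniform attention is the identity*
  rather than shrinking activations by `1/F`.
* **Encoder**: three hidden ReLU layers of width 256 (dropout 0.2 during
  training) with two linear heads for `μ` and `log σ²` of a 50-dimensional
  diagonal Gaussian posterior; `log σ²` is clipped to [−10, 10] for
  numerical stability.
* **Latent sample**: `z = μ + σ ⊙ ε`, `ε ~ N(0, I)` (the
  reparameterization trick; gradients flow through `μ` and `σ`).
* **Decoder**: the mirror MLP mapping `z` back to a reconstruction `ĝ` of
  the *gated* vector. The decoder likelihood is a unit-variance Gaussian,
  so the reconstruction term reduces to mean squared error up to
  constants.

Training minimises the negative evidence lower bound written as the
convex combination

    loss = 0.5 · MSE(g, ĝ) + 0.5 · mean_b ½ Σ_d (μ_d² + σ_d² − log σ_d² − 1)

i.e. equal reconstruction and KL weights, with the closed-form KL against
a standard-normal prior. Attention, encoder and decoder parameters are
trained jointly with Adam (α = 0.001, β = (0.9, 0.999)), L2 weight decay
0.001 on weight matrices, batch size 32, He initialization. Default
hyperparameters (epochs 100, hidden 256, latent 50, dropout 0.2, weights
0.5/0.5) are the published configuration; the phantom benchmark uses 20
epochs, which this data does not need more of (the loss plateaus well
before).

Two deliberate numerical deviations from a naive reading of "He-initialise
everything":

* The **final attention layer is zero-initialised** (the rest of the score
  network is He-initialised). With `F ≈ 8000`, He-scaled scores have
  spread of several units, so the initial softmax is already near-one-hot
  and the gate multiplies a few features by thousands before any learning
  occurs; training then optimises a degenerate gated representation. Zero
  init starts at exactly uniform gating (identity) and lets attention
  depart from it only where the objective wants it to.
* The **public `attention` op computes its softmax in float64** so that
  the weights sum to 1 within 10⁻⁹ regardless of the float32 training
  arithmetic.

Everything runs in seeded float32 numpy with a fixed operation order, so
two runs with the same configuration produce bit-identical loss
histories. Gradients are derived by hand and verified against central
finite differences in the test-suite.

## Detection and calibration

At inference no sampling takes place: the latent is the posterior mean
`μ`, making the score a pure function of (image, checkpoint). The
per-feature error is the attention-re-weighted squared residual
`e_i = F·w_i·(g_i − ĝ_i)²` and the anomaly score is `mean_i e_i` — the
"attention ratings" thus enter the decision twice, once gating the input
and once re-weighting the residual. The decision threshold is the
empirical 0.95 quantile (linear interpolation) of scores on normal
training/validation images; `score > threshold` ⇒ MBD, with ties labelled
non-MBD to favour specificity. By construction ~95 % of comparable normal
images fall below the threshold, so specificity is anchored near 0.95
while sensitivity is whatever the score separation delivers.

The model is trained on non-MBD images only. Nothing in the training
objective sees a disease label; the MBD/non-MBD call is entirely an
out-of-distribution statement, which is the appropriate regime for a rare
disease with scarce positives.

## The phantom generator

The generator emulates a stylised *midsagittal* corpus callosum: an
arched band (quadratic thickness profile through genu / body / splenium
control values) on a textured dark background, with additive Gaussian
noise (σ = 0.02 in [0, 1] units). Geometry uses 2.0 mm/pixel at 64×64
(128 mm field of view), so a 60–70 mm callosum spans 30–35 pixels.
Normal morphometry is sampled uniformly inside the published normal
intervals; MBD morphometry is sampled from the spans of the ten published
case instances (shipped as `data/table2_instances.csv` with a loader), so
thinning, shortening and ADC reduction match tabulated disease ranges.

Rendering choices where no rule is published:

* **ADC** enters as a mild brightness modulation of the band
  (lower ADC → locally altered contrast), a stand-in for diffusion
  contrast on a single structural slice.
* **Widths** (an out-of-plane quantity in a 2-D midsagittal slice) act as
  a partial-volume surrogate: segment brightness scales weakly with the
  local width relative to mid-normal.
* **Focal lesions** are soft ellipses on the band: T2-hyperintense
  (+0.22), T1-hypointense (−0.22) or mixed (per-blob sign).
* **Cysts** are rendered CSF-*bright* in the phantom's T2-like intensity
  convention. A dark cavity on a 2–5-pixel-thick band strictly lowers
  sub-band energy (replacing one large intensity jump with two smaller
  jumps lowers squared edge energy), which would contradict the intended
  property that cystic change *adds* wavelet energy; bright fluid matches
  T2 appearance and adds energy robustly.
* **Necrosis** is a ragged dark patch; **atrophy** carves the outer band
  margin over a random arc segment.
* **Gadolinium enhancement** draws a bright rim around each focal lesion
  (mild/moderate/strong = +0.08/+0.15/+0.25; "variable" samples the rim
  intensity per lesion).
* **Signal non-uniformity** multiplies the band by a low-frequency
  sinusoidal ripple (±8 %).

The lesion mask is defined *exactly*: lesion randomness is drawn from a
seed stream independent of the anatomy/noise stream, the same scene is
rendered with and without lesions, and the mask marks precisely the
pixels whose noise-free intensities differ. Outside the mask the two
renders agree bit for bit, which the test-suite checks.

**What the phantom does not model:** 3-D anatomy, partial-volume physics,
k-space acquisition, bias fields beyond the ripple, surrounding brain
structures, other pathologies, scanner/protocol variation. Passing the
phantom benchmark therefore demonstrates that the pipeline's machinery —
features, attention, ELBO optimisation, calibration — works end to end
and separates the modelled lesion phenotypes; it says nothing
quantitative about clinical MRI performance.

## Benchmark scale and reproducibility

The documented benchmark trains on 200 normal phantoms (64×64, 20
epochs) and evaluates on an independent 100 normal + 100 MBD set — sizes
chosen to exercise every stage in well under a minute on one CPU core
while leaving the score distributions stable across seeds. Typical
results (seeds 0–7): AUC 0.98–1.00, specificity 0.93–0.98, sensitivity
0.97–1.00. `scripts/acceptance.py` recomputes this benchmark and the
metric-module worked example from scratch for any seed.

## Known limitations

* The q-shift stopband (≈ −14 dB) is modest; deeper-level shift
  invariance is looser (5–15 % energy movement per pixel shift) than at
  level 1 (< 2 %). Longer lattice filters would improve this at some cost.
* Scores are calibrated on the training normals themselves; with heavier
  overfitting (many more epochs or fewer images) the threshold would
  be biased low and specificity on held-out data would drop. The
  `calibrate()` method accepts held-out normals for that regime.
* The attention mechanism is per-feature (gating wavelet coefficients),
  not spatial-patch attention; attention maps are diagnostic aids, not a
  lesion segmentation.
* Binary MBD / non-MBD only; no multi-disease differential.
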
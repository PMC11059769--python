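"""Anomaly-based MBD / non-MBD classification (the DetectMBD stage).

The detector is trained on *non-MBD* images only: the attention VAE learns
to reconstruct the gated wavelet features of healthy corpus-callosum
slices, so disease manifests as reconstruction error.  At inference the
posterior mean is used as the latent (no sampling), the per-feature
squared residual is re-weighted by the attention ratings, and the mean of
the weighted residuals is the anomaly score.  A score threshold is
calibrated as an empirical quantile (default 0.95) of scores on normal
validation images; an image is called MBD when its score exceeds the
threshold, with ties resolved to non-MBD to favour specificity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dtcwt import DTCWTFeatureExtractor
from .vae import AttentionVAE, TrainingConfig, attention, apply_attention, decode, encode

__all__ = [
    "AnomalyResult",
    "MBDDetector",
    "anomaly_score",
    "calibrate_threshold",
    "detect",
    "run_phantom_benchmark",
]


@dataclass
class AnomalyResult:
    """Outcome of scoring one image.

    ``score`` is the mean attention-weighted squared residual;
    ``label`` is ``"MBD"`` iff ``score > threshold`` (``None`` before a
    threshold is applied).
    """

    score: float
    label: str | None
    threshold: float
    per_feature_error: np.ndarray


def _score_features(x: np.ndarray, params) -> tuple[float, np.ndarray]:
    F = x.shape[-1]
    w = attention(x, params)
    g = apply_attention(x, w)
    dist = encode(g, params)
    xhat = decode(dist.mu, params)
    per_feature = F * np.asarray(w.weights, dtype=np.float64) * (
        np.asarray(g, dtype=np.float64) - np.asarray(xhat, dtype=np.float64)
    ) ** 2
    return float(per_feature.mean()), per_feature


def anomaly_score(image: np.ndarray, model: "MBDDetector", levels: int | None = None) -> AnomalyResult:
    """Score one 2-D image through the full trained pipeline (no label)."""
    if levels is not None and levels != model.levels:
        raise ValueError(
            f"requested {levels} levels but the model was trained with {model.levels}"
        )
    x = model.extractor_.transform(np.asarray(image, dtype=float)[None])[0]
    score, pfe = _score_features(x, model.vae_.params_)
    return AnomalyResult(score=score, label=None, threshold=float("nan"), per_feature_error=pfe)


def calibrate_threshold(normal_scores, quantile: float = 0.95) -> float:
    """Empirical (linearly interpolated) quantile of validation scores."""
    scores = np.asarray(normal_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot calibrate a threshold from no scores")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie strictly inside (0, 1)")
    return float(np.quantile(scores, quantile))


def detect(image: np.ndarray, model: "MBDDetector", threshold: float) -> AnomalyResult:
    """Classify one image: MBD iff the anomaly score exceeds ``threshold``."""
    res = anomaly_score(image, model)
    res.threshold = float(threshold)
    res.label = "MBD" if res.score > threshold else "non_MBD"
    return res


class MBDDetector:
    """One-class detector: DTCWT features -> attention VAE -> thresholding.

    Fit on a stack of normal (non-MBD) 2-D slices.  ``predict`` returns 1
    for MBD calls and 0 otherwise; ``score_samples`` returns the raw
    anomaly scores (higher = more anomalous).

    Parameters
    ----------
    levels : DTCWT decomposition depth.
    quantile : normal-score quantile used for threshold calibration.
    percentile : per-sub-band magnitude percentile used to scale features.
    epochs, learning_rate, ... : VAE training hyperparameters (published
        defaults; ``epochs`` defaults to the published 100).
    """

    def __init__(
        self,
        levels: int = 4,
        quantile: float = 0.95,
        percentile: float = 95.0,
        learning_rate: float = 0.001,
        epochs: int = 100,
        batch_size: int = 32,
        encoder_layers: int = 3,
        decoder_layers: int = 3,
        attention_layers: int = 2,
        hidden_size: int = 256,
        latent_dim: int = 50,
        dropout: float = 0.2,
        weight_decay: float = 0.001,
        kl_weight: float = 0.5,
        recon_weight: float = 0.5,
        seed: int = 0,
    ):
        self.levels = levels
        self.quantile = quantile
        self.percentile = percentile
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.encoder_layers = encoder_layers
        self.decoder_layers = decoder_layers
        self.attention_layers = attention_layers
        self.hidden_size = hidden_size
        self.latent_dim = latent_dim
        self.dropout = dropout
        self.weight_decay = weight_decay
        self.kl_weight = kl_weight
        self.recon_weight = recon_weight
        self.seed = seed

    _OWN = ("levels", "quantile", "percentile")

    def get_params(self, deep: bool = True) -> dict:
        names = list(self._OWN) + [f for f in TrainingConfig().__dataclass_fields__]
        return {k: getattr(self, k) for k in names}

    def set_params(self, **kw):
        valid = self.get_params()
        for k, v in kw.items():
            if k not in valid:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _vae_kwargs(self) -> dict:
        return {k: getattr(self, k) for k in TrainingConfig().__dataclass_fields__}

    def fit(self, X, y=None):
        """Train on normal images and calibrate the score threshold."""
        X = np.asarray(X, dtype=float)
        self.extractor_ = DTCWTFeatureExtractor(levels=self.levels, percentile=self.percentile)
        feats = self.extractor_.fit_transform(X)
        self.vae_ = AttentionVAE(**self._vae_kwargs()).fit(feats)
        self.train_scores_ = self._scores_from_features(feats)
        self.threshold_ = calibrate_threshold(self.train_scores_, self.quantile)
        return self

    def calibrate(self, images, quantile: float | None = None) -> float:
        """Re-calibrate the threshold on held-out normal images."""
        scores = self.score_samples(images)
        self.threshold_ = calibrate_threshold(scores, quantile or self.quantile)
        return self.threshold_

    def _scores_from_features(self, feats: np.ndarray) -> np.ndarray:
        return np.array([_score_features(x, self.vae_.params_)[0] for x in feats])

    def score_samples(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        return self._scores_from_features(self.extractor_.transform(X))

    def predict(self, X) -> np.ndarray:
        return (self.score_samples(X) > self.threshold_).astype(int)

    def score_result(self, image) -> AnomalyResult:
        return detect(np.asarray(image, dtype=float), self, self.threshold_)

    # persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Write ``<path>.npz`` (VAE params + feature scales + threshold)
        and a ``<path>.json`` sidecar (config + feature layout)."""
        path = Path(path)
        arrays = dict(self.vae_.params_)
        arrays["__scales__"] = self.extractor_.scales_
        arrays["__threshold__"] = np.array([self.threshold_])
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "detector_params": {k: getattr(self, k) for k in self._OWN},
            "vae_config": self.vae_.config.to_dict(),
            "n_features": int(self.vae_.n_features_in_),
            "feature_layout": [
                {**blk, "shape": list(blk["shape"])} for blk in self.extractor_.layout_
            ],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "MBDDetector":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        det = cls(**meta["detector_params"], **TrainingConfig.from_dict(meta["vae_config"]).to_dict())
        with np.load(path.with_suffix(".npz")) as z:
            arrays = {k: z[k] for k in z.files}
        det.threshold_ = float(arrays.pop("__threshold__")[0])
        scales = arrays.pop("__scales__")
        det.vae_ = AttentionVAE(**det._vae_kwargs())
        det.vae_.params_ = arrays
        det.vae_.n_features_in_ = arrays["enc_W0"].shape[0]
        det.extractor_ = DTCWTFeatureExtractor(levels=det.levels, percentile=det.percentile)
        det.extractor_.scales_ = scales
        det.extractor_.layout_ = [
            {**blk, "shape": tuple(blk["shape"])} for blk in meta["feature_layout"]
        ]
        det.extractor_.n_features_ = meta["n_features"]
        return det


def run_phantom_benchmark(
    seed: int = 0,
    n_train: int = 200,
    n_test_normal: int = 100,
    n_test_mbd: int = 100,
    image_size: int = 64,
    epochs: int = 20,
    levels: int = 4,
    quantile: float = 0.95,
) -> dict:
    """Train-on-normal / test-on-mixed phantom benchmark.

    Generates ``n_train`` normal phantoms for training and an independent
    held-out set of ``n_test_normal`` + ``n_test_mbd`` phantoms, fits the
    detector, and evaluates the score-based ROC plus thresholded confusion
    counts.  Returns a dict with the detector, scores and summary metrics.
    """
    from . import metrics as m
    from .phantom import generate_dataset

    train_ds = generate_dataset(n_train, 0, image_size=image_size, rng_seed=seed)
    test_ds = generate_dataset(
        n_test_normal, n_test_mbd, image_size=image_size, rng_seed=seed + 1
    )
    det = MBDDetector(levels=levels, quantile=quantile, epochs=epochs, seed=seed)
    det.fit(train_ds.pixel_stack())
    scores = det.score_samples(test_ds.pixel_stack())
    truths = (test_ds.labels == "MBD").astype(int)
    pred = (scores > det.threshold_).astype(int)
    cm = m.ConfusionMatrix.from_predictions(truths, pred)
    return {
        "detector": det,
        "scores": scores,
        "truths": truths,
        "threshold": det.threshold_,
        "auc": m.auc_roc(m.ScoredLabels(scores=scores, truths=truths)),
        "confusion": cm,
        "accuracy": m.accuracy(cm),
        "sensitivity": m.sensitivity(cm),
        "specificity": m.specificity(cm),
        "f1": m.f1(cm),
        "history": det.vae_.history_,
    }
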
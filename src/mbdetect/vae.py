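"""Attention-gated variational autoencoder over DTCWT feature vectors.

The model is a plain fully connected VAE whose input is first re-weighted
by a learned soft-attention distribution: a small score network produces
one raw score per feature, a softmax turns the scores into weights that
sum to one, and the input is multiplied elementwise by ``n_features *
weights`` (so uniform attention is the identity).  Encoder and decoder are
mirrored ReLU multilayer perceptrons; the encoder emits the mean and
log-variance of a diagonal Gaussian posterior, a latent sample is drawn
with the reparameterization trick ``z = mu + sigma * eps``, and the decoder
reconstructs the gated feature vector.

Training minimises the negative evidence lower bound (ELBO), written as a
convex combination of a Gaussian reconstruction term (mean squared error)
and the closed-form KL divergence from the posterior to the standard
normal prior:

    loss = w_rec * MSE(g, g_hat) + w_kl * mean_b 0.5 * sum_d
           (mu_d^2 + sigma_d^2 - log sigma_d^2 - 1)

All parameters (attention, encoder, decoder) are trained jointly with
Adam; everything is seeded and runs in float32 numpy, so two runs with the
same configuration produce bit-identical histories.  Gradients are derived
by hand and checked against finite differences in the test-suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

__all__ = [
    "TrainingConfig",
    "LatentDistribution",
    "AttentionWeights",
    "LossBreakdown",
    "AttentionVAE",
    "attention",
    "apply_attention",
    "encode",
    "decode",
    "reparameterize",
    "elbo_loss",
    "gaussian_kl",
    "train",
    "DivergenceError",
]

_LOGVAR_CLIP = 10.0


class DivergenceError(RuntimeError):
    """Raised when the training loss stops being finite."""


@dataclass
class TrainingConfig:
    """Hyperparameters of the attention VAE (published defaults)."""

    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 32
    encoder_layers: int = 3
    decoder_layers: int = 3
    attention_layers: int = 2
    hidden_size: int = 256
    latent_dim: int = 50
    dropout: float = 0.2
    weight_decay: float = 0.001
    kl_weight: float = 0.5
    recon_weight: float = 0.5
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        names = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})


@dataclass
class LatentDistribution:
    """Diagonal Gaussian posterior: per-image mu and log-variance."""

    mu: np.ndarray
    log_var: np.ndarray

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(0.5 * self.log_var)


@dataclass
class AttentionWeights:
    """Softmax-normalised per-feature weights and the raw scores."""

    weights: np.ndarray
    raw_scores: np.ndarray


@dataclass
class LossBreakdown:
    """ELBO components; ``total`` always equals the stated combination."""

    total: float
    reconstruction: float
    kl: float


def _softmax(scores: np.ndarray) -> np.ndarray:
    s = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)).astype(np.float32)


def init_params(n_features: int, config: TrainingConfig) -> dict[str, np.ndarray]:
    """He-initialised parameter dictionary for all three sub-networks."""
    rng = np.random.default_rng(np.random.SeedSequence([0x1417, int(config.seed)]))
    H, D, F = config.hidden_size, config.latent_dim, n_features
    p: dict[str, np.ndarray] = {}

    def stack(prefix, sizes):
        for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            p[f"{prefix}_W{i}"] = _he_init(rng, a, b)
            p[f"{prefix}_b{i}"] = np.zeros(b, dtype=np.float32)

    stack("att", [F] + [H] * config.attention_layers + [F])
    # the score head starts at zero so gating begins exactly uniform
    # (identity); a spread-out initial softmax over thousands of features
    # would otherwise concentrate the gate before learning starts
    p[f"att_W{config.attention_layers}"][:] = 0.0
    stack("enc", [F] + [H] * config.encoder_layers)
    p["mu_W"] = _he_init(rng, H, D)
    p["mu_b"] = np.zeros(D, dtype=np.float32)
    p["lv_W"] = _he_init(rng, H, D)
    p["lv_b"] = np.zeros(D, dtype=np.float32)
    stack("dec", [D] + [H] * config.decoder_layers + [F])
    return p


# ---------------------------------------------------------------------------
# functional forward pieces (evaluation-mode, used by the detection stage)
# ---------------------------------------------------------------------------

def _as_batch(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(getattr(x, "values", x), dtype=np.float32)
    if arr.ndim == 1:
        return arr[None, :], True
    return arr, False


def _mlp_forward(x, params, prefix, n_layers, training=False, dropout=0.0, rng=None):
    """ReLU stack; returns activations list for backprop."""
    acts = [x]
    masks = []
    h = x
    for i in range(n_layers):
        h = _relu(h @ params[f"{prefix}_W{i}"] + params[f"{prefix}_b{i}"])
        if training and dropout > 0.0:
            mask = (rng.uniform(size=h.shape) >= dropout).astype(np.float32) / (1.0 - dropout)
            h = h * mask
            masks.append(mask)
        else:
            masks.append(None)
        acts.append(h)
    return h, acts, masks


def attention(features, params) -> AttentionWeights:
    """Soft-attention weights ``softmax(f_att(x))`` for one feature vector.

    The weights lie in (0, 1), sum to one, and are invariant to adding any
    constant to all raw scores.
    """
    x, single = _as_batch(features)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite feature values")
    n_att = sum(1 for k in params if k.startswith("att_W")) - 1
    h, _, _ = _mlp_forward(x, params, "att", n_att)
    scores = (h @ params[f"att_W{n_att}"] + params[f"att_b{n_att}"]).astype(np.float64)
    if not np.all(np.isfinite(scores)):
        raise FloatingPointError("non-finite attention scores")
    w = _softmax(scores)
    if single:
        return AttentionWeights(weights=w[0], raw_scores=scores[0])
    return AttentionWeights(weights=w, raw_scores=scores)


def apply_attention(features, weights: AttentionWeights):
    """Gate features by ``n_features * weights`` (uniform == identity)."""
    x, single = _as_batch(features)
    w = np.atleast_2d(np.asarray(weights.weights, dtype=np.float32))
    if w.shape[-1] != x.shape[-1]:
        raise ValueError(
            f"weights length {w.shape[-1]} != features length {x.shape[-1]}"
        )
    g = x * (x.shape[-1] * w)
    return g[0] if single else g


def encode(gated_features, params) -> LatentDistribution:
    """Evaluation-mode encoder posterior for gated features."""
    g, single = _as_batch(gated_features)
    n_enc = sum(1 for k in params if k.startswith("enc_W"))
    if g.shape[-1] != params["enc_W0"].shape[0]:
        raise ValueError(
            f"feature length {g.shape[-1]} does not match trained input "
            f"dimension {params['enc_W0'].shape[0]}"
        )
    h, _, _ = _mlp_forward(g, params, "enc", n_enc)
    mu = h @ params["mu_W"] + params["mu_b"]
    lv = np.clip(h @ params["lv_W"] + params["lv_b"], -_LOGVAR_CLIP, _LOGVAR_CLIP)
    if single:
        return LatentDistribution(mu=mu[0], log_var=lv[0])
    return LatentDistribution(mu=mu, log_var=lv)


def reparameterize(dist: LatentDistribution, noise: np.ndarray) -> np.ndarray:
    """Pathwise latent sample ``mu + sigma * noise``."""
    noise = np.asarray(noise, dtype=np.float32)
    if noise.shape[-1] != np.asarray(dist.mu).shape[-1]:
        raise ValueError("noise length must equal the latent dimension")
    return np.asarray(dist.mu) + dist.sigma * noise


def decode(latent, params):
    """Evaluation-mode decoder: latent vector -> reconstructed features."""
    z, single = _as_batch(latent)
    if z.shape[-1] != params["dec_W0"].shape[0]:
        raise ValueError(
            f"latent length {z.shape[-1]} != expected {params['dec_W0'].shape[0]}"
        )
    n_dec = sum(1 for k in params if k.startswith("dec_W")) - 1
    h, _, _ = _mlp_forward(z, params, "dec", n_dec)
    out = h @ params[f"dec_W{n_dec}"] + params[f"dec_b{n_dec}"]
    return out[0] if single else out


def gaussian_kl(mu: np.ndarray, log_var: np.ndarray) -> np.ndarray:
    """Closed-form KL( N(mu, sigma^2) || N(0, 1) ), summed over dimensions."""
    mu = np.asarray(mu, dtype=np.float64)
    lv = np.asarray(log_var, dtype=np.float64)
    return 0.5 * np.sum(mu**2 + np.exp(lv) - lv - 1.0, axis=-1)


def elbo_loss(x, x_hat, dist: LatentDistribution, config: TrainingConfig | None = None) -> LossBreakdown:
    """Negative-ELBO breakdown for a (batch of) reconstruction(s)."""
    if config is None:
        config = TrainingConfig()
    x, _ = _as_batch(x)
    xh, _ = _as_batch(x_hat)
    if x.shape != xh.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {xh.shape}")
    recon = float(np.mean((x.astype(np.float64) - xh.astype(np.float64)) ** 2))
    kl = float(np.mean(gaussian_kl(np.atleast_2d(dist.mu), np.atleast_2d(dist.log_var))))
    total = config.recon_weight * recon + config.kl_weight * kl
    return LossBreakdown(total=total, reconstruction=recon, kl=kl)


# ---------------------------------------------------------------------------
# training: joint forward/backward with hand-derived gradients
# ---------------------------------------------------------------------------

def _forward_backward(X, params, config, rng, training=True):
    """One batch of forward + backward.  Returns (loss parts, grads)."""
    B, F = X.shape
    n_att = config.attention_layers
    n_enc = config.encoder_layers
    n_dec = config.decoder_layers
    drop = config.dropout if training else 0.0

    # ---- forward ----
    ha, acts_a, _ = _mlp_forward(X, params, "att", n_att)
    scores = ha @ params[f"att_W{n_att}"] + params[f"att_b{n_att}"]
    w = _softmax(scores)
    g = X * (F * w)

    he, acts_e, masks_e = _mlp_forward(g, params, "enc", n_enc, training, drop, rng)
    mu = he @ params["mu_W"] + params["mu_b"]
    lv_pre = he @ params["lv_W"] + params["lv_b"]
    lv = np.clip(lv_pre, -_LOGVAR_CLIP, _LOGVAR_CLIP)
    sigma = np.exp(0.5 * lv)
    eps = rng.standard_normal(size=mu.shape).astype(np.float32) if training else np.zeros_like(mu)
    z = mu + sigma * eps

    hd, acts_d, masks_d = _mlp_forward(z, params, "dec", n_dec, training, drop, rng)
    xhat = hd @ params[f"dec_W{n_dec}"] + params[f"dec_b{n_dec}"]

    recon = float(np.mean((g.astype(np.float64) - xhat.astype(np.float64)) ** 2))
    kl = float(np.mean(gaussian_kl(mu, lv)))
    if not (np.isfinite(recon) and np.isfinite(kl)):
        raise DivergenceError("non-finite loss")

    grads = {k: None for k in params}

    def mlp_backward(dh, acts, masks, prefix, n_layers, x_in):
        for i in range(n_layers - 1, -1, -1):
            if masks[i] is not None:
                dh = dh * masks[i]
            dh = dh * (acts[i + 1] > 0)
            grads[f"{prefix}_W{i}"] = acts[i].T @ dh
            grads[f"{prefix}_b{i}"] = dh.sum(axis=0)
            dh = dh @ params[f"{prefix}_W{i}"].T
        return dh

    cr, ck = config.recon_weight, config.kl_weight

    # reconstruction path
    dxhat = (cr * 2.0 / (B * F)) * (xhat - g)
    grads[f"dec_W{n_dec}"] = acts_d[-1].T @ dxhat
    grads[f"dec_b{n_dec}"] = dxhat.sum(axis=0)
    dh = dxhat @ params[f"dec_W{n_dec}"].T
    dz = mlp_backward(dh, acts_d, masks_d, "dec", n_dec, z)

    dmu = dz.copy()
    dlv = dz * eps * 0.5 * sigma
    # KL path
    dmu += (ck / B) * mu
    dlv += (ck * 0.5 / B) * (np.exp(lv) - 1.0)
    dlv = dlv * ((lv_pre > -_LOGVAR_CLIP) & (lv_pre < _LOGVAR_CLIP))

    grads["mu_W"] = acts_e[-1].T @ dmu
    grads["mu_b"] = dmu.sum(axis=0)
    grads["lv_W"] = acts_e[-1].T @ dlv
    grads["lv_b"] = dlv.sum(axis=0)
    dh = dmu @ params["mu_W"].T + dlv @ params["lv_W"].T
    dg = mlp_backward(dh, acts_e, masks_e, "enc", n_enc, g)

    # the gated vector is also the reconstruction target
    dg = dg + (cr * 2.0 / (B * F)) * (g - xhat)

    # gating and softmax
    dw = F * X * dg
    ds = w * (dw - np.sum(dw * w, axis=1, keepdims=True))
    grads[f"att_W{n_att}"] = acts_a[-1].T @ ds
    grads[f"att_b{n_att}"] = ds.sum(axis=0)
    dh = ds @ params[f"att_W{n_att}"].T
    mlp_backward(dh, acts_a, [None] * n_att, "att", n_att, X)

    # decoupled-from-loss L2 regularisation on weight matrices
    if config.weight_decay:
        for k in params:
            if "_W" in k:
                grads[k] = grads[k] + config.weight_decay * params[k]
    return recon, kl, grads


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, gr in grads.items():
            gr = gr.astype(np.float32)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gr
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gr * gr
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def train(dataset, config: TrainingConfig | None = None, params=None):
    """Train all three sub-networks jointly; returns (params, history).

    ``dataset`` is an ``(n, F)`` array (or list of equal-length feature
    vectors).  Optimisation is Adam at the configured learning rate with L2
    weight decay, shuffled mini-batches, and one LossBreakdown per epoch.
    Fully reproducible given ``config.seed``.
    """
    if config is None:
        config = TrainingConfig()
    X = np.asarray(
        [np.asarray(getattr(v, "values", v), dtype=np.float32) for v in dataset],
        dtype=np.float32,
    )
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("dataset must be a non-empty collection of equal-length vectors")
    n, F = X.shape
    if params is None:
        params = init_params(F, config)
    opt = _Adam(params, config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([0x7124, int(config.seed)]))
    history: list[LossBreakdown] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        recon_sum = kl_sum = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            try:
                recon, kl, grads = _forward_backward(X[idx], params, config, rng)
            except DivergenceError as err:
                raise DivergenceError(f"training diverged at epoch {epoch + 1}") from err
            opt.step(params, grads)
            recon_sum += recon * idx.size
            kl_sum += kl * idx.size
        recon_e = recon_sum / n
        kl_e = kl_sum / n
        history.append(
            LossBreakdown(
                total=config.recon_weight * recon_e + config.kl_weight * kl_e,
                reconstruction=recon_e,
                kl=kl_e,
            )
        )
    return params, history


class AttentionVAE:
    """Scikit-learn style estimator wrapping the functional pieces.

    Parameters mirror :class:`TrainingConfig`.  After :meth:`fit` the
    trained arrays live in ``params_`` and the per-epoch loss history in
    ``history_``.
    """

    def __init__(
        self,
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

    _PARAM_NAMES = [f.name for f in fields(TrainingConfig)]

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._PARAM_NAMES}

    def set_params(self, **kw):
        for k, v in kw.items():
            if k not in self._PARAM_NAMES:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @property
    def config(self) -> TrainingConfig:
        return TrainingConfig(**self.get_params())

    def fit(self, X, y=None):
        self.params_, self.history_ = train(X, self.config)
        self.n_features_in_ = self.params_["enc_W0"].shape[0]
        return self

    # evaluation-mode conveniences -----------------------------------------
    def attention_weights(self, X) -> AttentionWeights:
        return attention(X, self.params_)

    def gate(self, X):
        return apply_attention(X, self.attention_weights(X))

    def encode(self, X) -> LatentDistribution:
        return encode(self.gate(X), self.params_)

    def reconstruct(self, X):
        """Deterministic gated-input reconstruction (posterior mean latent)."""
        g = self.gate(X)
        dist = encode(g, self.params_)
        return g, decode(dist.mu, self.params_)

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.history_) + 1),
                "total": [h.total for h in self.history_],
                "reconstruction": [h.reconstruction for h in self.history_],
                "kl": [h.kl for h in self.history_],
            }
        )

    # persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Write ``<path>.npz`` (arrays) and ``<path>.json`` (config)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params_)
        path.with_suffix(".json").write_text(
            json.dumps({"config": self.config.to_dict()}, indent=2)
        )

    @classmethod
    def load(cls, path) -> "AttentionVAE":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(**TrainingConfig.from_dict(meta["config"]).to_dict())
        with np.load(path.with_suffix(".npz")) as z:
            model.params_ = {k: z[k] for k in z.files}
        model.n_features_in_ = model.params_["enc_W0"].shape[0]
        return model
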
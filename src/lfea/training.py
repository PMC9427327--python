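"""Greedy layer-wise adversarial training.

Layer i is trained with all earlier layers frozen: their mean-mode forward
pass produces the residual s^{i-1} once, detached, so no gradient ever
traverses a frozen layer. Within each batch the discriminator takes one (or
more) ascent steps on its binary cross-entropy, then the encoder/decoder
take one descent step on the composite loss with the discriminator held
fixed. Gradients are composed by hand from the closed-form loss derivatives
and the MLP backward passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam
from .model import (GaussianPosterior, LFEAModel, LOG_VAR_CLAMP,
                    posterior_of, split)
from .objectives import (DEFAULT_BETA, DEFAULT_LAMBDA, LossBreakdown,
                         discriminator_bce, icm_loss, iem_loss, ism_estimate,
                         total_layer_loss)
from .signals import WindowSet

__all__ = ["TrainOptions", "TrainHistory", "train_layer", "fit",
           "LayerOrderError", "NonFiniteLossError"]


class LayerOrderError(RuntimeError):
    """Layers must be trained strictly in order 1..n."""


class NonFiniteLossError(FloatingPointError):
    """Training produced a non-finite loss; message carries step context."""


@dataclass
class TrainOptions:
    epochs_per_layer: int = 50
    batch_size: int = 128
    lr_model: float = 1e-3
    lr_disc: float = 1e-4
    lambda_: float = DEFAULT_LAMBDA
    beta: float = DEFAULT_BETA
    seed: int = 0
    disc_steps_per_model_step: int = 1

    def __post_init__(self) -> None:
        if self.epochs_per_layer < 1:
            raise ValueError("epochs_per_layer must be >= 1")
        if min(self.lr_model, self.lr_disc) <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class TrainHistory:
    """Per-step loss records for one layer, plus per-epoch means."""

    layer: int
    records: list[dict] = field(default_factory=list)

    def add(self, step: int, epoch: int, loss: LossBreakdown,
            disc_loss: float) -> None:
        self.records.append(dict(step=step, epoch=epoch, layer=self.layer,
                                 icm=loss.icm, recon=loss.recon, ism=loss.ism,
                                 total=loss.total, disc_loss=disc_loss))

    def epoch_means(self) -> dict[int, dict[str, float]]:
        out: dict[int, dict[str, float]] = {}
        for key in ("icm", "recon", "ism", "total", "disc_loss"):
            for r in self.records:
                out.setdefault(r["epoch"], {}).setdefault(key, []).append(r[key])
        return {e: {k: float(np.mean(v)) for k, v in d.items()}
                for e, d in out.items()}

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.records).to_csv(path, index=False)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _frozen_residual(model: LFEAModel, i: int, x: np.ndarray) -> np.ndarray:
    """Mean-mode forward through layers < i; detached by construction."""
    s = x
    for j in range(1, i):
        lay = model.layers[j - 1]
        post = posterior_of(lay, s)
        _, s = split(post.mean, lay.config.z_dim)
    return s


def train_layer(model: LFEAModel, i: int, windows: WindowSet,
                opts: TrainOptions, rng: np.random.Generator | None = None
                ) -> TrainHistory:
    """Train layer i only; every other parameter is bit-identical afterwards."""
    if model.trained_up_to != i - 1:
        raise LayerOrderError(
            f"cannot train layer {i}: trained_up_to = {model.trained_up_to}")
    if rng is None:
        rng = np.random.default_rng([opts.seed, i])
    lay = model.layers[i - 1]
    cfg = lay.config
    x = windows.flat()
    n = x.shape[0]
    s_prev = _frozen_residual(model, i, x)

    opt_model = Adam(lay.encoder.params + lay.decoder.params, opts.lr_model)
    opt_disc = Adam(lay.discriminator.params, opts.lr_disc)
    history = TrainHistory(layer=i)
    step = 0

    for epoch in range(1, opts.epochs_per_layer + 1):
        order = rng.permutation(n)
        for lo in range(0, n, opts.batch_size):
            idx = order[lo:lo + opts.batch_size]
            if idx.size < 2:
                continue  # a single row cannot be shuffled into negatives
            xb, sb_prev = x[idx], s_prev[idx]
            B = idx.size

            # --- discriminator step(s): joint vs batch-shuffled pairs
            disc_loss = 0.0
            for _ in range(opts.disc_steps_per_model_step):
                disc_loss = _disc_step(lay, sb_prev, opt_disc, rng)

            # --- encoder/decoder step with D fixed
            loss = _model_step(lay, xb, sb_prev, opts, opt_model, rng)
            step += 1
            if not np.isfinite(loss.total):
                raise NonFiniteLossError(
                    f"non-finite loss at layer {i}, epoch {epoch}, step {step}: "
                    f"{loss}")
            history.add(step, epoch, loss, disc_loss)

    model.trained_up_to = i
    return history


def _encode_cached(lay, sb_prev, rng):
    """Sample-mode encode keeping the caches needed for backprop."""
    raw, enc_cache = lay.encoder.forward(sb_prev)
    h_dim = lay.config.h_dim
    raw_lv = raw[:, h_dim:]
    mean = raw[:, :h_dim]
    log_var = np.clip(raw_lv, -LOG_VAR_CLAMP, LOG_VAR_CLAMP)
    std = np.exp(0.5 * log_var)
    eps = rng.standard_normal(mean.shape)
    h = mean + std * eps
    clamp_mask = (np.abs(raw_lv) < LOG_VAR_CLAMP).astype(float)
    return mean, log_var, std, eps, h, enc_cache, clamp_mask


def _disc_step(lay, sb_prev, opt_disc: Adam, rng) -> float:
    *_, h, _, _ = _encode_cached(lay, sb_prev, rng)
    z, s = split(h, lay.config.z_dim)
    B = h.shape[0]
    s_shuf = s[rng.permutation(B)]
    stacked = np.concatenate(
        [np.concatenate([z, s], axis=1), np.concatenate([z, s_shuf], axis=1)],
        axis=0)
    logits, cache = lay.discriminator.forward(stacked)
    logits = logits.reshape(-1)
    lp, ln = logits[:B], logits[B:]
    loss = discriminator_bce(lay.discriminator, z, s, s_shuf)
    grad = np.concatenate([(_sigmoid(lp) - 1.0) / (2 * B),
                           _sigmoid(ln) / (2 * B)]).reshape(-1, 1)
    grads, _ = lay.discriminator.backward(cache, grad)
    opt_disc.step(grads)
    return loss


def _model_step(lay, xb, sb_prev, opts: TrainOptions, opt_model: Adam, rng
                ) -> LossBreakdown:
    cfg = lay.config
    B = xb.shape[0]
    mean, log_var, std, eps, h, enc_cache, clamp_mask = _encode_cached(
        lay, sb_prev, rng)
    z, s = split(h, cfg.z_dim)

    # forward values
    x_hat, dec_cache = lay.decoder.forward(z)
    d_logits, disc_cache = lay.discriminator.forward(h)
    post = GaussianPosterior(mean, log_var)
    loss = total_layer_loss(icm_loss(post), iem_loss(xb, x_hat),
                            float(d_logits.mean()),
                            lambda_=opts.lambda_, beta=opts.beta)

    # reconstruction path: lambda * d recon / d x_hat -> decoder grads, dz
    d_xhat = opts.lambda_ * (x_hat - xb) / B
    dec_grads, dz_recon = lay.decoder.backward(dec_cache, d_xhat)

    # separation path: beta * d mean-logit / d h, discriminator params fixed
    d_logit = np.full((h.shape[0], 1), opts.beta / B)
    _, dh_ism = lay.discriminator.backward(disc_cache, d_logit)

    dh = dh_ism.copy()
    dh[:, :cfg.z_dim] += dz_recon

    # reparameterization: h = mean + std * eps
    d_mean = dh.copy()
    d_log_var = dh * 0.5 * std * eps

    # compression path: closed-form KL derivatives
    d_mean += mean / B
    d_log_var += 0.5 * (np.exp(log_var) - 1.0) / B

    d_raw = np.concatenate([d_mean, d_log_var * clamp_mask], axis=1)
    enc_grads, _ = lay.encoder.backward(enc_cache, d_raw)
    opt_model.step(enc_grads + dec_grads)
    return loss


def fit(model: LFEAModel, windows: WindowSet, opts: TrainOptions,
        log_dir=None) -> tuple[LFEAModel, list[TrainHistory]]:
    """Train all layers greedily in order; returns the model and histories.

    When ``log_dir`` is given, each layer's loss log is written as CSV and a
    checkpoint is saved after each layer completes.
    """
    if model.trained_up_to != 0:
        raise LayerOrderError("fit expects an untrained model")
    histories = []
    for i in range(1, model.n_layers + 1):
        hist = train_layer(model, i, windows, opts)
        histories.append(hist)
        if log_dir is not None:
            import os
            from .model import save_model
            os.makedirs(log_dir, exist_ok=True)
            hist.to_csv(os.path.join(log_dir, f"loss_layer{i}.csv"))
            save_model(model, os.path.join(log_dir, f"checkpoint_layer{i}.h5"))
    return model, histories
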
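"""Layered architecture: per-layer stochastic encoder h = (z, s), decoder to X.

Layer i compresses the previous residual s^{i-1} (s^0 = the flattened window
X) into a diagonal-Gaussian code h^i, splits it into an expressive block z^i
and a residual block s^i, and decodes z^i back to the ORIGINAL input X. The
concatenation Z = (z^1, ..., z^n) is the extracted feature; the final
residual s^n is computed but excluded from Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from ._nn import MLP
from .signals import WindowSet

__all__ = ["LayerConfig", "GaussianPosterior", "LFEALayer", "LFEAModel",
           "Representation", "default_layer_configs", "init_model",
           "encode_layer", "split", "decode", "forward_extract",
    "save_model", "load_model",
           "DimensionChainError", "UntrainedModelError"]

LOG_VAR_CLAMP = 10.0  # log-variance clipped to [-10, 10] for stability


class DimensionChainError(ValueError):
    """Consecutive layer widths do not chain (in_dim != previous s_dim)."""


class UntrainedModelError(RuntimeError):
    """Feature extraction requested from a model that is not fully trained."""


@dataclass(frozen=True)
class LayerConfig:
    """Widths of one layer: input, code h, expressive block z, hidden bodies."""

    in_dim: int
    h_dim: int
    z_dim: int = 5
    enc_hidden: tuple[int, ...] = (64,)
    dec_hidden: tuple[int, ...] = (128, 256)
    disc_hidden: tuple[int, ...] = (64, 64)

    def __post_init__(self) -> None:
        if not (1 <= self.z_dim < self.h_dim):
            raise ValueError("need 1 <= z_dim < h_dim")

    @property
    def s_dim(self) -> int:
        return self.h_dim - self.z_dim


@dataclass
class GaussianPosterior:
    """Diagonal-Gaussian posterior q(h | s_prev) for a batch."""

    mean: np.ndarray      # batch x h_dim
    log_var: np.ndarray   # batch x h_dim, clamped

    def std(self) -> np.ndarray:
        return np.exp(0.5 * self.log_var)


@dataclass
class LFEALayer:
    encoder: MLP        # s_prev -> (mean, log_var) stacked, width 2*h_dim
    decoder: MLP        # z -> x_hat, width T*C
    discriminator: MLP  # (z, s) -> 1 logit
    config: LayerConfig


@dataclass
class LFEAModel:
    layers: list[LFEALayer]
    T: int
    C: int
    seed: int
    trained_up_to: int = 0  # index of last trained layer, 0 = none

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def input_dim(self) -> int:
        return self.T * self.C

    def all_params(self) -> list[np.ndarray]:
        out = []
        for lay in self.layers:
            out += lay.encoder.params + lay.decoder.params + lay.discriminator.params
        return out


@dataclass
class Representation:
    """Per-layer codes z^1..z^n plus the final residual for a batch."""

    z_blocks: list[np.ndarray]   # each batch x z_dim_i
    s_final: np.ndarray          # batch x s_dim of last layer
    deterministic: bool

    def Z(self, layer_indices: tuple[int, ...] | None = None) -> np.ndarray:
        """Concatenate the selected z-blocks (1-based indices; default all)."""
        if layer_indices is None:
            layer_indices = tuple(range(1, len(self.z_blocks) + 1))
        return np.concatenate([self.z_blocks[i - 1] for i in layer_indices], axis=1)


def default_layer_configs(T: int = 200, C: int = 12,
                          h_dims: tuple[int, ...] = (64, 32, 16, 10),
                          z_dim: int = 5,
                          enc_hidden_first: tuple[int, ...] = (256, 128),
                          enc_hidden_rest: tuple[int, ...] = (64,),
                          dec_hidden: tuple[int, ...] = (128, 256),
                          disc_hidden: tuple[int, ...] = (64, 64),
                          ) -> list[LayerConfig]:
    """Chained configs: layer 1 reads the flattened window, layer i reads s^{i-1}."""
    configs = []
    in_dim = T * C
    for i, h in enumerate(h_dims):
        cfg = LayerConfig(in_dim=in_dim, h_dim=h, z_dim=z_dim,
                          enc_hidden=enc_hidden_first if i == 0 else enc_hidden_rest,
                          dec_hidden=dec_hidden, disc_hidden=disc_hidden)
        configs.append(cfg)
        in_dim = cfg.s_dim
    return configs


def init_model(T: int, C: int, layer_configs: list[LayerConfig] | None = None,
               seed: int = 0) -> LFEAModel:
    """Build a model with seeded parameter initialization; trained_up_to = 0."""
    if layer_configs is None:
        layer_configs = default_layer_configs(T, C)
    if layer_configs[0].in_dim != T * C:
        raise DimensionChainError(
            f"layer 1 in_dim {layer_configs[0].in_dim} != T*C = {T * C}")
    for i in range(1, len(layer_configs)):
        if layer_configs[i].in_dim != layer_configs[i - 1].s_dim:
            raise DimensionChainError(
                f"layer {i + 1} in_dim {layer_configs[i].in_dim} != "
                f"layer {i} s_dim {layer_configs[i - 1].s_dim}")
    rng = np.random.default_rng(seed)
    layers = []
    for cfg in layer_configs:
        enc = MLP((cfg.in_dim, *cfg.enc_hidden, 2 * cfg.h_dim), rng)
        dec = MLP((cfg.z_dim, *cfg.dec_hidden, T * C), rng)
        disc = MLP((cfg.h_dim, *cfg.disc_hidden, 1), rng)
        layers.append(LFEALayer(enc, dec, disc, cfg))
    return LFEAModel(layers, T, C, seed)


def encode_layer(model: LFEAModel, i: int, s_prev: np.ndarray,
                 mode: str = "mean", rng: np.random.Generator | None = None
                 ) -> tuple[np.ndarray, GaussianPosterior]:
    """Posterior of layer i (1-based) and a code h drawn from it.

    mode="sample" uses reparameterized sampling h = mean + std * eps with eps
    from ``rng``; mode="mean" returns the posterior mean (deterministic).
    """
    if not 1 <= i <= model.n_layers:
        raise IndexError(f"layer index {i} outside 1..{model.n_layers}")
    lay = model.layers[i - 1]
    if s_prev.ndim != 2 or s_prev.shape[1] != lay.config.in_dim:
        raise ValueError(f"layer {i} expects input width {lay.config.in_dim}, "
                         f"got {s_prev.shape}")
    post = posterior_of(lay, s_prev)
    if mode == "mean":
        h = post.mean.copy()
    elif mode == "sample":
        if rng is None:
            raise ValueError("mode='sample' requires an rng")
        h = post.mean + post.std() * rng.standard_normal(post.mean.shape)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return h, post


def posterior_of(lay: LFEALayer, s_prev: np.ndarray) -> GaussianPosterior:
    raw = lay.encoder(s_prev)
    h_dim = lay.config.h_dim
    mean = raw[:, :h_dim]
    log_var = np.clip(raw[:, h_dim:], -LOG_VAR_CLAMP, LOG_VAR_CLAMP)
    return GaussianPosterior(mean, log_var)


def split(h: np.ndarray, z_dim: int) -> tuple[np.ndarray, np.ndarray]:
    """h = (z, s): z is the first z_dim coordinates, s the remainder."""
    if z_dim >= h.shape[1]:
        raise ValueError(f"z_dim {z_dim} must be < h width {h.shape[1]}")
    return h[:, :z_dim], h[:, z_dim:]


def decode(model: LFEAModel, i: int, z: np.ndarray) -> np.ndarray:
    """Deterministic decoder mean of layer i; targets the original window X."""
    lay = model.layers[i - 1]
    if z.ndim != 2 or z.shape[1] != lay.config.z_dim:
        raise ValueError(f"layer {i} decoder expects z width {lay.config.z_dim}, "
                         f"got {z.shape}")
    return lay.decoder(z)


def forward_extract(model: LFEAModel, windows: WindowSet | np.ndarray,
                    mode: str = "mean", rng: np.random.Generator | None = None,
                    allow_untrained: bool = False) -> Representation:
    """Chain all layers, feeding each residual forward; collect z^1..z^n."""
    if model.trained_up_to < model.n_layers and not allow_untrained:
        raise UntrainedModelError(
            f"model trained up to layer {model.trained_up_to} of "
            f"{model.n_layers}; pass allow_untrained=True to override")
    x = windows.flat() if isinstance(windows, WindowSet) else np.asarray(windows)
    s = x
    z_blocks = []
    for i in range(1, model.n_layers + 1):
        h, _ = encode_layer(model, i, s, mode=mode, rng=rng)
        z, s = split(h, model.layers[i - 1].config.z_dim)
        z_blocks.append(z)
    return Representation(z_blocks, s, deterministic=(mode == "mean"))


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model: LFEAModel, path) -> None:
    """Write every parameter tensor plus configs to a keyed HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs.update(T=model.T, C=model.C, seed=model.seed,
                       trained_up_to=model.trained_up_to,
                       n_layers=model.n_layers)
        for li, lay in enumerate(model.layers):
            g = f.create_group(f"layer{li}")
            cfg = lay.config
            g.attrs.update(in_dim=cfg.in_dim, h_dim=cfg.h_dim, z_dim=cfg.z_dim,
                           enc_hidden=list(cfg.enc_hidden),
                           dec_hidden=list(cfg.dec_hidden),
                           disc_hidden=list(cfg.disc_hidden))
            for name, net in (("encoder", lay.encoder), ("decoder", lay.decoder),
                              ("discriminator", lay.discriminator)):
                for pi, p in enumerate(net.params):
                    g.create_dataset(f"{name}/{pi}", data=p)


def load_model(path) -> LFEAModel:
    with h5py.File(path, "r") as f:
        T, C = int(f.attrs["T"]), int(f.attrs["C"])
        configs = []
        for li in range(int(f.attrs["n_layers"])):
            a = f[f"layer{li}"].attrs
            configs.append(LayerConfig(
                in_dim=int(a["in_dim"]), h_dim=int(a["h_dim"]),
                z_dim=int(a["z_dim"]),
                enc_hidden=tuple(int(v) for v in a["enc_hidden"]),
                dec_hidden=tuple(int(v) for v in a["dec_hidden"]),
                disc_hidden=tuple(int(v) for v in a["disc_hidden"])))
        model = init_model(T, C, configs, seed=int(f.attrs["seed"]))
        model.trained_up_to = int(f.attrs["trained_up_to"])
        for li, lay in enumerate(model.layers):
            g = f[f"layer{li}"]
            for name, net in (("encoder", lay.encoder), ("decoder", lay.decoder),
                              ("discriminator", lay.discriminator)):
                for pi in range(len(net.params)):
                    net.params[pi] = g[f"{name}/{pi}"][...]
    return model
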
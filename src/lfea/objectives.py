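"""The three per-layer information losses and the composite objective.

Compression (ICM): a variational upper bound on I(S^{i-1}; H^i), the batch
mean of the closed-form KL between the diagonal-Gaussian posterior and a
standard-normal prior.

Expression (IEM): the reconstruction term. Maximizing the variational lower
bound on I(z^i; X) under a unit-variance Gaussian decoder is, up to an
additive constant, minimizing the mean squared reconstruction error, so the
loss reported here is mean(0.5 * ||x - x_hat||^2).

Separation (ISM): a density-ratio estimate of I(z^i; s^i). A discriminator D
is trained to tell joint (z, s) rows from rows with s shuffled across the
batch (product of marginals); at the optimum its mean logit — exactly
log(D/(1-D)) — estimates the mutual information. The model minimizes that
estimate with D held fixed (the adversarial step).

Composite (minimized): total = icm + lambda * recon + beta * ism, i.e. the
upper compression bound, minus lambda times the expression lower bound,
plus beta times the separation estimate. Defaults lambda=0.1, beta=0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import MLP
from .model import GaussianPosterior

__all__ = ["LossBreakdown", "icm_loss", "iem_loss", "discriminator_logit",
           "ism_estimate", "discriminator_bce", "total_layer_loss",
           "AnalyticDiscriminator", "DEFAULT_LAMBDA", "DEFAULT_BETA"]

DEFAULT_LAMBDA = 0.1
DEFAULT_BETA = 0.2


@dataclass(frozen=True)
class LossBreakdown:
    icm: float     # nats per sample
    recon: float   # error units per sample (= minus the expression bound + const)
    ism: float     # nats per sample
    lambda_: float
    beta: float

    @property
    def total(self) -> float:
        return self.icm + self.lambda_ * self.recon + self.beta * self.ism


class AnalyticDiscriminator:
    """Discriminator whose logit is a user-supplied function of (z, s).

    Used to plug in the analytically optimal log density ratio when checking
    the separation estimator against closed-form mutual information.
    """

    def __init__(self, logit_fn):
        self._fn = logit_fn

    def logit(self, z: np.ndarray, s: np.ndarray) -> np.ndarray:
        return np.asarray(self._fn(z, s), dtype=float).reshape(-1)


def icm_loss(posterior: GaussianPosterior) -> float:
    """Batch mean of KL(q(h|s) || N(0, I)), closed form, in nats. Always >= 0."""
    mean, log_var = posterior.mean, posterior.log_var
    if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(log_var))):
        raise ValueError("non-finite posterior parameters")
    kl = 0.5 * (mean ** 2 + np.exp(log_var) - 1.0 - log_var).sum(axis=1)
    return float(kl.mean())


def iem_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Reconstruction loss: batch mean of 0.5 * squared error, summed over dims."""
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(0.5 * ((x - x_hat) ** 2).sum(axis=1).mean())


def discriminator_logit(D, z: np.ndarray, s: np.ndarray) -> np.ndarray:
    """One real logit per (z, s) row; D(.) = sigmoid(logit)."""
    if z.shape[0] != s.shape[0]:
        raise ValueError("z and s must have the same number of rows")
    if isinstance(D, MLP):
        return D(np.concatenate([z, s], axis=1)).reshape(-1)
    return D.logit(z, s)


def ism_estimate(D, z: np.ndarray, s: np.ndarray) -> float:
    """Density-ratio MI estimate: mean logit over joint (z, s) rows, in nats."""
    return float(discriminator_logit(D, z, s).mean())


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    # stable log(sigmoid(x)) = -softplus(-x)
    return -np.logaddexp(0.0, -x)


def discriminator_bce(D, z_joint: np.ndarray, s_joint: np.ndarray,
                      s_shuffled: np.ndarray) -> float:
    """Binary cross-entropy: joint pairs labeled 1, shuffled pairs labeled 0."""
    if z_joint.shape[0] < 2:
        raise ValueError("discriminator training needs a batch of >= 2 rows")
    lp = discriminator_logit(D, z_joint, s_joint)
    ln = discriminator_logit(D, z_joint, s_shuffled)
    return float(-(_log_sigmoid(lp).mean() + _log_sigmoid(-ln).mean()) / 2.0)


def total_layer_loss(icm: float, recon: float, ism: float,
                     lambda_: float = DEFAULT_LAMBDA,
                     beta: float = DEFAULT_BETA) -> LossBreakdown:
    """Composite minimized objective; breakdown returned for logging."""
    for name, v in (("icm", icm), ("recon", recon), ("ism", ism)):
        if not np.isfinite(v):
            raise ValueError(f"non-finite {name} component: {v}")
    return LossBreakdown(float(icm), float(recon), float(ism),
                         float(lambda_), float(beta))
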
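"""Disentanglement and feature-quality metrics.

Block total correlation (TC) over the per-layer codes z^1..z^n — zero iff
the blocks are mutually independent, lower = more disentangled — with a
Gaussian-moment estimator (exact closed form under normality) and a
nearest-neighbor entropy-sum estimator as an assumption-free alternative.
The mutual information gap (MIG) scores how exclusively each ground-truth
factor is captured by a single latent. The discrimination value is the
accuracy drop Acc(C1) - Acc(Ci) when one z-block is removed from the
feature combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log, pi

import numpy as np
from scipy.special import digamma
from sklearn.neighbors import NearestNeighbors

__all__ = ["MetricReport", "tc_gaussian_closed_form", "tc_estimate", "mig",
           "discrimination", "gap_report"]


@dataclass
class MetricReport:
    """Row of the evaluation surface: TC / MIG / accuracy / discrimination."""

    method: str
    tc: float | None = None
    mig: float | None = None
    accuracy: tuple[float, float] | None = None   # mean, sd
    discrimination: dict[str, float] | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dict(method=self.method, tc=self.tc, mig=self.mig,
                 discrimination=self.discrimination, **self.metadata)
        if self.accuracy is not None:
            d["accuracy_mean"], d["accuracy_sd"] = self.accuracy
        return d


def tc_gaussian_closed_form(cov: np.ndarray,
                            block_sizes: list[int] | None = None) -> float:
    """TC of a Gaussian in nats: 0.5 * (sum of block log-dets - full log-det).

    With no blocks given, every coordinate is its own block (the classic
    sum-of-marginal-entropies form).
    """
    cov = np.asarray(cov, dtype=float)
    d = cov.shape[0]
    if cov.shape != (d, d) or not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("cov must be a symmetric matrix")
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0 or np.min(np.linalg.eigvalsh(cov)) <= 0:
        raise ValueError("cov must be positive definite")
    if block_sizes is None:
        block_sizes = [1] * d
    if sum(block_sizes) != d:
        raise ValueError("block sizes must sum to the dimension")
    total = 0.0
    at = 0
    for b in block_sizes:
        sub = cov[at:at + b, at:at + b]
        total += np.linalg.slogdet(sub)[1]
        at += b
    return float(0.5 * (total - logdet))


def _knn_entropy(x: np.ndarray, k: int = 3) -> float:
    """Kozachenko-Leonenko differential entropy estimate, nats."""
    n, d = x.shape
    if n <= k:
        raise ValueError(f"need more than k={k} samples, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist, _ = nn.kneighbors(x)
    eps = np.maximum(dist[:, k], 1e-300)
    log_ball = d / 2.0 * log(pi) - lgamma(d / 2.0 + 1.0)
    return float(digamma(n) - digamma(k) + log_ball + d * np.mean(np.log(eps)))


def tc_estimate(samples: np.ndarray, block_sizes: list[int],
                method: str = "gaussian", k: int = 3) -> float:
    """Estimate block TC from samples, in nats.

    gaussian: fit the sample covariance, apply the closed form.
    knn: sum of block entropies minus the joint entropy, each from the
    nearest-neighbor estimator.
    """
    samples = np.asarray(samples, dtype=float)
    n, d = samples.shape
    if sum(block_sizes) != d:
        raise ValueError("block sizes must sum to the sample dimension")
    if n <= d:
        raise ValueError("need more samples than dimensions")
    if method == "gaussian":
        cov = np.cov(samples, rowvar=False).reshape(d, d)
        return tc_gaussian_closed_form(cov, block_sizes)
    if method == "knn":
        if n < 10 * (k + 1):
            raise ValueError("too few samples for the knn estimator")
        total = -_knn_entropy(samples, k)
        at = 0
        for b in block_sizes:
            total += _knn_entropy(samples[:, at:at + b], k)
            at += b
        return float(total)
    raise ValueError(f"unknown TC estimation method {method!r}")


def _equal_freq_bins(col: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin indices; already-discrete columns pass through."""
    uniq = np.unique(col)
    if uniq.size <= n_bins:
        return np.searchsorted(uniq, col)
    edges = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, col, side="right")


def _discrete_mi(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information between two integer-coded columns, nats."""
    joint = np.zeros((a.max() + 1, b.max() + 1))
    np.add.at(joint, (a, b), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def _discrete_entropy(a: np.ndarray) -> float:
    p = np.bincount(a).astype(float)
    p = p[p > 0] / p.sum()
    return float(-(p * np.log(p)).sum())


def mig(latents: np.ndarray, factors: np.ndarray, n_bins: int = 20) -> float:
    """Mutual information gap in [0, 1]; higher = more disentangled.

    Latents (and continuous factors) are discretized into equal-frequency
    bins; for each factor, the normalized gap between its two most
    informative latents is averaged over factors.
    """
    latents = np.asarray(latents, dtype=float)
    factors = np.asarray(factors, dtype=float)
    n, d = latents.shape
    K = factors.shape[1]
    if d < 2:
        raise ValueError("MIG needs at least two latents")
    if n < 10 * n_bins:
        raise ValueError("too few samples for the chosen bin count")
    lat_binned = [_equal_freq_bins(latents[:, j], n_bins) for j in range(d)]
    total = 0.0
    for kf in range(K):
        v = _equal_freq_bins(factors[:, kf], n_bins)
        hv = _discrete_entropy(v)
        mis = sorted((_discrete_mi(lb, v) for lb in lat_binned), reverse=True)
        if hv > 0:
            total += (mis[0] - mis[1]) / hv
    return float(np.clip(total / K, 0.0, 1.0))


def discrimination(acc_by_combo: dict[str, float]) -> dict[str, float]:
    """Disc(Ci) = Acc(C1) - Acc(Ci); Disc(C1) = 0 by definition."""
    if "C1" not in acc_by_combo:
        raise ValueError("discrimination requires the full combination C1")
    base = acc_by_combo["C1"]
    return {combo: float(base - acc) for combo, acc in acc_by_combo.items()}


def gap_report(table: dict, designated: str | None = None) -> dict[str, float]:
    """Lead-over-runner-up gaps across methods.

    For a {method: (tc, mig)} table: tc_gap = second-lowest TC minus lowest,
    mig_gap = highest MIG minus second-highest. For a {method: accuracy}
    table: acc_gap = highest accuracy minus the designated method's (or the
    runner-up's, when the designated method leads). Ties report 0.
    """
    if len(table) < 2:
        raise ValueError("gap_report needs at least two methods")
    values = list(table.values())
    if isinstance(values[0], (tuple, list)):
        tcs = sorted(v[0] for v in values)
        migs = sorted((v[1] for v in values), reverse=True)
        return {"tc_gap": float(tcs[1] - tcs[0]),
                "mig_gap": float(migs[0] - migs[1])}
    accs = sorted(values, reverse=True)
    if designated is not None:
        ours = table[designated]
        best = max(v for k, v in table.items() if k != designated)
        return {"acc_gap": float(max(best, ours) - ours)}
    return {"acc_gap": float(accs[0] - accs[1])}
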
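"""Total correlation, MIG, discrimination and gap-report oracles."""

import numpy as np
import pytest

import lfea


# ------------------------------------------------------------ TC closed form

def test_tc_closed_form_reference_values():
    assert lfea.tc_gaussian_closed_form(np.eye(5)) == pytest.approx(0.0)
    cov2 = np.array([[1.0, 0.9], [0.9, 1.0]])
    assert lfea.tc_gaussian_closed_form(cov2) == pytest.approx(
        -0.5 * np.log(0.19), rel=1e-12)
    cov3 = np.full((3, 3), 0.5) + 0.5 * np.eye(3)  # equicorrelated rho=0.5
    assert lfea.tc_gaussian_closed_form(cov3) == pytest.approx(
        -0.5 * np.log(0.5), rel=1e-12)  # det = (1-rho)^2 (1+2rho) = 0.5


def test_tc_closed_form_rejects_non_pd():
    with pytest.raises(ValueError):
        lfea.tc_gaussian_closed_form(np.array([[1.0, 2.0], [2.0, 1.0]]))


def _mvn(cov, n, seed):
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov)
    return rng.standard_normal((n, cov.shape[0])) @ L.T


def test_tc_gaussian_estimator_matches_closed_form():
    cov = np.array([[1.0, 0.9], [0.9, 1.0]])
    x = _mvn(cov, 50000, seed=0)
    est = lfea.tc_estimate(x, [1, 1], method="gaussian")
    assert est == pytest.approx(-0.5 * np.log(0.19), rel=0.05)


def test_tc_of_independently_shuffled_blocks_is_near_zero():
    cov = np.array([[1.0, 0.9], [0.9, 1.0]])
    x = _mvn(cov, 50000, seed=1)
    rng = np.random.default_rng(2)
    x[:, 1] = x[rng.permutation(len(x)), 1]  # break the dependence
    assert abs(lfea.tc_estimate(x, [1, 1], method="gaussian")) < 0.05


def _random_block_cov(d, seed):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((d, d + 8))
    cov = A @ A.T / (d + 8)
    s = np.sqrt(np.diag(cov))
    return cov / np.outer(s, s)


def test_knn_and_gaussian_estimators_agree_on_normal_data():
    cov = _random_block_cov(8, seed=3)
    x = _mvn(cov, 50000, seed=4)
    blocks = [2, 2, 2, 2]
    g = lfea.tc_estimate(x, blocks, method="gaussian")
    k = lfea.tc_estimate(x, blocks, method="knn")
    assert k == pytest.approx(g, rel=0.10)


def test_gaussian_estimator_error_shrinks_with_n():
    cov = np.array([[1.0, 0.8], [0.8, 1.0]])
    truth = lfea.tc_gaussian_closed_form(cov)
    errs = []
    for n in (5000, 50000):
        x = _mvn(cov, n, seed=5)
        errs.append(abs(lfea.tc_estimate(x, [1, 1]) - truth))
    assert errs[1] < errs[0]


def test_tc_invariant_under_sample_and_block_permutations():
    cov = _random_block_cov(4, seed=6)
    x = _mvn(cov, 20000, seed=7)
    base = lfea.tc_estimate(x, [2, 2])
    rng = np.random.default_rng(8)
    rowperm = lfea.tc_estimate(x[rng.permutation(len(x))], [2, 2])
    within = lfea.tc_estimate(x[:, [1, 0, 3, 2]], [2, 2])
    assert rowperm == pytest.approx(base, rel=1e-9)
    assert within == pytest.approx(base, rel=1e-9)


# ------------------------------------------------------------ MIG

def _mig_bruteforce(latents, factors, n_bins=20):
    """Independent re-implementation: histogram-based MI on quantile bins."""
    n, d = latents.shape
    K = factors.shape[1]

    def bins(col):
        u = np.unique(col)
        if u.size <= n_bins:
            return np.searchsorted(u, col)
        qs = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
        return np.searchsorted(qs, col, side="right")

    def mi(a, b):
        tbl, _, _ = np.histogram2d(a, b, bins=[np.arange(a.max() + 2) - 0.5,
                                               np.arange(b.max() + 2) - 0.5])
        tbl /= tbl.sum()
        pa, pb = tbl.sum(1), tbl.sum(0)
        out = 0.0
        for i in range(tbl.shape[0]):
            for j in range(tbl.shape[1]):
                if tbl[i, j] > 0:
                    out += tbl[i, j] * np.log(tbl[i, j] / (pa[i] * pb[j]))
        return out

    score = 0.0
    for k in range(K):
        v = bins(factors[:, k])
        pv = np.bincount(v).astype(float)
        pv = pv[pv > 0] / pv.sum()
        hv = -(pv * np.log(pv)).sum()
        mis = sorted((mi(bins(latents[:, j]), v) for j in range(d)),
                     reverse=True)
        score += (mis[0] - mis[1]) / hv
    return float(np.clip(score / K, 0, 1))


def test_perfect_code_scores_near_one():
    rng = np.random.default_rng(10)
    factors = rng.integers(8, size=(5000, 3)).astype(float)
    noise = rng.standard_normal((5000, 2))
    latents = np.concatenate([factors, noise], axis=1)
    assert lfea.mig(latents, factors) >= 0.95


def test_duplicated_latent_kills_the_gap():
    rng = np.random.default_rng(11)
    v = rng.integers(8, size=(5000, 1)).astype(float)
    latents = np.concatenate([v, v, rng.standard_normal((5000, 1))], axis=1)
    assert lfea.mig(latents, v) == pytest.approx(0.0, abs=0.02)


def test_mig_agrees_with_bruteforce_reimplementation():
    rng = np.random.default_rng(12)
    factors = rng.uniform(size=(20000, 3))
    latents = np.concatenate(
        [factors + 0.1 * rng.standard_normal((20000, 3)),
         rng.standard_normal((20000, 2))], axis=1)
    ours = lfea.mig(latents, factors)
    brute = _mig_bruteforce(latents, factors)
    assert ours == pytest.approx(brute, abs=0.02)
    assert ours > 0.2  # the noisy copy is clearly disentangled


def test_mig_invariant_under_monotone_latent_transform():
    rng = np.random.default_rng(13)
    factors = rng.uniform(size=(20000, 2))
    latents = np.concatenate(
        [factors + 0.2 * rng.standard_normal((20000, 2)),
         rng.standard_normal((20000, 1))], axis=1)
    base = lfea.mig(latents, factors)
    warped = latents.copy()
    warped[:, 0] = np.exp(warped[:, 0])        # strictly increasing
    warped[:, 1] = np.arctan(warped[:, 1])     # strictly increasing, bounded
    # equal-frequency binning makes MIG rank-based, up to boundary ties
    assert lfea.mig(warped, factors) == pytest.approx(base, abs=0.01)


def test_mig_needs_two_latents():
    with pytest.raises(ValueError):
        lfea.mig(np.zeros((1000, 1)), np.zeros((1000, 1)))


# ------------------------------------------------------------ discrimination

def test_discrimination_definition_and_reference_row():
    accs = {"C1": 0.79, "C2": 0.72, "C3": 0.74, "C4": 0.53, "C5": 0.61}
    disc = lfea.discrimination(accs)
    assert disc["C1"] == 0.0
    assert disc["C4"] == pytest.approx(0.26)
    assert disc["C2"] == pytest.approx(0.07)
    same = lfea.discrimination({"C1": 0.6, "C2": 0.6})
    assert same["C2"] == 0.0
    with pytest.raises(ValueError):
        lfea.discrimination({"C2": 0.5})


def test_discrimination_invariant_to_common_accuracy_shift():
    accs = {"C1": 0.79, "C2": 0.72, "C4": 0.53}
    shifted = {k: v + 0.1 for k, v in accs.items()}
    assert lfea.discrimination(accs) == lfea.discrimination(shifted)


# ------------------------------------------------------------ gap report

def test_gap_report_on_disentanglement_table():
    table = {"ours": (12.3, 0.72), "vae": (23.6, 0.54),
             "beta_vae": (25.8, 0.61), "pca": (18.5, 0.49)}
    gaps = lfea.gap_report(table)
    assert gaps["tc_gap"] == pytest.approx(6.2)
    assert gaps["mig_gap"] == pytest.approx(0.11)


def test_gap_report_ties_and_errors():
    assert lfea.gap_report({"a": (1.0, 0.5), "b": (1.0, 0.5)}) == {
        "tc_gap": 0.0, "mig_gap": 0.0}
    with pytest.raises(ValueError):
        lfea.gap_report({"only": (1.0, 0.5)})


def test_gap_report_accuracy_with_designated_method():
    table = {"ours": 75.2, "best": 75.4, "worst": 61.1}
    assert lfea.gap_report(table, designated="ours")["acc_gap"] == \
        pytest.approx(0.2)
    # when the designated method leads, the gap is zero
    assert lfea.gap_report(table, designated="best")["acc_gap"] == 0.0
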
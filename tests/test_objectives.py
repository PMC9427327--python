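"""Analytic oracles for the compression, expression and separation losses."""

import numpy as np
import pytest

import lfea
from lfea._nn import MLP, Adam
from lfea.model import GaussianPosterior
from lfea.objectives import _log_sigmoid


# ------------------------------------------------------------ compression

def test_kl_closed_form_values():
    zero = GaussianPosterior(np.zeros((3, 4)), np.zeros((3, 4)))
    assert lfea.icm_loss(zero) == pytest.approx(0.0)
    one = GaussianPosterior(np.ones((1, 1)), np.zeros((1, 1)))
    assert lfea.icm_loss(one) == pytest.approx(0.5)
    wide = GaussianPosterior(np.zeros((1, 1)), np.full((1, 1), np.log(4.0)))
    assert lfea.icm_loss(wide) == pytest.approx(0.5 * (4 - 1 - np.log(4)))


def test_kl_matches_monte_carlo():
    # KL(N(0,4) || N(0,1)) via a 1e5-draw log-density-ratio average
    rng = np.random.default_rng(0)
    x = rng.normal(0.0, 2.0, 100000)
    log_q = -0.5 * np.log(2 * np.pi * 4) - x ** 2 / 8
    log_p = -0.5 * np.log(2 * np.pi) - x ** 2 / 2
    mc = (log_q - log_p).mean()
    post = GaussianPosterior(np.zeros((1, 1)), np.full((1, 1), np.log(4.0)))
    assert lfea.icm_loss(post) == pytest.approx(mc, rel=0.02)


def test_kl_nonnegative_over_random_posteriors():
    rng = np.random.default_rng(1)
    for _ in range(20):
        post = GaussianPosterior(rng.standard_normal((5, 3)),
                                 rng.uniform(-3, 3, (5, 3)))
        assert lfea.icm_loss(post) >= 0.0


def test_icm_upper_bounds_true_mi_linear_gaussian():
    """Toy encoder h = a*s + noise(sigma): the variational bound
    0.5*(a^2 + sigma^2 - 1 - ln sigma^2) must dominate the exact
    I(S;H) = 0.5*ln(1 + a^2/sigma^2), with equality iff a^2+sigma^2=1."""
    rng = np.random.default_rng(2)
    s = rng.standard_normal((200000, 1))
    for a in (0.1, 0.5, 0.6, 1.0, 2.0):
        for sigma in (0.3, 0.6, 0.8, 1.0, 1.5):
            post = GaussianPosterior(a * s, np.full_like(s, 2 * np.log(sigma)))
            upper = lfea.icm_loss(post)
            true_mi = 0.5 * np.log(1 + a ** 2 / sigma ** 2)
            assert upper >= true_mi - 1e-3
            if abs(a ** 2 + sigma ** 2 - 1.0) < 1e-12:
                assert upper == pytest.approx(true_mi, abs=5e-3)


# ------------------------------------------------------------ expression

def test_reconstruction_loss_values_and_homogeneity():
    x = np.zeros((1, 1))
    assert lfea.iem_loss(x, x) == 0.0
    assert lfea.iem_loss(np.array([[0.0]]), np.array([[2.0]])) == pytest.approx(2.0)
    rng = np.random.default_rng(3)
    a, b = rng.standard_normal((4, 6)), rng.standard_normal((4, 6))
    assert lfea.iem_loss(a, a + 3 * (b - a)) == pytest.approx(9 * lfea.iem_loss(a, b))
    with pytest.raises(ValueError):
        lfea.iem_loss(np.zeros((2, 3)), np.zeros((3, 2)))


# ------------------------------------------------------------ separation

def _bivariate(rho, n, seed):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 1))
    s = rho * z + np.sqrt(1 - rho ** 2) * rng.standard_normal((n, 1))
    return z, s


def _optimal_logit(rho):
    def fn(z, s):
        z, s = z[:, 0], s[:, 0]
        return (-0.5 * np.log(1 - rho ** 2)
                - (rho ** 2 * (z ** 2 + s ** 2) - 2 * rho * z * s)
                / (2 * (1 - rho ** 2)))
    return lfea.AnalyticDiscriminator(fn)


@pytest.mark.parametrize("rho", [0.0, 0.5, 0.8, 0.9])
def test_ism_estimate_matches_gaussian_mi(rho):
    z, s = _bivariate(rho, 100000, seed=10)
    est = lfea.ism_estimate(_optimal_logit(rho), z, s)
    truth = -0.5 * np.log(1 - rho ** 2)
    assert est == pytest.approx(truth, abs=0.02)


def test_ism_invariant_under_joint_row_permutation():
    z, s = _bivariate(0.8, 1000, seed=11)
    perm = np.random.default_rng(0).permutation(1000)
    D = _optimal_logit(0.8)
    assert lfea.ism_estimate(D, z, s) == pytest.approx(
        lfea.ism_estimate(D, z[perm], s[perm]))


def test_fresh_discriminator_outputs_finite_logits():
    D = MLP((4, 8, 1), np.random.default_rng(0))
    z, s = np.ones((5, 2)), np.ones((5, 2))
    logits = lfea.discriminator_logit(D, z, s)
    assert logits.shape == (5,) and np.all(np.isfinite(logits))
    perm = [4, 2, 0, 1, 3]
    zp, sp = z.copy(), s.copy()
    zp[0, 0] = 7.0
    lp = lfea.discriminator_logit(D, zp[perm], sp[perm])
    assert np.allclose(lp, lfea.discriminator_logit(D, zp, sp)[perm])


def test_uninformative_discriminator_bce_is_ln2():
    D = lfea.AnalyticDiscriminator(lambda z, s: np.zeros(len(z)))
    z, s = _bivariate(0.5, 100, seed=12)
    s_shuf = s[::-1].copy()
    assert lfea.discriminator_bce(D, z, s, s_shuf) == pytest.approx(np.log(2))


def test_bce_symmetric_under_class_swap():
    D = _optimal_logit(0.6)
    z, s = _bivariate(0.6, 500, seed=13)
    s_shuf = s[np.random.default_rng(1).permutation(500)]
    lp = lfea.discriminator_logit(D, z, s)
    ln = lfea.discriminator_logit(D, z, s_shuf)
    direct = lfea.discriminator_bce(D, z, s, s_shuf)
    # swap the classes (shuffled pairs positive, joint negative) and negate
    # the logits: the cross-entropy must be unchanged
    swapped = float(-(_log_sigmoid(-ln).mean()
                      + _log_sigmoid(lp).mean()) / 2.0)
    assert direct == pytest.approx(swapped)


def test_trained_discriminator_separates_toy_pairs():
    """An MLP discriminator fit on clearly separable joint vs shuffled pairs
    reaches BCE < 0.1 (trained with the same backprop path as the model)."""
    rng = np.random.default_rng(14)
    n = 512
    z = rng.standard_normal((n, 1))
    s = z + 0.01 * rng.standard_normal((n, 1))  # near-copy: highly dependent
    D = MLP((2, 32, 32, 1), rng)
    opt = Adam(D.params, lr=1e-2)
    for _ in range(800):
        s_shuf = s[rng.permutation(n)]
        stacked = np.concatenate([np.concatenate([z, s], axis=1),
                                  np.concatenate([z, s_shuf], axis=1)])
        logits, cache = D.forward(stacked)
        logits = logits.reshape(-1)
        p = 1 / (1 + np.exp(-logits))
        grad = np.concatenate([(p[:n] - 1) / (2 * n), p[n:] / (2 * n)])
        grads, _ = D.backward(cache, grad.reshape(-1, 1))
        opt.step(grads)
    final = lfea.discriminator_bce(D, z, s, s[rng.permutation(n)])
    assert final < 0.1


# ------------------------------------------------------------ composite

def test_composite_arithmetic():
    lb = lfea.total_layer_loss(1.0, 2.0, 3.0, lambda_=0.1, beta=0.2)
    assert lb.total == pytest.approx(1.8)
    assert lfea.total_layer_loss(1.0, 2.0, 3.0, 0.0, 0.0).total == 1.0
    defaults = lfea.total_layer_loss(0.0, 0.0, 0.0)
    assert defaults.lambda_ == 0.1 and defaults.beta == 0.2
    with pytest.raises(ValueError):
        lfea.total_layer_loss(np.nan, 0.0, 0.0)


def test_losses_are_batch_size_independent():
    rng = np.random.default_rng(15)
    post = GaussianPosterior(rng.standard_normal((8, 3)),
                             rng.uniform(-1, 1, (8, 3)))
    doubled = GaussianPosterior(np.tile(post.mean, (2, 1)),
                                np.tile(post.log_var, (2, 1)))
    assert lfea.icm_loss(post) == pytest.approx(lfea.icm_loss(doubled))
    x, xh = rng.standard_normal((8, 4)), rng.standard_normal((8, 4))
    assert lfea.iem_loss(x, xh) == pytest.approx(
        lfea.iem_loss(np.tile(x, (2, 1)), np.tile(xh, (2, 1))))
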
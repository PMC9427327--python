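# Methods

## Model and objectives

The model is a greedy stack of variational encoder layers over flattened
sEMG windows. Layer *i* maps the previous residual `s^{i-1}` (layer 1 reads
the window itself) to a diagonal-Gaussian posterior over a code `h^i`,
sampled with the reparameterization `h = μ + exp(log σ²/2)·ε`. The code is
split positionally — `z^i` is the first `z_dim` coordinates, `s^i` the
remainder — and a per-layer decoder maps `z^i` back to the original window,
never to the intermediate residual. Per layer, three losses are combined as
`total = icm + λ·recon + β·ism`:

- **icm** — the closed-form KL between the posterior and a standard-normal
  prior, averaged over the batch. It upper-bounds the mutual information
  between the layer input and its code, with slack equal to the KL between
  the aggregate posterior and the prior; the linear-Gaussian bound test
  verifies the domination numerically over a grid of encoder gains.
- **recon** — mean of `½‖x − x̂‖²`. Under a unit-variance Gaussian decoder
  likelihood this equals (up to an additive constant) the negative of the
  variational lower bound on `I(z; X)`; constants are dropped as they carry
  no gradient.
- **ism** — the density-ratio estimate of `I(z; s)`: the mean logit of a
  discriminator over joint `(z, s)` rows. The discriminator is trained by
  binary cross-entropy against negatives built by shuffling `s` across the
  batch (an unbiased sample from the product of marginals); the
  encoder/decoder step then minimizes the estimate with the discriminator
  held fixed. Although the separation principle is stated as a quantity to
  drive down, its estimator is adversarial: the discriminator ascends, the
  encoder descends.

Training is strictly layer-wise: before layer *i* is trained, layers below
produce `s^{i-1}` in mean mode in a single detached forward pass, so no
gradient can traverse a frozen layer and their parameters are bit-identical
before and after (asserted in tests). Mean mode for frozen layers
stabilizes the targets the upper layer sees; the current layer always
samples, as the reparameterized noise is what gives the KL term its
regularizing effect.

## Defaults and their rationale

| parameter | default | note |
|---|---|---|
| layers / z width | 4 / 5 | canonical configuration for (200, 12) windows |
| λ, β | 0.1, 0.2 | loss weights of the composite objective |
| h widths | 64, 32, 16, 10 | monotone compression; residual widths 59, 27, 11, 5 |
| encoder hidden | (256, 128) first layer, (64,) later | smallest bodies that train well on CPU |
| nonlinearity | leaky rectifier, slope 0.2 | |
| optimizer | Adam, 1e-3 model / 1e-4 discriminator | smaller discriminator rate for adversarial stability; see the caveat below |
| epochs per layer / batch | 50 / 128 | fixed budget, no early stopping, for reproducibility |
| log-variance clamp | ±10 | numerical safety of `exp` |
| windowing | 200 samples, stride 100, majority label (ties → smallest id) | 200 ms at 1 kHz; half-open 0-based intervals |
| filter | zero-phase Butterworth, order 4 | cutoff is a mandatory parameter — there is no defensible universal default |
| standardization | per-channel z-scoring before the model | the Gaussian-prior KL is scale-sensitive |

All neural components (dense networks, backprop, Adam) are implemented in
numpy with explicit forward caches; gradient flow is composed by hand and
validated against central finite differences. This keeps the adversarial
step exact: the discriminator update never touches encoder parameters and
the encoder's separation gradient treats the discriminator as a fixed
function.

## Synthetic generator

The generator produces windows from K ≤ 4 independent uniform factors:
burst amplitude (gain 0.5 + 1.5·v₁), envelope onset (v₂·T/2), envelope
width (T/8 + v₃·T/4) and a cosine channel-gain profile with phase v₄·π.
The carrier is a single band-limited noise realization per dataset (white
noise through the same zero-phase Butterworth used in preprocessing,
normalized to unit RMS per channel); per-window sensor noise is additive
white Gaussian. Keeping one carrier per dataset is deliberate: it places
the factor structure in the conditional mean of the window, which a
squared-error decoder can learn. With an independent stochastic carrier
per window the conditional mean is identically zero and *no*
reconstruction-based method can retain amplitude information — a
fundamental property of mean-square objectives on amplitude-modulated
zero-mean noise, and the reason real sEMG pipelines often work on
rectified or enveloped signals.

Consequences for interpretation: the synthetic data are far simpler than
real sEMG — no motor-unit structure, no electrode crosstalk beyond the
smooth gain profile, no within-class waveform variability beyond sensor
noise. Passing tests demonstrate that the machinery optimizes what it
claims to optimize and that the pipeline recovers planted structure; they
say nothing about accuracy on real recordings.

Gesture datasets draw the class uniformly and then sample factors from
per-gesture Beta distributions (concentration 20) whose means sit on a
per-factor permuted grid `(g + 0.5)/G`, keeping factors conditionally
independent while making classes separable (a linear classifier on
per-channel RMS exceeds 0.8 accuracy at the default window shape).

## Metrics

Block total correlation is reported in nats. The Gaussian-moment estimator
applies the exact identity `TC = ½(Σ_b ln det Σ_bb − ln det Σ)` to the
sample covariance; the alternative nearest-neighbor estimator sums
Kozachenko–Leonenko block entropies minus the joint entropy (k = 3). Both
are exposed and the choice is recorded, as the appropriate estimator for
strongly non-Gaussian codes is an open question. MIG uses 20
equal-frequency bins and plug-in discrete mutual information, normalized
by the factor entropy and clipped to [0, 1]; it requires an explicit
factor matrix. The discrimination value of a feature combination is
`Acc(C1) − Acc(Ci)` from an RBF-SVM (C = 1, scaled gamma) under repeated
stratified 2/3–1/3 splits, or repetition-wise hold-out when repetition ids
exist.

## Desk-scale study and a known limitation

The bundled study (tests and `scripts/acceptance.py`) runs at a reduced
scale chosen so the full pipeline is exercised in minutes on one CPU:
windows of 50 samples × 4 channels, h widths (16, 12, 10, 8), z width 2,
20 epochs per layer, n = 5000 factor windows and n = 2000 five-gesture
windows, medians over three seeds.

At this scale the classification claims hold comfortably (median SVM
accuracy on the full combination ≈ 0.95; dropping the most predictive
layer produces by far the largest discrimination value). The separation
ablation does **not** reproduce the full-scale ordering: median block TC
with β = 0.2 comes out slightly *higher* (≈ 0.12) than with β = 0
(≈ 0.085). The diagnosis is instructive: at input dimension 200 the KL
term dominates the fixed λ = 0.1 reconstruction weight, posterior
variances stay near 1, and the *sampled* `(z, s)` pairs the discriminator
sees are already nearly independent (≈ 0.003 nats) — the adversarial term
has no signal and its gradient only perturbs a mean-code solution whose
block TC is already near the estimator floor. Raising the discriminator
rate to 1e-3 (so it at least calibrates) or scaling λ with dimension
narrows but does not reverse the gap. The separation machinery itself is
validated independently: with the analytically optimal discriminator the
estimator recovers closed-form Gaussian mutual information to Monte-Carlo
precision, and a trained discriminator separates genuinely dependent toy
pairs. The β ablation should therefore be read as meaningful only in
regimes where the representation retains enough information for block
dependence to be material — large windows, weaker relative compression —
not at this desk scale.

## Degenerate inputs and numerical choices

Zero-variance channels, non-finite cells, cutoffs at or above Nyquist,
windows longer than the recording, inconsistent layer widths, out-of-order
layer training and non-finite losses all raise distinct named errors.
Majority window labels break ties toward the smallest id. All randomness
flows through explicit `numpy` generators seeded from user-supplied
integers; identical seeds give bit-identical models, histories and
datasets on the same platform.
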
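# lfea — layer-wise information-theoretic feature extraction for sEMG

`lfea` learns disentangled, unsupervised features from fixed-size windows of
multichannel surface electromyography (sEMG). It is aimed at researchers in
myoelectric control and neurophysiological signal processing who want
compact window representations for gesture classification without labels at
training time.

## The model

A window `X` (time × channels, canonically 200 × 12, flattened) is passed
through a stack of stochastic layers. Layer *i* compresses the previous
residual `s^{i-1}` (with `s^0 = X`) into a diagonal-Gaussian code
`h^i ~ q_φi(h^i | s^{i-1})`, splits it into an expressive block `z^i` and a
residual block `s^i`, and decodes `z^i` back to the **original** window.
Each layer is trained greedily (earlier layers frozen) by minimizing

```
L  =  KL(q_φ(h|s) ‖ N(0, I))  +  λ · ½‖X − dec_θ(z)‖²  +  β · Î(z; s)
```

with defaults λ = 0.1, β = 0.2 and 4 layers of `z` width 5. The three terms
enforce, in order: *compression* (a variational upper bound on
`I(S^{i-1}; H^i)`), *expression* (a variational lower bound on `I(z^i; X)`
under a unit-variance Gaussian decoder), and *separation* — `Î(z; s)` is a
density-ratio estimate of `I(z^i; s^i)`, the mean logit of an adversarially
trained discriminator that tells joint `(z, s)` rows from rows with `s`
shuffled across the batch. The extracted feature is
`Z = (z^1, z^2, z^3, z^4)` (posterior means).

The package also ships the evaluation surface: block total correlation
(Gaussian-moment and nearest-neighbor estimators), the mutual information
gap (MIG), an RBF-SVM classification harness, the C1–C5 layer-ablation
study with its discrimination score `Acc(C1) − Acc(Ci)`, a PCA baseline,
and a synthetic generator of factor-structured burst windows with known
independent ground-truth factors.

## Worked example

```
lfea simulate --n 2000 --gestures 5 --t 50 --c 4 --noise-sd 0.05 --seed 1 --out ds.h5
lfea train --config cfg.yaml --data ds.h5 --out run --seed 0
lfea classify --model run/model.h5 --data ds.h5 --combo C1 --repeats 3
```

with `cfg.yaml` holding the reduced desk-scale architecture
(`h_dims: [16, 12, 10, 8]`, `z_dim: 2`, `epochs_per_layer: 20`). The last
command prints

```
C1: accuracy 0.924 +/- 0.009 over 3 splits
```

i.e. an RBF-SVM on the 8-dimensional concatenated `Z` separates the five
synthetic gestures with 92% accuracy. The same library calls are available
in Python (`lfea.make_gesture_dataset`, `lfea.fit`,
`lfea.extract_features`, `lfea.classify_svm`).

Gap reports over published method-comparison tables:

```
lfea report --table table.csv
tc_gap = 6.2
mig_gap = 0.11
```

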
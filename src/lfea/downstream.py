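"""Downstream evaluation: SVM gesture classification and layer-ablation study.

The extracted feature is the concatenation of z-blocks selected by a
feature combination: C1 = (z1,z2,z3,z4), C2 = (z2,z3,z4), C3 = (z1,z3,z4),
C4 = (z1,z2,z4), C5 = (z1,z2,z3). Classifying each combination and
comparing to C1 measures how much task information each dropped block
carried. A PCA score baseline on the raw windows is included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .metrics import discrimination
from .model import LFEAModel, forward_extract
from .signals import WindowSet

__all__ = ["FeatureCombo", "SplitSpec", "COMBOS", "extract_features",
           "classify_svm", "ablation", "pca_features", "MissingClassError"]


class MissingClassError(ValueError):
    """A class is absent from the train or test side of a split."""


@dataclass(frozen=True)
class FeatureCombo:
    name: str
    layers: tuple[int, ...]  # 1-based layer indices whose z-blocks are used


COMBOS: dict[str, FeatureCombo] = {
    "C1": FeatureCombo("C1", (1, 2, 3, 4)),
    "C2": FeatureCombo("C2", (2, 3, 4)),
    "C3": FeatureCombo("C3", (1, 3, 4)),
    "C4": FeatureCombo("C4", (1, 2, 4)),
    "C5": FeatureCombo("C5", (1, 2, 3)),
}


@dataclass
class SplitSpec:
    """Train/test protocol: repetition-wise hold-out or random stratified.

    "by_repetition" holds out one repetition id of every movement per repeat
    (the 2-train : 1-test convention); it degrades to a random stratified
    train_fraction split when no repetition ids exist.
    """

    mode: str = "random"           # by_repetition | random
    train_fraction: float = 2 / 3
    n_repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("by_repetition", "random"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def extract_features(model: LFEAModel, windows: WindowSet | np.ndarray,
                     combo: FeatureCombo | str = "C1") -> np.ndarray:
    """Mean-mode z-block concatenation for the chosen combination."""
    if isinstance(combo, str):
        combo = COMBOS[combo]
    rep = forward_extract(model, windows, mode="mean")
    return rep.Z(combo.layers)


def _splits(labels: np.ndarray, repetition: np.ndarray | None, spec: SplitSpec):
    rng = np.random.default_rng(spec.seed)
    for r in range(spec.n_repeats):
        if spec.mode == "by_repetition" and repetition is not None:
            reps = np.unique(repetition)
            held_out = reps[r % len(reps)]
            test = repetition == held_out
            yield ~test, test
        else:
            idx_tr, idx_te = train_test_split(
                np.arange(len(labels)), train_size=spec.train_fraction,
                stratify=labels, random_state=int(rng.integers(2 ** 31)))
            tr = np.zeros(len(labels), bool)
            te = np.zeros(len(labels), bool)
            tr[idx_tr] = True
            te[idx_te] = True
            yield tr, te


def classify_svm(features: np.ndarray, labels: np.ndarray,
                 split: SplitSpec | None = None,
                 repetition: np.ndarray | None = None
                 ) -> tuple[float, float]:
    """RBF-kernel SVM accuracy, mean and sd over the repeated splits."""
    split = split or SplitSpec()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("classification needs at least two classes")
    accs = []
    for tr, te in _splits(labels, repetition, split):
        for c in classes:
            side = "train" if c not in labels[tr] else (
                "test" if c not in labels[te] else None)
            if side:
                raise MissingClassError(f"class {c} missing from the {side} split")
        clf = SVC(kernel="rbf", C=1.0, gamma="scale")
        clf.fit(features[tr], labels[tr])
        accs.append(float(np.mean(clf.predict(features[te]) == labels[te])))
    return float(np.mean(accs)), float(np.std(accs))


def ablation(model: LFEAModel, windows: WindowSet, labels: np.ndarray,
             split: SplitSpec | None = None,
             repetition: np.ndarray | None = None
             ) -> dict[str, dict[str, float]]:
    """Accuracy and discrimination for every combination C1..C5."""
    results = {}
    for name, combo in COMBOS.items():
        feats = extract_features(model, windows, combo)
        mean, sd = classify_svm(feats, labels, split, repetition)
        results[name] = {"accuracy": mean, "accuracy_sd": sd}
    disc = discrimination({k: v["accuracy"] for k, v in results.items()})
    for name in results:
        results[name]["discrimination"] = disc[name]
    return results


def pca_features(windows: WindowSet | np.ndarray, d: int = 20,
                 seed: int = 0) -> np.ndarray:
    """Top-d principal-component scores of the flattened windows (baseline)."""
    x = windows.flat() if isinstance(windows, WindowSet) else np.asarray(windows)
    if d > x.shape[1]:
        raise ValueError(f"d={d} exceeds the input dimension {x.shape[1]}")
    if x.shape[0] <= d:
        raise ValueError("need more windows than components")
    return PCA(n_components=d, random_state=seed).fit_transform(x)
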
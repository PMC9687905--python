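"""Evaluation protocol: stratified 4:1 splits, 5-fold hyperparameter
tuning on the training portion only, and metrics aggregated over repeated
splits.

Each dataset (and each class within it) is split 4:1 into train and test;
accuracy, macro F1 and AUC-ROC (one-vs-rest macro for multi-class) are
reported as mean +/- standard deviation over ``n_splits`` seeded repeats.
A master seed derives per-split and per-fold seeds by fixed offsets so any
single split is reproducible in isolation. Test indices never reach tuning
or training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .graph import MolecularGraph
from .model import HBCompareClassifier

DEFAULT_GRID = {
    "lr": [5e-4, 1e-4, 5e-3, 1e-3],
    "batch_size": [1, 2, 4, 8, 16],
    "n_layers": [1, 2, 3, 4, 5, 6],
}


@dataclass
class Hyperparams:
    """Model/training knobs; defaults are batch 4, 3 GCN layers, 50 epochs."""

    lr: float = 1e-3
    batch_size: int = 4
    n_layers: int = 3
    epochs: int = 50
    hidden_dim: int = 64
    concat: bool = True
    seed: int = 0

    def make_classifier(self, random_state: int | None = None) -> HBCompareClassifier:
        return HBCompareClassifier(
            n_layers=self.n_layers,
            hidden_dim=self.hidden_dim,
            lr=self.lr,
            batch_size=self.batch_size,
            epochs=self.epochs,
            concat=self.concat,
            random_state=self.seed if random_state is None else random_state,
        )


@dataclass
class SplitMetrics:
    seed: int
    accuracy: float
    f1: float
    auc_roc: float
    n_correct: int
    n_total: int
    confusion: np.ndarray


@dataclass
class MetricsReport:
    """Per-split metrics plus mean +/- std across splits."""

    splits: list[SplitMetrics] = field(default_factory=list)

    def _col(self, name: str) -> np.ndarray:
        return np.array([getattr(s, name) for s in self.splits])

    @property
    def mean(self) -> dict[str, float]:
        return {m: float(self._col(m).mean()) for m in ("accuracy", "f1", "auc_roc")}

    @property
    def std(self) -> dict[str, float]:
        return {m: float(self._col(m).std(ddof=0)) for m in ("accuracy", "f1", "auc_roc")}

    def summary(self) -> dict:
        return {
            "n_splits": len(self.splits),
            "mean": self.mean,
            "std": self.std,
            "seeds": [s.seed for s in self.splits],
        }

    def to_rows(self) -> list[dict]:
        return [
            {
                "split": i,
                "seed": s.seed,
                "accuracy": s.accuracy,
                "f1": s.f1,
                "auc_roc": s.auc_roc,
                "n_correct": s.n_correct,
                "n_total": s.n_total,
            }
            for i, s in enumerate(self.splits)
        ]


def _derive_seed(master: int, *offsets: int) -> int:
    """Deterministic child seed below 2**31."""
    h = (int(master) * 2654435761) & 0xFFFFFFFFFFFFFFFF
    for k in offsets:
        h = ((h ^ (k + 1)) * 40503) & 0xFFFFFFFFFFFFFFFF
    return h % (2**31 - 1)


def stratified_split(
    labels, train_fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Split each class independently at ``train_fraction`` (default 4:1).

    The test share per class is rounded to nearest with at least one test
    member. Returns (train_indices, test_indices), disjoint and exhaustive,
    deterministic per seed. Singleton classes raise.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has a single member and cannot be split")
        members = rng.permutation(members)
        n_test = max(1, round(len(members) * (1.0 - train_fraction)))
        test_idx.extend(members[:n_test].tolist())
        train_idx.extend(members[n_test:].tolist())
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def train_gcn(
    graphs: list[MolecularGraph], labels, h: Hyperparams | None = None
) -> HBCompareClassifier:
    """Fit the classifier under the given hyperparameters."""
    h = h or Hyperparams()
    return h.make_classifier().fit(graphs, labels)


def predict(model: HBCompareClassifier, g: MolecularGraph):
    """Class label and probability vector for a single graph."""
    proba = model.predict_proba([g])[0]
    return model.classes_[int(np.argmax(proba))], proba


def tune_hyperparams(
    graphs: list[MolecularGraph],
    labels,
    grid: dict | None = None,
    seed: int = 0,
    epochs: int = 50,
    hidden_dim: int = 64,
    concat: bool = True,
    selection: str = "best_fold",
    n_folds: int = 5,
) -> Hyperparams:
    """Grid-search lr/batch/L with stratified k-fold CV on the training set.

    ``selection='best_fold'`` picks the grid point whose single best fold
    accuracy is highest (ties toward better mean, then grid order);
    ``selection='mean'`` keys on mean fold accuracy. Classes with fewer
    members than ``n_folds`` reduce the fold count with a warning.
    """
    if selection not in ("best_fold", "mean"):
        raise ValueError(f"unknown selection rule {selection!r}")
    grid = grid or DEFAULT_GRID
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    k = min(n_folds, int(counts.min()))
    if k < n_folds:
        warnings.warn(
            f"smallest class has {counts.min()} members; reducing folds {n_folds} -> {k}",
            stacklevel=2,
        )
    if k < 2:
        raise ValueError("need at least 2 members per class for cross-validation")

    keys = sorted(grid)
    best_key = None
    best: Hyperparams | None = None
    for combo_id, values in enumerate(product(*(grid[key] for key in keys))):
        params = dict(zip(keys, values))
        h = Hyperparams(
            epochs=epochs,
            hidden_dim=hidden_dim,
            concat=concat,
            seed=_derive_seed(seed, combo_id),
            **params,
        )
        folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=_derive_seed(seed, 9999))
        accs = []
        for fold_id, (tr, va) in enumerate(folds.split(np.zeros(len(labels)), labels)):
            clf = h.make_classifier(random_state=_derive_seed(seed, combo_id, fold_id))
            clf.fit([graphs[i] for i in tr], labels[tr])
            accs.append(accuracy_score(labels[va], clf.predict([graphs[i] for i in va])))
        accs_arr = np.array(accs)
        key = (
            (accs_arr.max(), accs_arr.mean()) if selection == "best_fold" else (accs_arr.mean(),)
        )
        if best_key is None or key > best_key:
            best_key, best = key, h
    assert best is not None
    return best


def _auc(y_true_idx: np.ndarray, proba: np.ndarray, n_classes: int) -> float:
    if n_classes == 2:
        return float(roc_auc_score(y_true_idx, proba[:, 1]))
    return float(
        roc_auc_score(y_true_idx, proba, multi_class="ovr", average="macro", labels=range(n_classes))
    )


def evaluate(
    graphs: list[MolecularGraph],
    labels,
    h: Hyperparams | None = None,
    n_splits: int = 10,
    seed: int = 0,
    tune: bool = False,
    grid: dict | None = None,
    train_fraction: float = 0.8,
) -> MetricsReport:
    """Repeated stratified 4:1 evaluation.

    For each of ``n_splits`` seeded splits: optionally tune on the training
    portion, train, then score the held-out test portion. Reports accuracy,
    macro F1 and AUC-ROC per split with mean and standard deviation.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    h = h or Hyperparams()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    class_index = {c: i for i, c in enumerate(classes)}
    report = MetricsReport()
    for split_id in range(n_splits):
        split_seed = _derive_seed(seed, split_id)
        train_idx, test_idx = stratified_split(labels, train_fraction, seed=split_seed)
        train_graphs = [graphs[i] for i in train_idx]
        train_labels = labels[train_idx]
        if tune:
            h_split = tune_hyperparams(
                train_graphs,
                train_labels,
                grid=grid,
                seed=_derive_seed(seed, split_id, 1),
                epochs=h.epochs,
                hidden_dim=h.hidden_dim,
                concat=h.concat,
            )
        else:
            h_split = h
        clf = h_split.make_classifier(random_state=_derive_seed(seed, split_id, 2))
        clf.fit(train_graphs, train_labels)

        test_graphs = [graphs[i] for i in test_idx]
        y_true = labels[test_idx]
        y_pred = clf.predict(test_graphs)
        proba = clf.predict_proba(test_graphs)
        y_true_idx = np.array([class_index[c] for c in y_true])
        cm = confusion_matrix(y_true, y_pred, labels=classes)
        n_correct = int(np.trace(cm))
        n_total = int(cm.sum())
        report.splits.append(
            SplitMetrics(
                seed=split_seed,
                accuracy=n_correct / n_total,
                f1=float(f1_score(y_true, y_pred, labels=classes, average="macro")),
                auc_roc=_auc(y_true_idx, proba, len(classes)),
                n_correct=n_correct,
                n_total=n_total,
                confusion=cm,
            )
        )
    return report
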
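"""Random-forest classification under single- and cross-instrument protocols.

The classifier is a standard random forest: each of ``n_trees`` decision
trees is grown on a bootstrap resample of the training spectra, choosing at
each node the Gini-optimal split over a random subset of features (sqrt(p)
by default), with leaves holding at least ``min_leaf`` spectra; prediction
is a majority vote across trees. Node impurity is the Gini index
G = sum_k p_k (1 - p_k).

Evaluation protocols mirror the two study designs: a per-class ordered 7:3
split on one instrument (first 70% of each class's spectra in acquisition
order train, the rest test), and a cross-instrument split (one instrument's
full dataset trains, the other's tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureTable

__all__ = [
    "ForestConfig",
    "ForestModel",
    "ClassificationReport",
    "gini_impurity",
    "fit_forest",
    "predict",
    "evaluate",
    "split_protocol",
]


def gini_impurity(p: Sequence[float]) -> float:
    """Gini index G = sum_k p_k (1 - p_k) of a node's class distribution.

    Accepts probabilities (summing to 1) or raw class counts.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities/counts must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("empty node")
    p = p / total
    return float(np.sum(p * (1.0 - p)))


@dataclass
class ForestConfig:
    """Random-forest hyperparameters (500 trees, minimum leaf size 20)."""

    n_trees: int = 500
    min_leaf: int = 20
    seed: int = 0
    features_per_split: str | float = "sqrt"
    bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


@dataclass
class ForestModel:
    """Fitted forest plus the training feature schema (wavelength order)."""

    estimator: RandomForestClassifier
    feature_wavelengths: np.ndarray
    classes: list[str]
    config: ForestConfig


def save_model(model: ForestModel, path) -> None:
    """Persist a fitted forest with a version stamp."""
    import pickle

    from . import __version__

    with open(path, "wb") as fh:
        pickle.dump({"version": __version__, "model": model}, fh)


def load_model(path) -> ForestModel:
    """Load a persisted forest; warns when the package version differs."""
    import pickle

    from . import __version__

    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != __version__:
        import warnings

        warnings.warn(
            f"model saved with version {payload.get('version')}, "
            f"loading under {__version__}"
        )
    return payload["model"]


def fit_forest(train: FeatureTable, cfg: ForestConfig | None = None) -> ForestModel:
    """Fit a random forest on a feature table; deterministic for a fixed seed.

    Class order is the sorted label set; majority-vote ties therefore break
    to the lowest (alphabetically first) class index.
    """
    cfg = cfg or ForestConfig()
    classes = sorted(set(train.labels))
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if not np.all(np.isfinite(train.matrix)):
        raise ValueError("training matrix contains missing/non-finite values")
    est = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        min_samples_leaf=cfg.min_leaf,
        max_features=cfg.features_per_split,
        criterion="gini",
        bootstrap=cfg.bootstrap,
        random_state=cfg.seed,
        n_jobs=1,
    )
    est.fit(train.matrix, np.asarray(train.labels))
    return ForestModel(est, train.wavelengths.copy(), classes, cfg)


def predict(model: ForestModel, test: FeatureTable) -> np.ndarray:
    """Majority-vote predictions; the test schema must match training."""
    if len(test.features) != model.feature_wavelengths.size or not np.allclose(
        test.wavelengths, model.feature_wavelengths, atol=1e-9
    ):
        got = [f"{w:.2f}" for w in test.wavelengths]
        want = [f"{w:.2f}" for w in model.feature_wavelengths]
        raise ValueError(
            f"feature schema mismatch: test columns {got} != training {want}"
        )
    if test.n_spectra == 0:
        return np.array([], dtype=object)
    return model.estimator.predict(test.matrix)


@dataclass
class ClassificationReport:
    """Confusion matrix (rows true, cols predicted) with derived metrics.

    Per-class precision/recall with an empty denominator are reported as
    None (printed "NA"), never propagated as NaN.
    """

    classes: list[str]
    confusion: np.ndarray
    n_evaluated: int
    accuracy: float
    precision: dict[str, float | None] = field(default_factory=dict)
    recall: dict[str, float | None] = field(default_factory=dict)

    def to_dict(self) -> dict:
        fmt = lambda v: None if v is None else round(float(v), 10)
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "n_evaluated": int(self.n_evaluated),
            "accuracy": round(float(self.accuracy), 10),
            "precision": {c: fmt(self.precision[c]) for c in self.classes},
            "recall": {c: fmt(self.recall[c]) for c in self.classes},
        }


def evaluate(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str] | None = None
) -> ClassificationReport:
    """Tally a confusion matrix and per-class precision/recall."""
    y_true = list(map(str, y_true))
    y_pred = list(map(str, y_pred))
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[index[t], index[p]] += 1
    n = conf.sum()
    acc = float(np.trace(conf) / n) if n else 0.0
    precision: dict[str, float | None] = {}
    recall: dict[str, float | None] = {}
    for c in classes:
        i = index[c]
        col = conf[:, i].sum()
        row = conf[i, :].sum()
        precision[c] = float(conf[i, i] / col) if col else None
        recall[c] = float(conf[i, i] / row) if row else None
    return ClassificationReport(classes, conf, int(n), acc, precision, recall)


def split_protocol(
    table: FeatureTable,
    mode: str = "single",
    train_frac: float = 0.7,
    other: FeatureTable | None = None,
) -> tuple[FeatureTable, FeatureTable]:
    """Split feature tables per the two study protocols.

    ``mode="single"``: within each class, the first 70% of spectra in
    acquisition order train and the remaining 30% test (ordered, not
    shuffled). ``mode="cross"``: all of ``table`` (instrument A) trains and
    all of ``other`` (instrument B) tests; the instruments must differ.
    """
    if mode == "cross":
        if other is None:
            raise ValueError("cross mode requires the second instrument's table")
        if other.instrument_id == table.instrument_id:
            raise ValueError("cross mode requires two distinct instruments")
        return table, other
    if mode != "single":
        raise ValueError("mode must be 'single' or 'cross'")
    labels = np.asarray(table.labels)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in sorted(set(table.labels)):
        idx = np.flatnonzero(labels == c)
        if idx.size < 10:
            raise ValueError(
                f"class {c!r} has {idx.size} spectra; ordered "
                f"{train_frac:.0%} split requires at least 10"
            )
        cut = int(round(train_frac * idx.size))
        train_idx.extend(idx[:cut])
        test_idx.extend(idx[cut:])
    return table.subset_rows(sorted(train_idx)), table.subset_rows(sorted(test_idx))
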
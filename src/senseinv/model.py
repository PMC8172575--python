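"""Binary synonym classifier over string-similarity features.

A pair of long forms is classified as "same sense" from its five-element
similarity feature vector.  The default backend is gradient-boosted trees
(LightGBM), the best-performing feature-based model for this task; a plain
logistic-regression backend is available for quick tests and as a sanity
baseline.  Both are deterministic under a fixed seed.

Evaluation is stratified K-fold cross-validation reporting per-fold
precision, recall and F1.  Because cross-mapping errors propagate into
merged groups, deployment uses an extremely high-specificity decision
threshold: :func:`select_threshold` picks the smallest probability cutoff
reaching a target precision (default 0.99) on validation pairs, trading
recall (some residual redundancy) for near-certain precision.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .candidates import CandidatePair
from .features import FEATURE_NAMES, PairFeatures


@dataclass(frozen=True)
class LabeledPair:
    """A featurized pair with its binary synonym label (1 = synonyms)."""

    pair_id: tuple[str, str]
    features: PairFeatures
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class FoldScores:
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class EvalReport:
    """Per-fold and mean precision/recall/F1 of a cross-validation run."""

    per_fold: tuple[FoldScores, ...]
    mean_precision: float
    mean_recall: float
    mean_f1: float


@dataclass(frozen=True)
class PredictedPair:
    pair: CandidatePair
    probability: float
    is_synonym: bool


_LIGHTGBM_DEFAULTS = dict(
    n_estimators=200,
    learning_rate=0.1,
    num_leaves=7,
    min_child_samples=2,
    min_split_gain=0.0,
    min_data_in_bin=1,
    deterministic=True,
    force_row_wise=True,
    n_jobs=1,
    verbose=-1,
)


class SynonymClassifier:
    """Pluggable binary classifier handle with a fixed feature ordering."""

    def __init__(self, backend: str = "lightgbm", params: dict | None = None, seed: int = 0):
        if backend not in ("lightgbm", "logistic"):
            raise ValueError(f"unknown backend {backend!r}")
        self.backend = backend
        self.params = dict(params or {})
        self.seed = seed
        self.feature_names = FEATURE_NAMES
        self._estimator = None

    def _build(self):
        if self.backend == "lightgbm":
            from lightgbm import LGBMClassifier

            params = dict(_LIGHTGBM_DEFAULTS)
            params.update(self.params)
            params["random_state"] = self.seed
            return LGBMClassifier(**params)
        from sklearn.linear_model import LogisticRegression

        params = dict(C=10.0, max_iter=1000)
        params.update(self.params)
        params["random_state"] = self.seed
        return LogisticRegression(**params)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SynonymClassifier":
        self._estimator = self._build()
        self._estimator.fit(X, y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self._estimator is None:
            raise RuntimeError("classifier is not fitted")
        with warnings.catch_warnings():
            # lightgbm's sklearn wrapper invents "Column_i" feature names at
            # fit time, tripping sklearn's name check on plain arrays
            warnings.filterwarnings(
                "ignore", message="X does not have valid feature names"
            )
            return self._estimator.predict_proba(np.asarray(X, dtype=float))[:, 1]

    def save(self, path: str | Path) -> Path:
        """Persist the model, backend, params and feature order to one file."""
        path = Path(path)
        payload = {
            "meta": json.dumps(
                {
                    "backend": self.backend,
                    "params": self.params,
                    "seed": self.seed,
                    "feature_names": list(self.feature_names),
                }
            ),
            "estimator": self._estimator,
        }
        with path.open("wb") as fh:
            pickle.dump(payload, fh)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SynonymClassifier":
        with Path(path).open("rb") as fh:
            payload = pickle.load(fh)
        meta = json.loads(payload["meta"])
        model = cls(backend=meta["backend"], params=meta["params"], seed=meta["seed"])
        model._estimator = payload["estimator"]
        model.feature_names = tuple(meta["feature_names"])
        return model


def _design_matrix(data: Sequence[LabeledPair]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([p.features.as_tuple() for p in data], dtype=float)
    y = np.array([p.label for p in data], dtype=int)
    return X, y


def _check_trainable(data: Sequence[LabeledPair]) -> None:
    if not data:
        raise ValueError("cannot train on empty data")
    labels = {p.label for p in data}
    if len(labels) < 2:
        raise ValueError("training data must contain both classes")
    X, _ = _design_matrix(data)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")


def train_classifier(
    data: Sequence[LabeledPair],
    params: dict | None = None,
    seed: int = 0,
    backend: str = "lightgbm",
) -> SynonymClassifier:
    """Fit the synonym classifier; deterministic under fixed seed/params."""
    _check_trainable(data)
    X, y = _design_matrix(data)
    return SynonymClassifier(backend=backend, params=params, seed=seed).fit(X, y)


def _canonical_order(data: Sequence[LabeledPair]) -> list[LabeledPair]:
    return sorted(data, key=lambda p: (p.label, p.features.as_tuple(), p.pair_id))


def crossvalidate(
    data: Sequence[LabeledPair],
    k: int = 5,
    seed: int = 0,
    params: dict | None = None,
    backend: str = "lightgbm",
) -> EvalReport:
    """Stratified k-fold cross-validation with per-fold precision/recall/F1.

    Rows are put into a canonical order before folding so the report does
    not depend on input row order.
    """
    from sklearn.metrics import f1_score, precision_score, recall_score
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    _check_trainable(data)
    ordered = _canonical_order(data)
    X, y = _design_matrix(ordered)
    counts = np.bincount(y)
    if counts.min() < k:
        raise ValueError(f"each class needs at least k={k} members, got counts {counts.tolist()}")
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    for train_idx, test_idx in folds.split(X, y):
        model = SynonymClassifier(backend=backend, params=params, seed=seed)
        model.fit(X[train_idx], y[train_idx])
        pred = (model.predict_proba(X[test_idx]) >= 0.5).astype(int)
        per_fold.append(
            FoldScores(
                precision=float(precision_score(y[test_idx], pred, zero_division=0)),
                recall=float(recall_score(y[test_idx], pred, zero_division=0)),
                f1=float(f1_score(y[test_idx], pred, zero_division=0)),
            )
        )
    return EvalReport(
        per_fold=tuple(per_fold),
        mean_precision=float(np.mean([f.precision for f in per_fold])),
        mean_recall=float(np.mean([f.recall for f in per_fold])),
        mean_f1=float(np.mean([f.f1 for f in per_fold])),
    )


class ThresholdWarning(UserWarning):
    """Target precision unattainable; best-precision threshold returned."""


def select_threshold(
    model: SynonymClassifier,
    validation: Sequence[LabeledPair],
    target_precision: float = 0.99,
) -> float:
    """Smallest probability threshold reaching the target precision.

    Sweeps the observed predicted probabilities on the validation pairs.
    If no threshold attains the target, returns the threshold maximizing
    precision and emits a :class:`ThresholdWarning`.
    """
    if not validation:
        raise ValueError("validation data must be non-empty")
    labels = {p.label for p in validation}
    if len(labels) < 2:
        raise ValueError("validation data must contain both classes")
    X, y = _design_matrix(_canonical_order(validation))
    probs = model.predict_proba(X)
    candidates = np.unique(probs)
    best_t, best_precision = None, -1.0
    for t in candidates:
        pred = probs >= t
        if not pred.any():
            continue
        precision = float(y[pred].mean())
        if precision >= target_precision:
            return float(t)
        if precision > best_precision:
            best_t, best_precision = float(t), precision
    warnings.warn(
        f"target precision {target_precision} unattainable on validation; "
        f"returning threshold {best_t} with precision {best_precision:.4f}",
        ThresholdWarning,
    )
    return best_t


def predict_pairs(
    model: SynonymClassifier,
    pairs: Sequence[tuple[CandidatePair, PairFeatures]],
    threshold: float,
) -> list[PredictedPair]:
    """Score featurized candidate pairs; positive when probability >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if not pairs:
        return []
    X = np.array([feats.as_tuple() for _, feats in pairs], dtype=float)
    probs = model.predict_proba(X)
    return [
        PredictedPair(pair=pair, probability=float(p), is_synonym=bool(p >= threshold))
        for (pair, _), p in zip(pairs, probs)
    ]
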
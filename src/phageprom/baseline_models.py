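"""Uniform train/predict interface over the ten baseline ML algorithms.

The encoding-vs-model selection experiment compares every feature encoding
against AdaBoost, multinomial naive Bayes, XGBoost, gradient boosting,
logistic regression, k-nearest neighbours, a decision tree, an SVM, a
multilayer perceptron and SVM bagging — plus the CNN as an eleventh model —
under stratified k-fold cross-validation. Baselines are seeded wrappers over
scikit-learn / xgboost with library-default hyperparameters pinned here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .cnn_model import CNNConfig, PromoterCNN
from .encoders import EncoderParams, POSITIONAL_SCHEMES, encode_dataset
from .evaluation import compute_metrics, confusion_from_predictions
from .sequence_io import DataError, SequenceDataset

ALGORITHMS = (
    "adaboost",
    "multinomial_naive_bayes",
    "xgboost",
    "gradient_boosting",
    "logistic_regression",
    "knn",
    "decision_tree",
    "svm",
    "mlp",
    "svm_bagging",
)


@dataclass(frozen=True)
class BaselineSpec:
    """One named baseline algorithm with overridable hyperparameters."""

    algorithm: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise DataError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )


def _make_estimator(spec: BaselineSpec):
    s = spec.seed
    p = spec.params
    if spec.algorithm == "adaboost":
        return AdaBoostClassifier(random_state=s, **p)
    if spec.algorithm == "multinomial_naive_bayes":
        return MultinomialNB(**p)
    if spec.algorithm == "xgboost":
        return XGBClassifier(random_state=s, eval_metric="logloss", **p)
    if spec.algorithm == "gradient_boosting":
        return GradientBoostingClassifier(random_state=s, **p)
    if spec.algorithm == "logistic_regression":
        return LogisticRegression(random_state=s, max_iter=1000, **p)
    if spec.algorithm == "knn":
        return KNeighborsClassifier(**p)
    if spec.algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=s, **p)
    if spec.algorithm == "svm":
        return SVC(random_state=s, probability=True, **p)
    if spec.algorithm == "mlp":
        return MLPClassifier(random_state=s, max_iter=500, **p)
    if spec.algorithm == "svm_bagging":
        return BaggingClassifier(
            estimator=SVC(probability=True, random_state=s),
            n_estimators=p.pop("n_estimators", 10),
            random_state=s,
            **p,
        )
    raise AssertionError(spec.algorithm)


class FittedBaseline:
    """Fitted model exposing ``predict_proba`` with the CNN's contract."""

    def __init__(self, spec: BaselineSpec, estimator):
        self.spec = spec
        self._est = estimator

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._est.predict_proba(np.asarray(X))[:, 1]

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def train_baseline(spec: BaselineSpec, X: np.ndarray, y) -> FittedBaseline:
    """Fit one baseline on flattened 1-D feature vectors.

    Multinomial naive Bayes requires non-negative features; a negative-valued
    encoding (e.g. DACC or Moran) raises an explicit error advising a
    non-negative scheme.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise DataError(f"baselines need 2-D feature arrays, got shape {X.shape}")
    if np.unique(y).size < 2:
        raise DataError("training labels contain a single class")
    if spec.algorithm == "multinomial_naive_bayes" and (X < 0).any():
        raise DataError(
            "multinomial_naive_bayes requires non-negative features; "
            "use a frequency-style encoding (kmer, pseeiip, Pse* compositions)"
        )
    est = _make_estimator(spec)
    est.fit(X, y)
    return FittedBaseline(spec, est)


def _cv_metrics(X, y, fit_fn, k: int, seed: int) -> dict:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs, sns, sps, mccs = [], [], [], []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        model = fit_fn(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        rep = compute_metrics(confusion_from_predictions(y[test_idx], pred))
        accs.append(rep.acc)
        sns.append(rep.sn)
        sps.append(rep.sp)
        mccs.append(rep.mcc)
    return {
        "acc": float(np.mean(accs)),
        "sn": float(np.mean(sns)),
        "sp": float(np.mean(sps)),
        "mcc": float(np.mean(mccs)),
    }


def benchmark_grid(
    encodings: list[str],
    specs: list[BaselineSpec | str],
    ds: SequenceDataset,
    k: int = 5,
    seed: int = 0,
    encoder_params: EncoderParams | None = None,
    cnn_config: CNNConfig | None = None,
    positive_label: str = "promoter",
) -> pd.DataFrame:
    """Cross-validated metrics for every encoding x model pair.

    ``specs`` may contain the string ``"cnn"`` to include the CNN (positional
    encodings only; incompatible pairs are recorded with status ``failed``
    rather than raising). Rows are sorted by accuracy descending and the
    result is deterministic given ``seed``.
    """
    labels = ds.labels()
    if any(l is None for l in labels):
        raise DataError("benchmark_grid requires a fully labeled dataset")
    y = np.array([1 if l == positive_label else 0 for l in labels])
    if np.unique(y).size < 2:
        raise DataError("benchmark_grid requires two classes")
    rows = []
    for enc in encodings:
        X_flat = encode_dataset(ds.sequences(), enc, encoder_params, flatten=True)
        for spec in specs:
            name = spec if isinstance(spec, str) else spec.algorithm
            row = {"encoding": enc, "model": name, "status": "ok",
                   "acc": np.nan, "sn": np.nan, "sp": np.nan, "mcc": np.nan}
            try:
                if name == "cnn":
                    if enc not in POSITIONAL_SCHEMES:
                        raise DataError(
                            f"cnn requires a positional encoding, got {enc!r}"
                        )
                    X = encode_dataset(ds.sequences(), enc, encoder_params)
                    cfg = cnn_config or CNNConfig(seed=seed)

                    def fit_cnn(Xtr, ytr, cfg=cfg, shape=X.shape[1:]):
                        return PromoterCNN(cfg, shape).fit(Xtr, ytr)

                    row.update(_cv_metrics(X, y, fit_cnn, k, seed))
                else:
                    bspec = (
                        BaselineSpec(name, seed=seed)
                        if isinstance(spec, str)
                        else spec
                    )

                    def fit_base(Xtr, ytr, bspec=bspec):
                        return train_baseline(bspec, Xtr, ytr)

                    row.update(_cv_metrics(X_flat, y, fit_base, k, seed))
            except DataError as exc:
                row["status"] = f"failed: {exc}"
            rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("acc", ascending=False, na_position="last").reset_index(
        drop=True
    )
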
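"""Binary P300 / non-P300 base learners with a uniform probability contract.

Every supported algorithm exposes ``predict_prob`` returning the probability
rho in [0, 1] that an epoch's feature vector contains a P300 response:

- ``lda``    : linear discriminant analysis, native posterior;
- ``logreg`` : logistic regression, native posterior;
- ``svm``    : linear-kernel SVM with Platt-style probability calibration;
- ``pls``    : partial least squares regression of the {0, 1} label,
               continuous prediction clipped to [0, 1].

``training_weight`` estimates each learner's training accuracy by k-fold
cross-validation; heterogeneous weighted voting uses it as the vote weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "SUPPORTED_ALGORITHMS",
    "ClassifierSpec",
    "TrainedClassifier",
    "OracleScorer",
    "train_binary",
    "predict_prob",
    "training_weight",
]

SUPPORTED_ALGORITHMS = ("lda", "svm", "pls", "logreg")

TARGET, NONTARGET = "target", "nontarget"


@dataclass(frozen=True)
class ClassifierSpec:
    """Algorithm choice + hyperparameters + RNG seed for one base learner."""

    algorithm: str = "lda"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in SUPPORTED_ALGORITHMS:
            raise ValueError(
                f"unsupported algorithm {self.algorithm!r}; choose from {SUPPORTED_ALGORITHMS}"
            )


def _build_estimator(spec: ClassifierSpec) -> Any:
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "lda":
        return LinearDiscriminantAnalysis(**hp)
    if spec.algorithm == "logreg":
        hp.setdefault("max_iter", 2000)
        return LogisticRegression(**hp)
    if spec.algorithm == "svm":
        hp.setdefault("kernel", "linear")
        hp.setdefault("random_state", spec.seed)
        folds = hp.pop("calibration_folds", 5)
        # Platt-style sigmoid calibration maps the SVM margin to [0, 1]
        return CalibratedClassifierCV(SVC(**hp), method="sigmoid", cv=folds, ensemble=False)
    if spec.algorithm == "pls":
        hp.setdefault("n_components", 2)
        return PLSRegression(**hp)
    raise AssertionError(spec.algorithm)


def _encode_labels(labels) -> np.ndarray:
    y = np.asarray([1 if l == TARGET else 0 for l in labels], dtype=int)
    return y


@dataclass
class TrainedClassifier:
    """A fitted base learner; ``predict_prob`` maps feature vectors to rho in [0, 1]."""

    spec: ClassifierSpec
    model: Any
    n_features: int

    def predict_prob(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match training dimension "
                f"{self.n_features}"
            )
        if self.spec.algorithm == "pls":
            p = np.asarray(self.model.predict(X)).ravel()
        else:
            p = self.model.predict_proba(X)[:, 1]
        return np.clip(p, 0.0, 1.0)

    def score_epoch_features(self, x: np.ndarray) -> float:
        return float(self.predict_prob(x.reshape(1, -1))[0])


class OracleScorer:
    """Diagnostic scorer that reads the ground-truth epoch label instead of the EEG.

    Returns rho = 1.0 for epochs labeled ``target`` and 0.0 otherwise.  Used
    to exercise the aggregation and decision layers independently of any
    trained model; it can never be applied to unlabeled data.
    """

    def score_epoch(self, epoch) -> float:
        if epoch.label == "unknown":
            raise ValueError("oracle scorer requires labeled epochs")
        return 1.0 if epoch.label == TARGET else 0.0


def train_binary(spec: ClassifierSpec, features: np.ndarray, labels) -> TrainedClassifier:
    """Fit one binary learner on per-epoch feature vectors.

    Deterministic given ``spec.seed``; raises if only one class is present.
    """
    X = np.asarray(features, dtype=float)
    y = _encode_labels(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n_epochs, n_features) matching labels")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least one example of each class")
    est = _build_estimator(spec)
    est.fit(X, y)
    return TrainedClassifier(spec=spec, model=est, n_features=X.shape[1])


def predict_prob(model: TrainedClassifier, x: np.ndarray) -> float:
    """rho for a single feature vector (Eq. contract: always within [0, 1])."""
    return model.score_epoch_features(np.asarray(x, dtype=float).ravel())


def training_weight(spec: ClassifierSpec, features: np.ndarray, labels, folds: int = 5) -> float:
    """Cross-validated binary accuracy in [0, 1], used as a voting weight.

    A fresh estimator is fitted per fold (stratified k-fold, shuffled with
    ``spec.seed``); resubstitution accuracy would degenerate to 1.0 for
    flexible models.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(features, dtype=float)
    y = _encode_labels(labels)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} examples of each class for {folds}-fold CV, "
            f"got {counts.tolist()}"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    accs = []
    for tr, te in cv.split(X, y):
        est = _build_estimator(spec)
        est.fit(X[tr], y[tr])
        if spec.algorithm == "pls":
            pred = (np.asarray(est.predict(X[te])).ravel() >= 0.5).astype(int)
        else:
            pred = est.predict(X[te])
        accs.append(float(np.mean(pred == y[te])))
    return float(np.mean(accs))
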
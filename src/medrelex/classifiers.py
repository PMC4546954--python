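"""Classifiers: a Bernoulli Naïve Bayes implemented from its closed form, and
soft-margin SVMs (linear and RBF) behind one light contract.

Naïve Bayes applies Bayes' rule with class-conditional independence over the
binary presence features: P(c|D) ∝ P(c) · Π_j P(d_j|c), where d_j is the
presence (1) or absence (0) of vocabulary term j. The event model is
Bernoulli — absent terms contribute P(d_j=0|c) — with Laplace smoothing
(default alpha=1), without which a single unseen term annihilates the
product. All arithmetic is done in log space.

The SVM side wraps scikit-learn's libsvm-based SVC with the two documented
presets: linear kernel at cost 0.5, and RBF at cost 8 with gamma 0.05; other
solver parameters stay at libsvm defaults (tolerance 1e-3, shrinking on, no
class weighting). Features are already 0/1, so no scaling is applied.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.svm import SVC

LabelT = Union[int, str]


@dataclass(frozen=True)
class Prediction:
    label: LabelT
    posterior: Optional[dict[LabelT, float]] = None


@dataclass(frozen=True)
class NBModel:
    classes: tuple[LabelT, ...]
    class_log_priors: np.ndarray          # (n_classes,)
    feature_log_prob1: np.ndarray         # (n_classes, n_features), log P(d_j=1|c)
    feature_log_prob0: np.ndarray         # (n_classes, n_features), log P(d_j=0|c)
    alpha: float = 1.0

    @property
    def n_features(self) -> int:
        return self.feature_log_prob1.shape[1]


def _as_matrix(vectors: Sequence[Sequence[int]]) -> np.ndarray:
    X = np.asarray(vectors)
    if X.ndim != 2:
        raise ValueError("all feature vectors must have the same length")
    return X.astype(np.float64)


def nb_train(
    vectors: Sequence[Sequence[int]],
    labels: Sequence[LabelT],
    alpha: float = 1.0,
) -> NBModel:
    """Fit the Bernoulli model: P(c) = n_c/n, P(d_j=1|c) = (n_jc + a)/(n_c + 2a)."""
    X = _as_matrix(vectors)
    y = list(labels)
    if len(y) != X.shape[0]:
        raise ValueError(f"{X.shape[0]} vectors but {len(y)} labels")
    classes = tuple(sorted(set(y)))
    if not classes:
        raise ValueError("training set is empty")
    counts = np.array([sum(1 for lab in y if lab == c) for c in classes], dtype=np.float64)
    if (counts == 0).any():
        raise ValueError("every class needs at least one training example")
    ones = np.stack(
        [X[[lab == c for lab in y]].sum(axis=0) for c in classes]
    )  # (n_classes, n_features)
    p1 = (ones + alpha) / (counts[:, None] + 2.0 * alpha)
    return NBModel(
        classes=classes,
        class_log_priors=np.log(counts / counts.sum()),
        feature_log_prob1=np.log(p1),
        feature_log_prob0=np.log1p(-p1),
        alpha=alpha,
    )


def _joint_log_likelihood(model: NBModel, X: np.ndarray) -> np.ndarray:
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"vector length {X.shape[1]} does not match model ({model.n_features})"
        )
    return (
        model.class_log_priors
        + X @ model.feature_log_prob1.T
        + (1.0 - X) @ model.feature_log_prob0.T
    )


def nb_predict_many(model: NBModel, vectors: Sequence[Sequence[int]]) -> list[Prediction]:
    X = _as_matrix(vectors)
    jll = _joint_log_likelihood(model, X)
    # normalize in log space for the posterior
    m = jll.max(axis=1, keepdims=True)
    post = np.exp(jll - m)
    post /= post.sum(axis=1, keepdims=True)
    out = []
    for row_jll, row_post in zip(jll, post):
        best = int(np.argmax(row_jll))  # argmax keeps first (smallest class) on ties
        out.append(
            Prediction(
                label=model.classes[best],
                posterior={c: float(p) for c, p in zip(model.classes, row_post)},
            )
        )
    return out


def nb_predict(model: NBModel, vector: Sequence[int]) -> Prediction:
    """Posterior over classes for one binary vector, label = argmax (ties → smallest class)."""
    return nb_predict_many(model, [list(vector)])[0]


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "linear"
    cost: float = 0.5
    gamma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"kernel must be 'linear' or 'rbf', got {self.kernel!r}")
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        if self.kernel == "rbf" and self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @classmethod
    def linear(cls) -> "SVMConfig":
        return cls(kernel="linear", cost=0.5)

    @classmethod
    def rbf(cls) -> "SVMConfig":
        return cls(kernel="rbf", cost=8.0, gamma=0.05)


def svm_train(
    vectors: Sequence[Sequence[int]],
    labels: Sequence[LabelT],
    config: Optional[SVMConfig] = None,
) -> SVC:
    """Train a soft-margin SVM with the configured kernel and parameters."""
    if config is None:
        config = SVMConfig.linear()
    X = _as_matrix(vectors)
    y = np.asarray(labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("SVM training needs at least two classes")
    clf = SVC(
        kernel=config.kernel,
        C=config.cost,
        gamma=config.gamma if (config.kernel == "rbf" and config.gamma) else "scale",
        tol=1e-3,
        shrinking=True,
        random_state=0,
    )
    clf.fit(X, y)
    return clf


def svm_predict(handle: SVC, vector: Sequence[int]) -> Prediction:
    label = handle.predict(np.asarray([list(vector)], dtype=np.float64))[0]
    return Prediction(label=label.item() if hasattr(label, "item") else label)


class _NBWrapper:
    def __init__(self, alpha: float = 1.0) -> None:
        self.alpha = alpha
        self.model: Optional[NBModel] = None

    def fit(self, X, y) -> "_NBWrapper":
        self.model = nb_train(X, y, alpha=self.alpha)
        return self

    def predict(self, X) -> np.ndarray:
        preds = nb_predict_many(self.model, X)
        return np.asarray([p.label for p in preds])


class _SVMWrapper:
    def __init__(self, config: SVMConfig) -> None:
        self.config = config
        self.handle: Optional[SVC] = None

    def fit(self, X, y) -> "_SVMWrapper":
        self.handle = svm_train(X, y, self.config)
        return self

    def predict(self, X) -> np.ndarray:
        return self.handle.predict(np.asarray(X, dtype=np.float64))


#: classifier kinds usable in the evaluation grid and on the command line
CLASSIFIER_KINDS = ("nb", "svm-linear", "svm-rbf")


def make_classifier(kind: str, alpha: float = 1.0, config: Optional[SVMConfig] = None):
    """Factory for the evaluation grid: 'nb', 'svm-linear' or 'svm-rbf'."""
    if kind == "nb":
        return _NBWrapper(alpha=alpha)
    if kind == "svm-linear":
        return _SVMWrapper(config or SVMConfig.linear())
    if kind == "svm-rbf":
        return _SVMWrapper(config or SVMConfig.rbf())
    raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")
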
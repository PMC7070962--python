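"""Classifier adapters with fixed, untuned default settings.

1-nearest-neighbour and the decision stump are implemented natively;
the remaining models wrap scikit-learn estimators configured to match
the untuned defaults of the original study setup: random forest with
100 trees, a fully random single tree, Gaussian naive Bayes, an SVM
with polynomial kernel and C = 1, and a single-hidden-layer perceptron
with (n_features + n_classes)/2 units, learning rate 0.3, momentum 0.2.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier


class ClassifierAdapter:
    """fit(X, y) then predict(X) -> class labels; deterministic under a
    fixed seed."""

    name = "base"

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassifierAdapter":
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class OneNearestNeighbor(ClassifierAdapter):
    """Brute-force Euclidean 1-NN; ties broken by first training index."""

    name = "knn"

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneNearestNeighbor":
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0], dtype=self._y.dtype)
        for i, x in enumerate(X):
            d2 = np.sum((self._X - x) ** 2, axis=1)
            out[i] = self._y[int(np.argmin(d2))]
        return out


class DecisionStump(ClassifierAdapter):
    """One-level decision tree: a single (feature, threshold) split.

    The split minimising training misclassification over all feature
    midpoints is chosen; ties break on lower feature index, then lower
    threshold. Each side predicts its training majority class (ties to
    the class that is globally more frequent in training).
    """

    name = "ds"

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DecisionStump":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        majority = classes[int(np.argmax(counts))]

        def side_majority(labels: np.ndarray):
            if labels.size == 0:
                return majority, 0
            c, n = np.unique(labels, return_counts=True)
            top = n.max()
            # tie -> globally more frequent class
            tied = c[n == top]
            pred = majority if majority in tied else tied[0]
            return pred, int(labels.size - top)

        n_err_all = int(y.size - counts.max())
        best = (n_err_all, -1, -np.inf, majority, majority)  # errors, feat, thr, left, right
        for j in range(X.shape[1]):
            uniq = np.unique(X[:, j])
            for thr in (uniq[:-1] + uniq[1:]) / 2.0:
                mask = X[:, j] <= thr
                left_pred, e_l = side_majority(y[mask])
                right_pred, e_r = side_majority(y[~mask])
                errors = e_l + e_r
                if (errors, j, thr) < (best[0], best[1], best[2]):
                    best = (errors, j, thr, left_pred, right_pred)
        self._feat = max(best[1], 0)
        self._thr = best[2]
        self._left, self._right = best[3], best[4]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        go_left = X[:, self._feat] <= self._thr
        out = np.where(go_left, self._left, self._right)
        return out


class SklearnAdapter(ClassifierAdapter):
    """Wraps a scikit-learn estimator factory behind the adapter contract."""

    def __init__(self, name: str, factory: Callable[[int], object],
                 seed: int = 0, standardize: bool = False) -> None:
        self.name = name
        self.factory = factory
        self.seed = seed
        self.standardize = standardize

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SklearnAdapter":
        X = np.asarray(X, dtype=float)
        if self.standardize:
            self._mu = X.mean(axis=0)
            self._sd = np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
            X = (X - self._mu) / self._sd
        self._model = self.factory(self.seed)
        self._model.fit(X, np.asarray(y))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.standardize:
            X = (X - self._mu) / self._sd
        return self._model.predict(X)


def builtin_classifiers(seed: int = 0) -> dict[str, ClassifierAdapter]:
    """The available adapters, keyed by short name."""

    def mlp(s: int) -> MLPClassifier:
        return MLPClassifier(
            hidden_layer_sizes=(14,),  # (26 features + 2 classes) / 2
            solver="sgd",
            learning_rate_init=0.3,
            momentum=0.2,
            batch_size=100,
            max_iter=500,
            random_state=s,
        )

    return {
        "knn": OneNearestNeighbor(),
        "ds": DecisionStump(),
        "nb": SklearnAdapter("nb", lambda s: GaussianNB(), seed),
        "svm": SklearnAdapter(
            "svm", lambda s: SVC(kernel="poly", degree=1, C=1.0, random_state=s), seed,
            standardize=True,
        ),
        "rf": SklearnAdapter(
            "rf", lambda s: RandomForestClassifier(n_estimators=100, random_state=s), seed
        ),
        "rt": SklearnAdapter(
            "rt", lambda s: DecisionTreeClassifier(splitter="random", random_state=s), seed
        ),
        "mlp": SklearnAdapter("mlp", mlp, seed, standardize=True),
    }


def get_classifier(name: str, seed: int = 0) -> ClassifierAdapter:
    adapters = builtin_classifiers(seed)
    if name not in adapters:
        raise KeyError(
            f"unknown classifier {name!r}; available adapters: {sorted(adapters)}"
        )
    return adapters[name]
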
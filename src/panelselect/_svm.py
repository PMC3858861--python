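"""Thin binary RBF-kernel SVM used by the panel search.

The exhaustive search fits hundreds of thousands of SVMs on ~50-sample
training folds, where the estimator-level overhead of ``sklearn.svm.SVC``
dominates the actual libsvm solve.  This wrapper calls scikit-learn's
low-level libsvm binding directly, which produces decision values
bit-identical to ``SVC.decision_function`` (the binding's raw decision value
is the negation of the class-1-oriented score; equality is asserted by the
test suite).  If the private binding is unavailable the public estimator is
used instead.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - import guard
    from sklearn.svm import _libsvm as _libsvm_mod

    _libsvm_mod.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover
    _libsvm_mod = None

from sklearn.svm import SVC

__all__ = ["RbfSvm"]


class RbfSvm:
    """Binary C-SVC with an RBF kernel; decision scores oriented to class 1."""

    def __init__(self, c_penalty: float = 1.0, gamma: float = 0.2):
        if c_penalty <= 0 or gamma <= 0:
            raise ValueError("C and gamma must be positive")
        self.c_penalty = float(c_penalty)
        self.gamma = float(gamma)
        self._model = None
        self._svc = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RbfSvm":
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.ascontiguousarray(y, dtype=np.float64)
        if set(np.unique(y)) != {0.0, 1.0}:
            raise ValueError("training labels must contain both classes 0 and 1")
        if _libsvm_mod is not None:
            self._model = _libsvm_mod.fit(
                X,
                y,
                svm_type=0,
                kernel="rbf",
                C=self.c_penalty,
                gamma=self.gamma,
            )
        else:  # pragma: no cover - exercised only without the private module
            self._svc = SVC(
                kernel="rbf", C=self.c_penalty, gamma=self.gamma
            ).fit(X, y)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float64)
        if self._model is not None:
            o = self._model
            dec = _libsvm_mod.decision_function(
                X,
                o[0],
                o[1],
                o[2],
                o[3],
                o[4],
                o[5],
                o[6],
                svm_type=0,
                kernel="rbf",
                gamma=self.gamma,
            )
            return -dec.ravel()
        if self._svc is not None:  # pragma: no cover
            return self._svc.decision_function(X)
        raise RuntimeError("model is not fitted")
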
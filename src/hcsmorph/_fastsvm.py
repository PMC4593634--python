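"""Thin wrapper around libsvm for very small precomputed-kernel problems.

The genetic-algorithm fitness function evaluates tens of thousands of tiny
RBF-SVM cross-validations; going through the public estimator API costs
~10 ms per fit in input validation alone.  This module calls the low-level
libsvm binding directly when available (~0.06 ms per fit) and falls back to
``sklearn.svm.SVC`` otherwise.  Equivalence with the public API is asserted
by the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # private API of the pinned scikit-learn; fallback below if it moves
    from sklearn.svm import _libsvm as _lv

    _lv.set_verbosity_wrap(0)
    _HAVE_FAST = True
except Exception:  # pragma: no cover
    _lv = None
    _HAVE_FAST = False

from sklearn.svm import SVC

__all__ = ["fit_predict_precomputed", "HAVE_FAST_BACKEND"]

HAVE_FAST_BACKEND = _HAVE_FAST


def _fit_predict_sklearn(Ktr: np.ndarray, ytr: np.ndarray, Kte: np.ndarray,
                         C: float) -> np.ndarray:
    model = SVC(kernel="precomputed", C=C)
    model.fit(Ktr, ytr)
    return model.predict(Kte)


def fit_predict_precomputed(Ktr: np.ndarray, ytr: np.ndarray, Kte: np.ndarray,
                            C: float) -> np.ndarray:
    """Train a C-SVC on a precomputed kernel and predict test rows.

    ``Ktr`` is the (n_train, n_train) kernel, ``Kte`` the (n_test, n_train)
    cross-kernel, ``ytr`` integer labels (two classes).
    """
    if not _HAVE_FAST:  # pragma: no cover
        return _fit_predict_sklearn(Ktr, ytr, Kte, C)
    y = np.asarray(ytr, dtype=np.float64)
    out = _lv.fit(np.ascontiguousarray(Ktr, dtype=np.float64), y,
                  svm_type=0, kernel="precomputed", C=float(C),
                  tol=1e-3, cache_size=16.0)
    support, sv_coef, intercept = out[0], out[3], out[4]
    dec = Kte[:, support] @ np.asarray(sv_coef).ravel() + float(intercept[0])
    # raw libsvm decision is the negation of SVC.decision_function, whose
    # positive side is the larger label: dec > 0 -> smaller label
    lo = ytr.min()
    hi = ytr.max()
    return np.where(dec > 0, lo, hi)
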
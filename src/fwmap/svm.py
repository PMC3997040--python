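"""Shared classifier machinery: scaling, folds, linear SVM, cross-validation.

The SVM is the standard soft-margin formulation: minimise ||w|| subject to
``y_i (w . x_i - b) >= 1`` up to hinge-loss slack with penalty C. It is solved
in the dual on the Gram matrix (see :mod:`fwmap._smo`), which keeps the
training cost a function of the sample count (here always ~30) rather than
the voxel count.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np

from ._smo import cv_accuracy_kernel, smo_solve

__all__ = [
    "FeatureScaler",
    "scale_features",
    "FoldScheme",
    "leave_two_out_folds",
    "LinearSVMModel",
    "train_linear_svm",
    "crossval_accuracy",
]

DEFAULT_C = 1.0
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 200_000


@dataclasses.dataclass
class FeatureScaler:
    """Per-feature affine map sending the observed min to -1 and max to +1.

    Constant features map to 0. ``factor`` and ``offset`` realise
    ``x' = factor * x + offset``.
    """

    factor: np.ndarray
    offset: np.ndarray

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return matrix * self.factor + self.offset

    @classmethod
    def fit(cls, matrix: np.ndarray, fit_rows: np.ndarray | None = None
            ) -> "FeatureScaler":
        sub = matrix if fit_rows is None else matrix[fit_rows]
        lo = sub.min(axis=0)
        hi = sub.max(axis=0)
        span = hi - lo
        factor = np.zeros_like(span, dtype=np.float64)
        nz = span > 0
        with np.errstate(over="ignore"):
            factor[nz] = 2.0 / span[nz]
        # a span below ~1e-308 overflows the factor: treat as constant
        bad = ~np.isfinite(factor)
        factor[bad] = 0.0
        nz &= ~bad
        offset = np.where(nz, -1.0 - lo * factor, 0.0)
        return cls(factor=factor, offset=offset)


def scale_features(matrix: np.ndarray, fit_rows: np.ndarray | None = None
                   ) -> tuple[np.ndarray, FeatureScaler]:
    """Scale each feature to [-1, +1] (fitted on ``fit_rows``, default all)."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.size == 0:
        raise ValueError("matrix is empty")
    scaler = FeatureScaler.fit(matrix, fit_rows)
    return scaler.transform(matrix), scaler


@dataclasses.dataclass
class FoldScheme:
    """Ordered leave-2-out folds: each test set is one sample of each class."""

    folds: list[tuple[np.ndarray, np.ndarray]]

    def __len__(self) -> int:
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)

    def test_pairs(self) -> np.ndarray:
        """(n_folds, 2) array of test indices (class A first)."""
        return np.array([test for _, test in self.folds], dtype=np.int64)


def leave_two_out_folds(labels: np.ndarray,
                        max_folds: int | None = None,
                        seed: int | None = None) -> FoldScheme:
    """All (class A, class B) ordered test pairs; train on the rest.

    ``max_folds`` reproducibly subsamples the folds (requires ``seed``).
    """
    labels = np.asarray(labels)
    idx_a = np.flatnonzero(labels == 1)
    idx_b = np.flatnonzero(labels == -1)
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("each class needs at least 2 samples for leave-2-out")
    n = labels.size
    pairs = list(itertools.product(idx_a, idx_b))
    if max_folds is not None and max_folds < len(pairs):
        rng = np.random.default_rng(0 if seed is None else seed)
        keep = rng.choice(len(pairs), size=max_folds, replace=False)
        pairs = [pairs[k] for k in sorted(keep)]
    folds = []
    all_idx = np.arange(n)
    for a, b in pairs:
        test = np.array([a, b], dtype=np.int64)
        train = np.setdiff1d(all_idx, test)
        folds.append((train, test))
    return FoldScheme(folds=folds)


@dataclasses.dataclass
class LinearSVMModel:
    """Trained linear SVM; the decision value of x is ``w . x - b``."""

    w: np.ndarray
    b: float
    C: float
    alpha: np.ndarray
    zero_margin: bool = False

    def decision(self, matrix: np.ndarray) -> np.ndarray:
        return np.asarray(matrix) @ self.w - self.b

    def predict(self, matrix: np.ndarray) -> np.ndarray:
        # tie rule: decision value exactly 0 predicts class +1
        return np.where(self.decision(matrix) >= 0, 1, -1)


def _solve_dual(K: np.ndarray, labels: np.ndarray, C: float,
                tol: float, max_iter: int) -> tuple[np.ndarray, float]:
    m = K.shape[0]
    tr = np.arange(m, dtype=np.int64)
    alpha = np.empty(m)
    grad = np.empty(m)
    b = smo_solve(np.ascontiguousarray(K, dtype=np.float64), tr,
                  np.ascontiguousarray(labels, dtype=np.int64),
                  float(C), float(tol), int(max_iter), alpha, grad)
    return alpha, float(b)


def train_linear_svm(matrix: np.ndarray, labels: np.ndarray,
                     C: float = DEFAULT_C, tol: float = DEFAULT_TOL,
                     max_iter: int = DEFAULT_MAX_ITER) -> LinearSVMModel:
    """Train a soft-margin linear SVM on all rows of ``matrix``.

    Deterministic for fixed input. Degenerate problems (no usable class
    separation, e.g. identical rows across classes) still return a model but
    flag ``zero_margin``.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if not ((labels == 1).any() and (labels == -1).any()):
        raise ValueError("both classes must be present")
    K = matrix @ matrix.T
    alpha, b = _solve_dual(K, labels, C, tol, max_iter)
    w = matrix.T @ (alpha * labels)
    zero_margin = bool(np.linalg.norm(w) < 1e-10)
    return LinearSVMModel(w=w, b=b, C=float(C), alpha=alpha,
                          zero_margin=zero_margin)


def crossval_accuracy(matrix: np.ndarray, labels: np.ndarray,
                      folds: FoldScheme, C: float = DEFAULT_C,
                      tol: float = DEFAULT_TOL,
                      max_iter: int = DEFAULT_MAX_ITER) -> float:
    """Mean fraction of correctly predicted test labels over the folds."""
    matrix = np.asarray(matrix, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    test_pairs = folds.test_pairs()
    if test_pairs.max(initial=-1) >= matrix.shape[0]:
        raise ValueError("fold references a missing row")
    K = np.ascontiguousarray(matrix @ matrix.T)
    return float(cv_accuracy_kernel(K, labels, test_pairs, float(C),
                                    float(tol), int(max_iter)))


def n_distinct_label_arrangements(labels: np.ndarray) -> int:
    labels = np.asarray(labels)
    n = labels.size
    k = int((labels == 1).sum())
    return math.comb(n, k)
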
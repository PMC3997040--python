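"""Numba SMO solver for the soft-margin linear SVM dual, kernel form.

The dual problem is

    min  1/2 a' Q a - e' a    s.t.  0 <= a_i <= C,  y' a = 0,

with Q_ij = y_i y_j K_ij. Pairs are selected by maximal KKT violation and
updated analytically; the bias uses the free support vectors (midpoint of the
KKT bounds when none are free). The decision value of a sample x is
``sum_i a_i y_i K(x_i, x) - b``.

Everything here operates on precomputed Gram matrices so that the searchlight
permutation machinery can re-solve millions of small problems without
touching feature space: a sphere's Gram entries are sums of voxelwise
products, so excluded (out-of-mask) voxels simply contribute nothing.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TAU = 1e-12


@njit(cache=True)
def smo_solve(K, tr, y, C, tol, max_iter, alpha, grad):  # pragma: no cover - jit
    """Solve the dual on the training subset ``tr`` of kernel ``K``.

    ``y`` holds the +-1 labels of the training rows; ``alpha`` and ``grad``
    are scratch arrays of length >= len(tr). Returns the bias b.
    """
    n = tr.shape[0]
    for t in range(n):
        alpha[t] = 0.0
        grad[t] = -1.0
    it = 0
    while it < max_iter:
        it += 1
        gmax = -1e300
        gmin = 1e300
        i = -1
        j = -1
        for t in range(n):
            v = -y[t] * grad[t]
            if (y[t] == 1 and alpha[t] < C) or (y[t] == -1 and alpha[t] > 0.0):
                if v > gmax:
                    gmax = v
                    i = t
            if (y[t] == 1 and alpha[t] > 0.0) or (y[t] == -1 and alpha[t] < C):
                if v < gmin:
                    gmin = v
                    j = t
        if i < 0 or j < 0 or gmax - gmin < tol:
            break
        Kii = K[tr[i], tr[i]]
        Kjj = K[tr[j], tr[j]]
        Kij = K[tr[i], tr[j]]
        old_ai = alpha[i]
        old_aj = alpha[j]
        quad = Kii + Kjj - 2.0 * Kij
        if quad <= 0.0:
            quad = _TAU
        if y[i] != y[j]:
            delta = (-grad[i] - grad[j]) / quad
            diff = alpha[i] - alpha[j]
            alpha[i] += delta
            alpha[j] += delta
            if diff > 0.0:
                if alpha[j] < 0.0:
                    alpha[j] = 0.0
                    alpha[i] = diff
            else:
                if alpha[i] < 0.0:
                    alpha[i] = 0.0
                    alpha[j] = -diff
            if diff > 0.0:
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = C - diff
            else:
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = C + diff
        else:
            delta = (grad[i] - grad[j]) / quad
            s = alpha[i] + alpha[j]
            alpha[i] -= delta
            alpha[j] += delta
            if s > C:
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = s - C
            else:
                if alpha[j] < 0.0:
                    alpha[j] = 0.0
                    alpha[i] = s
            if s > C:
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = s - C
            else:
                if alpha[i] < 0.0:
                    alpha[i] = 0.0
                    alpha[j] = s
        dai = alpha[i] - old_ai
        daj = alpha[j] - old_aj
        yi = y[i]
        yj = y[j]
        ti = tr[i]
        tj = tr[j]
        for t in range(n):
            grad[t] += (y[t] * yi * K[tr[t], ti] * dai
                        + y[t] * yj * K[tr[t], tj] * daj)
    # bias from KKT conditions
    nr_free = 0
    sum_free = 0.0
    ub = 1e300
    lb = -1e300
    for t in range(n):
        yg = y[t] * grad[t]
        if alpha[t] >= C:
            if y[t] == -1:
                ub = min(ub, yg)
            else:
                lb = max(lb, yg)
        elif alpha[t] <= 0.0:
            if y[t] == 1:
                ub = min(ub, yg)
            else:
                lb = max(lb, yg)
        else:
            nr_free += 1
            sum_free += yg
    if nr_free > 0:
        return sum_free / nr_free
    return (ub + lb) / 2.0


@njit(cache=True)
def decision_from_kernel(K, tr, y, alpha, b, test):  # pragma: no cover - jit
    """Decision values w.x - b for ``test`` rows via the kernel."""
    out = np.empty(test.shape[0])
    for s in range(test.shape[0]):
        acc = 0.0
        for t in range(tr.shape[0]):
            acc += alpha[t] * y[t] * K[tr[t], test[s]]
        out[s] = acc - b
    return out


@njit(cache=True)
def cv_accuracy_kernel(K, y, test_pairs, C, tol, max_iter):  # pragma: no cover
    """Mean leave-2-out accuracy from a full-sample Gram matrix.

    ``test_pairs`` holds one (class A sample, class B sample) test pair per
    fold; all remaining samples form the training set. Ties (decision value
    exactly 0) predict class +1.
    """
    m = K.shape[0]
    n_folds = test_pairs.shape[0]
    tr = np.empty(m - 2, dtype=np.int64)
    ytr = np.empty(m - 2, dtype=np.int64)
    alpha = np.empty(m - 2)
    grad = np.empty(m - 2)
    correct = 0
    for f in range(n_folds):
        a = test_pairs[f, 0]
        bidx = test_pairs[f, 1]
        k = 0
        for t in range(m):
            if t != a and t != bidx:
                tr[k] = t
                ytr[k] = y[t]
                k += 1
        b = smo_solve(K, tr, ytr, C, tol, max_iter, alpha, grad)
        for s in range(2):
            te = test_pairs[f, s]
            acc = 0.0
            for t in range(m - 2):
                acc += alpha[t] * ytr[t] * K[tr[t], te]
            pred = 1 if acc - b >= 0.0 else -1
            if pred == y[te]:
                correct += 1
    return correct / (2.0 * n_folds)


@njit(cache=True)
def searchlight_cv_batch(G, pair_idx, ys, test_pairs, C, tol, max_iter):
    """Leave-2-out accuracy per (label vector, centre voxel).

    G : (n_pairs_tri, n_centres) packed upper-triangular Gram field
        (G[pair_idx[i, j], v] = K_v[i, j] for centre v).
    pair_idx : (m, m) int map into the packed triangle.
    ys : (n_labelsets, m) label vectors (+-1); row 0 is usually the observed.
    test_pairs : (n_labelsets, n_folds, 2) per-labelset fold test pairs.

    Returns (n_labelsets, n_centres) accuracies.
    """  # pragma: no cover - jit
    n_lab = ys.shape[0]
    n_cent = G.shape[1]
    m = ys.shape[1]
    n_folds = test_pairs.shape[1]
    out = np.empty((n_lab, n_cent))
    K = np.empty((m, m))
    tr = np.empty(m - 2, dtype=np.int64)
    ytr = np.empty(m - 2, dtype=np.int64)
    alpha = np.empty(m - 2)
    grad = np.empty(m - 2)
    for v in range(n_cent):
        for i in range(m):
            for j in range(m):
                K[i, j] = G[pair_idx[i, j], v]
        for L in range(n_lab):
            y = ys[L]
            correct = 0
            for f in range(n_folds):
                a = test_pairs[L, f, 0]
                bidx = test_pairs[L, f, 1]
                k = 0
                for t in range(m):
                    if t != a and t != bidx:
                        tr[k] = t
                        ytr[k] = y[t]
                        k += 1
                b = smo_solve(K, tr, ytr, C, tol, max_iter, alpha, grad)
                for s in range(2):
                    te = test_pairs[L, f, s]
                    acc = 0.0
                    for t in range(m - 2):
                        acc += alpha[t] * ytr[t] * K[tr[t], te]
                    pred = 1 if acc - b >= 0.0 else -1
                    if pred == y[te]:
                        correct += 1
            out[L, v] = correct / (2.0 * n_folds)
    return out
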
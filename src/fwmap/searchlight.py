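"""Searchlight decoding: spherical-neighbourhood cross-validated accuracy maps.

For every in-mask centre voxel, the classifier sees the in-mask voxels within
a sphere of radius r around the centre; the mean leave-2-out cross-validation
accuracy of a linear SVM on that neighbourhood is stored at the centre. All
voxels are min-max scaled to [-1, +1] across samples once, before sphere
construction. Spheres are clipped to the mask; boundary centres simply use
the voxels that exist.

Implementation note: the SVM only needs the sphere's Gram matrix, which is a
sum of per-voxel sample products. Those sums are obtained for all centres at
once by convolving each pairwise product volume with the binary sphere
footprint (out-of-mask voxels are zeroed first, so they contribute nothing).
This is exactly equivalent to per-centre feature extraction (the ``naive``
engine, kept for cross-checking) but orders of magnitude faster under label
permutation, where the Gram field is reused unchanged.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from ._smo import searchlight_cv_batch
from .data import SampleStack, StatMap, flatten
from .svm import (DEFAULT_C, DEFAULT_MAX_ITER, FoldScheme, crossval_accuracy,
                  leave_two_out_folds, scale_features)

__all__ = ["SearchlightParams", "sphere_offsets", "sphere_footprint",
           "searchlight_map", "searchlight_accuracy_stack"]

_SL_TOL = 1e-6  # KKT tolerance; decision flips need |margin| below this


@dataclasses.dataclass
class SearchlightParams:
    """Searchlight radius (voxel or mm units), SVM penalty and fold options."""

    radius: float = 3.0
    radius_unit: str = "voxel"
    C: float = DEFAULT_C
    max_folds: int | None = None
    fold_seed: int = 0

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.radius_unit not in ("voxel", "mm"):
            raise ValueError("radius_unit must be 'voxel' or 'mm'")


def sphere_offsets(radius: float, voxel_size=(1.0, 1.0, 1.0),
                   unit: str = "voxel") -> np.ndarray:
    """Integer offsets d with ||d|| <= radius, including (0, 0, 0).

    With ``unit='mm'`` the Euclidean norm is taken after scaling each axis by
    the physical voxel size, honouring anisotropic voxels.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    vs = np.ones(3) if unit == "voxel" else np.asarray(voxel_size, dtype=float)
    reach = [int(np.floor(radius / v)) for v in vs]
    offs = []
    for dx in range(-reach[0], reach[0] + 1):
        for dy in range(-reach[1], reach[1] + 1):
            for dz in range(-reach[2], reach[2] + 1):
                d2 = (dx * vs[0]) ** 2 + (dy * vs[1]) ** 2 + (dz * vs[2]) ** 2
                if d2 <= radius ** 2 + 1e-12:
                    offs.append((dx, dy, dz))
    return np.array(offs, dtype=np.int64)


def sphere_footprint(radius: float, voxel_size=(1.0, 1.0, 1.0),
                     unit: str = "voxel") -> np.ndarray:
    """Boolean (2R+1)^3 footprint of :func:`sphere_offsets`."""
    offs = sphere_offsets(radius, voxel_size, unit)
    reach = np.abs(offs).max(axis=0)
    fp = np.zeros(2 * reach + 1, dtype=bool)
    fp[tuple((offs + reach).T)] = True
    return fp


def _scaled_masked_volumes(stack: SampleStack) -> np.ndarray:
    """Per-voxel [-1, +1] scaling over samples; out-of-mask voxels zeroed."""
    matrix, index = flatten(stack)
    scaled, _ = scale_features(matrix)
    vols = np.zeros_like(stack.data)
    vols[:, index[:, 0], index[:, 1], index[:, 2]] = scaled
    return vols


def sphere_gram_field(stack: SampleStack, params: SearchlightParams
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Packed Gram matrices of every centre's sphere neighbourhood.

    Returns ``(G, pair_idx, index)`` where ``G[pair_idx[i, j], c]`` is the
    kernel value K(sample i, sample j) for centre column c and ``index`` maps
    centre columns to voxel coordinates.
    """
    fp = sphere_footprint(params.radius, stack.voxel_size, params.radius_unit)
    vols = _scaled_masked_volumes(stack)
    index = np.argwhere(stack.mask)
    m = stack.n_samples
    n_pairs = m * (m + 1) // 2
    G = np.empty((n_pairs, index.shape[0]))
    pair_idx = np.empty((m, m), dtype=np.int64)
    kern = fp.astype(np.float64)
    k = 0
    for i in range(m):
        for j in range(i, m):
            prod = vols[i] * vols[j]
            conv = signal.fftconvolve(prod, kern, mode="same")
            G[k] = conv[index[:, 0], index[:, 1], index[:, 2]]
            pair_idx[i, j] = pair_idx[j, i] = k
            k += 1
    return G, pair_idx, index


def searchlight_accuracy_stack(stack: SampleStack, params: SearchlightParams,
                               label_sets: np.ndarray) -> np.ndarray:
    """Accuracy per (label vector, in-mask centre voxel).

    ``label_sets`` has one +-1 label vector per row (row 0 is typically the
    observed labelling, later rows permutations). Fold schemes are built per
    label vector so every fold tests one sample of each (permuted) class;
    with ``max_folds`` set, each row's folds are subsampled with a seed
    derived from ``(fold_seed, row)``.
    """
    label_sets = np.atleast_2d(np.asarray(label_sets, dtype=np.int64))
    G, pair_idx, _ = sphere_gram_field(stack, params)
    n_lab = label_sets.shape[0]
    schemes = []
    for r in range(n_lab):
        seed = None if params.max_folds is None else params.fold_seed + r
        schemes.append(leave_two_out_folds(label_sets[r],
                                           max_folds=params.max_folds,
                                           seed=seed))
    n_folds = min(len(s) for s in schemes)
    test_pairs = np.stack([s.test_pairs()[:n_folds] for s in schemes])
    return searchlight_cv_batch(G, pair_idx, label_sets, test_pairs,
                                float(params.C), _SL_TOL,
                                int(DEFAULT_MAX_ITER))


def _searchlight_map_naive(stack: SampleStack, params: SearchlightParams
                           ) -> np.ndarray:
    """Reference path: explicit per-centre feature extraction."""
    matrix, index = flatten(stack)
    scaled, _ = scale_features(matrix)
    col_of = -np.ones(stack.shape, dtype=np.int64)
    col_of[tuple(index.T)] = np.arange(index.shape[0])
    offs = sphere_offsets(params.radius, stack.voxel_size, params.radius_unit)
    seed = None if params.max_folds is None else params.fold_seed
    folds = leave_two_out_folds(stack.labels, max_folds=params.max_folds,
                                seed=seed)
    out = np.zeros(index.shape[0])
    shape = np.asarray(stack.shape)
    for c, centre in enumerate(index):
        pts = centre + offs
        ok = ((pts >= 0) & (pts < shape)).all(axis=1)
        cols = col_of[tuple(pts[ok].T)]
        cols = cols[cols >= 0]
        out[c] = crossval_accuracy(scaled[:, cols], stack.labels, folds,
                                   C=params.C, tol=_SL_TOL)
    return out


def searchlight_map(stack: SampleStack, params: SearchlightParams | None = None,
                    engine: str = "gram") -> StatMap:
    """Voxel-wise mean cross-validation accuracy map."""
    if params is None:
        params = SearchlightParams()
    index = np.argwhere(stack.mask)
    if index.size == 0:
        raise ValueError("mask is empty")
    if engine == "gram":
        acc = searchlight_accuracy_stack(stack, params, stack.labels[None, :])[0]
    elif engine == "naive":
        acc = _searchlight_map_naive(stack, params)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    values = np.zeros(stack.shape)
    values[tuple(index.T)] = acc
    return StatMap(values=values, kind="accuracy", mask=stack.mask.copy())
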
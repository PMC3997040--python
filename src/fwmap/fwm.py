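"""Feature weight mapping: PCA reduction, whole-data SVM, weight back-projection.

The pipeline is: flatten the stack to the sample-by-voxel matrix X, reduce it
to its n-1 leading principal components (computed by SVD of the column-
centred X; after centring at most n-1 components carry variance), scale each
component score to [-1, +1], train a linear SVM on the entire data set
without cross-validation, and map the component weights back to voxel space
through the orthonormal loading basis. The result is a signed weight per
voxel: positive weights push the decision toward class A (+1), negative
toward class B. No accuracies are produced — the map is the point.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import SampleStack, StatMap, flatten
from .svm import (DEFAULT_C, FeatureScaler, LinearSVMModel, _solve_dual,
                  scale_features, train_linear_svm)

__all__ = ["PCAModel", "pca_reduce", "backproject", "fwm_weights",
           "fwm_weight_stack"]


@dataclasses.dataclass
class PCAModel:
    """Column-centred PCA of a sample-by-feature matrix via SVD.

    ``scores @ loadings.T + column_means`` reconstructs the input when its
    rank does not exceed the retained components.
    """

    loadings: np.ndarray          # (features, components), orthonormal columns
    scores: np.ndarray            # (samples, components)
    column_means: np.ndarray      # (features,)
    explained_variance: np.ndarray  # (components,), non-increasing

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings.T + self.column_means


def pca_reduce(matrix: np.ndarray, n_components: int | None = None) -> PCAModel:
    """PCA by singular value decomposition of the column-centred matrix.

    Retains ``n_samples - 1`` components by default (the centred matrix has
    at most that rank); components are ordered by decreasing variance.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components is None:
        n_components = n - 1
    if not 1 <= n_components <= n - 1:
        raise ValueError("n_components must be in [1, n_samples - 1]")
    means = matrix.mean(axis=0)
    u, s, vt = np.linalg.svd(matrix - means, full_matrices=False)
    k = n_components
    return PCAModel(
        loadings=vt[:k].T,
        scores=u[:, :k] * s[:k],
        column_means=means,
        explained_variance=s[:k] ** 2 / (n - 1),
    )


def backproject(component_weights: np.ndarray, pca: PCAModel,
                scale_factors: np.ndarray | None = None) -> np.ndarray:
    """Map SVM component weights back to voxel weights.

    ``scale_factors`` are the per-component multiplicative factors of the
    [-1, +1] scaling applied to the scores before training; dividing them out
    first makes the voxel map refer to unscaled data units (a factor of 0,
    i.e. a constant component, contributes nothing). With unit scaling the
    orthonormal loading basis preserves the Euclidean norm of the weights.
    """
    component_weights = np.asarray(component_weights, dtype=np.float64)
    if component_weights.shape != (pca.n_components,):
        raise ValueError(
            f"expected {pca.n_components} component weights, "
            f"got {component_weights.shape}")
    if scale_factors is not None:
        component_weights = component_weights * np.asarray(scale_factors)
    return pca.loadings @ component_weights


@dataclasses.dataclass
class FWMFit:
    """Intermediate state shared by the observed map and its permutations."""

    pca: PCAModel
    scaler: FeatureScaler
    scores_scaled: np.ndarray
    kernel: np.ndarray
    index: np.ndarray
    shape: tuple[int, int, int]


def _prepare(stack: SampleStack, n_components: int | None) -> FWMFit:
    matrix, index = flatten(stack)
    pca = pca_reduce(matrix, n_components)
    scores_scaled, scaler = scale_features(pca.scores)
    return FWMFit(pca=pca, scaler=scaler, scores_scaled=scores_scaled,
                  kernel=np.ascontiguousarray(scores_scaled @ scores_scaled.T),
                  index=index, shape=stack.shape)


def _voxel_weights(fit: FWMFit, labels: np.ndarray, C: float
                   ) -> tuple[np.ndarray, LinearSVMModel]:
    model = train_linear_svm(fit.scores_scaled, labels, C=C)
    voxel_w = backproject(model.w, fit.pca, scale_factors=fit.scaler.factor)
    return voxel_w, model


def fwm_weights(stack: SampleStack, labels: np.ndarray | None = None,
                C: float = DEFAULT_C, n_components: int | None = None,
                ) -> StatMap:
    """Signed voxel weight map from a whole-data linear SVM on PCA scores."""
    if labels is None:
        labels = stack.labels
    fit = _prepare(stack, n_components)
    voxel_w, _ = _voxel_weights(fit, np.asarray(labels, dtype=np.int64), C)
    values = np.zeros(stack.shape)
    values[tuple(fit.index.T)] = voxel_w
    return StatMap(values=values, kind="weight", mask=stack.mask.copy())


def fwm_weight_stack(stack: SampleStack, label_sets: np.ndarray,
                     C: float = DEFAULT_C, n_components: int | None = None
                     ) -> np.ndarray:
    """Voxel weight vectors for many labelings of the same data.

    The PCA and score scaling are computed once from the data (they do not
    depend on labels); each row of ``label_sets`` is solved at the component
    level and back-projected, which is how label permutations are handled.
    Returns (n_labelsets, n_in-mask_voxels).
    """
    label_sets = np.atleast_2d(np.asarray(label_sets, dtype=np.int64))
    fit = _prepare(stack, n_components)
    comp_w = np.empty((label_sets.shape[0], fit.pca.n_components))
    for r, labels in enumerate(label_sets):
        alpha, _ = _solve_dual(fit.kernel, labels, C, tol=1e-8,
                               max_iter=200_000)
        comp_w[r] = fit.scores_scaled.T @ (alpha * labels)
    # undo score scaling, then project through the loadings, all rows at once
    return (fit.pca.loadings @ (comp_w * fit.scaler.factor).T).T
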
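"""Model/Results objects wrapping the mapping and inference pipelines.

Two model classes are built from a :class:`~fwmap.data.SampleStack`:

``SearchlightDecoder``
    local decoding; ``fit()`` yields a voxel-wise cross-validated accuracy
    map.
``FeatureWeightMap``
    global mapping; ``fit()`` yields a signed voxel weight map from a
    whole-data linear SVM on the PCA-reduced data.

Both results objects expose ``permutation_inference()``, which attaches the
shared non-parametric framework (voxel-wise permutation p-values, cluster-
extent correction, FDR over cluster p-values) and returns an
:class:`InferenceResults` with the cluster table, significance maps and a
``summary()`` text table.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data import SampleStack, StatMap, read_stack
from .fwm import fwm_weights
from .searchlight import SearchlightParams, searchlight_map
from .stats import (ClusterTable, CorrectionParams, NullEnsemble,
                    build_null_ensemble)
from .svm import DEFAULT_C

__all__ = ["SearchlightDecoder", "FeatureWeightMap", "MapResults",
           "InferenceResults"]


class _MapModel:
    """Shared constructor plumbing for the two mapping models."""

    def __init__(self, stack: SampleStack):
        self.stack = stack

    @classmethod
    def from_files(cls, volumes_path, labels_path, mask_path=None, **kwargs):
        return cls(read_stack(volumes_path, labels_path, mask_path), **kwargs)


class SearchlightDecoder(_MapModel):
    """Spherical-searchlight decoding model.

    Parameters
    ----------
    stack : SampleStack
    radius : float
        Sphere radius, in voxels or mm depending on ``radius_unit``.
    C : float
        SVM soft-margin penalty.
    max_folds : int, optional
        Reproducibly subsample the leave-2-out folds for speed.
    """

    method = "sld"
    default_sidedness = "one"
    default_alpha_vox = 0.001

    def __init__(self, stack: SampleStack, radius: float = 3.0,
                 radius_unit: str = "voxel", C: float = DEFAULT_C,
                 max_folds: int | None = None, fold_seed: int = 0):
        super().__init__(stack)
        self.params = SearchlightParams(radius=radius, radius_unit=radius_unit,
                                        C=C, max_folds=max_folds,
                                        fold_seed=fold_seed)

    def fit(self) -> "MapResults":
        stat_map = searchlight_map(self.stack, self.params)
        return MapResults(model=self, stat_map=stat_map)

    @property
    def method_params(self):
        return self.params


class FeatureWeightMap(_MapModel):
    """Global feature-weight-mapping model (PCA + whole-data linear SVM)."""

    method = "fwm"
    default_sidedness = "two"
    default_alpha_vox = 0.05

    def __init__(self, stack: SampleStack, C: float = DEFAULT_C,
                 n_components: int | None = None):
        super().__init__(stack)
        self.C = C
        self.n_components = n_components

    def fit(self) -> "MapResults":
        stat_map = fwm_weights(self.stack, C=self.C,
                               n_components=self.n_components)
        return MapResults(model=self, stat_map=stat_map)

    @property
    def method_params(self):
        return {"C": self.C, "n_components": self.n_components}


@dataclasses.dataclass
class MapResults:
    """A fitted information map (accuracy or signed weight)."""

    model: _MapModel
    stat_map: StatMap

    @property
    def values(self) -> np.ndarray:
        return self.stat_map.values

    def permutation_inference(self, n_perm: int = 1000,
                              alpha_vox: float | None = None,
                              sidedness: str | None = None,
                              q: float = 0.05, seed: int = 0,
                              corrected: bool = True) -> "InferenceResults":
        """Non-parametric voxel + cluster inference for this map."""
        sidedness = sidedness or self.model.default_sidedness
        alpha_vox = (self.model.default_alpha_vox
                     if alpha_vox is None else alpha_vox)
        correction = CorrectionParams(alpha_vox=alpha_vox, sidedness=sidedness,
                                      q=q, n_perm=n_perm, seed=seed)
        ens = build_null_ensemble(self.model.stack, self.model.method,
                                  self.model.method_params,
                                  n_perm=n_perm, seed=seed)
        if corrected:
            table, sig_map, null = ens.corrected(alpha_vox, sidedness, q)
        else:
            from .stats import extract_clusters
            sig_map = ens.uncorrected(alpha_vox, sidedness)
            table = extract_clusters(sig_map)
            for c in table.clusters:
                c.significant = True
            null = None
        return InferenceResults(results=self, ensemble=ens,
                                correction=correction, corrected=corrected,
                                cluster_table=table, significant_map=sig_map,
                                cluster_null=null)


@dataclasses.dataclass
class InferenceResults:
    """Cluster table, p-values and significance maps for a fitted map."""

    results: MapResults
    ensemble: NullEnsemble
    correction: CorrectionParams
    corrected: bool
    cluster_table: ClusterTable
    significant_map: np.ndarray  # signed int8 volume
    cluster_null: object | None = None

    @property
    def clusters(self) -> pd.DataFrame:
        return self.cluster_table.to_dataframe()

    def voxel_p_map(self) -> np.ndarray:
        """Smallest-tail voxel p map (in-mask; 1 elsewhere)."""
        from .stats import voxel_pvalues
        p, _ = voxel_pvalues(self.results.stat_map, self.ensemble,
                             self.correction.sidedness)
        return p

    @property
    def n_significant_clusters(self) -> int:
        return int(sum(c.significant for c in self.cluster_table))

    def summary(self) -> str:
        model = self.results.model
        lines = [
            "Permutation cluster inference",
            "=" * 64,
            f"method:            {model.method}",
            f"samples:           {model.stack.n_samples} "
            f"({int((model.stack.labels == 1).sum())} class A, "
            f"{int((model.stack.labels == -1).sum())} class B)",
            f"volume:            {'x'.join(map(str, model.stack.shape))}, "
            f"{int(model.stack.mask.sum())} in-mask voxels",
            f"permutations:      {self.correction.n_perm} "
            f"(seed {self.correction.seed})",
            f"voxel threshold:   {self.correction.alpha_vox} "
            f"({self.correction.sidedness}-sided)",
            f"correction:        "
            f"{'cluster-extent + FDR q=%g' % self.correction.q if self.corrected else 'none (uncorrected)'}",
            f"clusters:          {len(self.cluster_table)} "
            f"({self.n_significant_clusters} significant)",
            f"significant voxels: {int((self.significant_map != 0).sum())}",
            "-" * 64,
        ]
        df = self.clusters
        if len(df):
            lines.append(df.to_string(index=False))
        else:
            lines.append("(no suprathreshold clusters)")
        return "\n".join(lines)
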
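"""Permutation inference shared by searchlight and feature weight maps.

The null hypothesis of no class information is simulated by re-labelling the
samples: each permutation reshuffles the (balanced) label vector, the full
map is recomputed, and the observed statistic of every voxel is ranked within
its permutation distribution. Empirical p-values use the conservative
``(b + 1) / (m + 1)`` convention, so no p-value is ever zero. Accuracy maps
are tested one-sided (upper tail); weight maps two-sided, flagging a voxel
positive when its upper-tail p is below alpha/2 and negative for the lower
tail.

Cluster-extent correction then thresholds the observed and every permuted map
at the same voxel-wise level, extracts 6-connected components (positive and
negative clusters separately for signed maps), pools the cluster sizes of the
permuted maps into an empirical null of cluster sizes, assigns each observed
cluster the tail probability of its size, and keeps the clusters surviving
Benjamini-Hochberg FDR at level q.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

from .data import SampleStack, StatMap
from .svm import n_distinct_label_arrangements

__all__ = [
    "CorrectionParams", "permute_labels", "voxel_pvalues", "binarize",
    "Cluster", "ClusterTable", "extract_clusters", "cluster_null_edf",
    "ClusterSizeNull", "fdr_select", "NullEnsemble", "build_null_ensemble",
    "run_corrected_pipeline",
]

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclasses.dataclass
class CorrectionParams:
    """Voxel threshold, sidedness, FDR level and permutation settings."""

    alpha_vox: float = 0.05
    sidedness: str = "two"
    q: float = 0.05
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_vox <= 1:
            raise ValueError("alpha_vox must be in (0, 1]")
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if self.sidedness not in ("one", "two"):
            raise ValueError("sidedness must be 'one' or 'two'")


def permute_labels(labels: np.ndarray, n_perm: int, seed: int | None = 0
                   ) -> np.ndarray:
    """Draw ``n_perm`` distinct random re-labelings (class balance preserved).

    Shuffling the label vector permutes a fixed multiset, so every draw keeps
    the 15/15 (or whatever) balance. The identity labelling and duplicate
    arrangements are excluded; raises if more distinct arrangements are
    requested than exist.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    available = n_distinct_label_arrangements(labels) - 1
    if n_perm > available:
        raise ValueError(
            f"requested {n_perm} permutations but only {available} distinct "
            "non-identity label arrangements exist")
    rng = np.random.default_rng(seed)
    seen = {labels.tobytes()}
    out = np.empty((n_perm, labels.size), dtype=np.int64)
    k = 0
    while k < n_perm:
        perm = rng.permutation(labels)
        key = perm.tobytes()
        if key in seen:
            continue
        seen.add(key)
        out[k] = perm
        k += 1
    return out


# ---------------------------------------------------------------------------
# voxel-level p-values


@njit(cache=True)
def _tail_counts(null):  # pragma: no cover - jit
    """Within-ensemble tail counts (self included) per permutation and voxel."""
    n, nvox = null.shape
    cnt_ge = np.empty((n, nvox), dtype=np.uint32)
    cnt_le = np.empty((n, nvox), dtype=np.uint32)
    for v in range(nvox):
        col = null[:, v].copy()
        srt = np.sort(col)
        for k in range(n):
            x = col[k]
            cnt_ge[k, v] = n - np.searchsorted(srt, x, side="left")
            cnt_le[k, v] = np.searchsorted(srt, x, side="right")
    return cnt_ge, cnt_le


def voxel_pvalues(observed: StatMap, null: "NullEnsemble",
                  sidedness: str = "one"
                  ) -> tuple[np.ndarray, np.ndarray | None]:
    """Empirical per-voxel p map (and sign map for two-sided tests).

    Upper-tail p = (#{perm >= observed} + 1) / (n_perm + 1); ties count as
    exceeding. The returned p map holds, for two-sided tests, the smaller
    tail probability of each voxel, with the sign map giving the tail (+1
    upper, -1 lower).
    """
    if observed.kind != null.kind:
        raise ValueError(f"kind mismatch: map is {observed.kind!r}, "
                         f"null is {null.kind!r}")
    obs = observed.values[null.mask]
    p_up, p_lo = null.observed_pvalues(obs)
    if sidedness == "one":
        p = np.ones(observed.values.shape)
        p[null.mask] = p_up
        return p, None
    p_vec = np.minimum(p_up, p_lo)
    sign_vec = np.where(p_up <= p_lo, 1, -1)
    p = np.ones(observed.values.shape)
    sign = np.zeros(observed.values.shape, dtype=np.int8)
    p[null.mask] = p_vec
    sign[null.mask] = sign_vec
    return p, sign


def binarize(p_map: np.ndarray, sign_map: np.ndarray | None,
             alpha_vox: float, sidedness: str,
             mask: np.ndarray | None = None) -> np.ndarray:
    """Threshold a p map into a {0,1} (one-sided) or {-1,0,+1} map."""
    if mask is None:
        mask = np.ones(p_map.shape, dtype=bool)
    out = np.zeros(p_map.shape, dtype=np.int8)
    if sidedness == "one":
        out[mask & (p_map <= alpha_vox)] = 1
        return out
    if sign_map is None:
        raise ValueError("two-sided binarization needs a sign map")
    hit = mask & (p_map <= alpha_vox / 2.0)
    out[hit] = sign_map[hit]
    return out


# ---------------------------------------------------------------------------
# clusters


@dataclasses.dataclass
class Cluster:
    id: int
    sign: int
    size: int
    coords: np.ndarray
    p: float = float("nan")
    significant: bool = False


@dataclasses.dataclass
class ClusterTable:
    """Maximal 6-connected components of a thresholded map."""

    clusters: list[Cluster]

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.clusters], dtype=np.int64)

    @property
    def pvalues(self) -> np.ndarray:
        return np.array([c.p for c in self.clusters])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": [c.id for c in self.clusters],
             "size": [c.size for c in self.clusters],
             "sign": [c.sign for c in self.clusters],
             "p": [c.p for c in self.clusters],
             "significant": [c.significant for c in self.clusters]},
            columns=["cluster", "size", "sign", "p", "significant"])

    def voxel_map(self, shape, significant_only: bool = True) -> np.ndarray:
        """Signed map of cluster membership (significant clusters only)."""
        out = np.zeros(shape, dtype=np.int8)
        for c in self.clusters:
            if c.significant or not significant_only:
                out[tuple(c.coords.T)] = c.sign
        return out


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return _STRUCT_6
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def extract_clusters(binary_map: np.ndarray, connectivity: int = 6
                     ) -> ClusterTable:
    """Connected components of a signed/unsigned binary map.

    Positive and negative voxels cluster separately: a +1 voxel is never
    merged with a face-adjacent -1 voxel.
    """
    struct = _structure(connectivity)
    clusters: list[Cluster] = []
    cid = 0
    for sign in (1, -1):
        labeled, n = ndimage.label(binary_map == sign, structure=struct)
        for lab in range(1, n + 1):
            coords = np.argwhere(labeled == lab)
            cid += 1
            clusters.append(Cluster(id=cid, sign=sign, size=coords.shape[0],
                                    coords=coords))
    return ClusterTable(clusters=clusters)


def _cluster_sizes(binary_map: np.ndarray, connectivity: int = 6) -> np.ndarray:
    """Sizes of all (signed) clusters, without materialising coordinates."""
    struct = _structure(connectivity)
    sizes = []
    for sign in (1, -1):
        labeled, n = ndimage.label(binary_map == sign, structure=struct)
        if n:
            sizes.append(np.bincount(labeled.ravel())[1:])
    if not sizes:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(sizes).astype(np.int64)


@dataclasses.dataclass
class ClusterSizeNull:
    """Empirical distribution of cluster sizes pooled over permuted maps."""

    sizes: np.ndarray  # sorted ascending

    @property
    def n(self) -> int:
        return self.sizes.size

    def pvalue(self, size) -> np.ndarray:
        """P(null cluster size >= s), (b + 1)/(N + 1) convention."""
        size = np.atleast_1d(size)
        count_ge = self.n - np.searchsorted(self.sizes, size, side="left")
        return (count_ge + 1) / (self.n + 1)


def cluster_null_edf(permuted_binary_maps, connectivity: int = 6
                     ) -> ClusterSizeNull:
    """Pool cluster sizes from all permuted binarized maps into one null."""
    all_sizes = [_cluster_sizes(bm, connectivity) for bm in permuted_binary_maps]
    pooled = (np.concatenate(all_sizes) if all_sizes
              else np.empty(0, dtype=np.int64))
    return ClusterSizeNull(sizes=np.sort(pooled))


def fdr_select(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up selection at FDR level q."""
    pvalues = np.asarray(pvalues, dtype=np.float64)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if pvalues.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(pvalues, alpha=q, method="fdr_bh")[0]


# ---------------------------------------------------------------------------
# the null ensemble and the corrected pipeline


class NullEnsemble:
    """Observed map plus its per-voxel permutation distribution.

    Stores the statistic of every in-mask voxel for the observed labelling
    (``observed``, shape ``(n_voxels,)``) and for each permutation (``null``,
    shape ``(n_perm, n_voxels)``). All thresholding downstream reuses this
    object, so a sweep over voxel-wise thresholds costs no additional map
    recomputation.
    """

    def __init__(self, observed: np.ndarray, null: np.ndarray,
                 mask: np.ndarray, kind: str,
                 permutations: np.ndarray | None = None):
        self.observed = np.asarray(observed, dtype=np.float64)
        self.null = np.ascontiguousarray(null, dtype=np.float64)
        self.mask = np.asarray(mask).astype(bool)
        self.index = np.argwhere(self.mask)
        self.kind = kind
        self.permutations = permutations
        if self.null.shape[1] != self.observed.size:
            raise ValueError("null and observed voxel counts differ")
        if self.observed.size != int(self.mask.sum()):
            raise ValueError("mask does not match voxel count")
        self._tails: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def n_perm(self) -> int:
        return self.null.shape[0]

    # -- voxel-level p-values ------------------------------------------------
    def observed_pvalues(self, obs: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
        """(upper, lower) tail p-vectors of the observed map, (b+1)/(m+1)."""
        if obs is None:
            obs = self.observed
        cnt_ge = (self.null >= obs).sum(axis=0)
        cnt_le = (self.null <= obs).sum(axis=0)
        n = self.n_perm
        return (cnt_ge + 1) / (n + 1), (cnt_le + 1) / (n + 1)

    def _perm_tail_counts(self) -> tuple[np.ndarray, np.ndarray]:
        if self._tails is None:
            self._tails = _tail_counts(self.null)
        return self._tails

    # -- binarization --------------------------------------------------------
    def _to_volume(self, vec: np.ndarray, dtype=np.int8) -> np.ndarray:
        out = np.zeros(self.mask.shape, dtype=dtype)
        out[tuple(self.index.T)] = vec
        return out

    def binarize_observed(self, alpha_vox: float, sidedness: str) -> np.ndarray:
        p_up, p_lo = self.observed_pvalues()
        if sidedness == "one":
            return self._to_volume((p_up <= alpha_vox).astype(np.int8))
        vec = np.zeros(self.observed.size, dtype=np.int8)
        vec[p_up <= alpha_vox / 2.0] = 1
        vec[(p_lo <= alpha_vox / 2.0) & (p_lo < p_up)] = -1
        return self._to_volume(vec)

    def binarize_permutation(self, k: int, alpha_vox: float, sidedness: str
                             ) -> np.ndarray:
        """Permuted map k thresholded against the pooled ensemble.

        Each permutation is ranked within the full ensemble, itself included
        (p = count / n_perm). Ranking it among the other permutations with
        the (b+1)/(m+1) convention gives the identical value, so the two
        readings of the procedure coincide.
        """
        cnt_ge, cnt_le = self._perm_tail_counts()
        p_up = cnt_ge[k] / self.n_perm
        p_lo = cnt_le[k] / self.n_perm
        if sidedness == "one":
            return self._to_volume((p_up <= alpha_vox).astype(np.int8))
        vec = np.zeros(p_up.size, dtype=np.int8)
        vec[p_up <= alpha_vox / 2.0] = 1
        vec[(p_lo <= alpha_vox / 2.0) & (p_lo < p_up)] = -1
        return self._to_volume(vec)

    def observed_stat_map(self) -> StatMap:
        return StatMap(values=self._to_volume(self.observed, dtype=np.float64),
                       kind=self.kind, mask=self.mask.copy())

    # -- correction ----------------------------------------------------------
    def uncorrected(self, alpha_vox: float, sidedness: str) -> np.ndarray:
        """Signed significance map from voxel-wise thresholding alone."""
        return self.binarize_observed(alpha_vox, sidedness)

    def corrected(self, alpha_vox: float, sidedness: str, q: float = 0.05,
                  connectivity: int = 6
                  ) -> tuple[ClusterTable, np.ndarray, ClusterSizeNull]:
        """Cluster-extent correction with FDR over cluster p-values.

        Returns the observed cluster table (with p-values and significance
        flags), the signed significant-voxel map, and the cluster-size null.
        """
        obs_bin = self.binarize_observed(alpha_vox, sidedness)
        table = extract_clusters(obs_bin, connectivity)
        null = cluster_null_edf(
            (self.binarize_permutation(k, alpha_vox, sidedness)
             for k in range(self.n_perm)),
            connectivity)
        if len(table):
            pvals = null.pvalue(table.sizes)
            sig = fdr_select(pvals, q)
            for c, p, s in zip(table.clusters, pvals, sig):
                c.p = float(p)
                c.significant = bool(s)
        sig_map = table.voxel_map(self.mask.shape, significant_only=True)
        return table, sig_map, null


def build_null_ensemble(stack: SampleStack, method: str,
                        method_params=None, n_perm: int = 1000,
                        seed: int | None = 0) -> NullEnsemble:
    """Compute the observed map and its label-permutation ensemble.

    ``method`` is 'sld' (searchlight accuracies; the permutation list is held
    fixed across searchlight locations, preserving spatial correlations) or
    'fwm' (weight maps; permutations are applied at the principal-component
    level on a single PCA of the data).
    """
    from .fwm import fwm_weight_stack
    from .searchlight import SearchlightParams, searchlight_accuracy_stack

    perms = permute_labels(stack.labels, n_perm, seed)
    label_sets = np.vstack([stack.labels[None, :], perms])
    if method == "sld":
        params = method_params or SearchlightParams()
        maps = searchlight_accuracy_stack(stack, params, label_sets)
        kind = "accuracy"
    elif method == "fwm":
        kwargs = dict(method_params or {})
        maps = fwm_weight_stack(stack, label_sets, **kwargs)
        kind = "weight"
    else:
        raise ValueError(f"unknown method {method!r}")
    return NullEnsemble(observed=maps[0], null=maps[1:], mask=stack.mask,
                        kind=kind, permutations=perms)


def run_corrected_pipeline(stack: SampleStack, method: str,
                           method_params=None,
                           correction: CorrectionParams | None = None,
                           corrected: bool = True
                           ) -> tuple[StatMap, ClusterTable, np.ndarray]:
    """End-to-end: observed map, permutation null, clusters, FDR.

    With ``corrected=False`` the pipeline stops after voxel-wise
    binarization; every suprathreshold voxel is deemed significant and the
    cluster table is empty of p-values (clusters are still reported).
    """
    correction = correction or CorrectionParams()
    ens = build_null_ensemble(stack, method, method_params,
                              n_perm=correction.n_perm, seed=correction.seed)
    stat_map = ens.observed_stat_map()
    if corrected:
        table, sig_map, _ = ens.corrected(correction.alpha_vox,
                                          correction.sidedness, correction.q)
    else:
        sig_map = ens.uncorrected(correction.alpha_vox, correction.sidedness)
        table = extract_clusters(sig_map)
        for c in table.clusters:
            c.significant = True
    return stat_map, table, sig_map
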
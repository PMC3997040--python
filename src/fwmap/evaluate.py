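"""Precision/sensitivity of detected voxels against ground truth.

Precision = TP / (TP + FP), sensitivity = TP / (TP + FN), counted over
voxels: a detected voxel of either sign inside any informative block is a
true positive. For per-coarseness curves the volume is split into equal
thirds along the first axis, each of which contains exactly one half-cube
pair by the simulation layout. Precision with zero detections is undefined
and recorded as NaN, never imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import SampleStack, TruthMask
from .stats import CorrectionParams, NullEnsemble, build_null_ensemble

__all__ = ["precision_sensitivity", "region_thirds", "sweep_ensemble",
           "threshold_sweep", "write_pr_table", "read_pr_table",
           "precision_at_sensitivity"]

REGION_NAMES = ("fine", "intermediate", "coarse")

#: default voxel-wise threshold grid, spanning both methods' useful regimes
DEFAULT_THRESHOLDS = (0.0005, 0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5)


def region_thirds(shape) -> dict[str, tuple[slice, slice, slice]]:
    """Equal thirds of the volume along the first (pair layout) axis."""
    nx = shape[0]
    bounds = [0, nx // 3, 2 * nx // 3, nx]
    return {name: (slice(bounds[i], bounds[i + 1]), slice(None), slice(None))
            for i, name in enumerate(REGION_NAMES)}


def confusion_counts(detected: np.ndarray, truth: TruthMask,
                     region=None) -> tuple[int, int, int]:
    """(TP, FP, FN) voxel counts, optionally restricted to a region."""
    det = np.asarray(detected) != 0
    sup = truth.support
    if det.shape != sup.shape:
        raise ValueError("detected map and truth are on different grids")
    if region is not None:
        det = det[region]
        sup = sup[region]
    tp = int((det & sup).sum())
    fp = int((det & ~sup).sum())
    fn = int((~det & sup).sum())
    return tp, fp, fn


def precision_sensitivity(detected: np.ndarray, truth: TruthMask,
                          region=None) -> tuple[float, float]:
    """Precision (NaN when nothing is detected) and sensitivity."""
    tp, fp, fn = confusion_counts(detected, truth, region)
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    return precision, sensitivity


def sweep_ensemble(ens: NullEnsemble, truth: TruthMask, method: str,
                   thresholds=DEFAULT_THRESHOLDS, corrected: bool = True,
                   sidedness: str = "two", q: float = 0.05,
                   regions: str = "thirds") -> pd.DataFrame:
    """Precision/sensitivity per (threshold, region) on a shared ensemble.

    The permutation ensemble is computed once; each threshold only re-runs
    the (cheap) binarization / cluster stage. ``regions='thirds'`` evaluates
    the three coarseness regions, ``'whole'`` the full volume.
    """
    thresholds = list(thresholds)
    if any(t2 <= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    if regions == "thirds":
        region_map = region_thirds(truth.values.shape)
    elif regions == "whole":
        region_map = {"whole": None}
    else:
        raise ValueError("regions must be 'thirds' or 'whole'")
    rows = []
    for alpha in thresholds:
        if corrected:
            _, detected, _ = ens.corrected(alpha, sidedness, q)
        else:
            detected = ens.uncorrected(alpha, sidedness)
        for rname, rslice in region_map.items():
            tp, fp, fn = confusion_counts(detected, truth, rslice)
            rows.append({
                "method": method, "region": rname, "alpha_vox": alpha,
                "corrected": corrected, "TP": tp, "FP": fp, "FN": fn,
                "precision": tp / (tp + fp) if tp + fp else float("nan"),
                "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            })
    return pd.DataFrame(rows)


def threshold_sweep(stack: SampleStack, truth: TruthMask, method: str,
                    thresholds=DEFAULT_THRESHOLDS, corrected: bool = True,
                    correction: CorrectionParams | None = None,
                    method_params=None, regions: str = "thirds"
                    ) -> pd.DataFrame:
    """Build the permutation ensemble for ``method`` and sweep thresholds."""
    correction = correction or CorrectionParams()
    ens = build_null_ensemble(stack, method, method_params,
                              n_perm=correction.n_perm, seed=correction.seed)
    return sweep_ensemble(ens, truth, method, thresholds=thresholds,
                          corrected=corrected, sidedness=correction.sidedness,
                          q=correction.q, regions=regions)


def write_pr_table(points: pd.DataFrame, path) -> None:
    cols = ["method", "region", "alpha_vox", "corrected",
            "TP", "FP", "FN", "precision", "sensitivity"]
    out = points[cols] if len(points) else pd.DataFrame(columns=cols)
    out.to_csv(path, sep="\t", index=False)


def read_pr_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def plot_pr_curves(points: pd.DataFrame, ax=None):
    """Precision-sensitivity scatter per method (one panel, simple helper)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    colors = {"fwm": "tab:red", "sld": "tab:blue"}
    for method, sub in points.groupby("method"):
        sub = sub.sort_values("sensitivity")
        ax.plot(sub["sensitivity"], sub["precision"], "o-",
                color=colors.get(method, None), label=method)
    ax.set_xlabel("sensitivity")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def precision_at_sensitivity(points: pd.DataFrame, sensitivity: float) -> float:
    """Best precision among sweep points reaching at least this sensitivity.

    NaN when no point reaches the requested sensitivity or none of the
    qualifying points has a defined precision.
    """
    ok = points[(points["sensitivity"] >= sensitivity)
                & points["precision"].notna()]
    return float(ok["precision"].max()) if len(ok) else float("nan")
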
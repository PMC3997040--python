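"""Domain containers and volumetric/tabular I/O.

The central container is :class:`SampleStack`: a stack of 3-D volumes (one per
trial / beta-map) with a two-class label per volume and a boolean analysis
mask. Labels are encoded internally as +1 (class A) and -1 (class B).
Flattening a stack yields the ``n_samples x n_voxels`` feature matrix whose
columns are the in-mask voxels; an index table maps columns back to voxel
coordinates. Coordinates are 0-based voxel indices throughout; physical units
enter only through ``voxel_size`` (mm), used for mm-radius searchlights.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "SampleStack",
    "StatMap",
    "TruthMask",
    "read_stack",
    "read_labels",
    "write_stack",
    "write_labels",
    "write_stat_map",
    "read_stat_map",
    "write_cluster_table",
    "read_cluster_table",
    "flatten",
    "unflatten",
]


@dataclasses.dataclass
class SampleStack:
    """n samples of a 3-D volume, per-sample class labels, analysis mask.

    Parameters
    ----------
    data : ndarray, shape (n_samples, nx, ny, nz)
        One 3-D volume per sample, arbitrary signal units.
    labels : ndarray, shape (n_samples,)
        +1 for class A, -1 for class B.
    mask : ndarray of bool, shape (nx, ny, nz), optional
        Analysis mask; defaults to all voxels.
    voxel_size : tuple of float
        Physical voxel edge lengths in mm (default isotropic 1.0).
    """

    data: np.ndarray
    labels: np.ndarray
    mask: np.ndarray | None = None
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (sample, x, y, z)")
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, (-1, 1)).all():
            raise ValueError("labels must be +1 (class A) or -1 (class B)")
        self.labels = self.labels.astype(np.int64)
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError(
                f"label count {self.labels.shape} does not match "
                f"sample count {self.data.shape[0]}"
            )
        if self.mask is None:
            self.mask = np.ones(self.data.shape[1:], dtype=bool)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match volume shape "
                f"{self.data.shape[1:]}"
            )
        for lab in (1, -1):
            if int((self.labels == lab).sum()) < 2:
                raise ValueError("each class needs at least 2 samples")
        self.voxel_size = tuple(float(v) for v in np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float).ravel(), (3,)))

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclasses.dataclass
class StatMap:
    """One scalar per voxel; ``kind`` is 'accuracy' or 'weight'.

    Out-of-mask voxels hold 0 and are meaningless.
    """

    values: np.ndarray
    kind: str
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("accuracy", "weight"):
            raise ValueError(f"unknown map kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values")
        if self.kind == "accuracy":
            inm = self.values[self.mask]
            if inm.size and ((inm < 0) | (inm > 1)).any():
                raise ValueError("accuracy values must lie in [0, 1]")


@dataclasses.dataclass
class TruthMask:
    """Signed ground truth: +1 class-A informative, -1 class-B, 0 background."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValueError("truth values must be in {-1, 0, +1}")
        self.values = self.values.astype(np.int8)

    @property
    def support(self) -> np.ndarray:
        return self.values != 0

    @property
    def n_informative(self) -> int:
        return int(self.support.sum())


# ---------------------------------------------------------------------------
# label files


def read_labels(path: str | Path, mapping: dict[str, int] | None = None) -> np.ndarray:
    """Read a two-column TSV (sample index, class label) into +1/-1 labels.

    Arbitrary string labels are accepted; they are mapped to +1/-1 by
    first-seen order unless ``mapping`` gives an explicit assignment.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ValueError("label file needs (sample, label) columns")
    raw = table.iloc[:, 1].to_numpy()
    classes = list(dict.fromkeys(raw))
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 distinct labels, got {classes}")
    if mapping is None:
        mapping = {classes[0]: 1, classes[1]: -1}
    try:
        return np.array([mapping[str(v)] for v in raw], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"label {exc} missing from mapping") from exc


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    labels = np.asarray(labels)
    names = np.where(labels == 1, "A", "B")
    pd.DataFrame({"sample": np.arange(labels.size), "label": names}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _nifti_affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_stack(stack: SampleStack, volumes_path: str | Path,
                labels_path: str | Path | None = None,
                mask_path: str | Path | None = None) -> None:
    """Write a stack as a 4-D NIfTI (x, y, z, sample on disk)."""
    img = nib.Nifti1Image(np.moveaxis(stack.data, 0, -1),
                          _nifti_affine(stack.voxel_size))
    nib.save(img, str(volumes_path))
    if labels_path is not None:
        write_labels(stack.labels, labels_path)
    if mask_path is not None:
        nib.save(nib.Nifti1Image(stack.mask.astype(np.uint8),
                                 _nifti_affine(stack.voxel_size)),
                 str(mask_path))


def read_stack(volumes_path: str | Path, labels_path: str | Path,
               mask_path: str | Path | None = None,
               label_mapping: dict[str, int] | None = None) -> SampleStack:
    """Load a 4-D NIfTI + labels TSV (+ optional mask NIfTI) as a SampleStack."""
    img = nib.load(str(volumes_path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., None]
    if arr.ndim != 4:
        raise ValueError("volumes file must be a 3-D or 4-D NIfTI")
    data = np.moveaxis(arr, -1, 0)
    labels = read_labels(labels_path, mapping=label_mapping)
    if labels.shape[0] != data.shape[0]:
        raise ValueError(
            f"label file has {labels.shape[0]} rows for {data.shape[0]} volumes"
        )
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SampleStack(data=data, labels=labels, mask=mask, voxel_size=vs)


def write_stat_map(stat_map: StatMap, path: str | Path,
                   voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write a stat map as NIfTI; out-of-mask voxels are written as 0."""
    vals = np.where(stat_map.mask, stat_map.values, 0.0)
    nib.save(nib.Nifti1Image(vals, _nifti_affine(voxel_size)), str(path))


def read_stat_map(path: str | Path, kind: str,
                  mask: np.ndarray | None = None) -> StatMap:
    vals = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    return StatMap(values=vals, kind=kind, mask=mask)


def write_cluster_table(table: "pd.DataFrame", path: str | Path) -> None:
    """Write a cluster table (id, size, sign, p, significant) as TSV."""
    cols = ["cluster", "size", "sign", "p", "significant"]
    out = table[cols] if len(table) else pd.DataFrame(columns=cols)
    out.to_csv(path, sep="\t", index=False)


def read_cluster_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# flattening


def flatten(stack: SampleStack) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a stack to an (n_samples, n_in-mask_voxels) feature matrix.

    Returns
    -------
    matrix : ndarray
        Column j holds voxel j's value across samples.
    index : ndarray, shape (n_voxels, 3)
        Voxel coordinates (x, y, z) of each column.
    """
    if not stack.mask.any():
        raise ValueError("mask is empty")
    index = np.argwhere(stack.mask)
    matrix = stack.data[:, stack.mask]
    return matrix, index


def unflatten(matrix: np.ndarray, index: np.ndarray, shape: tuple[int, int, int],
              fill: float = 0.0) -> np.ndarray:
    """Inverse of :func:`flatten` for one vector or a sample-by-voxel matrix."""
    matrix = np.asarray(matrix)
    single = matrix.ndim == 1
    if single:
        matrix = matrix[None, :]
    out = np.full((matrix.shape[0],) + tuple(shape), fill, dtype=np.float64)
    out[:, index[:, 0], index[:, 1], index[:, 2]] = matrix
    return out[0] if single else out
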
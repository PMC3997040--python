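"""Synthetic two-class volume generator with ground-truth half-cube pairs.

Each sample is a 66 x 22 x 22 volume of i.i.d. standard-normal noise, lightly
smoothed (Gaussian, FWHM 1 voxel), to which a constant signal offset of 0.5 is
added inside the informative regions of the sample's own class. The
informative regions are three pairs of half-cubes of in-plane extent 6 x 6,
stacked above (+1, class A) and below (-1, class B) the volume mid-plane along
the third axis. The three pairs differ in how finely the information is
spread: thickness 1 with a 4-voxel gap (fine), thickness 2 with a 2-voxel gap
(intermediate), thickness 3 with no gap (coarse). Pairs are laid out
left-to-right along the first axis, so the three equal thirds of the volume
along that axis each contain exactly one pair.

The offset is added after smoothing, so truth-region edges are sharp. The
noise field is smoothed with nearest-edge replication to avoid variance
darkening at the volume boundary.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data import SampleStack, TruthMask

__all__ = ["SimulationParams", "build_truth_mask", "smooth_gaussian",
           "generate_dataset", "crop_region", "fwhm_to_sigma"]

#: FWHM of a Gaussian = sigma * sqrt(8 ln 2)
_FWHM_FACTOR = float(np.sqrt(8.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    return float(fwhm) / _FWHM_FACTOR


@dataclasses.dataclass
class SimulationParams:
    """Geometry and noise parameters of the synthetic data set.

    Defaults reproduce the study conditions: 30 samples (15 per class) of
    66 x 22 x 22 voxels, N(0, 1) noise, FWHM-1 smoothing, offset 0.5, and
    three half-cube pairs of 6 x 6 x {1, 2, 3} voxels with gaps {4, 2, 0}.
    """

    shape: tuple[int, int, int] = (66, 22, 22)
    n_per_class: int = 15
    offset: float = 0.5
    fwhm: float = 1.0
    base: tuple[int, int] = (6, 6)
    thicknesses: tuple[int, ...] = (1, 2, 3)
    gaps: tuple[int, ...] = (4, 2, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3:
            raise ValueError("shape must be a voxel triple")
        if len(self.thicknesses) != len(self.gaps):
            raise ValueError("thicknesses and gaps must have equal length")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.fwhm < 0:
            raise ValueError("fwhm must be >= 0")
        if self.n_per_class < 2:
            raise ValueError("need at least 2 samples per class")

    @property
    def n_pairs(self) -> int:
        return len(self.thicknesses)

    def pair_centers_x(self) -> list[int]:
        """Centres of the pairs along the first axis (evenly spaced)."""
        n = self.n_pairs
        span = self.shape[0] / n
        return [int(span * (i + 0.5)) for i in range(n)]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationParams":
        d = json.loads(Path(path).read_text())
        for key in ("shape", "base", "thicknesses", "gaps"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def build_truth_mask(params: SimulationParams) -> TruthMask:
    """Construct the signed ground-truth map of informative half-cubes.

    For pair i the upper block (+1) starts at ``mid + ceil(gap/2)`` along the
    third axis and the lower block (-1) ends just below ``mid - ceil(gap/2)``,
    where ``mid = nz // 2``; this splits the configured gap symmetrically
    about the volume mid-plane and makes a gap of 0 produce two touching
    blocks.
    """
    nx, ny, nz = params.shape
    bx, by = params.base
    truth = np.zeros(params.shape, dtype=np.int8)
    mid_z = nz // 2
    y0 = ny // 2 - by // 2
    for cx, thick, gap in zip(params.pair_centers_x(), params.thicknesses,
                              params.gaps):
        x0 = cx - bx // 2
        half_gap = int(np.ceil(gap / 2))
        z_up = mid_z + half_gap
        z_lo_end = mid_z - half_gap
        if (x0 < 0 or x0 + bx > nx or y0 < 0 or y0 + by > ny
                or z_up + thick > nz or z_lo_end - thick < 0):
            raise ValueError("half-cube geometry does not fit inside volume")
        if (truth[x0:x0 + bx, y0:y0 + by, z_up:z_up + thick] != 0).any():
            raise ValueError("half-cube pairs overlap")
        truth[x0:x0 + bx, y0:y0 + by, z_up:z_up + thick] = 1
        truth[x0:x0 + bx, y0:y0 + by, z_lo_end - thick:z_lo_end] = -1
    return TruthMask(values=truth)


def smooth_gaussian(volume: np.ndarray, fwhm: float) -> np.ndarray:
    """Separable Gaussian smoothing with a unit-sum kernel.

    ``sigma = fwhm / sqrt(8 ln 2)`` per axis; ``fwhm = 0`` returns the input
    unchanged. Boundaries use nearest-edge replication.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    volume = np.asarray(volume, dtype=np.float64)
    if fwhm == 0:
        return volume.copy()
    return ndimage.gaussian_filter(volume, sigma=fwhm_to_sigma(fwhm),
                                   mode="nearest")


def generate_dataset(params: SimulationParams) -> tuple[SampleStack, TruthMask]:
    """Draw the synthetic stack: noise, smooth, add class-specific offsets.

    Class A samples get ``+offset`` at +1 truth voxels only, class B samples
    at -1 truth voxels only. The first ``n_per_class`` samples are class A.
    Deterministic given ``params.seed``.
    """
    truth = build_truth_mask(params)
    rng = np.random.default_rng(params.seed)
    n = 2 * params.n_per_class
    data = np.empty((n,) + params.shape, dtype=np.float64)
    labels = np.concatenate([np.ones(params.n_per_class, dtype=np.int64),
                             -np.ones(params.n_per_class, dtype=np.int64)])
    up = truth.values == 1
    lo = truth.values == -1
    for i in range(n):
        vol = smooth_gaussian(rng.standard_normal(params.shape), params.fwhm)
        vol[up if labels[i] == 1 else lo] += params.offset
        data[i] = vol
    stack = SampleStack(data=data, labels=labels)
    return stack, truth


def crop_region(stack: SampleStack, truth: TruthMask,
                x_slice: slice, y_slice: slice, z_slice: slice
                ) -> tuple[SampleStack, TruthMask]:
    """Crop stack and truth to a subvolume (used for scaled-down analyses)."""
    sub = SampleStack(
        data=stack.data[:, x_slice, y_slice, z_slice].copy(),
        labels=stack.labels.copy(),
        mask=stack.mask[x_slice, y_slice, z_slice].copy(),
        voxel_size=stack.voxel_size,
    )
    return sub, TruthMask(values=truth.values[x_slice, y_slice, z_slice].copy())
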
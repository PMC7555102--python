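"""Group-level probability maps and maximum probability maps (MPMs).

Subject parcellations living on one template grid are binarized per label
and averaged into a per-voxel fraction-of-subjects map; thresholding that
fraction (inclusively, at 50% by default, i.e. "at least half of the
sample") gives the binary MPM from which volumes and centers of gravity
are reported in template mm coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cbp_engine import LabelParcellation, ShapeError


class GeometryError(ValueError):
    pass


@dataclass
class ProbabilityMap:
    """Per-voxel fraction of subjects whose parcel covers the voxel."""

    fraction: np.ndarray
    label_name: str
    n_subjects: int

    def __post_init__(self) -> None:
        self.fraction = np.asarray(self.fraction, dtype=float)
        if np.any(self.fraction < 0) or np.any(self.fraction > 1):
            raise ValueError("fractions must lie in [0, 1]")
        counts = self.fraction * self.n_subjects
        if not np.allclose(counts, np.round(counts), atol=1e-6):
            raise ValueError("fraction x n_subjects must be integral")


@dataclass
class MPMask:
    """Thresholded binary maximum probability map with its affine."""

    mask: np.ndarray
    label_name: str
    threshold_fraction: float
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must lie in (0, 1]")
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")


def build_probability_map(
    parcels: Sequence[LabelParcellation], label: str
) -> ProbabilityMap:
    """Fraction of subjects whose parcel for `label` covers each voxel."""
    if not parcels:
        raise ValueError("need at least one parcellation")
    if label not in parcels[0].label_names:
        raise KeyError(f"unknown label {label!r}; have {parcels[0].label_names}")
    shape = parcels[0].labels.shape
    count = np.zeros(shape, dtype=float)
    for p in parcels:
        if p.labels.shape != shape:
            raise ShapeError(f"parcellation grid {p.labels.shape} != {shape}")
        count += p.mask(label)
    return ProbabilityMap(fraction=count / len(parcels), label_name=label, n_subjects=len(parcels))


def threshold_mpm(
    pmap: ProbabilityMap, threshold_fraction: float = 0.5, affine: np.ndarray | None = None
) -> MPMask:
    """Retain voxels covered in at least ``threshold_fraction`` of subjects.

    The comparison is inclusive (>=): a voxel present in exactly half of
    the sample survives the default 50% threshold.
    """
    if affine is None:
        affine = np.eye(4)
    return MPMask(
        mask=pmap.fraction >= threshold_fraction,
        label_name=pmap.label_name,
        threshold_fraction=threshold_fraction,
        affine=affine,
    )


def mask_volume_mm3(mask: MPMask) -> float:
    """Mask volume = voxel count x |det| of the affine's linear part."""
    lin = mask.affine[:3, :3]
    det = np.linalg.det(lin)
    if det == 0:
        raise GeometryError("singular affine: voxel volume undefined")
    return float(mask.mask.sum() * abs(det))


def center_of_gravity(mask: MPMask, weights: np.ndarray | None = None) -> np.ndarray:
    """Centroid of the mask voxels, in template mm coordinates.

    By default the unweighted centroid of the binary mask; pass the
    probability fractions as ``weights`` for a sensitivity variant weighted
    by subject coverage.
    """
    voxels = np.argwhere(mask.mask)
    if voxels.size == 0:
        raise ValueError(f"empty mask {mask.label_name!r}: COG undefined")
    if weights is None:
        centroid_vox = voxels.mean(axis=0)
    else:
        w = np.asarray(weights, dtype=float)[mask.mask]
        centroid_vox = (voxels * w[:, None]).sum(axis=0) / w.sum()
    return mask.affine[:3, :3] @ centroid_vox + mask.affine[:3, 3]
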
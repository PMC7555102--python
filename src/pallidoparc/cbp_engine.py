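"""Winner-takes-all connectivity-based parcellation.

The hard-segmentation core: per-target track-density maps restricted to a
seed ROI are intensity-normalized and each seed voxel is assigned to the
target with the largest normalized density there. Chaining two such stages
— relay nuclei parcellated by cortical connectivity, then the pallidal
segments parcellated against the relay clusters — yields one label map per
(pallidal nucleus, pathway) combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np


class NormalizationError(ValueError):
    """Raised when a density map cannot be normalized (all-zero in ROI)."""


class ShapeError(ValueError):
    """Raised when maps or ROIs disagree on grid or seed."""


@dataclass
class DensityMap:
    """Nonnegative connectivity-density volume from one seed to one target.

    ``values`` must be zero outside ``seed_roi`` and finite everywhere.
    """

    values: np.ndarray
    seed_roi: np.ndarray
    target_label: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.seed_roi = np.asarray(self.seed_roi, dtype=bool)
        if self.values.shape != self.seed_roi.shape:
            raise ShapeError(
                f"density grid {self.values.shape} != ROI grid {self.seed_roi.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite density values ({self.subject_id}/{self.target_label})")
        if np.any(self.values < 0):
            raise ValueError(f"negative density values ({self.subject_id}/{self.target_label})")
        if np.any(self.values[~self.seed_roi] != 0):
            raise ValueError(
                f"density nonzero outside seed ROI ({self.subject_id}/{self.target_label})"
            )


@dataclass
class LabelParcellation:
    """Hard segmentation of a seed ROI: integer labels, 0 = unlabeled."""

    labels: np.ndarray
    label_names: list[str]
    seed_roi: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.seed_roi = np.asarray(self.seed_roi, dtype=bool)
        if self.labels.shape != self.seed_roi.shape:
            raise ShapeError("label grid does not match ROI grid")
        if np.any(self.labels[~self.seed_roi] != 0):
            raise ValueError("labels nonzero outside seed ROI")

    def mask(self, label: str | int) -> np.ndarray:
        """Binary mask of one parcel, by name or 1-based index."""
        if isinstance(label, str):
            label = self.label_names.index(label) + 1
        return self.labels == label


def normalize_density(dmap: DensityMap, mean_mode: str = "positive") -> DensityMap:
    """Divide in-ROI intensities by their mean intensity value.

    ``mean_mode`` selects the voxels over which the mean is taken:
    ``"positive"`` (default) averages only strictly positive in-ROI voxels,
    so sparsely covered maps are not deflated by their zeros; ``"all"``
    averages every ROI voxel. Zeros stay zero either way, and the mean of
    the output's positive (resp. all-ROI) values is 1.
    """
    inroi = dmap.values[dmap.seed_roi]
    pos = inroi[inroi > 0]
    if pos.size == 0:
        raise NormalizationError(
            f"all-zero density map for subject={dmap.subject_id!r} "
            f"target={dmap.target_label!r}: cannot normalize"
        )
    if mean_mode == "positive":
        mean = pos.mean()
    elif mean_mode == "all":
        mean = inroi.mean()
    else:
        raise ValueError(f"unknown mean_mode {mean_mode!r}")
    return replace(dmap, values=dmap.values / mean)


def winner_takes_all(maps: Sequence[DensityMap]) -> LabelParcellation:
    """Assign each seed voxel to the target with the largest density.

    Voxels where every map is zero stay unlabeled (0); exact ties go to the
    lowest target index, with targets ordered as the input sequence.
    Expects >= 2 maps sharing one grid and seed ROI (already normalized when
    called on raw track densities).
    """
    if len(maps) < 2:
        raise ValueError(f"winner-takes-all needs >= 2 maps, got {len(maps)}")
    roi = maps[0].seed_roi
    for m in maps[1:]:
        if m.values.shape != maps[0].values.shape or not np.array_equal(m.seed_roi, roi):
            raise ShapeError(
                f"map {m.target_label!r} disagrees on grid or seed ROI with {maps[0].target_label!r}"
            )
    stack = np.stack([m.values for m in maps])
    # argmax returns the first (lowest-index) maximum, which is the tie rule
    winner = np.argmax(stack, axis=0) + 1
    any_positive = np.any(stack > 0, axis=0)
    labels = np.where(roi & any_positive, winner, 0).astype(np.int32)
    return LabelParcellation(
        labels=labels,
        label_names=[m.target_label for m in maps],
        seed_roi=roi,
    )


def parcellate_subject(
    maps: Sequence[DensityMap], mean_mode: str = "positive"
) -> LabelParcellation:
    """Normalize each map then run winner-takes-all — one subject, one seed."""
    return winner_takes_all([normalize_density(m, mean_mode=mean_mode) for m in maps])


def two_stage_parcellate(
    stage1: Mapping[str, tuple[np.ndarray, Sequence[DensityMap]]],
    stage2: Mapping[str, Mapping[str, Sequence[DensityMap]]],
    mean_mode: str = "positive",
) -> dict[tuple[str, str], LabelParcellation]:
    """Chain two winner-takes-all stages.

    Stage 1 parcellates each relay nucleus (striatum, subthalamic nucleus,
    thalamus) by its cortical connectivity: ``stage1`` maps relay name to
    ``(seed_roi, cortical density maps)``. Stage 2 parcellates each pallidal
    segment against the relay clusters: ``stage2`` maps pallidal nucleus to
    a mapping pathway -> per-relay-cluster density maps, where the pathway
    name must match a stage-1 relay.

    Returns one :class:`LabelParcellation` per (pallidal nucleus, pathway),
    with stage-1 provenance (which relay clusters served as stage-2 targets)
    recorded in the output metadata. With 4 functional groups this yields
    12 maps for a nucleus parcellated against 3 pathways and 8 for one
    against 2 — counted as parcels (groups x pathways).
    """
    stage1_parcels: dict[str, LabelParcellation] = {}
    for relay, (roi, maps) in stage1.items():
        stage1_parcels[relay] = parcellate_subject(list(maps), mean_mode=mean_mode)

    missing = [
        (nucleus, pathway)
        for nucleus, pathways in stage2.items()
        for pathway in pathways
        if pathway not in stage1_parcels
    ]
    if missing:
        raise ValueError(
            "stage-2 pathways missing a stage-1 parcellation: "
            + ", ".join(f"{n}/{p}" for n, p in missing)
        )

    out: dict[tuple[str, str], LabelParcellation] = {}
    for nucleus, pathways in stage2.items():
        for pathway, maps in pathways.items():
            expected = set(stage1_parcels[pathway].label_names)
            got = {m.target_label for m in maps}
            if got != expected:
                raise ValueError(
                    f"{nucleus}/{pathway}: stage-2 targets {sorted(got)} do not "
                    f"match stage-1 clusters {sorted(expected)}"
                )
            parcel = parcellate_subject(list(maps), mean_mode=mean_mode)
            parcel.provenance = {
                "nucleus": nucleus,
                "pathway": pathway,
                "stage1_clusters": list(stage1_parcels[pathway].label_names),
            }
            out[(nucleus, pathway)] = parcel
    return out
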
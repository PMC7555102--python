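"""Overlap statistics for binary maps and parcellations.

Two families of measures are used:

* the Dice coefficient D = 2|A∩B| / (|A|+|B|) between two binary maps —
  here, functionally homologous group MPMs from different pathways;
* Tanimoto-based reproducibility measures across subjects. With the
  Tanimoto coefficient T = N(A∩B)/N(A∪B) and an inverse-size weighting
  α = 2/(N(A)+N(B)) that keeps large parcels from dominating, the
  overlap-by-label

      OBL = Σ_m α N(A∩B) / Σ_m α N(A∪B)

  sums over all m = C(S,2) unordered subject pairs for one cluster, and the
  total accumulated overlap (TAO) additionally sums over the n clusters of
  a parcellation, giving one reproducibility number per parcellation type.

Pairs where both masks are empty are excluded (α is undefined there); the
number of skipped pairs is reported via ``warnings``.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Sequence

import numpy as np

from .cbp_engine import LabelParcellation, ShapeError


def _count(mask: np.ndarray) -> int:
    return int(np.count_nonzero(mask))


def _check_pair(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise ShapeError(f"mask grids differ: {A.shape} vs {B.shape}")
    return A, B


def dice(A: np.ndarray, B: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) of two binary masks."""
    A, B = _check_pair(A, B)
    na, nb = _count(A), _count(B)
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks empty")
    return 2.0 * _count(A & B) / (na + nb)


def tanimoto(A: np.ndarray, B: np.ndarray) -> float:
    """Tanimoto coefficient N(A∩B)/N(A∪B) of two binary masks."""
    A, B = _check_pair(A, B)
    union = _count(A | B)
    if union == 0:
        raise ValueError("Tanimoto undefined: both masks empty")
    return _count(A & B) / union


def weighting_alpha(A: np.ndarray, B: np.ndarray) -> float:
    """Inverse mean-size weight α = 2/(N(A)+N(B))."""
    A, B = _check_pair(A, B)
    total = _count(A) + _count(B)
    if total == 0:
        raise ValueError("alpha undefined: both masks empty")
    return 2.0 / total


def overlap_by_label(masks: Sequence[np.ndarray]) -> float:
    """Groupwise weighted Tanimoto overlap of one cluster across subjects.

    ``masks`` holds one binary parcel mask per subject; all C(S,2) unordered
    subject pairs contribute α-weighted intersection and union counts, and
    OBL is the ratio of the two sums. Pairs with both masks empty are
    skipped with a warning.
    """
    if len(masks) < 2:
        raise ValueError(f"OBL needs >= 2 subjects, got {len(masks)}")
    num = 0.0
    den = 0.0
    skipped = 0
    for A, B in itertools.combinations(masks, 2):
        A, B = _check_pair(A, B)
        total = _count(A) + _count(B)
        if total == 0:
            skipped += 1
            continue
        alpha = 2.0 / total
        num += alpha * _count(A & B)
        den += alpha * _count(A | B)
    if skipped:
        warnings.warn(f"OBL: skipped {skipped} subject pair(s) with both masks empty")
    if den == 0:
        raise ValueError("OBL undefined: every subject pair empty")
    return num / den


def total_accumulated_overlap(parcellations: Sequence[LabelParcellation]) -> float:
    """Parcellation-wise reproducibility: the OBL double sum over clusters.

    Sums α-weighted intersections and unions over all unordered subject
    pairs and all labels of the shared label set, returning one number per
    parcellation type. Label pairs empty in both subjects are skipped as in
    :func:`overlap_by_label`.
    """
    if len(parcellations) < 2:
        raise ValueError(f"TAO needs >= 2 subjects, got {len(parcellations)}")
    names = parcellations[0].label_names
    for p in parcellations[1:]:
        if p.label_names != names:
            raise ValueError("parcellations disagree on label names")
    num = 0.0
    den = 0.0
    skipped = 0
    for pa, pb in itertools.combinations(parcellations, 2):
        for label in names:
            A, B = pa.mask(label), pb.mask(label)
            total = _count(A) + _count(B)
            if total == 0:
                skipped += 1
                continue
            alpha = 2.0 / total
            num += alpha * _count(A & B)
            den += alpha * _count(A | B)
    if skipped:
        warnings.warn(f"TAO: skipped {skipped} label pair(s) empty in both subjects")
    if den == 0:
        raise ValueError("TAO undefined: all label pairs empty")
    return num / den
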
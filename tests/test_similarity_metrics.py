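"""Dice/Tanimoto/OBL/TAO against literal brute-force formula oracles."""

import itertools

import numpy as np
import pytest

from pallidoparc.cbp_engine import LabelParcellation, ShapeError
from pallidoparc.similarity_metrics import (
    dice,
    overlap_by_label,
    tanimoto,
    total_accumulated_overlap,
    weighting_alpha,
)


# ---- literal oracles, written directly from the definitions -------------

def _dice_oracle(A, B):
    inter = int(np.sum(A & B))
    return 2 * inter / (int(A.sum()) + int(B.sum()))


def _tanimoto_oracle(A, B):
    return int(np.sum(A & B)) / int(np.sum(A | B))


def _obl_oracle(masks):
    num = den = 0.0
    for A, B in itertools.combinations(masks, 2):
        if A.sum() + B.sum() == 0:
            continue
        alpha = 2.0 / (int(A.sum()) + int(B.sum()))
        num += alpha * int(np.sum(A & B))
        den += alpha * int(np.sum(A | B))
    return num / den


def _tao_oracle(parcels):
    num = den = 0.0
    n_labels = len(parcels[0].label_names)
    for pa, pb in itertools.combinations(parcels, 2):
        for i in range(1, n_labels + 1):
            A, B = pa.labels == i, pb.labels == i
            if A.sum() + B.sum() == 0:
                continue
            alpha = 2.0 / (int(A.sum()) + int(B.sum()))
            num += alpha * int(np.sum(A & B))
            den += alpha * int(np.sum(A | B))
    return num / den


def _random_mask(rng, shape=(5, 6, 4), p=0.4, ensure_nonempty=True):
    m = rng.random(shape) < p
    if ensure_nonempty and not m.any():
        m[tuple(s // 2 for s in shape)] = True
    return m


# ---- examples -----------------------------------------------------------

class TestPairwise:
    def test_identical_masks(self, rng):
        A = _random_mask(rng)
        assert dice(A, A) == 1.0
        assert tanimoto(A, A) == 1.0

    def test_disjoint_masks(self):
        A = np.zeros((4, 4, 4), dtype=bool)
        B = np.zeros((4, 4, 4), dtype=bool)
        A[0, 0, 0] = B[1, 1, 1] = True
        assert dice(A, B) == 0.0
        assert tanimoto(A, B) == 0.0

    def test_constructed_counts(self):
        """|A|=100, |B|=60, |A∩B|=40 -> Dice 0.5; |A∪B|=120 -> Tanimoto 1/3."""
        A = np.zeros(200, dtype=bool)
        B = np.zeros(200, dtype=bool)
        A[:100] = True
        B[60:120] = True  # overlap = 60..100 -> 40 voxels
        A, B = A.reshape(10, 20, 1), B.reshape(10, 20, 1)
        assert dice(A, B) == pytest.approx(0.5)
        assert tanimoto(A, B) == pytest.approx(40 / 120)
        assert weighting_alpha(A, B) == pytest.approx(2 / 160)

    def test_alpha_identities(self, rng):
        A, B = _random_mask(rng), _random_mask(rng)
        alpha = weighting_alpha(A, B)
        assert alpha * (A.sum() + B.sum()) / 2 == pytest.approx(1.0)
        one = np.zeros((3, 3, 3), dtype=bool)
        one[0, 0, 0] = True
        assert weighting_alpha(one, one) == 1.0

    def test_empty_pair_errors(self):
        empty = np.zeros((3, 3, 3), dtype=bool)
        for fn in (dice, tanimoto, weighting_alpha):
            with pytest.raises(ValueError):
                fn(empty, empty)

    def test_grid_mismatch(self, rng):
        with pytest.raises(ShapeError):
            dice(_random_mask(rng, (4, 4, 4)), _random_mask(rng, (5, 4, 4)))


# ---- randomized oracle equivalence --------------------------------------

class TestOracleEquivalence:
    def test_pairwise_metrics_match_bruteforce(self, rng):
        """>= 20 random fixtures: Dice/Tanimoto equal the literal formulas to
        1e-12, the identity D = 2T/(1+T) holds, and Dice >= Tanimoto."""
        for _ in range(25):
            A, B = _random_mask(rng), _random_mask(rng)
            d, t = dice(A, B), tanimoto(A, B)
            assert abs(d - _dice_oracle(A, B)) < 1e-12
            assert abs(t - _tanimoto_oracle(A, B)) < 1e-12
            assert abs(d - 2 * t / (1 + t)) < 1e-12
            assert d >= t
            assert 0.0 <= t <= d <= 1.0
            assert dice(A, B) == dice(B, A)

    def test_obl_matches_pairwise_enumeration(self, rng):
        for n_subj in (2, 3, 5):
            masks = [_random_mask(rng) for _ in range(n_subj)]
            assert overlap_by_label(masks) == pytest.approx(_obl_oracle(masks), abs=1e-12)

    def test_tao_matches_double_sum_enumeration(self, rng):
        for _ in range(5):
            parcels = []
            for _s in range(3):
                labels = rng.integers(0, 3, size=(5, 6, 4))
                parcels.append(
                    LabelParcellation(labels=labels, label_names=["a", "b"], seed_roi=labels > 0)
                )
            assert total_accumulated_overlap(parcels) == pytest.approx(
                _tao_oracle(parcels), abs=1e-12
            )


# ---- groupwise behavior --------------------------------------------------

class TestGroupwise:
    def test_identical_subjects_give_one(self, rng):
        A = _random_mask(rng)
        assert overlap_by_label([A, A, A]) == 1.0
        labels = rng.integers(0, 3, size=(5, 6, 4))
        p = LabelParcellation(labels=labels, label_names=["a", "b"], seed_roi=labels > 0)
        assert total_accumulated_overlap([p, p, p]) == 1.0

    def test_two_disjoint_subjects_give_zero(self):
        A = np.zeros((4, 4, 4), dtype=bool)
        B = np.zeros((4, 4, 4), dtype=bool)
        A[0, 0, 0] = B[3, 3, 3] = True
        assert overlap_by_label([A, B]) == 0.0

    def test_single_label_tao_equals_obl(self, rng):
        masks = [_random_mask(rng) for _ in range(4)]
        parcels = [
            LabelParcellation(labels=m.astype(int), label_names=["only"], seed_roi=m)
            for m in masks
        ]
        assert total_accumulated_overlap(parcels) == pytest.approx(overlap_by_label(masks))

    def test_duplicating_every_pair_leaves_obl_unchanged(self, rng):
        """Doubling m (every subject pair counted twice) scales numerator and
        denominator together, so the ratio is invariant."""
        masks = [_random_mask(rng) for _ in range(4)]
        base = overlap_by_label(masks)
        pairs = list(itertools.combinations(masks, 2))
        num = den = 0.0
        for A, B in pairs + pairs:
            alpha = 2.0 / (int(A.sum()) + int(B.sum()))
            num += alpha * int(np.sum(A & B))
            den += alpha * int(np.sum(A | B))
        assert num / den == pytest.approx(base, abs=1e-12)

    def test_empty_pairs_skipped_with_warning(self):
        """A parcel absent in two subjects yields one empty-empty pair, which
        is excluded from both sums rather than treated as 0/0."""
        A = np.zeros((3, 3, 3), dtype=bool)
        B = np.zeros((3, 3, 3), dtype=bool)
        A[0, 0, 0] = B[0, 0, 0] = True
        empty1 = np.zeros((3, 3, 3), dtype=bool)
        empty2 = np.zeros((3, 3, 3), dtype=bool)
        with pytest.warns(UserWarning, match="skipped 1"):
            val = overlap_by_label([A, B, empty1, empty2])
        assert val == pytest.approx(_obl_oracle([A, B, empty1, empty2]))

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError):
            overlap_by_label([_random_mask(rng)])


def test_reproducibility_decreases_with_jitter():
    """OBL and TAO are 1 on a noiseless cohort and decrease as the
    subject-level jitter grows (fixed seed sweep)."""
    from dataclasses import replace

    from pallidoparc.cbp_engine import DensityMap, parcellate_subject
    from pallidoparc.synthetic_cohort import CohortConfig, simulate_cohort

    cfg = CohortConfig(n_subjects=5, grid_shape=(14, 18, 14), noise_cv=0.0,
                       jitter_sd_mm=0.0, rng_seed=13)
    taos = []
    for jitter in (0.0, 0.8, 2.5):
        subs = simulate_cohort(replace(cfg, jitter_sd_mm=jitter))
        parcels = [
            parcellate_subject(
                [DensityMap(values=s.densities[n], seed_roi=s.seed_roi, target_label=n)
                 for n in cfg.label_names]
            )
            for s in subs
        ]
        taos.append(total_accumulated_overlap(parcels))
    assert taos[0] == 1.0
    tol = 0.02
    assert taos[0] + tol >= taos[1] >= taos[2] - tol
    assert taos[2] < 1.0
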
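"""Normalization and winner-takes-all, checked against per-voxel oracles."""

import numpy as np
import pytest

from pallidoparc.cbp_engine import (
    DensityMap,
    NormalizationError,
    ShapeError,
    normalize_density,
    parcellate_subject,
    two_stage_parcellate,
    winner_takes_all,
)

from conftest import random_density_maps


def _map_1d(values, roi=None, label="t"):
    values = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    if roi is None:
        roi = np.ones_like(values, dtype=bool)
    else:
        roi = np.asarray(roi, dtype=bool).reshape(-1, 1, 1)
    return DensityMap(values=values, seed_roi=roi, target_label=label)


class TestNormalizeDensity:
    def test_constant_map_becomes_unity(self):
        out = normalize_density(_map_1d([3.5, 3.5, 3.5]))
        assert np.allclose(out.values, 1.0)

    def test_divides_by_mean_of_positive_voxels(self):
        out = normalize_density(_map_1d([1, 2, 3, 6]))
        assert np.allclose(out.values.ravel(), [1 / 3, 2 / 3, 1.0, 2.0])

    def test_zeros_excluded_from_mean_and_preserved(self):
        out = normalize_density(_map_1d([2, 4, 0, 0]))
        assert np.allclose(out.values.ravel(), [2 / 3, 4 / 3, 0.0, 0.0])

    def test_all_roi_mean_mode(self):
        out = normalize_density(_map_1d([2, 4, 0, 0]), mean_mode="all")
        assert np.allclose(out.values.ravel(), [4 / 3, 8 / 3, 0.0, 0.0])

    def test_output_positive_mean_is_one(self, rng):
        for maps in (random_density_maps(rng) for _ in range(5)):
            for m in maps:
                out = normalize_density(m)
                pos = out.values[out.seed_roi & (out.values > 0)]
                assert np.isclose(pos.mean(), 1.0)

    def test_all_zero_map_raises_with_identity(self):
        with pytest.raises(NormalizationError, match="sub-9.*limbic"):
            normalize_density(
                DensityMap(
                    values=np.zeros((3, 1, 1)),
                    seed_roi=np.ones((3, 1, 1), dtype=bool),
                    target_label="limbic",
                    subject_id="sub-9",
                )
            )


class TestWinnerTakesAll:
    def test_single_voxel_argmax(self):
        maps = [_map_1d([v], label=f"t{i}") for i, v in enumerate([0.5, 2.0, 1.0])]
        parcel = winner_takes_all(maps)
        assert parcel.labels.ravel()[0] == 2
        assert parcel.label_names[1] == "t1"

    def test_all_zero_voxel_stays_unlabeled(self):
        maps = [_map_1d([0.0, 1.0], label="a"), _map_1d([0.0, 2.0], label="b")]
        assert winner_takes_all(maps).labels.ravel()[0] == 0

    def test_two_voxel_toy(self):
        maps = [_map_1d([3, 1], label="A"), _map_1d([1, 3], label="B")]
        assert list(winner_takes_all(maps).labels.ravel()) == [1, 2]

    def test_tie_goes_to_lowest_index(self):
        maps = [_map_1d([2.0], label="a"), _map_1d([2.0], label="b")]
        assert winner_takes_all(maps).labels.ravel()[0] == 1

    def test_matches_bruteforce_voxel_scan(self, rng):
        """Oracle: an explicit per-voxel loop over all maps, ties and zeros included."""
        for _ in range(50):
            maps = random_density_maps(rng, n_maps=int(rng.integers(2, 5)))
            parcel = winner_takes_all(maps)
            roi = maps[0].seed_roi
            for idx in np.ndindex(*roi.shape):
                vals = [m.values[idx] for m in maps]
                if not roi[idx] or max(vals) == 0:
                    expected = 0
                else:
                    expected = int(np.argmax(vals)) + 1  # first max = lowest index
                assert parcel.labels[idx] == expected

    def test_exclusive_partition(self, rng):
        maps = random_density_maps(rng, n_maps=4)
        parcel = winner_takes_all(maps)
        stack = np.stack([m.values for m in maps])
        n_positive = int((np.any(stack > 0, axis=0) & maps[0].seed_roi).sum())
        assert sum(int((parcel.labels == k).sum()) for k in range(1, 5)) == n_positive
        assert n_positive <= int(maps[0].seed_roi.sum())

    def test_scale_invariance_through_normalization(self, rng):
        maps = random_density_maps(rng)
        base = parcellate_subject(maps)
        maps[1].values = maps[1].values * 37.5
        rescaled = parcellate_subject(maps)
        assert np.array_equal(base.labels, rescaled.labels)

    def test_errors(self):
        with pytest.raises(ValueError, match=">= 2 maps"):
            winner_takes_all([_map_1d([1.0])])
        a = _map_1d([1, 2], label="a")
        b = _map_1d([1, 0], roi=[1, 0], label="b")
        with pytest.raises(ShapeError):
            winner_takes_all([a, b])


class TestTwoStageParcellation:
    @staticmethod
    def _stage_inputs(rng, pathways):
        relay_roi = rng.random((5, 6, 4)) < 0.8
        groups = ["limbic", "associative", "sensorimotor", "other"]

        def relay_maps():
            maps = []
            for g in groups:
                vals = np.where(relay_roi, rng.gamma(2.0, 1.0, size=relay_roi.shape), 0.0)
                maps.append(DensityMap(values=vals, seed_roi=relay_roi, target_label=g))
            return relay_roi, maps

        stage1 = {p: relay_maps() for p in pathways}
        pall_roi = rng.random((6, 7, 5)) < 0.8
        stage2 = {}
        for nucleus, paths in {"GPi": pathways, "GPe": pathways[:2]}.items():
            stage2[nucleus] = {
                p: [
                    DensityMap(
                        values=np.where(pall_roi, rng.gamma(2.0, 1.0, size=pall_roi.shape), 0.0),
                        seed_roi=pall_roi,
                        target_label=g,
                    )
                    for g in groups
                ]
                for p in paths
            }
        return stage1, stage2

    def test_map_counts_four_groups(self, rng):
        """3 pathways x 4 groups = 12 parcels for GPi; 2 x 4 = 8 for GPe."""
        pathways = ["striatopallidal", "subthalamopallidal", "pallidothalamic"]
        stage1, stage2 = self._stage_inputs(rng, pathways)
        out = two_stage_parcellate(stage1, stage2)
        gpi = [k for k in out if k[0] == "GPi"]
        gpe = [k for k in out if k[0] == "GPe"]
        assert sum(len(out[k].label_names) for k in gpi) == 12
        assert sum(len(out[k].label_names) for k in gpe) == 8
        assert out[("GPi", "striatopallidal")].provenance["stage1_clusters"] == [
            "limbic", "associative", "sensorimotor", "other",
        ]

    def test_missing_pathway_raises(self, rng):
        pathways = ["striatopallidal", "subthalamopallidal", "pallidothalamic"]
        stage1, stage2 = self._stage_inputs(rng, pathways)
        del stage1["pallidothalamic"]
        with pytest.raises(ValueError, match="GPi/pallidothalamic"):
            two_stage_parcellate(stage1, stage2)

    def test_noiseless_stage2_recovers_generator_truth(self, small_config):
        from dataclasses import replace

        from pallidoparc.synthetic_cohort import simulate_cohort

        cfg = replace(small_config, noise_cv=0.0, jitter_sd_mm=0.0, n_subjects=1)
        sub = simulate_cohort(cfg)[0]
        maps = [
            DensityMap(values=sub.densities[n], seed_roi=sub.seed_roi, target_label=n)
            for n in cfg.label_names
        ]
        parcel = parcellate_subject(maps)
        assert np.array_equal(parcel.labels, sub.truth.labels)
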
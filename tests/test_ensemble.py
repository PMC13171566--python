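"""Probability-map construction and isoprobability set algebra."""

import numpy as np
import pytest

from ctveval import (
    build_probability_map,
    default_levels,
    generate_cohort_masks,
    iso_volume_difference,
    isoprobability_mask,
    isoprobability_set,
)

from conftest import cube_mask, make_mask, random_mask, small_cohort_config


def nested_cubes(k=4, shape=(14, 14, 14)):
    """Strictly nested cubes A ⊂ B ⊂ C ⊂ D."""
    return [cube_mask(shape, (i, i, i), (shape[0] - i, shape[1] - i, shape[2] - i))
            for i in range(k, 0, -1)]


class TestBuildProbabilityMap:
    def test_identical_masks_binary_values(self, rng):
        m = random_mask(rng)
        pmap = build_probability_map([m] * 4)
        assert set(np.unique(pmap.agreement)) <= {0.0, 1.0}

    def test_agreement_is_count_fraction(self):
        masks = nested_cubes(4)
        pmap = build_probability_map(masks)
        # voxels inside exactly 3 of the 4 nested cubes (masks are sorted
        # smallest first): in the three largest but not the smallest
        inner = masks[1].voxels & ~masks[0].voxels
        assert inner.any()
        assert np.all(pmap.agreement[inner] == 0.75)

    def test_attained_levels_are_quarters_for_k4(self, rng):
        masks = [random_mask(rng) for _ in range(4)]
        pmap = build_probability_map(masks)
        assert set(np.unique(pmap.agreement)) <= {0.0, 0.25, 0.5, 0.75, 1.0}

    def test_conservation_of_foreground(self, rng):
        masks = [random_mask(rng) for _ in range(4)]
        pmap = build_probability_map(masks)
        total = sum(m.foreground_count() for m in masks)
        assert int(pmap.counts.sum()) == total

    def test_permutation_invariance(self, rng):
        masks = [random_mask(rng) for _ in range(4)]
        a = build_probability_map(masks)
        b = build_probability_map(masks[::-1])
        assert np.array_equal(a.counts, b.counts)

    def test_too_few_models_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            build_probability_map([random_mask(rng)])

    def test_grid_mismatch_rejected(self, rng):
        a = random_mask(rng, (8, 8, 8))
        b = random_mask(rng, (9, 8, 8))
        with pytest.raises(ValueError, match="shape"):
            build_probability_map([a, b])


class TestIsoprobability:
    def test_100_is_intersection_25_is_union(self, rng):
        masks = [random_mask(rng) for _ in range(4)]
        pmap = build_probability_map(masks)
        inter = np.logical_and.reduce([m.voxels for m in masks])
        union = np.logical_or.reduce([m.voxels for m in masks])
        assert np.array_equal(isoprobability_mask(pmap, 100).voxels, inter)
        assert np.array_equal(isoprobability_mask(pmap, 25).voxels, union)

    def test_level_50_on_identical_masks_is_the_mask(self, rng):
        m = random_mask(rng)
        pmap = build_probability_map([m] * 4)
        assert np.array_equal(isoprobability_mask(pmap, 50).voxels, m.voxels)

    def test_nesting_across_levels(self, rng):
        masks = [random_mask(rng) for _ in range(4)]
        pmap = build_probability_map(masks)
        iso = isoprobability_set(pmap)
        for low, high in zip(iso.masks[:-1], iso.masks[1:]):
            assert not (high.voxels & ~low.voxels).any()

    def test_level_set_derivation(self):
        assert default_levels(4) == [25.0, 50.0, 75.0, 100.0]
        levels3 = default_levels(3)
        assert levels3[-1] == 100.0
        assert levels3[0] == pytest.approx(100.0 / 3.0)

    def test_k3_fractional_levels_threshold_correctly(self, rng):
        masks = [random_mask(rng) for _ in range(3)]
        pmap = build_probability_map(masks)
        levels = default_levels(3)
        union = np.logical_or.reduce([m.voxels for m in masks])
        inter = np.logical_and.reduce([m.voxels for m in masks])
        assert np.array_equal(isoprobability_mask(pmap, levels[0]).voxels, union)
        assert np.array_equal(isoprobability_mask(pmap, levels[2]).voxels, inter)

    def test_invalid_level_rejected(self, rng):
        pmap = build_probability_map([random_mask(rng)] * 2)
        for level in (0, -5, 101):
            with pytest.raises(ValueError):
                isoprobability_mask(pmap, level)


class TestIsoVolumeDifference:
    def test_identical_predictions_zero(self, rng):
        m = random_mask(rng)
        pmap = build_probability_map([m] * 4)
        assert iso_volume_difference(pmap) == 0.0

    def test_counting_case(self):
        # union 1100 voxels, intersection 900, spacing 1mm -> 0.2 cm^3
        a = np.zeros((20, 20, 20), bool)
        a[0:10, 0:10, 0:9] = True  # 900
        b = a.copy()
        b[0:10, 0:10, 9:11] = True  # +200 -> 1100
        masks = [make_mask(a), make_mask(b), make_mask(b), make_mask(a)]
        pmap = build_probability_map(masks)
        assert iso_volume_difference(pmap, 25, 100) == pytest.approx(0.2)

    def test_nested_predictions(self):
        masks = nested_cubes(4)
        pmap = build_probability_map(masks)
        biggest = max(masks, key=lambda m: m.foreground_count())
        smallest = min(masks, key=lambda m: m.foreground_count())
        want = (biggest.foreground_count() - smallest.foreground_count()) / 1000.0
        assert iso_volume_difference(pmap) == pytest.approx(want)


class TestEnsembleOnSyntheticCohort:
    def test_set_algebra_and_nesting_over_seeded_patients(self):
        """100% = AND, lowest level = OR, strict nesting, on generated cohorts."""
        cfg = small_cohort_config(seed=21, n_patients=5)
        for rec in generate_cohort_masks(cfg):
            preds = list(rec["predictions"].values())
            pmap = build_probability_map(preds)
            inter = np.logical_and.reduce([p.voxels for p in preds])
            union = np.logical_or.reduce([p.voxels for p in preds])
            assert np.array_equal(isoprobability_mask(pmap, 100).voxels, inter)
            assert np.array_equal(isoprobability_mask(pmap, 25).voxels, union)
            iso = isoprobability_set(pmap)
            for low, high in zip(iso.masks[:-1], iso.masks[1:]):
                assert not (high.voxels & ~low.voxels).any()
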
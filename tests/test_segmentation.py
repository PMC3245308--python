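import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stackquant import (
    CountingConfig,
    SceneConfig,
    count_stack,
    estimate_count,
    exclude_small,
    fill_holes,
    generate_stack,
    label_objects,
    sd_threshold_mask,
    split_touching,
)
from stackquant.errors import ConfigurationError

from helpers import ellipsoid_mask, make_object, make_stack


class TestSdThresholdMask:
    def test_constant_channel_empty_mask_with_warning(self):
        stack = make_stack(np.full((4, 4, 4), 7.0))
        with pytest.warns(UserWarning, match="constant"):
            mask = sd_threshold_mask(stack, "cells", 3.5)
        assert not mask.any()

    def test_hand_computed_mean_sd(self):
        # voxels {0,0,0,10}: mean 2.5, population SD 4.330; k=1 keeps only 10
        data = np.array([0.0, 0.0, 0.0, 10.0]).reshape(1, 2, 2)
        assert np.std(data) == pytest.approx(4.330127, abs=1e-6)
        mask = sd_threshold_mask(make_stack(data), "cells", 1.0)
        assert mask.sum() == 1
        assert mask[0, 1, 1]

    def test_monotone_in_k(self, rng):
        stack = make_stack(rng.gamma(2.0, 50.0, size=(6, 32, 32)))
        m_hi = sd_threshold_mask(stack, "cells", 3.7)
        m_lo = sd_threshold_mask(stack, "cells", 3.2)
        assert np.all(m_lo | ~m_hi)  # m_hi subset of m_lo

    def test_strictly_above(self):
        # voxels exactly at mean + k*SD stay background
        data = np.array([0.0, 2.0]).reshape(1, 1, 2)  # mean 1, SD 1
        mask = sd_threshold_mask(make_stack(data), "cells", 1.0)
        assert not mask.any()

    def test_k_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            sd_threshold_mask(make_stack(np.zeros((2, 2, 2))), "cells", 0.0)


class TestFillHoles:
    def test_hollow_shell_becomes_solid(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[1:6, 1:6, 1:6] = True
        mask[2:5, 2:5, 2:5] = False
        filled = fill_holes(mask)
        assert filled[1:6, 1:6, 1:6].all()

    def test_idempotent_without_cavities(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        assert np.array_equal(fill_holes(mask), mask)
        assert np.array_equal(fill_holes(fill_holes(mask)), fill_holes(mask))

    def test_open_channel_to_border_unchanged(self):
        # a "C"-shaped cavity reaching the border is not a hole
        mask = np.zeros((5, 7, 7), dtype=bool)
        mask[1:4, 1:6, 1:6] = True
        mask[1:4, 3, 0:4] = False  # channel out to the y-x border face
        mask[1:4, 3, 0] = False
        assert np.array_equal(fill_holes(mask), mask)

    def test_against_border_flood_fill_oracle(self, rng):
        mask = rng.random((8, 12, 12)) > 0.6
        filled = fill_holes(mask)
        # oracle: flood the background from the border; unreachable
        # background voxels are holes
        from scipy import ndimage
        bg = ~mask
        six_conn = np.array(
            [[[0, 0, 0], [0, 1, 0], [0, 0, 0]],
             [[0, 1, 0], [1, 1, 1], [0, 1, 0]],
             [[0, 0, 0], [0, 1, 0], [0, 0, 0]]], dtype=bool)
        labels, _ = ndimage.label(bg, structure=six_conn)
        border_labels = set(np.unique(np.concatenate([
            labels[0].ravel(), labels[-1].ravel(),
            labels[:, 0].ravel(), labels[:, -1].ravel(),
            labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
        ]))) - {0}
        expected = mask | (bg & ~np.isin(labels, sorted(border_labels)))
        assert np.array_equal(filled, expected)

    def test_never_shrinks(self, rng):
        mask = rng.random((6, 10, 10)) > 0.5
        assert np.all(fill_holes(mask) | ~mask)


class TestLabelObjects:
    def test_two_separated_blobs(self):
        mask = np.zeros((3, 8, 8), dtype=bool)
        mask[1, 1:3, 1:3] = True
        mask[1, 5:7, 5:7] = True
        stack = make_stack(mask.astype(float) * 100)
        assert len(label_objects(mask, stack)) == 2

    def test_single_voxel_volume(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        stack = make_stack(mask.astype(float), voxel_size=(1.0, 0.5, 0.5))
        objs = label_objects(mask, stack)
        assert len(objs) == 1
        assert objs[0].volume == pytest.approx(0.25)

    def test_diagonal_voxels_connect_26(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = True
        mask[2, 2, 2] = True
        stack = make_stack(mask.astype(float))
        assert len(label_objects(mask, stack)) == 1

    def test_volume_conservation(self, rng):
        mask = rng.random((6, 20, 20)) > 0.7
        stack = make_stack(mask.astype(float), voxel_size=(2.0, 0.5, 0.5))
        objs = label_objects(mask, stack)
        total = sum(o.volume for o in objs)
        assert total == pytest.approx(mask.sum() * 0.5)

    def test_mean_intensities_attached(self):
        mask = np.zeros((3, 4, 4), dtype=bool)
        mask[1, 1:3, 1:3] = True
        arr = np.zeros((3, 4, 4))
        arr[mask] = 50.0
        stack = make_stack({"cells": arr, "marker": arr * 2})
        obj = label_objects(mask, stack)[0]
        assert obj.mean_intensity["cells"] == pytest.approx(50.0)
        assert obj.mean_intensity["marker"] == pytest.approx(100.0)

    def test_empty_mask(self):
        stack = make_stack(np.zeros((3, 3, 3)))
        assert label_objects(np.zeros((3, 3, 3), bool), stack) == []


class TestExcludeSmall:
    def test_boundary_kept(self):
        objs = [make_object(v) for v in (15.0, 20.0, 300.0)]
        kept = exclude_small(objs, 20.0)
        assert sorted(o.volume for o in kept) == [20.0, 300.0]

    def test_identity_when_all_large(self):
        objs = [make_object(v) for v in (25.0, 30.0)]
        assert exclude_small(objs, 20.0) == objs

    @given(st.lists(st.floats(1.0, 1000.0), max_size=100))
    def test_matches_brute_force_filter(self, volumes):
        objs = [make_object(v, label=i) for i, v in enumerate(volumes)]
        kept = exclude_small(objs, 20.0)
        assert [o.label for o in kept] == [
            i for i, v in enumerate(volumes) if v >= 20.0]


class TestSplitTouching:
    def test_small_object_unchanged(self):
        obj = make_object(400.0)
        out = split_touching([obj], 750.0)
        assert len(out) == 1
        assert out[0].volume == 400.0

    def test_dumbbell_splits_in_two(self):
        r = (3 * 750 / (4 * math.pi)) ** (1 / 3)
        shape = (24, 24, 40)
        m1 = ellipsoid_mask(shape, (12, 12, 14), (r, r, r))
        m2 = ellipsoid_mask(shape, (12, 12, 14 + 1.8 * r), (r, r, r))
        mask = m1 | m2
        stack = make_stack(mask.astype(float))
        parents = label_objects(mask, stack)
        assert len(parents) == 1
        children = split_touching(parents, 750.0)
        assert len(children) == 2
        assert sum(c.volume for c in children) == pytest.approx(
            parents[0].volume)

    def test_volume_conservation_random_blobs(self, rng):
        mask = np.zeros((10, 24, 24), dtype=bool)
        mask[2:8, 4:20, 4:20] = rng.random((6, 16, 16)) > 0.3
        stack = make_stack(mask.astype(float))
        parents = label_objects(mask, stack)
        children = split_touching(parents, 50.0)
        assert sum(c.volume for c in children) == pytest.approx(
            sum(p.volume for p in parents))

    def test_relabeled_sequentially(self):
        objs = [make_object(100.0), make_object(100.0)]
        out = split_touching(objs, 750.0)
        assert [o.label for o in out] == [1, 2]

    def test_v_min_reapplied(self):
        # a 2-voxel object split in two leaves 0.5-um3 shards, re-excluded
        mask = np.zeros((3, 3, 4), dtype=bool)
        mask[1, 1, 1:3] = True
        stack = make_stack(mask.astype(float), voxel_size=(1, 1, 1))
        parents = label_objects(mask, stack)
        children = split_touching(parents, 1.0, v_min=1.5)
        assert children == []


class TestEstimateCount:
    def config(self, **kw):
        defaults = dict(k_sd=3.5, v_min=20.0, size_guide=200.0, v_avg=300.0,
                        single_cell_max=600.0, cluster_fraction_threshold=0.20)
        defaults.update(kw)
        return CountingConfig(**defaults)

    def test_all_singles(self):
        objs = [make_object(v) for v in (300.0, 280.0, 320.0)]
        est = estimate_count(objs, self.config())
        assert est.n_total == 3
        assert not est.fallback_used

    def test_fallback_branch(self):
        # clustered 900/1200 = 75% > 20% -> round(1200/300) = 4
        objs = [make_object(300.0), make_object(900.0)]
        est = estimate_count(objs, self.config())
        assert est.fallback_used
        assert est.clustered_volume_fraction == pytest.approx(0.75)
        assert est.n_total == 4

    def test_both_branches_same_scene(self):
        volumes = [300.0] * 8 + [650.0]
        objs = [make_object(v) for v in volumes]
        est = estimate_count(objs, self.config())
        assert est.clustered_volume_fraction == pytest.approx(650 / 3050)
        assert est.fallback_used
        assert est.n_total == 10  # round(3050/300)
        est2 = estimate_count(objs, self.config(cluster_fraction_threshold=0.25))
        assert not est2.fallback_used
        assert est2.n_single == 8
        assert est2.n_from_clusters == 2  # round(650/300)
        assert est2.n_total == 10

    def test_empty(self):
        est = estimate_count([], self.config())
        assert est.n_total == 0
        assert not est.fallback_used

    def test_min_one_cell_per_clustered_object(self):
        objs = [make_object(610.0)]  # round(610/300) = 2
        est = estimate_count(objs, self.config(cluster_fraction_threshold=0.99))
        assert est.n_from_clusters == 2
        objs = [make_object(610.0), make_object(620.0)]
        est = estimate_count(objs, self.config(cluster_fraction_threshold=0.99))
        assert est.n_from_clusters >= 2

    @given(st.lists(st.floats(20.0, 2000.0), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, volumes, random):
        objs = [make_object(v, label=i) for i, v in enumerate(volumes)]
        est1 = estimate_count(objs, self.config())
        random.shuffle(objs)
        est2 = estimate_count(objs, self.config())
        assert est1.n_total == est2.n_total
        assert est1.fallback_used == est2.fallback_used

    def test_invalid_config(self):
        with pytest.raises(ConfigurationError):
            CountingConfig(v_min=0.0)
        with pytest.raises(ConfigurationError):
            CountingConfig(v_avg=10.0)  # v_avg < v_min default 20
        with pytest.raises(ConfigurationError):
            CountingConfig(cluster_fraction_threshold=0.0)


class TestPipelineSmoke:
    def test_full_chain_recovers_truth_count(self):
        for seed in (0, 1, 2):
            cfg = SceneConfig(stack_shape=(40, 128, 128), n_cells=40,
                              cell_volume_mean=220.0, cell_volume_cv=0.2,
                              cell_volume_range=(60.0, 380.0), seed=seed)
            stack, scene = generate_stack(cfg)
            _, est = count_stack(stack, "cells", CountingConfig())
            assert est.n_total == cfg.n_cells
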
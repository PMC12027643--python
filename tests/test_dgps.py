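"""Dynamic granular partition synergy attention: tiling, similarity, synergy."""

import numpy as np
import pytest

from mgraunet import (
    DGPS,
    PartitionStrategy,
    aggregate,
    assemble,
    partition,
    similarity_matrix,
    synergy_weights,
)
from mgraunet.blocks.dgps import PartitionSet
from mgraunet.tensor import Tensor


def as_pset(regions_with_placements, source_shape):
    placements = [p for p, _ in regions_with_placements]
    regions = [r for _, r in regions_with_placements]
    descriptors = np.stack([r.mean(axis=(1, 2)) for r in regions])
    return PartitionSet(placements, regions, descriptors, source_shape)


class TestPartition:
    def test_uniform_grid_tiles_exactly(self, rng):
        f = rng.normal(size=(3, 8, 8))
        p = partition(f, PartitionStrategy(policy="grid", grid=(2, 2)))
        assert p.placements == [(0, 0, 4, 4), (0, 4, 4, 4), (4, 0, 4, 4), (4, 4, 4, 4)]
        for (t, l, h, w), r in zip(p.placements, p.regions):
            np.testing.assert_array_equal(r, f[:, t : t + h, l : l + w])

    def test_tiny_map_falls_back_to_single_region(self, rng):
        f = rng.normal(size=(2, 2, 2))
        p = partition(f, PartitionStrategy(policy="quadtree", min_region=2))
        assert p.n == 1 and p.placements == [(0, 0, 2, 2)]
        np.testing.assert_allclose(p.descriptors[0], f.mean(axis=(1, 2)))

    def test_partition_always_tiles_disjointly(self, rng):
        for _ in range(20):
            H, W = rng.integers(4, 33, size=2)
            f = rng.normal(size=(2, H, W))
            p = partition(f, PartitionStrategy())
            cover = np.zeros((H, W), dtype=int)
            for t, l, h, w in p.placements:
                cover[t : t + h, l : l + w] += 1
            np.testing.assert_array_equal(cover, 1)

    def test_adaptive_policy_splits_only_the_high_variance_quadrant(self, rng):
        f = np.zeros((2, 8, 8))
        f[:, :4, :4] = rng.normal(size=(2, 4, 4))  # all variance top-left
        p = partition(f, PartitionStrategy(policy="quadtree"))
        # brute-force recomputation of the split rule
        quads = [(0, 0, 4, 4), (0, 4, 4, 4), (4, 0, 4, 4), (4, 4, 4, 4)]
        scores = [f[:, t : t + h, l : l + w].var() for t, l, h, w in quads]
        want_split = [s > np.mean(scores) for s in scores]
        assert want_split == [True, False, False, False]
        assert p.n == 7  # top-left quartered, three quadrants intact
        assert set(p.placements) >= set(quads[1:])
        assert (0, 0, 2, 2) in p.placements

    def test_region_count_capped(self, rng):
        f = rng.normal(size=(1, 32, 32))
        p = partition(f, PartitionStrategy(max_regions=16))
        assert p.n <= 16


class TestSimilarity:
    def test_orthogonal_descriptors(self):
        p = as_pset([((0, 0, 1, 1), np.array([[[1.0]], [[0.0]]])),
                     ((0, 1, 1, 1), np.array([[[0.0]], [[1.0]]]))], (2, 1, 2))
        np.testing.assert_allclose(similarity_matrix(p), np.eye(2))

    def test_identical_descriptors_give_all_ones(self):
        r = np.ones((3, 2, 2))
        p = as_pset([((0, 0, 2, 2), r), ((0, 2, 2, 2), r.copy())], (3, 2, 4))
        np.testing.assert_allclose(similarity_matrix(p), np.ones((2, 2)))

    def test_matches_scalar_loop_cosine_oracle(self, rng):
        descs = rng.normal(size=(3, 4))
        p = PartitionSet([(0, 0, 1, 1)] * 3, [None] * 3, descs, (4, 1, 3))
        S = similarity_matrix(p)
        for i in range(3):
            for j in range(3):
                num = sum(descs[i, k] * descs[j, k] for k in range(4))
                den = np.sqrt(sum(v * v for v in descs[i])) * np.sqrt(
                    sum(v * v for v in descs[j])
                )
                want = 1.0 if i == j else num / den
                assert abs(S[i, j] - want) < 1e-7

    def test_zero_norm_descriptor_convention(self):
        descs = np.array([[0.0, 0.0], [1.0, 2.0]])
        p = PartitionSet([(0, 0, 1, 1)] * 2, [None] * 2, descs, (2, 1, 2))
        S = similarity_matrix(p)
        np.testing.assert_allclose(S, np.eye(2))

    def test_invariants_on_random_partitions(self, rng):
        for _ in range(10):
            f = rng.normal(size=(4, 16, 16))
            S = similarity_matrix(partition(f))
            np.testing.assert_allclose(S, S.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(S), 1.0)
            assert (S >= -1 - 1e-12).all() and (S <= 1 + 1e-12).all()


class TestSynergy:
    def test_single_region(self):
        np.testing.assert_allclose(synergy_weights(np.array([[1.0]])), [[1.0]])

    def test_two_identical_partitions_share_weight_equally(self):
        np.testing.assert_allclose(synergy_weights(np.ones((2, 2))), 0.5 * np.ones((2, 2)))

    def test_hand_evaluated_softmax(self):
        a = synergy_weights(np.eye(2))
        e = np.e
        np.testing.assert_allclose(a[0], [e / (e + 1), 1 / (e + 1)], atol=1e-12)
        np.testing.assert_allclose(a[0], [0.7311, 0.2689], atol=1e-4)

    def test_rows_always_stochastic(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 16))
            S = np.clip(rng.normal(size=(n, n)), -1, 1)
            a = synergy_weights(S)
            np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-6)
            assert (a > 0).all() and (a <= 1).all()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            synergy_weights(np.array([[np.inf]]))


class TestAggregate:
    def test_single_region_identity(self, rng):
        f = rng.normal(size=(2, 4, 4))
        p = partition(f, PartitionStrategy(policy="grid", grid=(1, 1)))
        out = aggregate(p, np.array([[1.0]]))
        np.testing.assert_allclose(out.regions[0], f)

    def test_convex_combination_of_identical_regions_is_identity(self, rng):
        r = rng.normal(size=(3, 4, 4))
        f = np.concatenate([r, r], axis=2)
        p = partition(f, PartitionStrategy(policy="grid", grid=(1, 2)))
        out = aggregate(p, 0.5 * np.ones((2, 2)))
        np.testing.assert_allclose(out.regions[0], r, atol=1e-12)

    def test_scalar_weighted_sum_of_constant_regions(self):
        f = np.concatenate(
            [np.full((1, 2, 2), 1.0), np.full((1, 2, 2), 3.0)], axis=2
        )
        p = partition(f, PartitionStrategy(policy="grid", grid=(1, 2)))
        out = aggregate(p, np.array([[0.75, 0.25], [0.25, 0.75]]))
        np.testing.assert_allclose(out.regions[0], 1.5)
        np.testing.assert_allclose(out.regions[1], 2.5)

    def test_dimension_mismatch_rejected(self, rng):
        p = partition(rng.normal(size=(1, 4, 4)), PartitionStrategy(policy="grid"))
        with pytest.raises(ValueError, match="match"):
            aggregate(p, np.ones((3, 3)) / 3)


class TestAssembleAndForward:
    def test_reassembly_is_lossless_without_aggregation(self, rng):
        f = rng.normal(size=(3, 12, 20))
        np.testing.assert_array_equal(assemble(partition(f)), f)

    def test_permutation_equivariance(self, rng):
        f = rng.normal(size=(2, 8, 8))
        p = partition(f)
        a = synergy_weights(similarity_matrix(p))
        ref = aggregate(p, a)
        perm = rng.permutation(p.n)
        p2 = PartitionSet(
            [p.placements[i] for i in perm],
            [p.regions[i] for i in perm],
            p.descriptors[perm],
            p.source_shape,
        )
        out2 = aggregate(p2, synergy_weights(similarity_matrix(p2)))
        for k, i in enumerate(perm):
            np.testing.assert_allclose(out2.regions[k], ref.regions[i], atol=1e-10)

    def test_zero_input_maps_to_zero_output(self, rng):
        block = DGPS(4, rng)
        block.bn.freeze_stats()
        block.eval()
        out = block(Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_forward_equals_functional_composition(self, rng):
        """Module output reproduces partition -> cosine -> softmax -> mix -> conv/BN."""
        block = DGPS(4, rng)
        block.bn.freeze_stats()
        block.eval()
        x = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        got = block(Tensor(x)).data[0]

        p = partition(x[0], block.strategy)
        a = synergy_weights(similarity_matrix(p))
        mixed = assemble(aggregate(p, a))
        conv = (
            block.conv.weight.data.reshape(4, 4) @ mixed.reshape(4, -1)
        ).reshape(4, 8, 8)
        rm = block.bn._buffers["running_mean"].reshape(4, 1, 1)
        rv = block.bn._buffers["running_var"].reshape(4, 1, 1)
        bn = (conv - rm) / np.sqrt(rv + block.bn.eps)
        bn = bn * block.bn.weight.data.reshape(4, 1, 1) + block.bn.bias.data.reshape(4, 1, 1)
        want = np.maximum(bn + x[0], 0.0)
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_forward_preserves_shape_over_batches(self, rng):
        block = DGPS(6, rng)
        x = Tensor(rng.normal(size=(3, 6, 16, 16)).astype(np.float32))
        assert block(x).shape == x.shape
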
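"""Partition metrics (ARI, AVOI) and the iterative binary splitting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from glifkit.clustering import (
    Partition,
    SplitConfig,
    adjusted_rand_index,
    adjusted_variation_of_information,
    affinity_propagation_partition,
    avoi_upper_bound,
    build_feature_matrix,
    composition_table,
    iterative_binary_split,
    variation_of_information,
)
from glifkit.core import GLIFParameters


def brute_force_ari(a, b):
    """Pair-counting oracle: same/different agreement over all element pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    pairs = list(itertools.combinations(range(n), 2))
    ss = sum(1 for i, j in pairs if a[i] == a[j] and b[i] == b[j])
    dd = sum(1 for i, j in pairs if a[i] != a[j] and b[i] != b[j])
    index = ss + dd
    # expected index from marginal pair counts
    sa = sum(1 for i, j in pairs if a[i] == a[j])
    sb = sum(1 for i, j in pairs if b[i] == b[j])
    n_pairs = len(pairs)
    exp_ss = sa * sb / n_pairs
    exp_dd = (n_pairs - sa) * (n_pairs - sb) / n_pairs
    expected = exp_ss + exp_dd
    return (index - expected) / (n_pairs - expected)


def brute_force_vi(a, b):
    """Plug-in entropy oracle over the joint label distribution (nats)."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    pj = {}
    for x, y in zip(a, b):
        pj[(x, y)] = pj.get((x, y), 0) + 1 / n
    pa, pb = {}, {}
    for (x, y), p in pj.items():
        pa[x] = pa.get(x, 0) + p
        pb[y] = pb.get(y, 0) + p
    h = lambda d: -sum(p * np.log(p) for p in d.values() if p > 0)
    mi = h(pa) + h(pb) - h(pj)
    return h(pa) + h(pb) - 2 * mi


def part(labels):
    labels = np.asarray(labels)
    return Partition(labels=labels, cell_ids=tuple(range(labels.size)))


class TestARI:
    def test_identical_partitions(self):
        p = part([0, 0, 1, 1, 2])
        assert adjusted_rand_index(p, p) == pytest.approx(1.0)

    def test_crossed_pairs_example(self):
        # {1,1,2,2} vs {1,2,1,2}: brute-force pair counting gives -0.5
        a, b = [1, 1, 2, 2], [1, 2, 1, 2]
        assert brute_force_ari(a, b) == pytest.approx(-0.5)
        assert adjusted_rand_index(part(a), part(b)) == pytest.approx(-0.5)

    def test_matches_pair_counting_oracle(self, rng):
        a = rng.integers(0, 4, 30)
        b = rng.integers(0, 3, 30)
        assert adjusted_rand_index(part(a), part(b)) == pytest.approx(
            brute_force_ari(a, b)
        )

    def test_label_permutation_invariance(self, rng):
        a = rng.integers(0, 4, 50)
        b = rng.integers(0, 4, 50)
        remap = {0: 7, 1: 3, 2: 9, 3: 0}
        b2 = np.array([remap[x] for x in b])
        assert adjusted_rand_index(part(a), part(b)) == pytest.approx(
            adjusted_rand_index(part(a), part(b2))
        )

    def test_random_partitions_average_to_chance(self):
        rng = np.random.default_rng(0)
        vals = [
            adjusted_rand_index(
                part(rng.integers(0, 8, 1000)), part(rng.integers(0, 8, 1000))
            )
            for _ in range(50)
        ]
        assert abs(np.mean(vals)) < 0.01

    def test_mismatched_cells_rejected(self):
        p = part([0, 1])
        q = Partition(labels=np.array([0, 1]), cell_ids=("a", "b"))
        with pytest.raises(ValueError):
            adjusted_rand_index(p, q)


class TestAVOI:
    def test_upper_bound_is_log_n(self):
        assert avoi_upper_bound(645) == pytest.approx(np.log(645))
        assert round(avoi_upper_bound(645), 2) == 6.47

    def test_vi_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            a = rng.integers(0, 3, 6)
            b = rng.integers(0, 3, 6)
            assert variation_of_information(a, b) == pytest.approx(brute_force_vi(a, b))

    def test_identical_partitions_have_zero_vi(self):
        a = np.array([0, 0, 1, 2, 2])
        assert variation_of_information(a, a) == pytest.approx(0.0)

    def test_independent_random_partitions_near_zero(self):
        rng = np.random.default_rng(1)
        vals = [
            adjusted_variation_of_information(
                rng.integers(0, 8, 500), rng.integers(0, 8, 500), n_shuffles=200, seed=s
            )
            for s in range(10)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_all_singletons_equal_shuffled_baseline(self):
        # every shuffle of singleton labels is still a bijection: VI stays 0,
        # so the adjusted value equals the (zero) shuffled estimate
        n = 20
        labels = np.arange(n)
        assert adjusted_variation_of_information(labels, labels, n_shuffles=100) == (
            pytest.approx(0.0)
        )

    def test_agreement_beats_chance(self, rng):
        a = np.repeat(np.arange(4), 50)
        noisy = a.copy()
        flip = rng.integers(0, a.size, 20)
        noisy[flip] = rng.integers(0, 4, flip.size)
        assert adjusted_variation_of_information(a, noisy, n_shuffles=300, seed=0) > 0.5

    def test_relabeling_invariance(self, rng):
        a = rng.integers(0, 4, 100)
        b = rng.integers(0, 4, 100)
        b2 = (b + 2) % 4 + 10
        v1 = adjusted_variation_of_information(a, b, n_shuffles=300, seed=5)
        v2 = adjusted_variation_of_information(a, b2, n_shuffles=300, seed=5)
        assert v1 == pytest.approx(v2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            adjusted_variation_of_information(np.array([]), np.array([]))


def _params(level=1, **kw):
    base = dict(
        level=level, C=100e-12, R=100e6, E_L=-70e-3, theta_inf=-45e-3, spike_cut=3e-3
    )
    base.update(kw)
    return GLIFParameters(**base)


class TestFeatureMatrix:
    def test_level1_columns(self):
        cells = {f"c{i}": _params(C=(50 + i) * 1e-12) for i in range(6)}
        m = build_feature_matrix(cells, level=1)
        assert m.columns == ("R", "C", "E_L", "theta_inf", "spike_cut")

    def test_level4_columns_include_charges(self):
        cells = {
            f"c{i}": _params(
                level=4,
                C=(50 + i) * 1e-12,
                f_v=0.3,
                delta_V=4e-3,
                b_s=50.0,
                delta_theta_s=4e-3,
                k=(100.0, 10.0),
                delta_I=(-20e-12, 5e-12),
            )
            for i in range(6)
        }
        m = build_feature_matrix(cells, level=4)
        assert len(m.columns) == 9
        assert "Q1" in m.columns and "Q2" in m.columns

    def test_columns_standardized(self, rng):
        cells = {
            f"c{i}": _params(C=c * 1e-12, R=r * 1e6)
            for i, (c, r) in enumerate(zip(rng.uniform(50, 300, 20), rng.uniform(50, 300, 20)))
        }
        m = build_feature_matrix(cells, level=1)
        assert np.allclose(m.values.mean(axis=0), 0, atol=1e-12)
        varying = [m.columns.index("R"), m.columns.index("C")]
        assert np.allclose(m.values.std(axis=0)[varying], 1, atol=1e-12)
        constant = [m.columns.index("E_L"), m.columns.index("spike_cut")]
        assert np.allclose(m.values[:, constant], 0, atol=1e-9)

    def test_inverse_transform_recovers_raw(self, rng):
        cells = {
            f"c{i}": _params(C=c * 1e-12, R=r * 1e6)
            for i, (c, r) in enumerate(zip(rng.uniform(50, 300, 10), rng.uniform(50, 300, 10)))
        }
        m = build_feature_matrix(cells, level=1)
        back = m.inverse_transform()
        assert np.allclose(back.to_numpy(), m.raw.to_numpy(), rtol=1e-10)

    def test_missing_values_named(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]}, index=["x", "y"])
        with pytest.raises(ValueError, match="y"):
            build_feature_matrix(df)


class TestIterativeBinarySplit:
    def _blobs(self, rng, centers, n=100, sd=1.0, dims=5):
        xs, labels = [], []
        for i, c in enumerate(centers):
            xs.append(rng.normal(c, sd, size=(n, dims)))
            labels += [i] * n
        x = np.vstack(xs)
        df = pd.DataFrame(x, columns=[f"f{j}" for j in range(dims)])
        df.index = [f"c{i}" for i in range(len(df))]
        m = build_feature_matrix(df)
        truth = Partition(labels=np.array(labels), cell_ids=m.cell_ids)
        return m, truth

    def test_two_separated_blobs_split_once(self, rng):
        m, truth = self._blobs(rng, [np.zeros(5), np.full(5, 10.0)])
        partition, scores = iterative_binary_split(m, SplitConfig(seed=0))
        assert partition.n_clusters == 2
        assert scores["r"] >= 0.95
        assert adjusted_rand_index(partition, truth) == pytest.approx(1.0)

    def test_single_blob_stays_whole(self, rng):
        m, _ = self._blobs(rng, [np.zeros(5)])
        partition, _ = iterative_binary_split(m, SplitConfig(seed=0))
        assert partition.n_clusters == 1

    def test_four_planted_archetypes_recovered(self, rng):
        centers = [np.zeros(5)]
        centers.append(np.array([8.0, 0, 0, 0, 0]))
        centers.append(np.array([0, 8.0, 8.0, 0, 0]))
        centers.append(np.array([4.0, 4.0, 0, 8.0, 0]))
        m, truth = self._blobs(rng, centers, n=50)
        partition, _ = iterative_binary_split(m, SplitConfig(seed=1))
        assert adjusted_rand_index(partition, truth) >= 0.8

    def test_affinity_backend_satisfies_partition_contract(self, rng):
        m, truth = self._blobs(rng, [np.zeros(5), np.full(5, 10.0)], n=40)
        partition = affinity_propagation_partition(m, seed=0)
        assert partition.n_cells == 80
        assert adjusted_rand_index(partition, truth) > 0.9


class TestCompositionTable:
    def test_matching_partition_is_permutation_matrix(self):
        p = Partition(labels=np.array([0, 0, 1, 1]), cell_ids=("a", "b", "c", "d"))
        labels = {"a": "X", "b": "X", "c": "Y", "d": "Y"}
        table = composition_table(p, labels)
        assert np.allclose(np.sort(table.to_numpy(), axis=0), [[0, 0], [1, 1]])

    def test_single_cluster_row_of_ones(self):
        p = Partition(labels=np.zeros(4, dtype=int), cell_ids=("a", "b", "c", "d"))
        table = composition_table(p, {"a": "X", "b": "X", "c": "Y", "d": "Y"})
        assert np.allclose(table.to_numpy(), 1.0)

    def test_columns_sum_to_one(self, rng):
        ids = tuple(f"c{i}" for i in range(60))
        p = Partition(labels=rng.integers(0, 3, 60), cell_ids=ids)
        labels = {c: ("A" if i % 2 else "B") for i, c in enumerate(ids)}
        table = composition_table(p, labels)
        assert np.allclose(table.sum(axis=0), 1.0)

    def test_unlabeled_cell_rejected(self):
        p = Partition(labels=np.array([0, 1]), cell_ids=("a", "b"))
        with pytest.raises(ValueError, match="b"):
            composition_table(p, {"a": "X"})
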
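"""Variant separation: column selection, distances, trees, DBSCAN."""

import math
import random

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from tecurate.clustering import (
    K2P_MAX,
    NOISE,
    ClusterAssignment,
    ClusteringParams,
    DistanceMatrix,
    UndefinedDistanceError,
    UniformMsaError,
    build_pseudo_msa,
    dbscan_cluster,
    k2p_distance,
    nj_patristic,
    noise_qualifies,
    partition_msa,
    patristic_from_newick,
    select_divergent_columns,
    select_gap_blocks,
    tree_relative_distances,
)
from tecurate.msa import Msa
from tecurate.synthetic import mutate_sequence, random_sequence

from conftest import msa_from
from oracles import dbscan_oracle, random_additive_matrix


def column_msa(*columns: str) -> Msa:
    n_rows = len(columns[0])
    return msa_from(*["".join(col[i] for col in columns) for i in range(n_rows)])


class TestDivergentColumns:
    def test_proportion_at_threshold_not_divergent(self):
        assert select_divergent_columns(column_msa("A" * 8 + "C" * 2)) == []

    def test_proportion_below_threshold_divergent(self):
        assert select_divergent_columns(column_msa("A" * 7 + "C" * 3)) == [0]

    def test_uniform_column_not_divergent(self):
        assert select_divergent_columns(column_msa("A" * 10)) == []


class TestGapBlocks:
    def build(self, gap_rows):
        # 50 rows so gap proportions are exact to 2%
        return gap_rows

    def test_smooth_block_with_conserved_flanks(self):
        # gap fractions [0, .5, .52, .5, 0]; flanks 100% A
        cols = [
            "A" * 50,
            "-" * 25 + "C" * 25,
            "-" * 26 + "C" * 24,
            "-" * 25 + "C" * 25,
            "A" * 50,
        ]
        assert select_gap_blocks(column_msa(*cols)) == [(1, 4)]

    def test_adjacent_delta_exceeded(self):
        cols = ["A" * 50, "-" * 25 + "C" * 25, "-" * 35 + "C" * 15, "A" * 50]
        assert select_gap_blocks(column_msa(*cols)) == []  # delta 0.2 > 0.1

    def test_gap_free_msa(self):
        assert select_gap_blocks(msa_from("ACGT", "ACGT")) == []

    def test_weak_flank_rejected(self):
        cols = ["A" * 30 + "C" * 20, "-" * 25 + "C" * 25, "A" * 50]
        assert select_gap_blocks(column_msa(*cols)) == []  # flank dominance 0.6


class TestPseudoMsa:
    def test_selected_columns_concatenated(self):
        msa = msa_from("ABCDEFGH".replace("B", "C")[:8] * 0 + "ACGTACGT", "ACGTACGT")
        pseudo = build_pseudo_msa(msa, [2, 7], [(4, 6)])
        assert pseudo.row_str(0) == "GACT"  # columns 2,4,5,7

    def test_overlapping_selection_deduplicated(self):
        msa = msa_from("ACGTACGT")
        pseudo = build_pseudo_msa(msa, [2, 4], [(4, 6)])
        assert pseudo.width == 3  # columns 2,4,5

    def test_empty_selection_raises_uniform_condition(self):
        with pytest.raises(UniformMsaError):
            build_pseudo_msa(msa_from("ACGT"), [], [])


class TestK2P:
    def test_identical_sequences(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_transitions_only_closed_form(self):
        a = "A" * 90 + "G" * 10
        b = "A" * 100
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)

    def test_mixed_closed_form(self):
        a = "A" * 90 + "G" * 5 + "C" * 5
        b = "A" * 100
        expected = -0.5 * math.log(0.85) - 0.25 * math.log(0.90)
        assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_gap_and_n_sites_skipped(self):
        assert k2p_distance("AC-GN", "ACCGT") == 0.0

    def test_no_comparable_sites_is_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            k2p_distance("AC--", "--GT")

    def test_saturated_distance_capped(self):
        assert k2p_distance("A" * 10, "G" * 10) == K2P_MAX


class TestTreeDistances:
    def test_nj_recovers_additive_matrices(self):
        rng = random.Random(5)
        for _ in range(100):
            n = rng.randint(4, 12)
            d = np.array(random_additive_matrix(n, rng))
            ids = [f"t{i}" for i in range(n)]
            pat = nj_patristic(d, ids)
            assert np.allclose(pat, d, atol=1e-9)

    def test_relative_distance_hand_path_sum(self):
        # unrooted tree ((A:1,B:1):1,C:1,D:1): d(A,B)=2, max d=3
        ids = ["A", "B", "C", "D"]
        rel = patristic_from_newick("((A:1,B:1):1,C:1,D:1);", ids)
        rel = rel / rel.max()
        assert rel[0, 1] == pytest.approx(2 / 3)

    def test_identical_rows_yield_zeros(self):
        msa = msa_from("ACGT", "ACGT", "ACGT")
        dm = tree_relative_distances(msa)
        assert (dm.d == 0).all()

    def test_entries_on_unit_scale(self, rng):
        rows = [
            mutate_sequence(random_sequence(200, rng), 0.2, rng) for _ in range(6)
        ]
        dm = tree_relative_distances(msa_from(*rows))
        assert dm.d.max() == pytest.approx(1.0)
        assert dm.d.min() >= 0.0


class TestDbscan:
    def test_pair_and_noise(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.05, 0.9], [0.05, 0, 0.9], [0.9, 0.9, 0]]),
        )
        asg = dbscan_cluster(dm, 0.1, 2)
        assert asg.clusters == [[0, 1]]
        assert asg.noise_indices == [2]

    def test_density_reachable_chain(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.08, 0.16], [0.08, 0, 0.08], [0.16, 0.08, 0]]),
        )
        assert dbscan_cluster(dm, 0.1, 2).clusters == [[0, 1, 2]]

    def test_all_noise(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]),
        )
        asg = dbscan_cluster(dm, 0.1, 2)
        assert asg.clusters == []
        assert set(asg.noise_indices) == {0, 1, 2}

    def test_matches_definition_bruteforce(self):
        rng = random.Random(19)
        for _ in range(200):
            n = rng.randint(2, 40)
            m = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    m[i, j] = m[j, i] = rng.random()
            eps = rng.choice([0.05, 0.1, 0.3, 0.5])
            min_samples = rng.randint(1, 4)
            got = dbscan_cluster(DistanceMatrix([str(i) for i in range(n)], m), eps, min_samples)
            exp = dbscan_oracle(m.tolist(), eps, min_samples)
            # compare partitions (label values may differ)
            got_sets = {frozenset(c) for c in got.clusters}
            exp_clusters = {}
            for i, lab in enumerate(exp):
                if lab != -1:
                    exp_clusters.setdefault(lab, set()).add(i)
            assert got_sets == {frozenset(c) for c in exp_clusters.values()}
            assert set(got.noise_indices) == {i for i, lab in enumerate(exp) if lab == -1}


class TestNoiseRule:
    params = ClusteringParams(max_cluster_num=5)

    def make(self, n_noise: int, total: int, n_clusters: int) -> ClusterAssignment:
        labels = np.full(total, NOISE)
        clustered = total - n_noise
        per = max(clustered // max(n_clusters, 1), 1) if n_clusters else 0
        pos = 0
        clusters = []
        for c in range(n_clusters):
            size = per if c < n_clusters - 1 else clustered - per * (n_clusters - 1)
            members = list(range(pos, pos + size))
            labels[members] = c
            clusters.append(members)
            pos += size
        return ClusterAssignment(labels=labels, clusters=clusters)

    def test_all_three_conditions_met(self):
        asg = self.make(16, 26, 2)  # 16 > 15, 16/26 = 61.5% > 60%, 2 < 5
        assert noise_qualifies(asg, 26, self.params)

    def test_size_condition_fails(self):
        asg = self.make(15, 24, 2)  # 62.5% but 15 is not > 15
        assert not noise_qualifies(asg, 24, self.params)

    def test_fraction_condition_fails(self):
        asg = self.make(16, 27, 2)  # 16 > 15 but 59.2% < 60%
        assert not noise_qualifies(asg, 27, self.params)

    def test_cluster_count_condition_fails(self):
        asg = self.make(16, 26, 5)  # 5 normal clusters is not < 5
        assert not noise_qualifies(asg, 26, self.params)


def planted_variant_msa(k: int, seed: int, copies: int = 9, core: int = 800):
    """Alignment of ``k`` diverged variants (pairwise >= 10%) with
    near-identical copies (within <= 2%)."""
    rng = np.random.default_rng([seed, k])
    base = random_sequence(core, rng)
    rows, truth = [], []
    for v in range(k):
        variant = mutate_sequence(base, 0.12, rng)
        for c in range(copies):
            rows.append((f"v{v}c{c}", mutate_sequence(variant, 0.005, rng)))
            truth.append(v)
    return Msa.from_rows(rows), truth


class TestPartition:
    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_planted_partition_recovered_exactly(self, k):
        for seed in range(5):
            msa, truth = planted_variant_msa(k, seed)
            subs = partition_msa(msa)
            assert len(subs) == k
            labels = {}
            for ci, sub in enumerate(subs):
                for sid in sub.ids:
                    labels[sid] = ci
            pred = [labels[sid] for sid in msa.ids]
            assert adjusted_rand_score(truth, pred) == 1.0

    def test_noise_cluster_appended_when_rule_fires(self):
        # 2 tight pairs + 21 mutually distant sequences (noise, 84% of 25)
        rng = np.random.default_rng(3)
        base = random_sequence(600, rng)
        rows = []
        for v in range(2):
            variant = mutate_sequence(base, 0.15, rng)
            rows += [(f"v{v}a", variant), (f"v{v}b", mutate_sequence(variant, 0.002, rng))]
        for j in range(21):
            rows.append((f"n{j}", mutate_sequence(base, 0.35, rng)))
        msa = Msa.from_rows(rows)
        subs = partition_msa(msa)
        sizes = sorted(sub.n_rows for sub in subs)
        assert sizes[-1] >= 16  # the processed noise cluster
        assert len(subs) >= 3

    def test_homogeneous_msa_single_cluster(self):
        msa = msa_from("ACGTACGTAC", "ACGTACGTAC", "ACGTACGTAC")
        subs = partition_msa(msa)
        assert len(subs) == 1
        assert subs[0].n_rows == 3

    def test_rows_partition_into_at_most_one_cluster(self):
        msa, _ = planted_variant_msa(3, 11)
        subs = partition_msa(msa)
        seen = [sid for sub in subs for sid in sub.ids]
        assert len(seen) == len(set(seen))
        assert set(seen) <= set(msa.ids)
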
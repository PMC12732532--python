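"""Clustering identity, greedy partitioning, consensus recovery."""

import numpy as np
import pytest

from pbscout._align import revcomp
from pbscout import synthetic_genome as sg
from pbscout.family_clustering import (
    Cluster,
    build_consensus,
    greedy_cluster,
    pairwise_identity,
)


def _mutate_fraction(seq: str, fraction: float, rng) -> str:
    """Substitute exactly round(fraction*len) distinct sites."""
    seq = list(seq)
    sites = rng.choice(len(seq), size=int(round(fraction * len(seq))), replace=False)
    for i in sites:
        seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    return "".join(seq)


class TestPairwiseIdentity:
    def test_identical_sequences(self, rng):
        s = sg.random_dna(1000, rng)
        assert pairwise_identity(s, s) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_non_dna_raises(self):
        with pytest.raises(ValueError):
            pairwise_identity("ACGU", "ACGT")

    def test_half_diverged_pair_scores_about_half(self, rng):
        master = sg.random_dna(2000, rng)
        other = _mutate_fraction(master, 0.5, np.random.default_rng(2))
        ident = pairwise_identity(master, other)
        assert 0.45 <= ident <= 0.55

    def test_unrelated_sequences_score_below_threshold(self, rng):
        a = sg.random_dna(2000, rng)
        b = sg.random_dna(2000, rng)
        assert pairwise_identity(a, b) < 0.45


class TestGreedyCluster:
    def test_single_sequence_is_own_centroid(self, rng):
        clusters = greedy_cluster({"x": sg.random_dna(500, rng)})
        assert len(clusters) == 1
        assert clusters[0].centroid_id == "x"
        assert clusters[0].member_ids == ["x"]

    def test_one_family_one_cluster(self, rng):
        master = sg.random_dna(2000, rng)
        seqs = {
            f"c{i}": sg.mutate_copy(master, 0.08, rng_seed=i)[0] for i in range(8)
        }
        clusters = greedy_cluster(seqs, 0.5)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_ids) == sorted(seqs)

    def test_two_unrelated_families_two_clusters(self, rng):
        m1, m2 = sg.random_dna(2000, rng), sg.random_dna(2000, rng)
        assert pairwise_identity(m1, m2) < 0.4
        seqs = {}
        for i in range(5):
            seqs[f"a{i}"] = sg.mutate_copy(m1, 0.05, rng_seed=i)[0]
            seqs[f"b{i}"] = sg.mutate_copy(m2, 0.05, rng_seed=100 + i)[0]
        clusters = greedy_cluster(seqs, 0.5)
        assert len(clusters) == 2
        parts = [set(c.member_ids) for c in clusters]
        assert {f"a{i}" for i in range(5)} in parts
        assert {f"b{i}" for i in range(5)} in parts

    def test_reverse_complement_member_joins_flipped(self, rng):
        master = sg.random_dna(1500, rng)
        seqs = {
            "fwd": master,
            "rev": revcomp(sg.mutate_copy(master, 0.03, rng_seed=1)[0]),
        }
        clusters = greedy_cluster(seqs, 0.5)
        assert len(clusters) == 1
        orientation = dict(zip(clusters[0].member_ids, clusters[0].orientations))
        assert orientation["rev"] == "-"

    def test_cluster_count_nonincreasing_in_threshold(self, rng):
        masters = [sg.random_dna(1500, rng) for _ in range(3)]
        seqs = {}
        idx = 0
        for m in masters:
            for _ in range(4):
                seqs[f"s{idx}"] = sg.mutate_copy(m, 0.15, rng_seed=idx)[0]
                idx += 1
        counts = [
            len(greedy_cluster(seqs, th)) for th in (0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts)

    def test_partition_invariant_under_relabeling(self, rng):
        masters = [sg.random_dna(1500, rng) for _ in range(2)]
        seqs = {}
        idx = 0
        for m in masters:
            for _ in range(4):
                seqs[f"s{idx}"] = sg.mutate_copy(m, 0.05, rng_seed=idx)[0]
                idx += 1
        relabeled = {f"z{k[1:]}": v for k, v in seqs.items()}
        parts_a = sorted(
            tuple(sorted(s[1:] for s in c.member_ids))
            for c in greedy_cluster(seqs, 0.5)
        )
        parts_b = sorted(
            tuple(sorted(s[1:] for s in c.member_ids))
            for c in greedy_cluster(relabeled, 0.5)
        )
        assert parts_a == parts_b


class TestBuildConsensus:
    def test_single_member_returns_member(self, rng):
        s = sg.random_dna(300, rng)
        c = Cluster("c1", "x", ["x"], [1.0], ["+"])
        assert build_consensus(c, {"x": s}) == s

    def test_column_majority(self):
        seqs = {"a": "AAT", "b": "AAT", "c": "AGT"}
        c = Cluster("c1", "a", ["a", "b", "c"], [1.0] * 3, ["+"] * 3)
        assert build_consensus(c, seqs) == "AAT"

    def test_consensus_recovers_master_against_majority_vote_oracle(self, rng):
        master = sg.random_dna(2400, rng)
        copies = {
            f"c{i:02d}": sg.mutate_copy(master, 0.05, rng_seed=i)[0]
            for i in range(20)
        }
        centroid = sorted(copies)[0]
        cluster = Cluster(
            "fam", centroid, sorted(copies), [1.0] * 20, ["+"] * 20
        )
        consensus = build_consensus(cluster, copies)
        # independent oracle: copies have no indels, so per-site majority
        # over raw columns reconstructs the master
        oracle = "".join(
            max("ACGT", key=lambda b: sum(copies[c][i] == b for c in copies))
            for i in range(len(master))
        )
        assert pairwise_identity(consensus, master) >= 0.99
        assert pairwise_identity(oracle, master) >= 0.99
        assert pairwise_identity(consensus, oracle) >= 0.995


class TestClusterRecoveryAgainstTruth:
    def test_adjusted_rand_index_is_one_on_planted_families(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(23)
        masters = {
            f"fam{j}": sg.random_dna(int(rng.integers(2074, 3465)), rng)
            for j in range(5)
        }
        # construction guarantees: inter-master < 0.45, intra >= 0.9
        labels_true, labels_ids, seqs = [], [], {}
        idx = 0
        for fam, master in masters.items():
            for _ in range(6):
                seqs[f"e{idx}"] = sg.mutate_copy(master, 0.03, rng_seed=idx)[0]
                labels_true.append(fam)
                labels_ids.append(f"e{idx}")
                idx += 1
        clusters = greedy_cluster(seqs, 0.5)
        assignment = {
            m: c.cluster_id for c in clusters for m in c.member_ids
        }
        labels_pred = [assignment[i] for i in labels_ids]
        assert adjusted_rand_score(labels_true, labels_pred) == 1.0
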
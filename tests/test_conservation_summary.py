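"""Logo information content, domain identity matrices, NJ reconstruction."""

import numpy as np
import pandas as pd
import pytest

from pbscout import conservation_summary as cs


class TestTirLogo:
    def test_monomorphic_position_is_two_bits(self):
        logo = cs.tir_logo(["ACGTACGT", "ACTTACGT", "ACGTACCT"], L=8)
        assert logo.information[0] == pytest.approx(2.0)
        assert logo.information[1] == pytest.approx(2.0)

    def test_uniform_position_is_zero_bits(self):
        logo = cs.tir_logo(["AAAA", "CAAA", "GAAA", "TAAA"], L=4)
        assert logo.information[0] == pytest.approx(0.0)
        assert logo.information[1] == pytest.approx(2.0)

    def test_shared_ccct_motif_scores_two_bits_over_first_four(self):
        rng = np.random.default_rng(0)
        tirs = [
            "CCCT" + "".join(rng.choice(list("ACGT"), 12)) for _ in range(10)
        ]
        logo = cs.tir_logo(tirs, L=16)
        assert np.allclose(logo.information[:4], 2.0)

    def test_frequencies_sum_to_one(self):
        logo = cs.tir_logo(["ACGT", "AGGT", "ACCT"], L=4)
        assert np.allclose(logo.freq.sum(axis=1), 1.0)

    def test_short_tirs_skip_tail_positions(self):
        logo = cs.tir_logo(["ACGTACGT", "ACGT"], L=8)
        assert logo.n_used[3] == 2 and logo.n_used[4] == 1

    def test_fewer_than_two_sequences_raises(self):
        with pytest.raises(ValueError):
            cs.tir_logo(["ACGT"])

    def test_information_invariant_under_relabeling(self):
        tirs = ["ACGTAC", "AGGTAC", "ACGTTC", "TCGTAC"]
        a = cs.tir_logo(tirs, L=6)
        b = cs.tir_logo(tirs[::-1], L=6)
        assert np.allclose(a.information, b.information)


def _domain_table(protein_ids, start=0, end=40):
    return pd.DataFrame(
        [(p, "DDD", start, end) for p in protein_ids],
        columns=["protein_id", "domain", "start", "end"],
    )


class TestDomainIdentityMatrix:
    def test_identical_pair_within_clade_is_100(self):
        prot = "MKVLAAGHST" * 4
        proteins = {"p1": prot, "p2": prot}
        mat = cs.domain_identity_matrix(
            proteins, _domain_table(["p1", "p2"]), {"p1": "A", "p2": "A"}, "DDD"
        )
        assert mat.loc["A", "A"] == pytest.approx(100.0)

    def test_matrix_symmetric(self):
        rng = np.random.default_rng(1)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        proteins = {f"p{i}": "".join(rng.choice(aas, 40)) for i in range(6)}
        clades = {f"p{i}": "ABC"[i % 3] for i in range(6)}
        mat = cs.domain_identity_matrix(
            proteins, _domain_table(list(proteins)), clades, "DDD"
        )
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)

    def test_constructed_fifty_percent_identity_recovered(self):
        rng = np.random.default_rng(7)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        base = "".join(rng.choice(aas, 100))
        # clade B differs from clade A at exactly half the positions
        half = list(base)
        sites = rng.choice(100, size=50, replace=False)
        for i in sites:
            half[i] = rng.choice([a for a in aas if a != half[i]])
        proteins = {"a1": base, "a2": base, "b1": "".join(half), "b2": "".join(half)}
        clades = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        mat = cs.domain_identity_matrix(
            proteins, _domain_table(list(proteins), 0, 100), clades, "DDD"
        )
        assert mat.loc["A", "B"] == pytest.approx(50.0, abs=3.0)
        assert mat.loc["A", "A"] == pytest.approx(100.0)

    def test_singleton_clade_diagonal_unavailable(self):
        proteins = {"p1": "MKVLAAGHST" * 4, "p2": "MKVLAAGHST" * 4}
        mat = cs.domain_identity_matrix(
            proteins, _domain_table(["p1", "p2"]), {"p1": "A", "p2": "B"}, "DDD"
        )
        assert np.isnan(mat.loc["A", "A"])
        assert mat.loc["A", "B"] == pytest.approx(100.0)

    def test_missing_annotation_raises(self):
        with pytest.raises(KeyError):
            cs.domain_identity_matrix(
                {"p1": "MKVL" * 10}, _domain_table(["other"]), {"p1": "A"}, "DDD"
            )


def _topology_set(newick: str):
    """Bipartitions of an unrooted tree via dendropy (independent oracle)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    taxa = {t.label for t in tree.taxon_namespace}
    out = set()
    for bp in tree.bipartition_encoding:
        left = {t.label for t in bp.leafset_taxa(tree.taxon_namespace)}
        side = min(
            (frozenset(left), frozenset(taxa - left)),
            key=lambda s: (len(s), tuple(sorted(s))),
        )
        if 1 < len(side) < len(taxa) - 1:
            out.add(side)
    return out


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovers_topology(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) gives these path distances
        labels = ["A", "B", "C", "D"]
        D = np.array([
            [0, 3, 5, 3],
            [3, 0, 6, 4],
            [5, 6, 0, 4],
            [3, 4, 4, 0],
        ], dtype=float)
        newick = cs.nj_tree(D, labels)
        assert _topology_set(newick) == {frozenset({"A", "B"})}

    def test_three_taxa_unique_topology(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        newick = cs.nj_tree(D, ["x", "y", "z"])
        assert newick.count(",") == 2

    def test_random_additive_trees_recovered(self, rng):
        for trial in range(20):
            n = int(rng.integers(5, 9))
            true_newick, D, labels = cs.random_additive_tree(n, rng)
            est = cs.nj_tree(D, labels)
            assert _topology_set(est) == _topology_set(true_newick), trial

    def test_tie_break_deterministic(self):
        # ultrametric with two equal merges
        D = np.array([
            [0, 2, 6, 6],
            [2, 0, 6, 6],
            [6, 6, 0, 2],
            [6, 6, 2, 0],
        ], dtype=float)
        outs = {cs.nj_tree(D, ["a", "b", "c", "d"]) for _ in range(5)}
        assert len(outs) == 1

    def test_asymmetric_matrix_raises(self):
        D = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            cs.nj_tree(D, ["a", "b", "c"])

    def test_branch_lengths_nonnegative(self, rng):
        _, D, labels = cs.random_additive_tree(6, rng)
        newick = cs.nj_tree(D, labels)
        lengths = [
            float(tok.split(")")[0].split(",")[0])
            for tok in newick.split(":")[1:]
        ]
        assert all(x >= 0 for x in lengths)


class TestExportAlignment:
    def test_phylip_header(self, tmp_path):
        path = tmp_path / "aln.phy"
        cs.export_alignment(
            {"s1": "ACGT", "s2": "AGGT", "s3": "ACCT"}, path, fmt="phylip"
        )
        header = path.read_text().splitlines()[0].split()
        assert header == ["3", "4"]

    def test_roundtrip_fasta_and_phylip(self, tmp_path):
        records = {
            "a_very_long_identifier_name": "ACGTACGT",
            "short": "AGGTACGT",
        }
        for fmt, name in (("fasta", "x.fa"), ("phylip", "x.phy")):
            path = tmp_path / name
            cs.export_alignment(records, path, fmt=fmt)
            back = cs.read_alignment(path, fmt=fmt)
            assert back == records

    def test_duplicate_ids_raise(self, tmp_path):
        class Dup(dict):
            def __iter__(self):
                return iter(["x", "x"])
        with pytest.raises(ValueError):
            cs.export_alignment(Dup(x="ACGT"), tmp_path / "y.fa")
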
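"""Translated search: six frames, filters, extraction, DP-oracle equivalence."""

import numpy as np
import pytest

from pbscout._align import revcomp
from pbscout import homology_search as hs
from pbscout import synthetic_genome as sg


class TestSixFrameTranslate:
    def test_forward_frame_one(self):
        frames = dict(hs.six_frame_translate("ATGGCC"))
        assert frames[1] == "MA"

    def test_reverse_frame_stop(self):
        frames = dict(hs.six_frame_translate("TTA"))
        assert frames[-1] == "*"

    def test_total_residue_bound(self, rng):
        # six frames of at most len/3 residues each: total <= 2*len
        contig = sg.random_dna(301, rng)
        frames = hs.six_frame_translate(contig)
        assert all(len(p) <= len(contig) // 3 for _, p in frames)
        assert sum(len(p) for _, p in frames) <= 2 * len(contig)

    def test_frame_provenance_complete(self):
        frames = dict(hs.six_frame_translate("ACGTACGTACGT"))
        assert set(frames) == {1, 2, 3, -1, -2, -3}


class TestQueryValidation:
    def test_short_query_rejected(self):
        with pytest.raises(ValueError):
            hs.ProteinQuery("q", "MKL")

    def test_bad_residues_rejected(self):
        with pytest.raises(ValueError):
            hs.ProteinQuery("q", "M" * 49 + "B")


class TestRetentionFilters:
    """Mining thresholds are strict inequalities."""

    @pytest.mark.parametrize(
        "identity,coverage,kept",
        [
            (0.79, 0.50, False),
            (0.81, 0.50, True),
            (0.90, 0.29, False),
            (0.90, 0.31, True),
            (0.80, 0.80, False),  # boundary value rejected
            (0.90, 0.30, False),
        ],
    )
    def test_strict_thresholds(self, identity, coverage, kept):
        hit = hs.TranslatedHit(
            contig="c", frame=1, genome_start=0, genome_end=300,
            query_start=0, query_end=100, identity=identity,
            coverage=coverage, score=100.0,
        )
        assert hs.passes_filters(hit, hs.SearchParams()) is kept


class TestSearch:
    def test_self_match_found_with_full_identity(self, small_template):
        t = small_template
        rng = np.random.default_rng(2)
        contig = sg.random_dna(3000, rng) + t.sequence + sg.random_dna(3000, rng)
        query = hs.ProteinQuery("q", t.dde_query)
        hits = hs.search(query, {"c1": contig})
        assert hits
        best = max(hits, key=lambda h: h.score)
        assert best.identity == 1.0
        assert best.coverage == pytest.approx(1.0)
        assert best.strand == "+"

    def test_minus_strand_hit_on_reverse_complemented_genome(self, small_template):
        t = small_template
        rng = np.random.default_rng(2)
        contig = sg.random_dna(2000, rng) + t.sequence + sg.random_dna(2000, rng)
        query = hs.ProteinQuery("q", t.dde_query)
        fwd = hs.search(query, {"c1": contig})
        rev = hs.search(query, {"c1": revcomp(contig)})
        assert len(fwd) == len(rev) == 1
        assert fwd[0].strand == "+" and rev[0].strand == "-"
        # mirrored coordinates
        n = len(contig)
        assert rev[0].genome_start == n - fwd[0].genome_end
        assert rev[0].genome_end == n - fwd[0].genome_start

    def test_query_shorter_than_word_raises(self):
        q = hs.ProteinQuery("q", "M" * 50)
        with pytest.raises(ValueError):
            hs.search(q, {"c": "ACGTACGT"}, hs.SearchParams(word_size=60))

    def test_best_hit_score_matches_smith_waterman_oracle(self, rng):
        # small instance: full DP per frame is feasible and independent
        protein = "".join(
            np.random.default_rng(5).choice(list("ACDEFGHIKLMNPQRSTVWY"), 55)
        )
        query = hs.ProteinQuery("q", protein)
        # plant a diverged copy of the query inside a short contig
        codons = _reverse_translate(protein)
        contig = (
            sg.random_dna(600, rng) + codons + sg.random_dna(600, rng)
        )
        params = hs.SearchParams(identity_min=0.0, coverage_min=0.0,
                                 min_ungapped_score=20)
        hits = hs.search(query, {"c": contig}, params)
        assert hits
        best = max(h.score for h in hits)
        oracle = max(
            _smith_waterman(protein, frame_seq)
            for _, frame_seq in hs.six_frame_translate(contig)
            if frame_seq
        )
        assert best == pytest.approx(oracle)


def _reverse_translate(protein: str) -> str:
    from Bio.Data.CodonTable import standard_dna_table

    by_aa = {}
    for codon, aa in standard_dna_table.forward_table.items():
        by_aa.setdefault(aa, codon)
    return "".join(by_aa[aa] for aa in protein)


def _smith_waterman(a: str, b: str) -> float:
    """Independent affine-gap local DP (BLOSUM62, open 11 extend 1)."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    idx = {aa: i for i, aa in enumerate(mat.alphabet)}
    NEG = -1e9
    n, m = len(a), len(b)
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[idx[a[i - 1]], idx[b[j - 1]]]
            M[i][j] = max(0.0, max(M[i - 1][j - 1], X[i - 1][j - 1],
                                   Y[i - 1][j - 1]) + s)
            X[i][j] = max(M[i - 1][j] - 11, X[i - 1][j] - 1)
            Y[i][j] = max(M[i][j - 1] - 11, Y[i][j - 1] - 1)
            best = max(best, M[i][j])
    return best


class TestExtractCandidates:
    def _hit(self, start, end, frame=1, contig="c"):
        return hs.TranslatedHit(
            contig=contig, frame=frame, genome_start=start, genome_end=end,
            query_start=0, query_end=100, identity=0.9, coverage=0.9,
            score=100.0,
        )

    def test_flank_arithmetic(self):
        genome = {"c": "A" * 20_000}
        loci = hs.extract_candidates([self._hit(10_000, 12_000)], genome, 4000)
        assert (loci[0].flank_start, loci[0].flank_end) == (6000, 16_000)
        assert (loci[0].core_start, loci[0].core_end) == (10_000, 12_000)

    def test_flank_clamped_at_contig_edge(self):
        genome = {"c": "A" * 20_000}
        loci = hs.extract_candidates([self._hit(1000, 3000)], genome, 4000)
        assert loci[0].flank_start == 0
        assert loci[0].flank_end == 7000

    def test_nearby_hits_merge_into_one_locus(self):
        genome = {"c": "A" * 30_000}
        hits = [self._hit(5000, 6000), self._hit(6500, 7500, frame=2)]
        loci = hs.extract_candidates(hits, genome, 4000, merge_distance=1000)
        assert len(loci) == 1
        assert (loci[0].core_start, loci[0].core_end) == (5000, 7500)

    def test_distant_hits_stay_separate(self):
        genome = {"c": "A" * 40_000}
        hits = [self._hit(5000, 6000), self._hit(9000, 10_000)]
        loci = hs.extract_candidates(hits, genome, 1000, merge_distance=2000)
        assert len(loci) == 2

    def test_unknown_contig_raises(self):
        with pytest.raises(KeyError):
            hs.extract_candidates([self._hit(0, 10, contig="nope")], {"c": "A" * 100})

    def test_minus_strand_sequence_is_sense_oriented(self, small_template):
        t = small_template
        rng = np.random.default_rng(4)
        left, right = sg.random_dna(5000, rng), sg.random_dna(5000, rng)
        contig = left + revcomp(t.sequence) + right
        query = hs.ProteinQuery("q", t.dde_query)
        hits = hs.search(query, {"c": contig})
        loci = hs.extract_candidates(hits, {"c": contig}, 1000)
        assert len(loci) == 1 and loci[0].strand == "-"
        # the oriented locus sequence contains the sense-strand element
        assert t.sequence in loci[0].sequence


class TestRecallOnPlantedGenome:
    def test_low_divergence_recall(self, tiny_sim):
        queries = [
            hs.ProteinQuery(qid, seq) for qid, seq in tiny_sim.queries().items()
        ]
        hits = hs.search_all(queries, tiny_sim.contigs)
        loci = hs.extract_candidates(hits, tiny_sim.contigs)
        truth = tiny_sim.truth[tiny_sim.truth.is_intact]
        recovered = 0
        for row in truth.itertuples():
            recovered += any(
                L.contig == row.contig
                and min(L.core_end, row.end) - max(L.core_start, row.start) > 0
                for L in loci
            )
        assert recovered >= 0.95 * len(truth)
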
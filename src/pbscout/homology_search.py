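"""Translated protein-vs-genome search with mining retention filters.

An in-repo stand-in for a local tBLASTN run: the genome is translated in
all six frames, exact amino-acid word matches between the query and each
frame seed ungapped X-drop extensions, and surviving regions are re-scored
by affine-gap local alignment (BLOSUM62, gap open 11 / extend 1).  Hits
are retained only when identity and query coverage strictly exceed the
mining thresholds (defaults >80% identity, >30% coverage), then extracted
with +/-4 kb flanks as candidate loci.

Identity is matches / aligned columns (gaps count as columns); coverage is
aligned query residues / query length — the BLAST conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from ._align import protein_local_aligner, revcomp

logger = logging.getLogger(__name__)


@dataclass
class ProteinQuery:
    query_id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if len(self.residues) < 50:
            raise ValueError(
                f"query {self.query_id}: length {len(self.residues)} < 50 aa"
            )
        allowed = set("ACDEFGHIKLMNPQRSTVWYX")
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(f"query {self.query_id}: non-standard residues {bad}")


@dataclass
class SearchParams:
    word_size: int = 4
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    identity_min: float = 0.8   # strict >
    coverage_min: float = 0.3   # strict >
    xdrop: float = 20.0
    min_ungapped_score: float = 40.0
    merge_distance: int = 2000
    flank_bp: int = 4000


@dataclass
class TranslatedHit:
    contig: str
    frame: int                  # +1..+3 forward, -1..-3 reverse
    genome_start: int           # forward-strand, 0-based half-open
    genome_end: int
    query_start: int            # aa, 0-based half-open
    query_end: int
    identity: float
    coverage: float
    score: float
    query_id: str = ""

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


@dataclass
class CandidateLocus:
    locus_id: str
    contig: str
    core_start: int
    core_end: int
    flank_start: int
    flank_end: int
    strand: str
    sequence: str = field(repr=False, default="")
    core_sequence: str = field(repr=False, default="")

    @property
    def core_in_locus(self) -> tuple[int, int]:
        """Core hit interval in locus-relative (oriented) coordinates."""
        if self.strand == "+":
            return (self.core_start - self.flank_start,
                    self.core_end - self.flank_start)
        return (self.flank_end - self.core_end,
                self.flank_end - self.core_start)


def six_frame_translate(contig: str) -> list[tuple[int, str]]:
    """Translate a contig in all six frames.

    Returns (frame, protein) pairs for frames +1..+3 (forward offsets
    0..2) and -1..-3 (reverse complement offsets 0..2).  Stops are '*',
    ambiguous codons 'X'.  Contigs shorter than one codon yield empty
    frame strings.
    """
    contig = contig.upper()
    out: list[tuple[int, str]] = []
    rc = revcomp(contig)
    for sign, seq in ((1, contig), (-1, rc)):
        for offset in range(3):
            n_codons = (len(seq) - offset) // 3
            if n_codons <= 0:
                out.append((sign * (offset + 1), ""))
                continue
            trimmed = seq[offset:offset + 3 * n_codons]
            out.append((sign * (offset + 1), str(Seq(trimmed).translate())))
    return out


def _frame_to_genome(frame: int, aa_start: int, aa_end: int, contig_len: int) -> tuple[int, int]:
    offset = abs(frame) - 1
    nt_a = offset + 3 * aa_start
    nt_b = offset + 3 * aa_end
    if frame > 0:
        return nt_a, nt_b
    return contig_len - nt_b, contig_len - nt_a


def _blosum_scorer(matrix_name: str):
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(matrix_name)
    alpha = mat.alphabet
    idx = {aa: i for i, aa in enumerate(alpha)}

    def score(a: str, b: str) -> float:
        ia, ib = idx.get(a), idx.get(b)
        if ia is None or ib is None:
            return -4.0
        return float(mat[ia, ib])

    return score


def _ungapped_extend(query: str, frame_seq: str, qpos: int, fpos: int,
                     word: int, scorer, xdrop: float) -> tuple[int, int, float]:
    """X-drop ungapped extension of a word seed; returns (qa, qb, score)."""
    score = sum(scorer(query[qpos + i], frame_seq[fpos + i]) for i in range(word))
    # right extension
    best = score
    cur = score
    qb = qpos + word
    best_qb = qb
    while qb < len(query) and fpos + (qb - qpos) < len(frame_seq):
        cur += scorer(query[qb], frame_seq[fpos + (qb - qpos)])
        qb += 1
        if cur > best:
            best, best_qb = cur, qb
        elif best - cur > xdrop:
            break
    # left extension
    cur = best
    total_best = best
    qa = qpos
    best_qa = qa
    while qa > 0 and fpos - (qpos - qa) > 0:
        qa -= 1
        cur += scorer(query[qa], frame_seq[fpos - (qpos - qa)])
        if cur > total_best:
            total_best, best_qa = cur, qa
        elif total_best - cur > xdrop:
            break
    return best_qa, best_qb, total_best


def search(
    query: ProteinQuery,
    genome: Mapping[str, str],
    params: SearchParams | None = None,
) -> list[TranslatedHit]:
    """Seed-and-extend translated search of one protein query.

    Exact ``word_size`` seeds between query and each frame are extended
    ungapped (X-drop), surviving regions are re-aligned with affine-gap
    local DP, overlapping hits in the same frame are merged keeping the
    best score, and only hits with identity > identity_min AND coverage >
    coverage_min are returned, sorted by (contig, genome_start).
    """
    params = params or SearchParams()
    q = query.residues
    if len(q) < params.word_size:
        raise ValueError(
            f"query {query.query_id} shorter than seed word ({params.word_size} aa)"
        )
    scorer = _blosum_scorer(params.matrix)
    aligner = protein_local_aligner(params.matrix)

    qindex: dict[str, list[int]] = {}
    for i in range(len(q) - params.word_size + 1):
        qindex.setdefault(q[i:i + params.word_size], []).append(i)

    hits: list[TranslatedHit] = []
    for contig_name, contig_seq in genome.items():
        contig_len = len(contig_seq)
        for frame, frame_seq in six_frame_translate(contig_seq):
            if len(frame_seq) < params.word_size:
                continue
            regions: list[tuple[int, int]] = []  # frame-aa intervals
            covered_until: dict[int, int] = {}   # per-diagonal extension memo
            for fpos in range(len(frame_seq) - params.word_size + 1):
                word = frame_seq[fpos:fpos + params.word_size]
                qposs = qindex.get(word)
                if not qposs:
                    continue
                for qpos in qposs:
                    diag = fpos - qpos
                    if covered_until.get(diag, -1) >= fpos:
                        continue
                    qa, qb, score = _ungapped_extend(
                        q, frame_seq, qpos, fpos, params.word_size,
                        scorer, params.xdrop,
                    )
                    fa = fpos - (qpos - qa)
                    fb = fpos + (qb - qpos)
                    covered_until[diag] = fb
                    if score >= params.min_ungapped_score:
                        regions.append((fa, fb))
            for fa, fb in _merge_intervals(regions, gap=len(q)):
                pad = len(q)
                wa, wb = max(0, fa - pad), min(len(frame_seq), fb + pad)
                window = frame_seq[wa:wb]
                alignment = aligner.align(q, window)
                if len(alignment) == 0:
                    continue
                aln = alignment[0]
                (qs, qe), (ws, we) = (
                    (aln.aligned[0][0][0], aln.aligned[0][-1][1]),
                    (aln.aligned[1][0][0], aln.aligned[1][-1][1]),
                )
                matches = 0
                for (ta, tb), (va, _) in zip(aln.aligned[0], aln.aligned[1]):
                    matches += sum(
                        q[ta + i] == window[va + i] for i in range(tb - ta)
                    )
                columns = _local_columns(aln)
                identity = matches / columns if columns else 0.0
                coverage = (qe - qs) / len(q)
                g_start, g_end = _frame_to_genome(frame, wa + ws, wa + we, contig_len)
                hits.append(
                    TranslatedHit(
                        contig=contig_name,
                        frame=frame,
                        genome_start=g_start,
                        genome_end=g_end,
                        query_start=qs,
                        query_end=qe,
                        identity=identity,
                        coverage=coverage,
                        score=float(aln.score),
                        query_id=query.query_id,
                    )
                )

    hits = _merge_same_frame(hits)
    kept = [h for h in hits if passes_filters(h, params)]
    kept.sort(key=lambda h: (h.contig, h.genome_start, h.genome_end, h.frame))
    logger.info(
        "query %s: %d hits, %d retained (identity > %.2f, coverage > %.2f)",
        query.query_id, len(hits), len(kept),
        params.identity_min, params.coverage_min,
    )
    return kept


def passes_filters(hit: TranslatedHit, params: SearchParams) -> bool:
    """Mining retention rule: identity AND coverage strictly above threshold."""
    return hit.identity > params.identity_min and hit.coverage > params.coverage_min


def _local_columns(aln) -> int:
    """Alignment columns of a local alignment (aligned region incl. gaps)."""
    qa = aln.aligned[0]
    wa = aln.aligned[1]
    q_span = qa[-1][1] - qa[0][0]
    w_span = wa[-1][1] - wa[0][0]
    q_aligned = sum(b - a for a, b in qa)
    # columns = aligned pairs + gaps on either side within the region
    return q_span + w_span - q_aligned


def _merge_intervals(intervals: Sequence[tuple[int, int]], gap: int = 0) -> list[tuple[int, int]]:
    if not intervals:
        return []
    merged = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1] + gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _merge_same_frame(hits: list[TranslatedHit]) -> list[TranslatedHit]:
    """Collapse overlapping hits in the same contig+frame, keeping best score."""
    hits = sorted(
        hits, key=lambda h: (h.contig, h.frame, h.genome_start, -h.score)
    )
    out: list[TranslatedHit] = []
    for h in hits:
        if (
            out
            and out[-1].contig == h.contig
            and out[-1].frame == h.frame
            and h.genome_start < out[-1].genome_end
        ):
            if h.score > out[-1].score:
                out[-1] = h
            continue
        out.append(h)
    return out


def search_all(
    queries: Iterable[ProteinQuery],
    genome: Mapping[str, str],
    params: SearchParams | None = None,
) -> list[TranslatedHit]:
    """Pool hits over several queries (one per family in synthetic runs)."""
    pooled: list[TranslatedHit] = []
    for query in queries:
        pooled.extend(search(query, genome, params))
    pooled.sort(key=lambda h: (h.contig, h.genome_start, h.genome_end, h.frame))
    return pooled


def extract_candidates(
    hits: Sequence[TranslatedHit],
    genome: Mapping[str, str],
    flank_bp: int = 4000,
    merge_distance: int = 2000,
) -> list[CandidateLocus]:
    """Collapse nearby same-strand hits and cut flanked candidate loci.

    Hits within ``merge_distance`` on the same contig and strand (any
    frame — decayed copies yield frameshifted split hits) become one
    locus.  Minus-strand locus sequences are reverse-complemented so
    downstream steps see the transposase sense strand; stored coordinates
    stay forward-strand.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    for h in hits:
        if h.contig not in genome:
            raise KeyError(f"hit references unknown contig {h.contig!r}")
    groups: dict[tuple[str, str], list[TranslatedHit]] = {}
    for h in hits:
        groups.setdefault((h.contig, h.strand), []).append(h)

    loci: list[CandidateLocus] = []
    for (contig_name, strand), members in sorted(groups.items()):
        members.sort(key=lambda h: h.genome_start)
        contig_seq = genome[contig_name]
        clusters: list[list[TranslatedHit]] = []
        for h in members:
            if clusters and h.genome_start - clusters[-1][-1].genome_end <= merge_distance:
                clusters[-1].append(h)
            else:
                clusters.append([h])
        for cluster in clusters:
            core_start = min(h.genome_start for h in cluster)
            core_end = max(h.genome_end for h in cluster)
            flank_start = max(0, core_start - flank_bp)
            flank_end = min(len(contig_seq), core_end + flank_bp)
            seq = contig_seq[flank_start:flank_end]
            core_seq = contig_seq[core_start:core_end]
            if strand == "-":
                seq = revcomp(seq)
                core_seq = revcomp(core_seq)
            loci.append(
                CandidateLocus(
                    locus_id=f"{contig_name}:{core_start}-{core_end}({strand})",
                    contig=contig_name,
                    core_start=core_start,
                    core_end=core_end,
                    flank_start=flank_start,
                    flank_end=flank_end,
                    strand=strand,
                    sequence=seq,
                    core_sequence=core_seq,
                )
            )
    loci.sort(key=lambda L: (L.contig, L.core_start, L.strand))
    return loci
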
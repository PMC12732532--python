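"""Greedy centroid clustering of candidate loci into element families.

Mirrors the UCLUST/USEARCH ``cluster_fast`` strategy: sequences are
processed in decreasing length order; each joins the first existing
centroid it matches at or above the identity threshold (default 0.5,
testing both orientations and flipping the member when the reverse
orientation wins), otherwise it founds a new cluster.

Identity is matches / alignment columns of a global affine-gap alignment
after stripping terminal-gap columns.  A shared-k-mer prefilter (k=8,
minimum Jaccard 0.05 in the better orientation) skips hopeless centroid
comparisons without changing results at the margins the pipeline operates
at (same-family copies share most 8-mers; unrelated core spans share
almost none).

Consensus building star-aligns members to the centroid: per centroid
column the most frequent residue wins (ties broken A<C<G<T), columns
gapped in more than half the members are dropped, and member insertions
relative to the centroid are ignored (the default simulator introduces no
indels; see the methods note).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._align import align_dna_global, revcomp

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")


@dataclass
class Cluster:
    cluster_id: str
    centroid_id: str
    member_ids: list[str] = field(default_factory=list)
    member_identities: list[float] = field(default_factory=list)
    orientations: list[str] = field(default_factory=list)  # '+' or '-'


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity of two DNA strings in [0, 1].

    matches / alignment columns after stripping terminal-gap columns;
    orientation is taken as given (callers handle reverse complements).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    for name, s in (("a", a), ("b", b)):
        bad = set(s.upper()) - _VALID
        if bad:
            raise ValueError(f"sequence {name} contains non-ACGTN characters: {bad}")
    return align_dna_global(a, b).identity


def _kmer_set(seq: str, k: int = 8) -> frozenset[str]:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def greedy_cluster(
    sequences: Mapping[str, str],
    threshold: float = 0.5,
    *,
    prefilter_k: int = 8,
    prefilter_jaccard: float = 0.05,
) -> list[Cluster]:
    """Greedy star clustering of id -> DNA sequence at an identity threshold.

    Deterministic: processing order is decreasing length, ties by id.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    order = sorted(sequences, key=lambda i: (-len(sequences[i]), i))
    clusters: list[Cluster] = []
    centroid_seqs: list[str] = []
    centroid_kmers: list[frozenset] = []

    for seq_id in order:
        seq = sequences[seq_id].upper()
        km_f = _kmer_set(seq, prefilter_k)
        km_r = _kmer_set(revcomp(seq), prefilter_k)
        placed = False
        for ci, cluster in enumerate(clusters):
            jf = _jaccard(km_f, centroid_kmers[ci])
            jr = _jaccard(km_r, centroid_kmers[ci])
            if max(jf, jr) < prefilter_jaccard:
                continue
            ident_f = align_dna_global(seq, centroid_seqs[ci]).identity if jf >= prefilter_jaccard else -1.0
            ident_r = align_dna_global(revcomp(seq), centroid_seqs[ci]).identity if jr >= prefilter_jaccard else -1.0
            ident, orientation = max((ident_f, "+"), (ident_r, "-"))
            if ident >= threshold:
                cluster.member_ids.append(seq_id)
                cluster.member_identities.append(ident)
                cluster.orientations.append(orientation)
                placed = True
                break
        if not placed:
            cid = f"cluster_{len(clusters) + 1}"
            clusters.append(
                Cluster(
                    cluster_id=cid,
                    centroid_id=seq_id,
                    member_ids=[seq_id],
                    member_identities=[1.0],
                    orientations=["+"],
                )
            )
            centroid_seqs.append(seq)
            centroid_kmers.append(km_f)
    logger.info("clustered %d sequences into %d clusters", len(order), len(clusters))
    return clusters


def cluster_loci(
    loci: Sequence,
    threshold: float = 0.5,
    *,
    sequence: str = "core",
    **kwargs,
) -> tuple[list[Cluster], dict[str, str]]:
    """Cluster candidate loci on core hit spans (default) or full loci.

    Core spans carry the homologous transposase region and give clean
    identity separation; full flanked loci dilute identity with unrelated
    flanking background (see methods note).  Returns (clusters, the
    sequence mapping used).
    """
    if sequence not in ("core", "locus"):
        raise ValueError("sequence must be 'core' or 'locus'")
    seqs = {
        L.locus_id: (L.core_sequence if sequence == "core" else L.sequence)
        for L in loci
    }
    return greedy_cluster(seqs, threshold, **kwargs), seqs


def oriented_member_sequences(
    cluster: Cluster, sequences: Mapping[str, str]
) -> dict[str, str]:
    """Member sequences flipped into centroid orientation."""
    out = {}
    for member_id, orientation in zip(cluster.member_ids, cluster.orientations):
        seq = sequences[member_id].upper()
        out[member_id] = seq if orientation == "+" else revcomp(seq)
    return out


def build_consensus(cluster: Cluster, sequences: Mapping[str, str]) -> str:
    """Majority-rule consensus over a star alignment to the centroid.

    Per centroid column the most frequent residue wins (ties A<C<G<T);
    columns gapped in more than 50% of members are dropped.
    """
    members = oriented_member_sequences(cluster, sequences)
    centroid = members[cluster.centroid_id]
    if len(members) == 1:
        return centroid
    n_cols = len(centroid)
    counts = [dict.fromkeys("ACGT-", 0) for _ in range(n_cols)]
    for member_id, seq in members.items():
        if member_id == cluster.centroid_id:
            column_residues = centroid
            for col, res in enumerate(column_residues):
                counts[col][res if res in "ACGT" else "-"] += 1
            continue
        pair = align_dna_global(centroid, seq, strip_terminal=False)
        col = -1
        for c_res, m_res in zip(pair.row_a, pair.row_b):
            if c_res == "-":
                continue  # member insertion: no centroid column
            col += 1
            counts[col][m_res if m_res in "ACGT" else "-"] += 1
    n_members = len(members)
    out = []
    for col in range(n_cols):
        if counts[col]["-"] > 0.5 * n_members:
            continue
        best = max("ACGT", key=lambda b: (counts[col][b], -"ACGT".index(b)))
        out.append(best)
    return "".join(out)
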
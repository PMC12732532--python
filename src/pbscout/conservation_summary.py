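"""TIR sequence-logo matrices, domain identity heat-map data, NJ trees.

Covers the conservation analyses around an element census: per-position
information content of the first L (default 24) TIR bases, mean pairwise
identity of transposase domains (NTD, DDBD1, DDD, DDBD2, CRD) within and
between clades, a neighbor-joining tree as a distance-based approximation
for external ML phylogenetics, and FASTA / relaxed-PHYLIP export so the
heavy lifting (MAFFT, IQ-TREE) can happen outside.

Information content per position is R = 2 - H where H is the Shannon
entropy (bits) of the base frequencies; no small-sample correction or
pseudocount is applied by default.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._align import align_protein_global

BASES = "ACGT"


@dataclass
class LogoMatrix:
    freq: pd.DataFrame         # positions x bases, rows sum to 1
    information: np.ndarray    # bits per position, in [0, 2]
    n_sequences: int
    n_used: np.ndarray         # sequences contributing per position


def tir_logo(
    tirs: Sequence[str],
    L: int = 24,
    *,
    pad: str = "skip",
    pseudocount: float = 0.0,
) -> LogoMatrix:
    """Per-position base frequencies and information content of TIRs.

    Positions count from the element-outer end; TIRs shorter than ``L``
    contribute only to the positions they cover when ``pad='skip'`` (the
    default).  Requires at least two sequences.
    """
    tirs = [t.upper() for t in tirs if t]
    if len(tirs) < 2:
        raise ValueError("tir_logo requires at least 2 sequences")
    if pad not in ("skip",):
        raise ValueError("only pad='skip' is supported")
    counts = np.zeros((L, 4))
    for t in tirs:
        for pos in range(min(L, len(t))):
            b = BASES.find(t[pos])
            if b >= 0:
                counts[pos, b] += 1
    counts += pseudocount
    n_used = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / n_used[:, None]
    info = np.zeros(L)
    for pos in range(L):
        if n_used[pos] == 0:
            continue
        p = freq[pos]
        h = -sum(x * math.log2(x) for x in p if x > 0)
        info[pos] = 2.0 - h
    freq_df = pd.DataFrame(
        np.nan_to_num(freq), columns=list(BASES),
        index=pd.RangeIndex(1, L + 1, name="position"),
    )
    return LogoMatrix(freq=freq_df, information=info,
                      n_sequences=len(tirs), n_used=n_used)


DOMAINS = ("NTD", "DDBD1", "DDD", "DDBD2", "CRD")


def read_domain_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"protein_id", "domain", "start", "end"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"domain table missing columns {missing}")
    return table


def domain_identity_matrix(
    proteins: Mapping[str, str],
    annotations: pd.DataFrame,
    clades: Mapping[str, str],
    domain: str,
) -> pd.DataFrame:
    """Mean pairwise percent identity of one domain, per clade pair.

    For each ordered clade pair the mean is over all cross pairs (within a
    clade: all unordered pairs of distinct members).  Cells for clades
    with fewer than two members on the diagonal are NaN.  The matrix is
    symmetric with clade labels sorted.
    """
    sub = annotations[annotations["domain"] == domain]
    coords = {r.protein_id: (int(r.start), int(r.end)) for r in sub.itertuples()}
    members: dict[str, list[str]] = {}
    for pid, clade in clades.items():
        if pid not in coords:
            raise KeyError(f"protein {pid} lacks a {domain} annotation")
        members.setdefault(clade, []).append(pid)
    for v in members.values():
        v.sort()
    labels = sorted(members)
    mat = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    cache: dict[tuple[str, str], float] = {}

    def seg(pid: str) -> str:
        a, b = coords[pid]
        return proteins[pid][a:b]

    def pair_identity(p1: str, p2: str) -> float:
        key = (p1, p2) if p1 <= p2 else (p2, p1)
        if key not in cache:
            cache[key] = align_protein_global(seg(p1), seg(p2)).identity
        return cache[key]

    for i, ca in enumerate(labels):
        for cb in labels[i:]:
            if ca == cb:
                group = members[ca]
                if len(group) < 2:
                    continue
                vals = [
                    pair_identity(group[x], group[y])
                    for x in range(len(group))
                    for y in range(x + 1, len(group))
                ]
            else:
                vals = [
                    pair_identity(p1, p2)
                    for p1 in members[ca] for p2 in members[cb]
                ]
            mean_pct = 100.0 * float(np.mean(vals))
            mat.loc[ca, cb] = mean_pct
            mat.loc[cb, ca] = mean_pct
    return mat


def nj_tree(
    distance_matrix: np.ndarray | Sequence[Sequence[float]],
    labels: Sequence[str],
) -> str:
    """Neighbor joining; returns a Newick string.

    Deterministic: at each agglomeration the minimal-Q pair with the
    lexicographically smallest (sorted) label pair is joined.  Negative
    branch lengths are clamped to zero.  Exact on additive matrices.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.all(np.isfinite(D)):
        raise ValueError("distances must be finite")
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    nodes = [str(lab) for lab in labels]           # newick fragments
    tie_keys = [str(lab) for lab in labels]        # smallest leaf label under node
    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((tie_keys[i], tie_keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_index = D.shape[0]
        new_row = np.zeros((1, D.shape[1]))
        D = np.vstack([D, new_row])
        D = np.hstack([D, np.zeros((D.shape[0], 1))])
        for k in active:
            if k in (i, j):
                continue
            D[new_index, k] = D[k, new_index] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(f"({nodes[i]}:{li:.6f},{nodes[j]}:{lj:.6f})")
        tie_keys.append(min(tie_keys[i], tie_keys[j]))
        active = [k for k in active if k not in (i, j)] + [new_index]

    i, j, k = active
    # final three-way join onto an internal node
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
    order = sorted(range(3), key=lambda idx: tie_keys[[i, j, k][idx]])
    parts = [
        f"{nodes[[i, j, k][idx]]}:{[li, lj, lk][idx]:.6f}" for idx in order
    ]
    return "(" + ",".join(parts) + ");"


def random_additive_tree(
    n_taxa: int, rng: np.random.Generator
) -> tuple[str, np.ndarray, list[str]]:
    """A random unrooted binary tree with positive branch lengths.

    Returns (newick, additive distance matrix, labels): the NJ validation
    oracle — NJ must reconstruct the generating topology exactly from the
    path-length distances.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    labels = [f"t{i + 1}" for i in range(n_taxa)]

    def blen() -> float:
        return float(rng.uniform(0.1, 1.0))

    adj: dict[int, dict[int, float]] = {}

    def add_edge(u: int, v: int, w: float) -> None:
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def del_edge(u: int, v: int) -> None:
        del adj[u][v]
        del adj[v][u]

    # leaves are 0..n-1; internal nodes from n upward
    next_node = n_taxa
    center = next_node
    next_node += 1
    for leaf in range(3):
        add_edge(center, leaf, blen())
    for leaf in range(3, n_taxa):
        edges = sorted(
            (u, v) for u in adj for v in adj[u] if u < v
        )
        u, v = edges[int(rng.integers(0, len(edges)))]
        w = adj[u][v]
        s = float(rng.uniform(0.2, 0.8))
        mid = next_node
        next_node += 1
        del_edge(u, v)
        add_edge(u, mid, w * s)
        add_edge(mid, v, w * (1 - s))
        add_edge(mid, leaf, blen())

    # all-pairs leaf distances by DFS from each leaf
    D = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        stack = [(src, -1, 0.0)]
        while stack:
            node, parent, dist = stack.pop()
            if node < n_taxa and node != src:
                D[src, node] = dist
            for nb, w in adj[node].items():
                if nb != parent:
                    stack.append((nb, node, dist + w))

    def newick(node: int, parent: int) -> str:
        children = [nb for nb in sorted(adj[node]) if nb != parent]
        if node < n_taxa:
            return labels[node]
        inner = ",".join(
            f"{newick(c, node)}:{adj[node][c]:.6f}" for c in children
        )
        return f"({inner})"

    return newick(center, -1) + ";", D, labels


def export_alignment(records: Mapping[str, str], path, fmt: str = "fasta") -> None:
    """Write sequences as FASTA or relaxed PHYLIP.

    Relaxed PHYLIP preserves identifiers longer than 10 characters.
    Duplicate identifiers raise.  Round-trips through
    :func:`read_alignment`.
    """
    ids = list(records)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate identifiers")
    if not ids:
        raise ValueError("nothing to export")
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    if fmt == "fasta":
        SeqIO.write(seqrecords, str(path), "fasta")
    elif fmt == "phylip":
        lengths = {len(s) for s in records.values()}
        if len(lengths) != 1:
            raise ValueError("relaxed PHYLIP requires equal-length sequences")
        AlignIO.write(
            MultipleSeqAlignment(seqrecords), str(path), "phylip-relaxed"
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_alignment(path, fmt: str = "fasta") -> dict[str, str]:
    biopython_fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}[fmt]
    if fmt == "fasta":
        return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    aln = AlignIO.read(str(path), biopython_fmt)
    return {r.id: str(r.seq) for r in aln}
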
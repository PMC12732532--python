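"""Element boundary detection: TIR pairs, TSDs, transposase ORFs, intactness.

Automates the manual curation step of transposon mining: given a candidate
locus (a translated-homology hit plus flanks), locate the terminal
inverted repeat (TIR) pair, read the 4-bp target-site duplications (TSDs)
immediately outside it, find the longest transposase ORF inside the
element, and classify the copy.

Intactness follows the strict census definition: a copy is intact iff it
has a scoring TIR pair AND a duplicated target site (both flanking 4-mers
equal) AND an uninterrupted ORF strictly exceeding ``min_orf_aa`` (default
500) amino acids.  Copies with a TIR pair that fail intactness are still
counted as elements, mirroring the PB vs intact-PB distinction.

TIR detection works through two channels that share one scoring rule
(score = matches - mismatches, plus a fixed bonus per flank that reads
TTAA immediately outside; extension halts after two consecutive
mismatches):

* TSD-anchored: every TTAA in the left search window is paired with every
  TTAA in the right window that brackets the homology core, and the
  terminal sequences just inside the anchors are compared against each
  other's reverse complement.
* Seed-based: exact reverse-complement k-mer matches between the windows
  are extended in both directions, catching elements whose TSD decayed.

The default acceptance threshold (28) reflects a false-call analysis on
both element-free loci and decayed-element loci: ~3 kb search windows
contain ~12 TTAA each, i.e. ~144 anchor pairs per locus, and requiring a
net score (matches - mismatches) of 12 inside canonical TSDs pushes
chance anchored inverted repeats below ~1e-5 per locus.  One step looser
(net 11) admits roughly one spurious element per few dozen loci — enough
to misclassify a truncated copy whose genuine right TIR pairs with a
chance 11-mer, so the stricter default is kept.  The sensitivity floor
with canonical TSDs is a 12 bp exact TIR (or 14 bp with one mismatch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

from ._align import revcomp

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class TIRParams:
    min_length: int = 6
    max_length: int = 50
    min_identity: float = 0.8
    window: int = 3000          # search span outside each core edge
    tsd_bonus: float = 8.0      # per flank reading TTAA immediately outside
    min_score: float = 28.0     # acceptance threshold on bonused score
    max_consecutive_mismatches: int = 2
    seed_k: int = 6
    tsd: str = "TTAA"


@dataclass
class TIRPair:
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    length: int
    identity: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.left_end > self.right_start:
            raise ValueError("left TIR must precede right TIR")


@dataclass
class PBElement:
    element_id: str
    locus_id: str
    start: int               # element span incl. TIRs, locus-relative
    end: int
    tir: Optional[TIRPair]
    tsd_left: Optional[str]
    tsd_right: Optional[str]
    tsd_canonical: bool
    orf_start: int
    orf_end: int
    orf_length_aa: int
    is_intact: bool
    family_id: str = ""
    protein: str = field(default="", repr=False)

    @property
    def length(self) -> int:
        return self.end - self.start


def _extend_anchored(
    seq: str, i: int, j: int, params: TIRParams
) -> tuple[int, int, int]:
    """Extend a TIR comparison anchored at element boundaries [i, j).

    Compares seq[i+k] with complement(seq[j-1-k]) for growing k, halting
    at the length cap, the midpoint, or two consecutive mismatches.
    Returns (best_length, matches_at_best, mismatches_at_best) maximising
    net score = matches - mismatches subject to the identity floor.
    """
    max_k = min(params.max_length, (j - i) // 2)
    best = (0, 0, 0)
    best_net = -1
    matches = mismatches = consec = 0
    for k in range(max_k):
        a = seq[i + k]
        b = seq[j - 1 - k]
        if a in COMPLEMENT and COMPLEMENT.get(b) == a:
            matches += 1
            consec = 0
        else:
            mismatches += 1
            consec += 1
            if consec >= params.max_consecutive_mismatches:
                break
        length = k + 1
        if length < params.min_length:
            continue
        identity = matches / length
        if identity < params.min_identity:
            continue
        net = matches - mismatches
        if net > best_net or (net == best_net and length > best[0]):
            best_net = net
            best = (length, matches, mismatches)
    return best


def _candidate_score(
    seq: str, i: int, j: int, length: int, matches: int, mismatches: int,
    params: TIRParams,
) -> float:
    score = float(matches - mismatches)
    t = len(params.tsd)
    if i >= t and seq[i - t:i] == params.tsd:
        score += params.tsd_bonus
    if j + t <= len(seq) and seq[j:j + t] == params.tsd:
        score += params.tsd_bonus
    return score


def find_tir_pair(
    locus: str, core: tuple[int, int], params: TIRParams | None = None
) -> Optional[TIRPair]:
    """Best-scoring TIR pair bracketing the homology core, or None.

    Candidate element boundaries (i, j) must satisfy i <= core_start and
    j >= core_end (the element contains the hit that defined the locus).
    Ties are broken by longer TIR, then leftmost left_start.
    """
    params = params or TIRParams()
    locus = locus.upper()
    n = len(locus)
    if n < 2 * params.min_length:
        return None
    core_start, core_end = core
    left_lo = max(0, core_start - params.window)
    right_hi = min(n, core_end + params.window)

    candidates: dict[tuple[int, int], tuple[int, int, int]] = {}

    # channel 1: TSD-anchored boundaries
    tsd, t = params.tsd, len(params.tsd)
    left_anchors = [
        p + t for p in _find_all(locus, tsd, left_lo, core_start)
        if p + t <= core_start
    ]
    right_anchors = [
        p for p in _find_all(locus, tsd, core_end, right_hi) if p >= core_end
    ]
    for i in left_anchors:
        for j in right_anchors:
            if j - i < 2 * params.min_length:
                continue
            length, matches, mismatches = _extend_anchored(locus, i, j, params)
            if length >= params.min_length:
                candidates[(i, j)] = (length, matches, mismatches)

    # channel 2: exact reverse-complement seed matches between the windows.
    # A seed left_win[p:p+k] == rc(right_win segment ending at right_hi - q)
    # fixes the pairing diagonal: left index x pairs with
    # y = p + (right_hi - q) - 1 - x.  The seed is extended outward (toward
    # the element boundary) while bases keep rc-pairing, which places the
    # candidate boundary (i, j); inward scoring then reuses the anchored
    # extension.
    left_win = locus[left_lo:core_start]
    right_win = locus[core_end:right_hi]
    k = params.seed_k
    if len(left_win) >= k and len(right_win) >= k:
        index: dict[str, list[int]] = {}
        for p in range(len(left_win) - k + 1):
            index.setdefault(left_win[p:p + k], []).append(p + left_lo)
        rc_right = revcomp(right_win)
        for q in range(len(rc_right) - k + 1):
            kmer = rc_right[q:q + k]
            if kmer not in index:
                continue
            for p in index[kmer]:
                diag = p + (right_hi - q) - 1
                x = p
                while (
                    x > 0
                    and diag - (x - 1) < n
                    and p - (x - 1) <= params.max_length
                    and locus[x - 1] in COMPLEMENT
                    and COMPLEMENT[locus[x - 1]] == locus[diag - (x - 1)]
                ):
                    x -= 1
                i0 = x
                j0 = diag - i0 + 1
                if i0 > core_start or j0 < core_end or (i0, j0) in candidates:
                    continue
                length, matches, mismatches = _extend_anchored(locus, i0, j0, params)
                if length >= params.min_length:
                    candidates[(i0, j0)] = (length, matches, mismatches)

    best: Optional[TIRPair] = None
    best_key = None
    for (i, j), (length, matches, mismatches) in candidates.items():
        score = _candidate_score(locus, i, j, length, matches, mismatches, params)
        if score < params.min_score:
            continue
        identity = matches / length
        key = (score, length, -i)
        if best_key is None or key > best_key:
            best_key = key
            best = TIRPair(
                left_start=i,
                left_end=i + length,
                right_start=j - length,
                right_end=j,
                length=length,
                identity=identity,
                score=score,
            )
    return best


def _find_all(s: str, pat: str, lo: int, hi: int) -> list[int]:
    out = []
    p = s.find(pat, lo)
    while p != -1 and p < hi:
        out.append(p)
        p = s.find(pat, p + 1)
    return out


def check_tsd(
    locus: str, tir: TIRPair, tsd_length: int = 4
) -> tuple[Optional[str], Optional[str], bool]:
    """Read the 4-mers immediately outside the TIR pair.

    Canonical iff both read TTAA.  A TIR flush against the locus edge
    yields an unknown (None) TSD on that side and canonical=False.
    Non-matching duplications are reported, not discarded.
    """
    locus = locus.upper()
    left = (
        locus[tir.left_start - tsd_length:tir.left_start]
        if tir.left_start >= tsd_length else None
    )
    right = (
        locus[tir.right_end:tir.right_end + tsd_length]
        if tir.right_end + tsd_length <= len(locus) else None
    )
    canonical = left == "TTAA" and right == "TTAA"
    return left, right, canonical


def find_transposase_orf(element: str) -> tuple[int, int, int, str]:
    """Longest ATG-initiated, stop-terminated ORF across all six frames.

    Returns (orf_start, orf_end, orf_length_aa, protein); coordinates are
    forward-strand, half-open, and include the stop codon.  Length in aa
    excludes the stop.  Returns (0, 0, 0, "") when no ORF exists.
    """
    element = element.upper()
    n = len(element)
    if n < 6:
        return 0, 0, 0, ""
    best = (0, 0, 0, "")
    for strand, seq in (("+", element), ("-", revcomp(element))):
        for offset in range(3):
            trimmed = seq[offset:offset + 3 * ((n - offset) // 3)]
            if len(trimmed) < 6:
                continue
            protein = str(Seq(trimmed).translate())
            start_aa = None
            for idx, aa in enumerate(protein):
                if aa == "M" and start_aa is None:
                    start_aa = idx
                elif aa == "*" and start_aa is not None:
                    length = idx - start_aa
                    if length > best[2]:
                        s_nt = offset + 3 * start_aa
                        e_nt = offset + 3 * (idx + 1)
                        if strand == "-":
                            s_nt, e_nt = n - e_nt, n - s_nt
                        best = (s_nt, e_nt, length, protein[start_aa:idx])
                    start_aa = None
                elif aa == "*":
                    start_aa = None
    return best


def classify_element(
    locus,
    tir: Optional[TIRPair],
    tsd: tuple[Optional[str], Optional[str], bool],
    orf: tuple[int, int, int, str],
    *,
    min_orf_aa: int = 500,
    element_id: str = "",
    family_id: str = "",
) -> Optional[PBElement]:
    """Assemble a PBElement; None when no TIR pair was found.

    ``locus`` may be a CandidateLocus or a raw string (then locus_id is
    empty).  Intact requires a TIR pair, a duplicated target site
    (tsd_left == tsd_right, both readable) and an ORF strictly exceeding
    ``min_orf_aa`` amino acids.
    """
    if tir is None:
        return None
    locus_id = getattr(locus, "locus_id", "")
    tsd_left, tsd_right, canonical = tsd
    orf_start, orf_end, orf_aa, protein = orf
    has_tsd = tsd_left is not None and tsd_left == tsd_right
    is_intact = has_tsd and orf_aa > min_orf_aa
    return PBElement(
        element_id=element_id or f"{locus_id}:elem",
        locus_id=locus_id,
        start=tir.left_start,
        end=tir.right_end,
        tir=tir,
        tsd_left=tsd_left,
        tsd_right=tsd_right,
        tsd_canonical=canonical,
        orf_start=tir.left_start + orf_start,
        orf_end=tir.left_start + orf_end,
        orf_length_aa=orf_aa,
        is_intact=is_intact,
        family_id=family_id,
        protein=protein,
    )


def annotate_locus_sequence(
    locus: str,
    core: tuple[int, int],
    params: TIRParams | None = None,
    *,
    min_orf_aa: int = 500,
    element_id: str = "",
    family_id: str = "",
) -> Optional[PBElement]:
    """Full annotation of a raw locus string: TIR -> TSD -> ORF -> class."""
    tir = find_tir_pair(locus, core, params)
    if tir is None:
        return None
    tsd = check_tsd(locus, tir)
    element_seq = locus[tir.left_start:tir.right_end]
    orf = find_transposase_orf(element_seq)
    return classify_element(
        locus, tir, tsd, orf,
        min_orf_aa=min_orf_aa, element_id=element_id, family_id=family_id,
    )
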
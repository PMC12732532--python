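"""Synthetic genomes with planted piggyBac-like elements and ground truth.

The simulator emulates the structure of the real mining substrate at desk
scale: multi-contig DNA with planted cut-and-paste elements carrying
terminal inverted repeats (TIRs), TTAA target-site duplications (TSDs), a
single transposase ORF (500-725 aa), element lengths in the observed
2074-3465 bp band, several independent families, per-family mutational
ages (expected K2P divergence 0-0.25), and a configurable fraction of
decayed copies (premature stops, truncations, scrambled TIRs).

Every planted copy is recorded in a machine-readable truth table
(0-based, half-open coordinates) so that downstream search, clustering,
annotation and divergence estimates can be scored against known answers.

Two modelling choices matter for interpreting results (see the methods
note): substitutions are drawn site-wise from the closed-form K2P
transition matrix at the requested divergence, so the K2P *estimator*
applied to a mutated copy recovers the requested K including the
multiple-hit correction; and copies designated intact are mutated under
functional constraints (start codon, no premature stops, terminal stop and
TIR bases preserved), mirroring the fact that transposition-competent
copies are precisely those whose functional sites survived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._align import revcomp
from .divergence_landscape import kimura2p

logger = logging.getLogger(__name__)

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}
#: transition partner under A=0, C=1, G=2, T=3
_TS_PARTNER = np.array([2, 3, 0, 1])
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])

TRUTH_COLUMNS = [
    "element_id", "contig", "start", "end", "strand", "family_id",
    "is_intact", "realized_K", "tir_length", "tsd_present",
]

#: transposase domain layout as fractions of protein length (N- to C-terminal)
DOMAIN_FRACTIONS = {
    "NTD": (0.00, 0.20),
    "DDBD1": (0.20, 0.40),
    "DDD": (0.40, 0.65),
    "DDBD2": (0.65, 0.85),
    "CRD": (0.85, 1.00),
}
#: slice of the transposase used as the DDE-domain search query
QUERY_FRACTIONS = (0.20, 0.80)


class GeometryError(ValueError):
    """Element geometry infeasible (ORF + TIRs exceed element length)."""


def random_dna(n: int, rng: np.random.Generator, gc: float = 0.35) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def _random_sense_codons(n: int, rng: np.random.Generator) -> list[str]:
    sense = [a + b + c for a in BASES for b in BASES for c in BASES
             if a + b + c not in STOP_CODONS]
    return [sense[i] for i in rng.integers(0, len(sense), size=n)]


@dataclass
class ElementTemplate:
    """A family's master element: TIRs, one transposase ORF, spacers."""

    family_id: str
    tir_seq: str
    orf_protein_length: int
    element_length: int
    sequence: str = ""
    orf_start: int = 0  # coding start (ATG), element-relative
    orf_end: int = 0    # coding end incl. stop codon, half-open

    @property
    def tir_length(self) -> int:
        return len(self.tir_seq)

    @property
    def protein(self) -> str:
        cds = self.sequence[self.orf_start:self.orf_end - 3]
        return str(Seq(cds).translate())

    @property
    def dde_query(self) -> str:
        """The central transposase slice used as the homology-search query."""
        prot = self.protein
        a, b = QUERY_FRACTIONS
        return prot[int(a * len(prot)):int(b * len(prot))]

    def domain_table(self) -> pd.DataFrame:
        n = self.orf_protein_length
        rows = [
            (f"{self.family_id}_tpase", dom, int(a * n), int(b * n))
            for dom, (a, b) in DOMAIN_FRACTIONS.items()
        ]
        return pd.DataFrame(rows, columns=["protein_id", "domain", "start", "end"])


@dataclass
class PlantSpec:
    template: ElementTemplate
    n_copies: int
    expected_K: float = 0.0
    decay_fraction: float = 0.0
    tsd: str = "TTAA"

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if not 0.0 <= self.expected_K <= 0.75:
            raise ValueError("expected_K must be in [0, 0.75] (K2P identifiability)")
        if not 0.0 <= self.decay_fraction <= 1.0:
            raise ValueError("decay_fraction must be in [0, 1]")


# geometry overhead beyond TIRs + coding: 2x2 inner guard bases, one in-frame
# guard stop before the ATG, and minimal spacer padding
_OVERHEAD = 12


def make_template(
    family_id: str,
    rng_seed: int,
    length_range: tuple[int, int] = (2074, 3465),
    tir_length: int = 13,
    orf_length: int | None = None,
    *,
    gc: float = 0.35,
    tir_prefix: str = "CCCT",
) -> ElementTemplate:
    """Build a master element with exact, annotatable structure.

    Layout: [TIR][guard][spacer ... TAA][ATG ... stop][spacer][guard][rc TIR].
    The two guard bases just inside each TIR are chosen to break
    reverse-complement extension, so the TIR boundary is unambiguous; the
    in-frame TAA immediately before the ATG prevents upstream ORF extension.
    Deterministic for a given seed.
    """
    lo, hi = length_range
    if not (500 <= lo <= hi <= 10000):
        raise GeometryError(f"length_range {length_range} outside [500, 10000]")
    if not 6 <= tir_length <= 50:
        raise GeometryError(f"tir_length {tir_length} outside [6, 50]")
    rng = np.random.default_rng(rng_seed)
    element_length = int(rng.integers(lo, hi + 1))
    if orf_length is None:
        max_orf = (element_length - 2 * tir_length - _OVERHEAD - 3) // 3 - 1
        if max_orf < 500:
            raise GeometryError(
                f"element length {element_length} cannot host a >=500 aa ORF "
                f"with {tir_length} bp TIRs"
            )
        orf_length = int(rng.integers(500, min(725, max_orf) + 1))
    coding = 3 * orf_length + 3
    if coding + 2 * tir_length + _OVERHEAD > element_length:
        raise GeometryError(
            f"ORF ({orf_length} aa) + TIRs ({tir_length} bp) + overhead exceed "
            f"element length {element_length}"
        )
    tir = (tir_prefix + random_dna(tir_length, rng, gc))[:tir_length].upper()

    # split the slack between the two spacers
    slack = element_length - coding - 2 * tir_length - 4 - 3
    pad1 = int(rng.integers(0, slack + 1))
    pad2 = slack - pad1

    spacer1 = random_dna(pad1, rng, gc)
    spacer2 = random_dna(pad2, rng, gc)
    codons = ["ATG"] + _random_sense_codons(orf_length - 1, rng)
    stop = ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
    cds = "".join(codons) + stop

    # guard bases: break rc-symmetry immediately inside the TIRs
    left_guard = _guard_bases(rng)
    right_guard = _anti_complement(left_guard, rng)
    seq = tir + left_guard + spacer1 + "TAA" + cds + spacer2 + right_guard + revcomp(tir)
    assert len(seq) == element_length, (len(seq), element_length)
    orf_start = tir_length + 2 + pad1 + 3
    template = ElementTemplate(
        family_id=family_id,
        tir_seq=tir,
        orf_protein_length=orf_length,
        element_length=element_length,
        sequence=seq,
        orf_start=orf_start,
        orf_end=orf_start + coding,
    )
    # the guard stop must sit in frame directly upstream: sanity by construction
    assert template.sequence[orf_start:orf_start + 3] == "ATG"
    return template


def _guard_bases(rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=2))


def _anti_complement(left_guard: str, rng: np.random.Generator) -> str:
    """Two bases whose pairing with the left guard is a double mismatch.

    The TIR detector compares element[T+k] with the complement of
    element[L-T-1-k]; choosing right-guard bases that are not the
    complement of the corresponding left-guard base forces two consecutive
    mismatches, which halts extension.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out = []
    for k in (1, 0):  # right guard position L-T-2+j pairs with left guard [1-j]
        avoid = comp[left_guard[k]]
        choices = [b for b in BASES if b != avoid]
        out.append(choices[int(rng.integers(0, 3))])
    return "".join(out)


@dataclass
class OrfProtection:
    """Functional constraints preserved while mutating an intact copy."""

    orf_start: int
    orf_end: int  # incl. stop codon
    protected_intervals: tuple[tuple[int, int], ...] = ()


def k2p_site_probabilities(expected_K: float, ts_tv_ratio: float) -> tuple[float, float]:
    """Per-site (transition, per-target transversion) probabilities.

    Closed-form K2P transition matrix at divergence ``expected_K`` with
    instantaneous rate ratio kappa = alpha/beta = ``ts_tv_ratio``:
    with bt = K/(kappa+2) and at = kappa*bt,
    P(transition) = 1/4 + 1/4 e^{-4 bt} - 1/2 e^{-2(at+bt)} and
    P(each transversion) = 1/4 - 1/4 e^{-4 bt}.
    """
    if expected_K < 0:
        raise ValueError("expected_K must be >= 0")
    if ts_tv_ratio <= 0:
        raise ValueError("ts_tv_ratio must be > 0")
    bt = expected_K / (ts_tv_ratio + 2.0)
    at = ts_tv_ratio * bt
    p_ts = 0.25 + 0.25 * np.exp(-4.0 * bt) - 0.5 * np.exp(-2.0 * (at + bt))
    p_tv = 0.25 - 0.25 * np.exp(-4.0 * bt)
    return float(p_ts), float(p_tv)


def mutate_copy(
    master: str,
    expected_K: float,
    ts_tv_ratio: float = 2.0,
    rng_seed: int | np.random.Generator = 0,
    *,
    protect: OrfProtection | None = None,
) -> tuple[str, float]:
    """Mutate a master sequence under the K2P model; return (copy, realized K).

    Substitutions are drawn independently per site from the K2P transition
    matrix at the requested divergence, so multiple hits are implicit and
    the K2P estimate of the returned copy against the master is centred on
    ``expected_K``.  ``realized_K`` is that estimate (computed, not the
    requested value).  With ``protect`` set, substitutions that would
    destroy the start codon, introduce an in-frame premature stop, remove
    the terminal stop, or fall in a protected interval (TIRs) are reverted
    or redirected to a neutral base; the handful of affected sites bias the
    realized divergence negligibly.  No indels are introduced.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    if expected_K == 0.0:
        return master, 0.0
    arr = np.frombuffer(master.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for i, b in enumerate(BASES):
        codes[arr == ord(b)] = i
    valid = codes >= 0

    p_ts, p_tv = k2p_site_probabilities(expected_K, ts_tv_ratio)
    u = rng.random(len(codes))
    out = codes.copy()
    ts_mask = valid & (u < p_ts)
    tv1_mask = valid & (u >= p_ts) & (u < p_ts + p_tv)
    tv2_mask = valid & (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts_mask] = _TS_PARTNER[codes[ts_mask]]
    out[tv1_mask] = _TV_PARTNERS[codes[tv1_mask], 0]
    out[tv2_mask] = _TV_PARTNERS[codes[tv2_mask], 1]

    copy = list(master.upper())
    for i in np.nonzero(out != codes)[0]:
        copy[i] = BASES[out[i]]

    if protect is not None:
        _enforce_protection(copy, master.upper(), protect, rng)

    mutated = "".join(copy)
    realized = kimura2p(master, mutated)
    return mutated, (realized.K if realized.defined else float("nan"))


def _enforce_protection(
    copy: list[str], master: str, protect: OrfProtection, rng: np.random.Generator
) -> None:
    for a, b in protect.protected_intervals:
        copy[a:b] = master[a:b]
    s, e = protect.orf_start, protect.orf_end
    copy[s:s + 3] = "ATG"
    # terminal stop: keep the master's stop codon
    copy[e - 3:e] = master[e - 3:e]
    for pos in range(s + 3, e - 3, 3):
        codon = "".join(copy[pos:pos + 3])
        if codon not in STOP_CODONS:
            continue
        # redirect one mutated base of the codon to a neutral alternative
        fixed = False
        for off in range(3):
            if copy[pos + off] == master[pos + off]:
                continue
            for alt in BASES:
                if alt == master[pos + off] or alt == copy[pos + off]:
                    continue
                trial = codon[:off] + alt + codon[off + 1:]
                if trial not in STOP_CODONS:
                    copy[pos + off] = alt
                    fixed = True
                    break
            if fixed:
                break
        if not fixed:  # mutated base has no neutral alternative: revert it
            for off in range(3):
                if copy[pos + off] != master[pos + off]:
                    copy[pos + off] = master[pos + off]
                    break


LESIONS = ("premature_stop", "truncation_5p", "truncation_3p", "scrambled_tir")


def apply_lesion(
    element: str, template: ElementTemplate, lesion: str, rng: np.random.Generator
) -> str:
    """Apply one disabling lesion to a mutated copy."""
    if lesion == "premature_stop":
        codon_idx = int(0.4 * template.orf_protein_length)
        pos = template.orf_start + 3 * codon_idx
        return element[:pos] + "TAA" + element[pos + 3:]
    if lesion == "truncation_5p":
        cut = int(len(element) * float(rng.uniform(0.30, 0.50)))
        return element[cut:]
    if lesion == "truncation_3p":
        cut = int(len(element) * float(rng.uniform(0.30, 0.50)))
        return element[:len(element) - cut]
    if lesion == "scrambled_tir":
        t = template.tir_length
        tail = list(element[-t:])
        rng.shuffle(tail)
        scrambled = "".join(tail)
        if scrambled == element[-t:]:  # force at least one change
            scrambled = scrambled[::-1]
        return element[:-t] + scrambled
    raise ValueError(f"unknown lesion {lesion!r}")


@dataclass
class SimulatedGenome:
    contigs: dict[str, str]
    truth: pd.DataFrame
    templates: dict[str, ElementTemplate] = field(default_factory=dict)

    @property
    def genome_bp(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def queries(self) -> dict[str, str]:
        """Per-family DDE-domain protein queries."""
        return {f"{fam}_dde": t.dde_query for fam, t in self.templates.items()}

    def domain_tables(self) -> pd.DataFrame:
        frames = [t.domain_table() for t in self.templates.values()]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["protein_id", "domain", "start", "end"]
        )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "genome.fasta", self.contigs)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        write_fasta(out / "query.faa", self.queries())
        write_fasta(
            out / "masters.fasta",
            {fam: t.sequence for fam, t in self.templates.items()},
        )
        self.domain_tables().to_csv(out / "domains.tsv", sep="\t", index=False)


def write_fasta(path: str | Path, records: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def plant_genome(
    specs: list[PlantSpec],
    n_contigs: int = 5,
    contig_length: int = 400_000,
    gc: float = 0.35,
    rng_seed: int = 0,
    *,
    min_separation: int = 5000,
    edge_margin: int = 200,
    annotate_truth: bool = True,
) -> SimulatedGenome:
    """Plant element copies into random background contigs.

    Each copy is inserted with the TSD written on both flanks
    (``TTAA-[element]-TTAA`` for the canonical duplication), at sites separated by
    at least ``min_separation`` bp so candidate loci stay resolvable.
    Truth rows are one-to-one with planted copies; ``is_intact`` is
    determined by running the structural annotator on the planted copy in
    situ, so the truth table and the annotator agree by construction.
    """
    from . import structural_annotation as sa  # deferred: avoids import cycle

    rng = np.random.default_rng(rng_seed)
    genome_bp = n_contigs * contig_length
    total_planted = sum(s.template.element_length * s.n_copies for s in specs)
    if total_planted >= 0.5 * genome_bp:
        raise ValueError(
            f"planted length {total_planted} exceeds half the genome ({genome_bp})"
        )

    copies = []  # (spec, copy_index, decayed, lesion)
    for spec_idx, spec in enumerate(specs):
        n_decay = int(round(spec.decay_fraction * spec.n_copies))
        for i in range(spec.n_copies):
            decayed = i >= spec.n_copies - n_decay
            # stagger the lesion mix across specs so every lesion type occurs
            k = spec_idx + (i - (spec.n_copies - n_decay))
            lesion = LESIONS[k % len(LESIONS)] if decayed else None
            copies.append((spec, i, decayed, lesion))

    # assign contigs round-robin after shuffling for dispersion
    order = rng.permutation(len(copies))
    contig_of = {int(order[j]): j % n_contigs for j in range(len(copies))}

    backgrounds = [random_dna(contig_length, rng, gc) for _ in range(n_contigs)]
    per_contig: dict[int, list] = {c: [] for c in range(n_contigs)}

    counter = 0
    for idx, (spec, i, decayed, lesion) in enumerate(copies):
        child = np.random.default_rng([rng_seed, counter])
        counter += 1
        protect = None
        if not decayed:
            t = spec.template
            protect = OrfProtection(
                orf_start=t.orf_start,
                orf_end=t.orf_end,
                protected_intervals=(
                    (0, t.tir_length),
                    (t.element_length - t.tir_length, t.element_length),
                ),
            )
        mutated, realized_K = mutate_copy(
            spec.template.sequence, spec.expected_K, rng_seed=child, protect=protect
        )
        if decayed:
            mutated = apply_lesion(mutated, spec.template, lesion, child)
        strand = "+" if child.random() < 0.5 else "-"
        per_contig[contig_of[idx]].append(
            (spec, i, decayed, mutated, realized_K, strand)
        )

    contigs: dict[str, str] = {}
    truth_rows = []
    for c in range(n_contigs):
        entries = per_contig[c]
        bg = backgrounds[c]
        n = len(entries)
        avail = contig_length - 2 * edge_margin - n * min_separation
        if n and avail <= 0:
            raise ValueError(
                f"contig of {contig_length} bp too small for {n} copies "
                f"at min separation {min_separation}"
            )
        raw = np.sort(rng.random(n)) * avail if n else np.array([])
        positions = [int(edge_margin + raw[j] + j * min_separation) for j in range(n)]
        parts = []
        prev = 0
        new_rows = []
        offset = 0
        for (spec, i, decayed, mutated, realized_K, strand), pos in zip(entries, positions):
            oriented = mutated if strand == "+" else revcomp(mutated)
            tsd = spec.tsd
            parts.append(bg[prev:pos])
            parts.append(tsd + oriented + tsd)
            start = pos + offset + len(tsd)
            end = start + len(oriented)
            offset += 2 * len(tsd) + len(oriented)
            prev = pos
            new_rows.append((spec, i, decayed, realized_K, strand, start, end))
        parts.append(bg[prev:])
        name = f"contig_{c + 1}"
        contigs[name] = "".join(parts)
        for spec, i, decayed, realized_K, strand, start, end in new_rows:
            truth_rows.append({
                "element_id": f"{spec.template.family_id}_{i:03d}",
                "contig": name,
                "start": start,
                "end": end,
                "strand": strand,
                "family_id": spec.template.family_id,
                "is_intact": not decayed,
                "realized_K": realized_K,
                "tir_length": spec.template.tir_length,
                "tsd_present": bool(spec.tsd),
            })

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    genome = SimulatedGenome(
        contigs=contigs,
        truth=truth,
        templates={s.template.family_id: s.template for s in specs},
    )

    if annotate_truth:
        _reconcile_truth_with_annotator(genome, sa)
    return genome


def _reconcile_truth_with_annotator(genome: SimulatedGenome, sa) -> None:
    """Set is_intact by running the structural annotator on each copy in situ."""
    flank = 300
    intact_flags = []
    for row in genome.truth.itertuples():
        contig = genome.contigs[row.contig]
        a = max(0, row.start - flank)
        b = min(len(contig), row.end + flank)
        locus = contig[a:b]
        if row.strand == "-":
            locus = revcomp(locus)
            core = (len(locus) - (row.end - a), len(locus) - (row.start - a))
        else:
            core = (row.start - a, row.end - a)
        element = sa.annotate_locus_sequence(locus, core)
        intact_flags.append(bool(element is not None and element.is_intact))
    claimed = genome.truth["is_intact"].tolist()
    demoted = sum(1 for c, f in zip(claimed, intact_flags) if c and not f)
    promoted = sum(1 for c, f in zip(claimed, intact_flags) if f and not c)
    if demoted or promoted:
        logger.info(
            "truth reconciliation: %d copies demoted, %d promoted by annotator",
            demoted, promoted,
        )
    genome.truth["is_intact"] = intact_flags


def default_study(rng_seed: int = 0) -> list[PlantSpec]:
    """The default study conditions: five independent families.

    TIR lengths, ORF lengths and element lengths sit inside the observed
    ranges (TIR 6-46 bp, transposase 500-725 aa, element 2074-3465 bp);
    expected divergences span recent (K=0) to moderately aged (K=0.05)
    insertions.  60 copies in total, 50 intact and 10 carrying disabling
    lesions; famA is fully intact at K=0 (a currently-active candidate by
    the tiering rules) and famB keeps more than ten intact copies (the
    putatively-active regime).
    """
    params = [
        # family, tir bp, orf aa, element bp, expected K, copies, decayed
        ("famA", 13, 520, 2200, 0.000, 12, 0),   # young, fully intact
        ("famB", 15, 560, 2500, 0.010, 14, 3),   # >10 intact copies
        ("famC", 16, 600, 2800, 0.020, 12, 2),
        ("famD", 17, 640, 3100, 0.035, 11, 2),
        ("famE", 19, 690, 3400, 0.050, 11, 3),
    ]
    specs = []
    for j, (fam, tir_len, orf_len, elem_len, K, n, n_decay) in enumerate(params):
        template = make_template(
            fam,
            rng_seed=rng_seed * 1000 + j,
            length_range=(elem_len, elem_len),
            tir_length=tir_len,
            orf_length=orf_len,
        )
        specs.append(
            PlantSpec(
                template=template,
                n_copies=n,
                expected_K=K,
                decay_fraction=n_decay / n,
            )
        )
    return specs


def simulate_default(rng_seed: int = 0, **plant_kwargs) -> SimulatedGenome:
    """Default 2 Mb study genome: 5 contigs x 400 kb, 5 families, 60 copies."""
    return plant_genome(default_study(rng_seed), rng_seed=rng_seed, **plant_kwargs)
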
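"""End-to-end orchestration: search -> cluster -> annotate -> landscape -> report.

``run_all`` executes every stage on a genome + protein-query FASTA pair,
writes all intermediate artifacts into the output directory, and returns a
per-family report shaped like the census summary table (family, copy
counts, length / transposase / TIR ranges, activity tier).  Runs are pure
functions of (inputs, config, seed): repeating a run with identical inputs
produces byte-identical artifacts.

``validate_against_truth`` scores a run against the simulator's truth
table: an element matches a planted copy when their reciprocal overlap is
at least 0.9; boundary-exact means both coordinates agree exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from ._align import revcomp
from .divergence_landscape import (
    ActivityCall,
    FamilyProfile,
    call_activity,
    family_divergences,
    landscape,
    landscape_frame,
)
from .family_clustering import Cluster, build_consensus, cluster_loci
from .homology_search import (
    CandidateLocus,
    ProteinQuery,
    SearchParams,
    extract_candidates,
    search_all,
)
from .io import hits_to_frame, read_fasta, write_bed, write_fasta, write_gff3
from .structural_annotation import PBElement, TIRParams, annotate_locus_sequence

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    identity_min: float = 0.8
    coverage_min: float = 0.3
    flank_bp: int = 4000
    merge_distance: int = 2000
    cluster_identity: float = 0.5
    cluster_on: str = "core"          # or "locus"
    min_orf_aa: int = 500             # strict >
    tir_min: int = 6
    tir_max: int = 50
    tir_pair_identity: float = 0.8
    young_K: float = 0.01
    old_K: float = 0.10
    min_intact_for_dynamics: int = 10
    min_aligned_sites: int = 100
    bin_width: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("identity_min", "coverage_min", "cluster_identity",
                     "tir_pair_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")

    def search_params(self) -> SearchParams:
        return SearchParams(
            identity_min=self.identity_min,
            coverage_min=self.coverage_min,
            merge_distance=self.merge_distance,
            flank_bp=self.flank_bp,
        )

    def tir_params(self) -> TIRParams:
        return TIRParams(
            min_length=self.tir_min,
            max_length=self.tir_max,
            min_identity=self.tir_pair_identity,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AnnotatedElement:
    element_id: str
    contig: str
    start: int          # genome-absolute, 0-based half-open
    end: int
    strand: str
    family_id: str
    element: PBElement
    sequence: str = field(repr=False, default="")
    locus: Optional[CandidateLocus] = field(repr=False, default=None)

    @property
    def is_intact(self) -> bool:
        return self.element.is_intact


@dataclass
class RunReport:
    table: pd.DataFrame
    metadata: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        self.table.to_csv(out / "report.tsv", sep="\t", index=False)
        payload = {
            "metadata": self.metadata,
            "families": self.table.to_dict(orient="records"),
        }
        with open(out / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


REPORT_COLUMNS = [
    "family_id", "n_PB", "n_intact", "length_min", "length_max",
    "tpase_aa_min", "tpase_aa_max", "tir_bp_min", "tir_bp_max",
    "median_K", "activity_tier",
]


def annotate_loci(
    loci: Sequence[CandidateLocus],
    clusters: Sequence[Cluster],
    config: PipelineConfig,
) -> list[AnnotatedElement]:
    """Run structural annotation on every locus, tagging cluster families."""
    family_of = {}
    orientation_of = {}
    for cluster in clusters:
        for member_id, orient in zip(cluster.member_ids, cluster.orientations):
            family_of[member_id] = cluster.cluster_id
            orientation_of[member_id] = orient
    params = config.tir_params()
    elements: list[AnnotatedElement] = []
    for locus in loci:
        pb = annotate_locus_sequence(
            locus.sequence, locus.core_in_locus, params,
            min_orf_aa=config.min_orf_aa,
        )
        if pb is None:
            continue
        if locus.strand == "+":
            abs_start = locus.flank_start + pb.start
            abs_end = locus.flank_start + pb.end
        else:
            abs_start = locus.flank_end - pb.end
            abs_end = locus.flank_end - pb.start
        family = family_of.get(locus.locus_id, "unclustered")
        seq = locus.sequence[pb.start:pb.end]
        if orientation_of.get(locus.locus_id, "+") == "-":
            seq = revcomp(seq)
        element_id = f"{family}_{locus.contig}_{abs_start}"
        pb.element_id = element_id
        pb.family_id = family
        elements.append(
            AnnotatedElement(
                element_id=element_id,
                contig=locus.contig,
                start=abs_start,
                end=abs_end,
                strand=locus.strand,
                family_id=family,
                element=pb,
                sequence=seq,
                locus=locus,
            )
        )
    elements.sort(key=lambda e: (e.contig, e.start))
    return elements


def build_family_profiles(
    elements: Sequence[AnnotatedElement],
    config: PipelineConfig,
) -> dict[str, FamilyProfile]:
    """Consensus + divergences + intactness per family of annotated copies."""
    by_family: dict[str, list[AnnotatedElement]] = {}
    for e in elements:
        by_family.setdefault(e.family_id, []).append(e)
    profiles: dict[str, FamilyProfile] = {}
    for family_id in sorted(by_family):
        members = by_family[family_id]
        seqs = {e.element_id: e.sequence for e in members}
        centroid_id = max(seqs, key=lambda i: (len(seqs[i]), i))
        star = Cluster(
            cluster_id=family_id,
            centroid_id=centroid_id,
            member_ids=sorted(seqs),
            member_identities=[1.0] * len(seqs),
            orientations=["+"] * len(seqs),
        )
        consensus = build_consensus(star, seqs)
        profile = FamilyProfile(
            family_id=family_id,
            consensus=consensus,
            copies=seqs,
            intact={e.element_id: e.is_intact for e in members},
        )
        family_divergences(profile, min_sites=config.min_aligned_sites)
        profiles[family_id] = profile
    return profiles


def elements_to_frame(elements: Sequence[AnnotatedElement]) -> pd.DataFrame:
    rows = []
    for e in elements:
        rows.append({
            "element_id": e.element_id,
            "contig": e.contig,
            "start": e.start,
            "end": e.end,
            "strand": e.strand,
            "family_id": e.family_id,
            "is_intact": e.is_intact,
            "tir_length": e.element.tir.length if e.element.tir else 0,
            "tsd_left": e.element.tsd_left or "",
            "tsd_right": e.element.tsd_right or "",
            "tsd_canonical": e.element.tsd_canonical,
            "orf_length_aa": e.element.orf_length_aa,
        })
    return pd.DataFrame(rows, columns=[
        "element_id", "contig", "start", "end", "strand", "family_id",
        "is_intact", "tir_length", "tsd_left", "tsd_right", "tsd_canonical",
        "orf_length_aa",
    ])


def elements_to_gff(elements: Sequence[AnnotatedElement]) -> list[dict]:
    features = []
    for e in elements:
        attrs = {
            "ID": e.element_id,
            "family": e.family_id,
            "intact": "true" if e.is_intact else "false",
            "tsd_left": e.element.tsd_left or "NA",
            "tsd_right": e.element.tsd_right or "NA",
        }
        features.append({
            "contig": e.contig, "type": "transposable_element",
            "start": e.start, "end": e.end, "strand": e.strand,
            "attributes": attrs,
        })
        tir = e.element.tir
        if tir is not None:
            if e.strand == "+":
                spans = [
                    (e.start, e.start + tir.length),
                    (e.end - tir.length, e.end),
                ]
            else:
                spans = [
                    (e.end - tir.length, e.end),
                    (e.start, e.start + tir.length),
                ]
            for k, (a, b) in enumerate(spans):
                features.append({
                    "contig": e.contig, "type": "terminal_inverted_repeat",
                    "start": a, "end": b, "strand": e.strand,
                    "attributes": {"ID": f"{e.element_id}_tir{k + 1}",
                                   "Parent": e.element_id},
                })
        if e.element.orf_length_aa > 0:
            rel_s = e.element.orf_start - e.element.start
            rel_e = e.element.orf_end - e.element.start
            if e.strand == "+":
                a, b = e.start + rel_s, e.start + rel_e
            else:
                a, b = e.end - rel_e, e.end - rel_s
            features.append({
                "contig": e.contig, "type": "CDS",
                "start": a, "end": b, "strand": e.strand,
                "attributes": {"ID": f"{e.element_id}_cds",
                               "Parent": e.element_id},
            })
    return features


def summarize_families(
    profiles: dict[str, FamilyProfile],
    elements: Sequence[AnnotatedElement],
    config: PipelineConfig,
) -> tuple[pd.DataFrame, list[ActivityCall]]:
    by_family: dict[str, list[AnnotatedElement]] = {}
    for e in elements:
        by_family.setdefault(e.family_id, []).append(e)
    rows = []
    calls = []
    for family_id in sorted(profiles):
        profile = profiles[family_id]
        members = by_family.get(family_id, [])
        call = call_activity(
            profile,
            young_K=config.young_K,
            old_K=config.old_K,
            min_intact_for_dynamics=config.min_intact_for_dynamics,
        )
        calls.append(call)
        counted = [e for e in members if e.is_intact] or members
        lengths = [e.end - e.start for e in counted]
        orfs = [e.element.orf_length_aa for e in counted]
        tirs = [e.element.tir.length for e in counted if e.element.tir]
        rows.append({
            "family_id": family_id,
            "n_PB": len(members),
            "n_intact": sum(e.is_intact for e in members),
            "length_min": min(lengths), "length_max": max(lengths),
            "tpase_aa_min": min(orfs), "tpase_aa_max": max(orfs),
            "tir_bp_min": min(tirs) if tirs else 0,
            "tir_bp_max": max(tirs) if tirs else 0,
            "median_K": round(call.median_K, 4),
            "activity_tier": call.tier,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS), calls


def run_all(
    config: PipelineConfig,
    genome_path: str | Path,
    query_path: str | Path,
    out_dir: str | Path,
) -> RunReport:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - stage-named abort contract
            raise StageError(name, exc) from exc
        return result

    genome = stage("read_genome", read_fasta, genome_path)
    queries = [
        ProteinQuery(qid, seq)
        for qid, seq in stage("read_query", read_fasta, query_path).items()
    ]
    params = config.search_params()

    hits = stage("search", search_all, queries, genome, params)
    hits_to_frame(hits).to_csv(out / "hits.tsv", sep="\t", index=False)
    logger.info("search: %d retained hits", len(hits))

    loci = stage(
        "extract", extract_candidates, hits, genome,
        config.flank_bp, config.merge_distance,
    )
    write_fasta(
        out / "candidates.fasta",
        {L.locus_id: L.sequence for L in loci},
        descriptions={
            L.locus_id: (
                f"contig={L.contig} span={L.flank_start}-{L.flank_end} "
                f"core={L.core_start}-{L.core_end} strand={L.strand}"
            )
            for L in loci
        },
    )
    write_bed(
        out / "candidates.bed",
        [(L.contig, L.flank_start, L.flank_end, L.locus_id, 0, L.strand)
         for L in loci],
    )
    logger.info("extract: %d candidate loci", len(loci))

    if loci:
        clusters, _ = stage(
            "cluster", cluster_loci, loci, config.cluster_identity,
            sequence=config.cluster_on,
        )
    else:
        clusters = []
    cluster_rows = [
        (c.cluster_id, m, round(i, 4), o)
        for c in clusters
        for m, i, o in zip(c.member_ids, c.member_identities, c.orientations)
    ]
    pd.DataFrame(
        cluster_rows, columns=["cluster_id", "member_id", "identity", "orientation"]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)

    elements = stage("annotate", annotate_loci, loci, clusters, config)
    elements_to_frame(elements).to_csv(out / "elements.tsv", sep="\t", index=False)
    write_gff3(out / "elements.gff3", elements_to_gff(elements))
    write_fasta(out / "elements.fasta", {e.element_id: e.sequence for e in elements})
    logger.info(
        "annotate: %d elements (%d intact)",
        len(elements), sum(e.is_intact for e in elements),
    )

    profiles = stage("divergence", build_family_profiles, elements, config)
    write_fasta(
        out / "consensus.fasta",
        {fam: p.consensus for fam, p in sorted(profiles.items())},
    )
    div_rows = [
        (r.family_id, r.element_id, round(r.K, 6), round(r.P, 6),
         round(r.Q, 6), r.aligned_sites)
        for p in profiles.values() for r in p.divergences
    ]
    pd.DataFrame(
        div_rows,
        columns=["family_id", "element_id", "K", "P", "Q", "aligned_sites"],
    ).sort_values(["family_id", "element_id"]).to_csv(
        out / "divergence.tsv", sep="\t", index=False
    )

    genome_bp = sum(len(s) for s in genome.values())
    all_records = [r for p in profiles.values() for r in p.divergences]
    lengths = {e.element_id: e.end - e.start for e in elements}
    points = stage(
        "landscape", landscape, all_records, lengths, genome_bp, config.bin_width
    )
    landscape_frame(points).to_csv(out / "landscape.tsv", sep="\t", index=False)

    table, calls = stage("summarize", summarize_families, profiles, elements, config)
    pd.DataFrame(
        [(c.family_id, c.intact_count, c.total_count,
          round(c.intact_fraction, 4), round(c.median_K, 4), c.tier)
         for c in calls],
        columns=["family_id", "intact_count", "total_count",
                 "intact_fraction", "median_K", "tier"],
    ).to_csv(out / "activity.tsv", sep="\t", index=False)

    report = RunReport(
        table=table,
        metadata={
            "config_hash": config.config_hash,
            "seed": config.seed,
            "pbscout_version": __version__,
            "genome_bp": genome_bp,
            "n_hits": len(hits),
            "n_loci": len(loci),
            "n_elements": len(elements),
        },
    )
    report.write(out)
    return report


@dataclass
class ValidationMetrics:
    n_truth: int
    n_predicted: int
    n_matched: int
    recall: float
    precision: float
    intact_recall: float
    boundary_exact_fraction: float      # among matched truth-intact copies
    intact_true_positives: int
    intact_false_positives: int         # predicted intact matching decayed truth
    intact_false_negatives: int
    decayed_classified_intact: int
    false_positive_elements: int        # predictions matching no truth copy

    def as_dict(self) -> dict:
        return asdict(self)


def validate_against_truth(
    elements: pd.DataFrame, truth: pd.DataFrame, min_reciprocal_overlap: float = 0.9
) -> ValidationMetrics:
    """Score predicted elements against the simulator truth table."""
    required = {"contig", "start", "end", "is_intact"}
    for name, frame in (("elements", elements), ("truth", truth)):
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"{name} table missing columns {missing}")

    pairs = []  # (overlap_fraction, pred_idx, truth_idx)
    for pi, p in elements.iterrows():
        for ti, t in truth.iterrows():
            if p["contig"] != t["contig"]:
                continue
            ov = min(p["end"], t["end"]) - max(p["start"], t["start"])
            if ov <= 0:
                continue
            rec = min(ov / (p["end"] - p["start"]), ov / (t["end"] - t["start"]))
            if rec >= min_reciprocal_overlap:
                pairs.append((rec, pi, ti))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    matched_pred: dict[int, int] = {}
    matched_truth: dict[int, int] = {}
    for rec, pi, ti in pairs:
        if pi in matched_pred or ti in matched_truth:
            continue
        matched_pred[pi] = ti
        matched_truth[ti] = pi

    n_truth = len(truth)
    n_pred = len(elements)
    n_matched = len(matched_truth)
    truth_intact = truth[truth["is_intact"].astype(bool)]
    n_truth_intact = len(truth_intact)

    intact_tp = intact_fn = 0
    boundary_exact = 0
    for ti, t in truth_intact.iterrows():
        pi = matched_truth.get(ti)
        if pi is None:
            intact_fn += 1
            continue
        p = elements.loc[pi]
        if bool(p["is_intact"]):
            intact_tp += 1
        else:
            intact_fn += 1
        if p["start"] == t["start"] and p["end"] == t["end"]:
            boundary_exact += 1

    # an intact call "hits" a decayed copy if it covers most of that copy,
    # whether or not the reciprocal-overlap match succeeded (a mis-detected
    # span around a decayed copy must still count against the classifier)
    decayed_intact = 0
    intact_truth_idx = set(truth_intact.index)
    for ti, t in truth[~truth["is_intact"].astype(bool)].iterrows():
        for pi, p in elements.iterrows():
            if not bool(p["is_intact"]) or p["contig"] != t["contig"]:
                continue
            if matched_pred.get(pi) in intact_truth_idx:
                continue
            ov = min(p["end"], t["end"]) - max(p["start"], t["start"])
            if ov >= 0.5 * (t["end"] - t["start"]):
                decayed_intact += 1
                break

    n_matched_intact = sum(
        1 for ti in truth_intact.index if ti in matched_truth
    )
    fp_elements = n_pred - len(matched_pred)
    return ValidationMetrics(
        n_truth=n_truth,
        n_predicted=n_pred,
        n_matched=n_matched,
        recall=n_matched / n_truth if n_truth else 1.0,
        precision=len(matched_pred) / n_pred if n_pred else 1.0,
        intact_recall=intact_tp / n_truth_intact if n_truth_intact else 1.0,
        boundary_exact_fraction=(
            boundary_exact / n_matched_intact if n_matched_intact else 1.0
        ),
        intact_true_positives=intact_tp,
        intact_false_positives=decayed_intact,
        intact_false_negatives=intact_fn,
        decayed_classified_intact=decayed_intact,
        false_positive_elements=fp_elements,
    )
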
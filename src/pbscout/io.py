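"""File-format helpers: FASTA, BED, GFF3, tabular hit/cluster outputs.

Conventions: FASTA via Biopython, 60-column wrapped; BED and truth/element
tables 0-based half-open; GFF3 1-based inclusive as the format requires.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

HITS_COLUMNS = [
    "query_id", "contig", "identity", "length", "query_start", "query_end",
    "genome_start", "genome_end", "frame", "coverage", "score",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def read_fasta_with_descriptions(path: str | Path) -> dict[str, tuple[str, str]]:
    return {
        r.id: (r.description, str(r.seq).upper())
        for r in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(
    path: str | Path, records: Mapping[str, str], width: int = 60,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            desc = f" {descriptions[name]}" if descriptions and name in descriptions else ""
            fh.write(f">{name}{desc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def hits_to_frame(hits: Iterable) -> pd.DataFrame:
    rows = [
        (h.query_id, h.contig, round(h.identity, 4),
         h.query_end - h.query_start, h.query_start, h.query_end,
         h.genome_start, h.genome_end, h.frame, round(h.coverage, 4),
         round(h.score, 1))
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HITS_COLUMNS)


def write_bed(path: str | Path, rows: Sequence[tuple]) -> None:
    """Rows: (contig, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_gff3(path: str | Path, features: Sequence[dict]) -> None:
    """Features: dicts with contig, source, type, start, end (0-based
    half-open, converted here), score, strand, attributes (dict)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f["attributes"].items())
            fh.write(
                "\t".join([
                    f["contig"], f.get("source", "pbscout"), f["type"],
                    str(f["start"] + 1), str(f["end"]), str(f.get("score", ".")),
                    f.get("strand", "."), ".", attrs,
                ]) + "\n"
            )


def read_gff3_elements(path: str | Path) -> pd.DataFrame:
    """Read back transposable_element features into a coordinate table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[2] != "transposable_element":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append({
                "element_id": attrs.get("ID", ""),
                "contig": parts[0],
                "start": int(parts[3]) - 1,
                "end": int(parts[4]),
                "strand": parts[6],
                "family_id": attrs.get("family", ""),
                "is_intact": attrs.get("intact", "false") == "true",
            })
    return pd.DataFrame(
        rows, columns=["element_id", "contig", "start", "end", "strand",
                       "family_id", "is_intact"],
    )
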
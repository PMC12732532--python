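"""Kimura 2-parameter divergence, repeat landscapes, and activity tiers.

Per-copy divergence follows the RepeatMasker ``calcDivergenceFromAlign``
convention: each element copy is globally aligned to its family consensus
and the Kimura 2-parameter (K2P) distance

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

is computed from the transition proportion P and transversion proportion Q
over ungapped, unambiguous columns.  K is a proxy for insertion age on a
relative time scale: recently mobilised copies have K near 0, long-resident
copies accumulate substitutions.

The landscape bins each copy's base pairs by its K value (default bin width
0.01) and reports genome coverage per bin, the familiar stacked-histogram
"repeat landscape" x-axis/y-axis.  Activity tiering applies the decision
rules used for calling candidate-active families: 100% intact copies with
median K at ~0 mark a currently-active candidate; an intact fraction above
one half with more than ten intact copies marks a putatively active family;
high median K marks a long-term resident; anything else is inactive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from ._align import align_dna_global

logger = logging.getLogger(__name__)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
DNA = set("ACGT")

#: tier labels, most to least active
TIER_CURRENT = "currently_active_candidate"
TIER_PUTATIVE = "putatively_active"
TIER_RESIDENT = "long_term_resident"
TIER_INACTIVE = "inactive"


class K2PResult(NamedTuple):
    K: float  # nan when the estimator is undefined (saturation)
    P: float
    Q: float
    aligned_sites: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.K)


@dataclass
class DivergenceRecord:
    element_id: str
    family_id: str
    K: float
    P: float
    Q: float
    aligned_sites: int


@dataclass
class ActivityCall:
    family_id: str
    intact_count: int
    total_count: int
    intact_fraction: float
    median_K: float
    tier: str


@dataclass
class FamilyProfile:
    """A clustered element family: consensus, copies, divergences, tier."""

    family_id: str
    consensus: str
    copies: dict[str, str] = field(default_factory=dict)
    intact: dict[str, bool] = field(default_factory=dict)
    divergences: list[DivergenceRecord] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return len(self.copies)

    @property
    def intact_count(self) -> int:
        return sum(bool(v) for v in self.intact.values())


def kimura2p(aligned_a: str, aligned_b: str) -> K2PResult:
    """K2P distance between two equal-length aligned DNA strings.

    Columns containing gaps or non-ACGT symbols are excluded.  Returns K as
    NaN when the estimator's log arguments are non-positive (saturation).
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError(
            f"aligned sequences differ in length ({len(aligned_a)} vs {len(aligned_b)})"
        )
    sites = transitions = transversions = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x not in DNA or y not in DNA:
            continue
        sites += 1
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        return K2PResult(float("nan"), 0.0, 0.0, 0)
    P = transitions / sites
    Q = transversions / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PResult(float("nan"), P, Q, sites)
    K = -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0  # normalise -0.0
    return K2PResult(K, P, Q, sites)


def family_divergences(
    family: FamilyProfile,
    copies: Mapping[str, str] | None = None,
    *,
    min_sites: int = 100,
) -> list[DivergenceRecord]:
    """K2P of every copy against the family consensus.

    Each copy is globally aligned to the consensus (terminal gaps stripped,
    so truncated copies are scored over their aligned span).  Copies
    aligning over fewer than ``min_sites`` unambiguous sites are dropped
    with a warning.  Records are ordered by element id and also stored on
    the profile.
    """
    if not family.consensus:
        raise ValueError(f"family {family.family_id} has no consensus")
    seqs = dict(copies) if copies is not None else family.copies
    records: list[DivergenceRecord] = []
    for element_id in sorted(seqs):
        pair = align_dna_global(family.consensus, seqs[element_id])
        res = kimura2p(pair.row_a, pair.row_b)
        if res.aligned_sites < min_sites:
            logger.warning(
                "dropping %s: only %d aligned sites (< %d)",
                element_id, res.aligned_sites, min_sites,
            )
            continue
        records.append(
            DivergenceRecord(
                element_id=element_id,
                family_id=family.family_id,
                K=res.K,
                P=res.P,
                Q=res.Q,
                aligned_sites=res.aligned_sites,
            )
        )
    family.divergences = records
    return records


@dataclass
class LandscapePoint:
    family_id: str
    K_bin: float  # left edge
    coverage_pct: float


def landscape(
    records: Iterable[DivergenceRecord],
    element_lengths: Mapping[str, int],
    genome_bp: int,
    bin_width: float = 0.01,
) -> list[LandscapePoint]:
    """Bin copy base pairs by K; coverage as percent of genome.

    Copies with undefined K (saturated estimator) are excluded and counted
    via a log message.  Coverage per family sums exactly to the included
    family bp / genome bp (conservation invariant).
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    binned: dict[tuple[str, int], int] = {}
    n_undefined = 0
    for rec in records:
        if math.isnan(rec.K):
            n_undefined += 1
            continue
        idx = int(rec.K // bin_width)
        key = (rec.family_id, idx)
        binned[key] = binned.get(key, 0) + element_lengths[rec.element_id]
    if n_undefined:
        logger.info("landscape: %d copies with undefined K excluded", n_undefined)
    points = [
        LandscapePoint(fam, idx * bin_width, 100.0 * bp / genome_bp)
        for (fam, idx), bp in sorted(binned.items())
    ]
    return points


def landscape_frame(points: Sequence[LandscapePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.family_id, p.K_bin, p.coverage_pct) for p in points],
        columns=["family_id", "K_bin", "coverage_pct"],
    )


def call_activity(
    family: FamilyProfile,
    *,
    young_K: float = 0.01,
    old_K: float = 0.10,
    min_intact_for_dynamics: int = 10,
) -> ActivityCall:
    """Tier a family by intact fraction and median K.

    Decision table (first matching row wins):

    ========================================  ============================
    condition                                 tier
    ========================================  ============================
    intact_fraction == 1 and median K <= young  currently_active_candidate
    intact_fraction > 0.5 and intact > 10       putatively_active
    median K >= old                             long_term_resident
    otherwise                                   inactive
    ========================================  ============================
    """
    total = family.total_count
    if total == 0:
        raise ValueError(f"family {family.family_id} has no copies")
    intact = family.intact_count
    fraction = intact / total
    ks = sorted(r.K for r in family.divergences if not math.isnan(r.K))
    median_K = _median(ks) if ks else float("nan")
    if fraction == 1.0 and not math.isnan(median_K) and median_K <= young_K:
        tier = TIER_CURRENT
    elif fraction > 0.5 and intact > min_intact_for_dynamics:
        tier = TIER_PUTATIVE
    elif not math.isnan(median_K) and median_K >= old_K:
        tier = TIER_RESIDENT
    else:
        tier = TIER_INACTIVE
    return ActivityCall(
        family_id=family.family_id,
        intact_count=intact,
        total_count=total,
        intact_fraction=fraction,
        median_K=median_K,
        tier=tier,
    )


def _median(values: Sequence[float]) -> float:
    n = len(values)
    mid = n // 2
    if n % 2:
        return values[mid]
    return 0.5 * (values[mid - 1] + values[mid])


def plot_landscape(points: Sequence[LandscapePoint], path: str) -> None:
    """Stacked-bar repeat landscape (optional; requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = landscape_frame(points)
    if frame.empty:
        fig, ax = plt.subplots()
        ax.set_xlabel("Kimura divergence (K)")
        ax.set_ylabel("genome coverage (%)")
        fig.savefig(path)
        plt.close(fig)
        return
    pivot = frame.pivot_table(
        index="K_bin", columns="family_id", values="coverage_pct", fill_value=0.0
    ).sort_index()
    fig, ax = plt.subplots(figsize=(8, 4))
    bottom = None
    for fam in pivot.columns:
        vals = pivot[fam].to_numpy()
        ax.bar(pivot.index, vals, width=0.009, bottom=bottom, label=str(fam))
        bottom = vals if bottom is None else bottom + vals
    ax.set_xlabel("Kimura divergence (K)")
    ax.set_ylabel("genome coverage (%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
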
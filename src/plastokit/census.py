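"""Gene inventory, start/stop codon census, and gene-overlap detection.

The codon census reproduces the classic per-genome comparison table: for every
annotated CDS the first and last strand-oriented codons are tallied over
{ATG, GTG, ATT, other} and {TAA, TAG, TGA, other}.  CDS whose length is not a
multiple of three, or whose terminal codons contain N, are routed to a
``skipped`` list with the reason rather than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .records import GeneFeature, ParameterError, PlastomeRecord, extract_cds

logger = logging.getLogger(__name__)

START_CATEGORIES = ("ATG", "GTG", "ATT", "other")
STOP_CATEGORIES = ("TAA", "TAG", "TGA", "other")


@dataclass
class CodonCensus:
    starts: dict[str, int]
    stops: dict[str, int]
    per_gene: list[tuple[str, str, str]]  # (gene, start codon, stop codon)
    skipped: list[tuple[str, str]]  # (gene, reason)

    def __post_init__(self) -> None:
        n = len(self.per_gene)
        if sum(self.starts.values()) != n or sum(self.stops.values()) != n:
            raise ParameterError("census tallies inconsistent with per-gene list")

    def genes_with_start(self, codon: str) -> list[str]:
        return [g for g, s, _ in self.per_gene if s == codon]

    def genes_with_stop(self, codon: str) -> list[str]:
        return [g for g, _, s in self.per_gene if s == codon]


@dataclass
class OverlapReport:
    pairs: list[tuple[str, str, int, bool]] = field(default_factory=list)
    # (geneA, geneB, overlap nt, same_strand)


def codon_census(record: PlastomeRecord) -> CodonCensus:
    """Tally first/last codons of every CDS (anomalies routed to ``skipped``)."""
    cds_feats = record.features_of_kind("CDS")
    if not cds_feats:
        raise ParameterError("record has no CDS features to census")
    starts = dict.fromkeys(START_CATEGORIES, 0)
    stops = dict.fromkeys(STOP_CATEGORIES, 0)
    per_gene: list[tuple[str, str, str]] = []
    skipped: list[tuple[str, str]] = []
    for feat in cds_feats:
        seq = extract_cds(record, feat)
        if len(seq) < 6:
            skipped.append((feat.name, f"too short ({len(seq)} nt)"))
            continue
        if len(seq) % 3 != 0:
            skipped.append((feat.name, f"length {len(seq)} not a multiple of 3"))
            continue
        first, last = seq[:3], seq[-3:]
        if "N" in first or "N" in last:
            skipped.append((feat.name, "ambiguous base in terminal codon"))
            continue
        s_cat = first if first in START_CATEGORIES else "other"
        e_cat = last if last in STOP_CATEGORIES else "other"
        starts[s_cat] += 1
        stops[e_cat] += 1
        per_gene.append((feat.name, first, last))
    if skipped:
        logger.warning("codon census skipped %d CDS: %s", len(skipped), skipped)
    return CodonCensus(starts=starts, stops=stops, per_gene=per_gene, skipped=skipped)


def gene_inventory(record: PlastomeRecord) -> dict[str, object]:
    """Feature counts per class and whether any feature is spliced (intron)."""
    counts = {kind: 0 for kind in ("CDS", "tRNA", "rRNA", "other")}
    for feat in record.features:
        counts[feat.kind] += 1
    return {
        "CDS": counts["CDS"],
        "tRNA": counts["tRNA"],
        "rRNA": counts["rRNA"],
        "other": counts["other"],
        "has_introns": any(f.has_intron for f in record.features),
    }


def _circular_overlap(f1: GeneFeature, f2: GeneFeature, n: int) -> int:
    """Total intersection (nt) of two possibly-wrapping intervals on a circle."""

    def arcs(f: GeneFeature) -> list[tuple[int, int]]:
        if f.wraps:
            return [(f.start, n), (0, f.end)]
        return [(f.start, f.end)]

    total = 0
    for s1, e1 in arcs(f1):
        for s2, e2 in arcs(f2):
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def find_overlaps(record: PlastomeRecord) -> OverlapReport:
    """Every unordered feature pair whose circular intervals intersect by >= 1 nt."""
    n = len(record.sequence)
    feats = record.features
    pairs: list[tuple[str, str, int, bool]] = []
    for idx, f1 in enumerate(feats):
        for f2 in feats[idx + 1 :]:
            ov = _circular_overlap(f1, f2, n)
            if ov >= 1:
                pairs.append((f1.name, f2.name, ov, f1.strand == f2.strand))
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    return OverlapReport(pairs=pairs)
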
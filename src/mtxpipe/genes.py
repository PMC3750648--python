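"""Gene vs intergenic classification, per-gene counting, significance, coverage.

A genome-assigned read is gene-assigned when at least half of its alignment
length (measured on the genome side, strand-agnostic — double-stranded cDNA
destroys transcript orientation) falls inside an annotated ORF; the gene
with the largest overlap wins, ties going to the lexicographically smaller
gene id.  "Significant" genes are the shortest count-ranked prefix capturing
95% of the gene-assigned reads.  Gene coverage is the interval union of the
alignment spans of the *distinct* clusters on the gene (multiplicity is an
abundance weight, not extra sequence, so it is ignored for coverage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .assign import AssignmentRecord
from .iokit import AlignmentHit, ReferenceBundle, Thresholds

INTERGENIC = "intergenic"
TIERS = ("genus", "family", "function_only")  # bit >= 148 / [110,148) / [74,110)


def classify_gene_read(
    hit: AlignmentHit,
    bundle: ReferenceBundle,
    orf_overlap_fraction: float = 0.50,
) -> str:
    """Gene id of the max-overlap ORF, or ``"intergenic"``.

    Overlap is the intersection of the subject-side alignment span with the
    gene span, compared against ``orf_overlap_fraction * alignment_length``
    (boundary inclusive: exactly half counts as gene-assigned).
    """
    candidates = bundle.genes_overlapping(hit.subject_id, hit.subject_start,
                                          hit.subject_end)
    best_gene = None
    best_overlap = 0
    for gene in candidates:  # sorted by gene_id -> lower id wins ties
        overlap = min(hit.subject_end, gene.end) - max(hit.subject_start, gene.start)
        if overlap > best_overlap:
            best_overlap = overlap
            best_gene = gene
    if best_gene is None or best_overlap < orf_overlap_fraction * hit.alignment_length:
        return INTERGENIC
    return best_gene.gene_id


def classify_records(
    records: Iterable[AssignmentRecord],
    bundle: ReferenceBundle,
    thresholds: Optional[Thresholds] = None,
) -> None:
    """Fill ``gene_id`` (or intergenic) in-place for every binned record.

    Function-only reads participate: their functional assignment exists even
    without a taxon.  Unassigned/filtered records keep ``gene_id=None``.
    """
    thresholds = thresholds or Thresholds()
    for record in records:
        if record.bin in ("genus", "family", "function_only"):
            record.gene_id = classify_gene_read(
                record.best_hit, bundle, thresholds.orf_overlap_fraction)
            if record.gene_id != INTERGENIC:
                record.cog_id = bundle.genes[record.gene_id].cog_id


@dataclass
class GeneExpressionTable:
    """Per-gene multiplicity-weighted counts with significance and coverage."""

    counts: dict = field(default_factory=dict)          # gene_id -> read count
    intergenic_count: int = 0
    significant: set = field(default_factory=set)
    coverage: dict = field(default_factory=dict)        # gene_id -> fraction [0,1]
    counts_by_tier: dict = field(default_factory=dict)  # gene_id -> {tier: count}
    normalized: dict = field(default_factory=dict)

    @property
    def gene_assigned_total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene_id in sorted(self.counts):
            tier = self.counts_by_tier.get(gene_id, {})
            rows.append({
                "gene_id": gene_id,
                "read_count": self.counts[gene_id],
                "significant": gene_id in self.significant,
                "coverage_fraction": self.coverage.get(gene_id, 0.0),
                "count_genus_tier": tier.get("genus", 0),
                "count_family_tier": tier.get("family", 0),
                "count_function_tier": tier.get("function_only", 0),
                "normalized_count": self.normalized.get(gene_id, float("nan")),
            })
        return pd.DataFrame(rows)


def count_gene_reads(records: Iterable[AssignmentRecord]) -> GeneExpressionTable:
    """Multiplicity-weighted per-gene counts; intergenic total kept separately."""
    table = GeneExpressionTable()
    for record in records:
        if record.gene_id is None:
            continue
        if record.gene_id == INTERGENIC:
            table.intergenic_count += record.multiplicity
        else:
            table.counts[record.gene_id] = (
                table.counts.get(record.gene_id, 0) + record.multiplicity)
            tier = table.counts_by_tier.setdefault(record.gene_id, {})
            tier[record.bin] = tier.get(record.bin, 0) + record.multiplicity
    return table


def select_significant(table: GeneExpressionTable,
                       capture_fraction: float = 0.95) -> GeneExpressionTable:
    """Flag the shortest count-ranked prefix capturing ``capture_fraction``.

    Genes sort by count descending, ties broken by gene id; the prefix stops
    as soon as its cumulative count reaches ``capture_fraction`` of the
    gene-assigned total.  An empty table yields an empty selection.
    """
    total = table.gene_assigned_total
    table.significant = set()
    if total == 0:
        return table
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    target = capture_fraction * total
    cumulative = 0
    for gene_id, count in ranked:
        table.significant.add(gene_id)
        cumulative += count
        if cumulative >= target:
            break
    return table


def interval_union_length(spans: Iterable[tuple]) -> int:
    """Total length of the union of half-open integer intervals."""
    spans = sorted(spans)
    total = 0
    current_start = current_end = None
    for start, end in spans:
        if current_end is None or start > current_end:
            if current_end is not None:
                total += current_end - current_start
            current_start, current_end = start, end
        else:
            current_end = max(current_end, end)
    if current_end is not None:
        total += current_end - current_start
    return total


def gene_coverage(
    records: Iterable[AssignmentRecord],
    bundle: ReferenceBundle,
    table: GeneExpressionTable,
) -> GeneExpressionTable:
    """Fill per-gene coverage fractions from the classified best hits.

    Coverage = |union of (alignment span intersected with the gene span)| /
    gene length, each distinct cluster counted once.
    """
    spans_by_gene: dict = {}
    for record in records:
        if record.gene_id in (None, INTERGENIC):
            continue
        gene = bundle.genes[record.gene_id]
        hit = record.best_hit
        start = max(hit.subject_start, gene.start)
        end = min(hit.subject_end, gene.end)
        if end > start:
            spans_by_gene.setdefault(record.gene_id, []).append((start, end))
    table.coverage = {}
    for gene_id in table.counts:
        spans = spans_by_gene.get(gene_id, [])
        gene = bundle.genes[gene_id]
        table.coverage[gene_id] = interval_union_length(spans) / gene.length
    return table


def coverage_histogram(table: GeneExpressionTable, n_bins: int = 20) -> pd.DataFrame:
    """Genes per coverage bin, with per-tier read counts of the binned genes.

    Bins partition [0, 1] into ``n_bins`` equal intervals (the last bin is
    closed at 1.0).
    """
    width = 1.0 / n_bins
    rows = []
    for b in range(n_bins):
        low, high = b * width, (b + 1) * width
        genes = [g for g, c in table.coverage.items()
                 if (low <= c < high) or (b == n_bins - 1 and c == 1.0)]
        tier_counts = {t: 0 for t in TIERS}
        for g in genes:
            for t, c in table.counts_by_tier.get(g, {}).items():
                tier_counts[t] += c
        rows.append({
            "coverage_low": low, "coverage_high": high, "n_genes": len(genes),
            "reads_genus_tier": tier_counts["genus"],
            "reads_family_tier": tier_counts["family"],
            "reads_function_tier": tier_counts["function_only"],
        })
    return pd.DataFrame(rows)


def build_expression_table(
    records: Sequence[AssignmentRecord],
    bundle: ReferenceBundle,
    thresholds: Optional[Thresholds] = None,
) -> GeneExpressionTable:
    """classify -> count -> select significant -> coverage, in one call."""
    thresholds = thresholds or Thresholds()
    classify_records(records, bundle, thresholds)
    table = count_gene_reads(records)
    select_significant(table, thresholds.capture_fraction)
    gene_coverage(records, bundle, table)
    return table
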
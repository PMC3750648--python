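"""Two-pass removal of rRNA/tRNA/phiX/adapter reads.

Pass 1 mirrors a dedicated rRNA screen (SortMeRNA-style): a pluggable
backend partitions clusters against the rRNA subset of the filter database.
The reference backend is the built-in aligner in sensitive mode (small word
size), so the suite needs no external binary; an external executable can be
substituted through the callable contract (FASTA in, removed-id set out).

Pass 2 sweeps the survivors against the full filter database (rRNA + tRNA +
phiX + adapters) and removes every cluster whose best local alignment
reaches the minimum bit score (54, inclusive).  Adapter contamination is
removed here as whole-read filter matches — no trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from .aligner import ScoringScheme, SeedIndex, align
from .iokit import FilterRecord, ReadCluster, Thresholds


@dataclass
class RemovedCluster:
    cluster: ReadCluster
    pass_number: int           # 1 | 2
    category: str              # rRNA | tRNA | phiX | adapter
    domain: str                # bacteria | archaea | eukaryota | none
    bit_score: Optional[float] = None
    matched_record: Optional[str] = None


@dataclass
class FilterPartition:
    removed: list = field(default_factory=list)    # RemovedCluster
    retained: list = field(default_factory=list)   # ReadCluster

    def check_conservation(self, input_clusters: Sequence[ReadCluster]) -> None:
        seen = [r.cluster.id for r in self.removed] + [c.id for c in self.retained]
        if sorted(seen) != sorted(c.id for c in input_clusters):
            raise AssertionError("filter partition lost or duplicated clusters")


class BuiltinFilterBackend:
    """Reference pass-1 backend: built-in aligner, sensitive word size.

    A cluster is matched when its best local alignment against the given
    filter records reaches ``min_bit``.
    """

    def __init__(self, records: Sequence[FilterRecord], min_bit: float,
                 word_size: int = 11, scheme: Optional[ScoringScheme] = None) -> None:
        self.records = {r.id: r for r in records}
        self.min_bit = min_bit
        self.scheme = scheme or ScoringScheme()
        self.index = SeedIndex({r.id: r.sequence for r in records}, word_size) \
            if records else None

    def best_match(self, cluster: ReadCluster):
        if self.index is None:
            return None
        hits = align(cluster.sequence, self.index, self.scheme,
                     min_bit=self.min_bit, query_id=cluster.id, pad=32)
        if not hits:
            return None
        best = hits[0]
        return self.records[best.subject_id], best.bit_score


def filter_pass1(
    clusters: Iterable[ReadCluster],
    rrna_records: Sequence[FilterRecord],
    backend: Optional[Callable] = None,
    min_bit: float = 54.0,
) -> FilterPartition:
    """Screen clusters against the rRNA subset of the filter database.

    ``backend`` may be a callable ``clusters -> {cluster_id: record_id}``
    wrapping an external tool; by default the built-in aligner is used.
    Backend failures propagate as raised exceptions carrying the backend log.
    """
    rrna_only = [r for r in rrna_records if r.category == "rRNA"]
    partition = FilterPartition()
    clusters = list(clusters)
    if backend is not None:
        matched = backend(clusters)
        by_id = {r.id: r for r in rrna_only}
        for cluster in clusters:
            record_id = matched.get(cluster.id)
            if record_id is not None:
                rec = by_id[record_id]
                partition.removed.append(RemovedCluster(
                    cluster=cluster, pass_number=1, category=rec.category,
                    domain=rec.domain, matched_record=rec.id))
            else:
                partition.retained.append(cluster)
        return partition
    builtin = BuiltinFilterBackend(rrna_only, min_bit)
    for cluster in clusters:
        match = builtin.best_match(cluster)
        if match is not None:
            rec, bits = match
            partition.removed.append(RemovedCluster(
                cluster=cluster, pass_number=1, category=rec.category,
                domain=rec.domain, bit_score=bits, matched_record=rec.id))
        else:
            partition.retained.append(cluster)
    return partition


def filter_pass2(
    retained: Iterable[ReadCluster],
    filter_db: Sequence[FilterRecord],
    min_bit: float = 54.0,
) -> FilterPartition:
    """Remove clusters whose best filter-database bit score is >= ``min_bit``.

    The matched record's category and domain annotate each removal; the
    survivors are the putative mRNA clusters.
    """
    if min_bit < 0:
        raise ValueError("min_bit must be >= 0")
    backend = BuiltinFilterBackend(list(filter_db), min_bit)
    partition = FilterPartition()
    for cluster in retained:
        match = backend.best_match(cluster)
        if match is not None:
            rec, bits = match
            partition.removed.append(RemovedCluster(
                cluster=cluster, pass_number=2, category=rec.category,
                domain=rec.domain, bit_score=bits, matched_record=rec.id))
        else:
            partition.retained.append(cluster)
    return partition


def run_filter(
    clusters: Sequence[ReadCluster],
    filter_db: Sequence[FilterRecord],
    thresholds: Optional[Thresholds] = None,
    pass1_backend: Optional[Callable] = None,
) -> FilterPartition:
    """Both passes chained; returns the combined partition."""
    thresholds = thresholds or Thresholds()
    p1 = filter_pass1(clusters, filter_db, backend=pass1_backend,
                      min_bit=thresholds.rrna_min_bit)
    p2 = filter_pass2(p1.retained, filter_db, min_bit=thresholds.rrna_min_bit)
    combined = FilterPartition(removed=p1.removed + p2.removed, retained=p2.retained)
    combined.check_conservation(clusters)
    return combined


def summarize_removed(partition: FilterPartition) -> dict:
    """Multiplicity-weighted composition of the removed reads.

    Returns ``{"by_category": {...}, "by_domain": {...}, "n_removed_reads": N}``
    with fractions summing to 1 over removed reads (empty dicts when nothing
    was removed).
    """
    cat: dict = {}
    dom: dict = {}
    total = 0
    for removal in partition.removed:
        m = removal.cluster.multiplicity
        total += m
        cat[removal.category] = cat.get(removal.category, 0) + m
        dom[removal.domain] = dom.get(removal.domain, 0) + m
    if total == 0:
        return {"by_category": {}, "by_domain": {}, "n_removed_reads": 0}
    return {
        "by_category": {k: v / total for k, v in sorted(cat.items())},
        "by_domain": {k: v / total for k, v in sorted(dom.items())},
        "n_removed_reads": total,
    }
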
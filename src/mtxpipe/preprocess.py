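"""Quality filtering and identical-read dereplication.

Reads below the mean-Phred cutoff (default 10, boundary inclusive: a read
with mean exactly 10.0 is kept) are removed; the survivors are pooled into
unique sequences whose multiplicity preserves the original read abundance.
All downstream transcript-abundance calculations re-expand counts by these
multiplicities.  Paired-end streams are dereplicated per mate independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .iokit import Read, ReadCluster


@dataclass
class QCReport:
    """Accounting of the mean-quality filter.

    ``phred_band_counts`` mirrors the conventional mean-Phred banding:
    >=30, [20, 30), [10, 20), <10.
    """

    n_input: int = 0
    n_quality_failed: int = 0
    n_passed: int = 0
    phred_band_counts: dict = None

    def __post_init__(self) -> None:
        if self.phred_band_counts is None:
            self.phred_band_counts = {">=30": 0, "[20,30)": 0, "[10,20)": 0, "<10": 0}

    def check(self) -> None:
        assert self.n_input == self.n_quality_failed + self.n_passed
        assert sum(self.phred_band_counts.values()) == self.n_input


def mean_phred(read: Read) -> float:
    return sum(read.qualities) / len(read.qualities)


def _band(mean_q: float) -> str:
    if mean_q >= 30:
        return ">=30"
    if mean_q >= 20:
        return "[20,30)"
    if mean_q >= 10:
        return "[10,20)"
    return "<10"


def filter_by_quality(reads: Iterable[Read], q_min: float = 10.0):
    """Split reads on mean Phred >= ``q_min``; order preserved.

    Returns ``(passed_reads, report)`` with the report populated eagerly.
    """
    if q_min < 0:
        raise ValueError("q_min must be >= 0")
    report = QCReport()
    passed: list[Read] = []
    for read in reads:
        mq = mean_phred(read)
        report.n_input += 1
        report.phred_band_counts[_band(mq)] += 1
        if mq >= q_min:
            report.n_passed += 1
            passed.append(read)
        else:
            report.n_quality_failed += 1
    report.check()
    return passed, report


def dereplicate(reads: Iterable[Read]) -> list[ReadCluster]:
    """Pool identical sequences into unique clusters.

    The clustering key is the exact sequence string; qualities are ignored
    and the representative keeps the first-seen read's id and qualities.
    """
    clusters: dict[str, ReadCluster] = {}
    for read in reads:
        cluster = clusters.get(read.sequence)
        if cluster is None:
            clusters[read.sequence] = ReadCluster(
                representative=read, multiplicity=1, members=[read.id]
            )
        else:
            cluster.multiplicity += 1
            cluster.members.append(read.id)
    return list(clusters.values())


def reinflate(per_cluster_values: dict, clusters: Iterable[ReadCluster]) -> dict:
    """Aggregate per-cluster values into multiplicity-weighted totals.

    ``per_cluster_values`` maps cluster id -> hashable key (e.g. a gene id);
    the result maps key -> total read count.  Unknown cluster ids raise.
    """
    mult = {c.id: c.multiplicity for c in clusters}
    totals: dict = {}
    for cluster_id, key in per_cluster_values.items():
        if cluster_id not in mult:
            raise KeyError(f"unknown cluster id {cluster_id!r}")
        totals[key] = totals.get(key, 0) + mult[cluster_id]
    return totals
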
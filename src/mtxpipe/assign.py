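"""Best-hit selection and bit-score binning of mRNA reads.

Reads are binned by the bit score of their best genome alignment using
half-open intervals: [148, inf) genus, [110, 148) family, [74, 110)
function-only, below 74 (or no hit) unassigned.  Taxon names always derive
from the single deterministic best hit; when equal-best hits disagree at the
assigned rank the record is flagged ambiguous but not re-resolved (no LCA) —
the threshold calibration measures exactly this best-hit rule.  Species
labels are carried for pair-congruence reporting only, never used for
binning.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .aligner import translated_search
from .iokit import AlignmentHit, ReadCluster, ReferenceBundle, Thresholds

BINS = ("genus", "family", "function_only", "unassigned", "filtered")


@dataclass
class AssignmentRecord:
    cluster_id: str
    bin: str
    multiplicity: int = 1
    best_hit: Optional[AlignmentHit] = None
    taxon_genus: Optional[str] = None
    taxon_family: Optional[str] = None
    taxon_species: Optional[str] = None
    genome_id: Optional[str] = None
    gene_id: Optional[str] = None
    cog_id: Optional[str] = None
    ambiguous: bool = False


def best_hit(hits: Sequence[AlignmentHit], bundle: Optional[ReferenceBundle] = None):
    """Top hit under the aligner's deterministic order, plus an ambiguity flag.

    ``ambiguous`` is True iff two or more hits share the top bit score but
    map to different genera (requires ``bundle`` for genus lookup).  An
    empty list returns ``(None, False)``.
    """
    if not hits:
        return None, False
    top = hits[0]
    ambiguous = False
    if bundle is not None:
        top_genus = bundle.lineage_of_contig(top.subject_id).taxon("genus")
        for other in hits[1:]:
            if other.bit_score != top.bit_score:
                break
            if bundle.lineage_of_contig(other.subject_id).taxon("genus") != top_genus:
                ambiguous = True
                break
    return top, ambiguous


def bin_read(
    cluster: ReadCluster,
    hits: Sequence[AlignmentHit],
    thresholds: Thresholds,
    bundle: ReferenceBundle,
) -> AssignmentRecord:
    """Bin one cluster from its hit list (half-open bit-score intervals)."""
    hit, ambiguous = best_hit(hits, bundle)
    record = AssignmentRecord(
        cluster_id=cluster.id, bin="unassigned",
        multiplicity=cluster.multiplicity, best_hit=hit, ambiguous=ambiguous,
    )
    if hit is None or hit.bit_score < thresholds.t_func:
        return record
    lineage = bundle.lineage_of_contig(hit.subject_id)
    record.genome_id = bundle.contig_to_genome[hit.subject_id]
    record.taxon_species = lineage.taxon("species")
    if hit.bit_score >= thresholds.t_genus:
        record.bin = "genus"
        record.taxon_genus = lineage.taxon("genus")
        record.taxon_family = lineage.taxon("family")
    elif hit.bit_score >= thresholds.t_family:
        record.bin = "family"
        record.taxon_family = lineage.taxon("family")
    else:
        record.bin = "function_only"
    return record


def assign_clusters(
    clusters: Iterable[ReadCluster],
    hits_by_cluster: dict,
    thresholds: Thresholds,
    bundle: ReferenceBundle,
) -> list:
    return [
        bin_read(c, hits_by_cluster.get(c.id, []), thresholds, bundle)
        for c in clusters
    ]


def bin_totals(records: Iterable[AssignmentRecord]) -> dict:
    totals = {b: 0 for b in BINS}
    for r in records:
        totals[r.bin] += r.multiplicity
    return totals


def phylo_profile(
    records: Iterable[AssignmentRecord],
    min_display_fraction: float = 0.02,
) -> dict:
    """Multiplicity-weighted rank-abundance profile at genus level.

    Family-binned reads pool into ``"family-classified"``; function-only and
    unassigned reads into ``"unclassified"``.  Genera below
    ``min_display_fraction`` collapse into ``"other"``.  Fractions sum to 1.
    """
    counts: dict = {}
    family_total = 0
    unclassified = 0
    total = 0
    for r in records:
        total += r.multiplicity
        if r.bin == "genus":
            counts[r.taxon_genus] = counts.get(r.taxon_genus, 0) + r.multiplicity
        elif r.bin == "family":
            family_total += r.multiplicity
        else:
            unclassified += r.multiplicity
    if total == 0:
        return {}
    profile: dict = {}
    other = 0
    for genus in sorted(counts):
        frac = counts[genus] / total
        if frac >= min_display_fraction:
            profile[genus] = frac
        else:
            other += counts[genus]
    if other:
        profile["other"] = other / total
    if family_total:
        profile["family-classified"] = family_total / total
    if unclassified:
        profile["unclassified"] = unclassified / total
    return profile


# ---------------------------------------------------------------------------
# paired-end congruence
# ---------------------------------------------------------------------------

@dataclass
class CongruenceReport:
    n_pairs_both_assigned: int = 0
    n_one_end_only: int = 0
    n_neither: int = 0
    same_genus: float = 0.0
    same_species: float = 0.0
    same_gene: float = 0.0
    same_cog: float = 0.0


def expand_to_reads(records: Iterable[AssignmentRecord],
                    clusters: Iterable[ReadCluster]) -> dict:
    """Per-read view of per-cluster assignments (via cluster member ids)."""
    members = {c.id: c.members for c in clusters}
    per_read: dict = {}
    for record in records:
        for read_id in members[record.cluster_id]:
            per_read[read_id] = record
    return per_read


def pair_congruence(records_left: dict, records_right: dict) -> CongruenceReport:
    """Agreement of independently assigned mates.

    Inputs map read id -> AssignmentRecord (mate suffixes already stripped,
    so the two dicts share key sets).  Congruence fractions are computed
    over pairs where *both* ends are genus-binned; pairs with exactly one
    end genus-binned are tallied separately.  Unpairable ids raise.
    """
    left_only = sorted(set(records_left) - set(records_right))
    right_only = sorted(set(records_right) - set(records_left))
    if left_only or right_only:
        raise ValueError(
            "unpairable read ids, e.g. "
            f"left-only={left_only[:3]} right-only={right_only[:3]}"
        )
    report = CongruenceReport()
    n_genus = n_species = n_gene = n_cog = 0
    for read_id in records_left:
        lrec, rrec = records_left[read_id], records_right[read_id]
        l_ok = lrec.bin == "genus"
        r_ok = rrec.bin == "genus"
        if l_ok and r_ok:
            report.n_pairs_both_assigned += 1
            n_genus += lrec.taxon_genus == rrec.taxon_genus
            n_species += (lrec.taxon_species is not None
                          and lrec.taxon_species == rrec.taxon_species)
            n_gene += (lrec.gene_id is not None and lrec.gene_id == rrec.gene_id)
            n_cog += (lrec.cog_id is not None and lrec.cog_id == rrec.cog_id)
        elif l_ok or r_ok:
            report.n_one_end_only += 1
        else:
            report.n_neither += 1
    if report.n_pairs_both_assigned:
        d = report.n_pairs_both_assigned
        report.same_genus = n_genus / d
        report.same_species = n_species / d
        report.same_gene = n_gene / d
        report.same_cog = n_cog / d
    return report


# ---------------------------------------------------------------------------
# salvage of unassigned reads
# ---------------------------------------------------------------------------

def subsample_unassigned(
    unassigned: Sequence[AssignmentRecord],
    fraction: float = 0.10,
    seed: int = 0,
) -> list:
    """Uniform sample without replacement of round(fraction * n) records.

    Banker's rounding (round-half-even) sets the sample size; a fixed seed
    reproduces the subset exactly.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = round(fraction * len(unassigned))
    rng = random.Random(seed)
    indices = sorted(rng.sample(range(len(unassigned)), n))
    return [unassigned[i] for i in indices]


@dataclass
class SalvageReport:
    n_input: int
    assigned_by_db: dict = field(default_factory=dict)     # db name -> count
    fractions_by_db: dict = field(default_factory=dict)    # db name -> fraction of input
    annotations: dict = field(default_factory=dict)        # cluster_id -> (db, protein, function)
    n_remaining: int = 0
    remaining_fraction: float = 0.0


def salvage(
    records: Sequence[AssignmentRecord],
    sequences: dict,
    protein_dbs: Sequence[tuple],
    min_bit: float = 40.0,
) -> SalvageReport:
    """Translated-search rescue of unassigned reads.

    ``protein_dbs`` is an ordered sequence of ``(name, proteins,
    functions)`` where ``proteins`` maps protein id -> amino-acid sequence
    and ``functions`` (may be empty) maps protein id -> annotation.
    Databases are tried in order; each only sees the reads every earlier
    database left unassigned.
    """
    if not protein_dbs:
        raise ValueError("at least one protein database is required")
    report = SalvageReport(n_input=len(records))
    pending = list(records)
    for name, proteins, functions in protein_dbs:
        still_pending = []
        n_assigned = 0
        for record in pending:
            hits = translated_search(sequences[record.cluster_id], proteins,
                                     min_bit=min_bit, query_id=record.cluster_id) \
                if proteins else []
            if hits:
                top = hits[0]
                report.annotations[record.cluster_id] = (
                    name, top.subject_id, functions.get(top.subject_id))
                n_assigned += 1
            else:
                still_pending.append(record)
        report.assigned_by_db[name] = n_assigned
        report.fractions_by_db[name] = (n_assigned / report.n_input
                                        if report.n_input else 0.0)
        pending = still_pending
    report.n_remaining = len(pending)
    report.remaining_fraction = (report.n_remaining / report.n_input
                                 if report.n_input else 0.0)
    return report
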
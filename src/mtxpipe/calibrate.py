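"""Bit-score threshold calibration by read simulation.

Error-free (optionally mutated) reads of known origin are drawn from the
protein-coding sequence of the reference genomes, re-aligned against the
full reference, and scored: at a candidate bit-score threshold *s* a read
counts as *assigned* when its best hit reaches *s*, and *correct* when the
best-hit genome carries the read's true taxon name at the rank under test
(for the COG rank: when the best-hit gene's COG equals the source gene's).
The confidence curve ``n_correct / n_assigned`` over all observed best-hit
bit scores yields, per rank, the minimal threshold meeting the target
confidence (0.80 for phylogenetic ranks, 0.95 for COG) — the procedure that
motivates the 148 / 110 / 74 binning cutoffs on full-scale references.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .aligner import GenomeAligner, ProteinScoringScheme, revcomp, translated_search
from .genes import INTERGENIC, classify_gene_read
from .iokit import ReferenceBundle, Thresholds

PHYLO_RANKS = ("species", "genus", "family", "order", "class", "phylum")
UNREACHABLE = "unreachable"


@dataclass
class LabeledRead:
    read_id: str
    sequence: str
    true_gene: str
    true_genome: str
    true_contig: str
    true_cog: Optional[str]


@dataclass
class CalibrationCurve:
    rank: str
    thresholds: np.ndarray          # ascending grid of observed best-hit bits
    n_assigned: np.ndarray
    n_correct: np.ndarray
    target_confidence: float
    extracted_threshold: object = UNREACHABLE  # float or the sentinel
    degenerate: bool = False

    @property
    def confidence(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_assigned > 0,
                            self.n_correct / np.maximum(self.n_assigned, 1), np.nan)


def simulate_calibration_reads(
    bundle: ReferenceBundle,
    n: int = 10000,
    length: int = 100,
    seed: int = 0,
    substitution_rate: float = 0.0,
) -> list:
    """Draw ``n`` reads uniformly over (gene, offset, strand) from coding sequence.

    Each read is labeled with its true gene, genome and COG.  Optional
    per-base substitution noise; error-free by default.  Genes shorter than
    ``length`` are excluded; if none qualifies this is an error.
    """
    eligible = [g for g in sorted(bundle.genes.values(), key=lambda g: g.gene_id)
                if g.length >= length]
    if not eligible:
        raise ValueError(f"no gene of length >= {length} in the reference")
    rng = random.Random(seed)
    # separate noise stream: layout is identical across substitution rates
    noise = random.Random(seed + 10_007)
    bases = "ACGT"
    reads = []
    for i in range(n):
        gene = rng.choice(eligible)
        offset = rng.randrange(gene.length - length + 1)
        start = gene.start + offset
        seq = bundle.contigs[gene.contig_id][start:start + length]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        if substitution_rate > 0:
            seq = "".join(
                noise.choice([b for b in bases if b != c])
                if noise.random() < substitution_rate else c
                for c in seq)
        reads.append(LabeledRead(
            read_id=f"calib_{i}", sequence=seq, true_gene=gene.gene_id,
            true_genome=gene.genome_id, true_contig=gene.contig_id,
            true_cog=gene.cog_id))
    return reads


def _mask_source(hits, read: LabeledRead, bundle: ReferenceBundle):
    gene = bundle.genes[read.true_gene]
    return [h for h in hits
            if not (h.subject_id == gene.contig_id
                    and h.subject_start < gene.end and h.subject_end > gene.start)]


def _curve_from_outcomes(bits: np.ndarray, correct: np.ndarray, rank: str,
                         target: float) -> CalibrationCurve:
    """Confidence curve on the exact grid of observed best-hit bit scores."""
    if bits.size == 0:
        return CalibrationCurve(rank=rank, thresholds=np.array([]),
                                n_assigned=np.array([], dtype=int),
                                n_correct=np.array([], dtype=int),
                                target_confidence=target)
    order = np.argsort(bits)
    bits_sorted = bits[order]
    correct_sorted = correct[order]
    grid = np.unique(bits_sorted)
    n = bits.size
    # reads with bit >= s: suffix counts at each grid point
    idx = np.searchsorted(bits_sorted, grid, side="left")
    total_correct = np.concatenate([np.cumsum(correct_sorted[::-1])[::-1], [0]])
    n_assigned = n - idx
    n_correct = total_correct[idx]
    curve = CalibrationCurve(rank=rank, thresholds=grid,
                             n_assigned=n_assigned.astype(int),
                             n_correct=n_correct.astype(int),
                             target_confidence=target)
    conf = curve.confidence
    ok = np.where((n_assigned > 0) & (conf >= target))[0]
    if ok.size:
        curve.extracted_threshold = float(grid[ok[0]])
    return curve


def calibration_curves(
    reads: Sequence[LabeledRead],
    aligner: GenomeAligner,
    bundle: ReferenceBundle,
    ranks: Sequence[str] = ("species", "genus", "family", "cog"),
    thresholds: Optional[Thresholds] = None,
    self_hit_policy: str = "leave-source-in",
) -> dict:
    """Per-rank confidence curves of the best-hit rule on labeled reads.

    ``self_hit_policy`` is ``"leave-source-in"`` (the read may hit its own
    source gene, matching a simulation drawn from the aligned database) or
    ``"mask-source-gene"`` (hits overlapping the source gene are discarded —
    a harder, leave-one-out-like variant).  A single-genome reference makes
    every phylogenetic rank trivially correct; such curves are flagged
    ``degenerate``.
    """
    thresholds = thresholds or Thresholds()
    if self_hit_policy not in ("leave-source-in", "mask-source-gene"):
        raise ValueError(f"unknown self_hit_policy {self_hit_policy!r}")
    bits_list = []
    outcome_by_rank = {rank: [] for rank in ranks}
    for read in reads:
        from .iokit import ReadCluster, Read  # local to avoid cycle at import time
        cluster = ReadCluster(Read(read.read_id, read.sequence,
                                   [40] * len(read.sequence)))
        result = aligner.two_pass_align([cluster])
        hits = result.hits_by_cluster[read.read_id]
        if self_hit_policy == "mask-source-gene":
            hits = _mask_source(hits, read, bundle)
        if not hits:
            continue
        best = hits[0]
        bits_list.append(best.bit_score)
        true_lineage = bundle.lineages[read.true_genome]
        hit_lineage = bundle.lineage_of_contig(best.subject_id)
        for rank in ranks:
            if rank == "cog":
                gene_id = classify_gene_read(best, bundle,
                                             thresholds.orf_overlap_fraction)
                predicted_cog = (bundle.genes[gene_id].cog_id
                                 if gene_id != INTERGENIC else None)
                correct = (read.true_cog is not None
                           and predicted_cog == read.true_cog)
            else:
                truth = true_lineage.taxon(rank)
                correct = (truth is not None
                           and hit_lineage.taxon(rank) == truth)
            outcome_by_rank[rank].append(correct)
    bits = np.asarray(bits_list, dtype=float)
    curves = {}
    single_genome = len(bundle.lineages) == 1
    for rank in ranks:
        target = thresholds.conf_cog if rank == "cog" else thresholds.conf_phylo
        curve = _curve_from_outcomes(
            bits, np.asarray(outcome_by_rank[rank], dtype=float), rank, target)
        if single_genome and rank != "cog":
            curve.degenerate = True
        curves[rank] = curve
    return curves


def calibrate_translated(
    reads: Sequence[LabeledRead],
    protein_db: dict,
    protein_labels: dict,
    target_confidence: float = 0.95,
    min_bit_grid_floor: float = 0.0,
    scheme_aa: Optional[ProteinScoringScheme] = None,
) -> CalibrationCurve:
    """Confidence curve of the translated search over protein bit scores.

    ``protein_labels`` maps protein id -> label (e.g. a COG); a read is
    correct when its best protein hit's label equals its true COG.  An
    empty protein database yields an all-unassigned curve.
    """
    bits_list = []
    outcomes = []
    for read in reads:
        hits = (translated_search(read.sequence, protein_db, scheme_aa=scheme_aa,
                                  min_bit=min_bit_grid_floor, query_id=read.read_id)
                if protein_db else [])
        if not hits:
            continue
        best = hits[0]
        bits_list.append(best.bit_score)
        outcomes.append(read.true_cog is not None
                        and protein_labels.get(best.subject_id) == read.true_cog)
    return _curve_from_outcomes(
        np.asarray(bits_list, dtype=float), np.asarray(outcomes, dtype=float),
        "cog_translated", target_confidence)


def curves_to_thresholds(curves: dict) -> dict:
    """Extracted thresholds as a JSON-ready dict (sentinel kept verbatim)."""
    return {rank: curve.extracted_threshold for rank, curve in curves.items()}
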
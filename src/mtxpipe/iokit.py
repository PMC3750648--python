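"""Shared data model, file formats, configuration and logging.

Conventions
-----------
All genomic and alignment coordinates are **0-based half-open on the forward
strand** internally.  External tabular alignment I/O uses the 1-based
inclusive 12-column convention (``outfmt 6``-like: qseqid sseqid pident
length mismatch gapopen qstart qend sstart send evalue bitscore), where
``sstart > send`` encodes a minus-strand hit.  Phred qualities are integers
(offset-33 ASCII in FASTQ); Illumina 1.9 data occupy [2, 40] but values up
to 60 are accepted with a warning.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, TextIO

from Bio import SeqIO
from intervaltree import IntervalTree

logger = logging.getLogger("mtxpipe")

VALID_BASES = frozenset("ACGTN")
RANK_ORDER = ("species", "genus", "family", "order", "class", "phylum")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Read:
    """A single sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: Sequence[int]
    mate: Optional[str] = None  # "left" | "right" | None

    def __post_init__(self) -> None:
        if len(self.sequence) == 0 or len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)} (both must be > 0)"
            )
        qmin, qmax = min(self.qualities), max(self.qualities)
        if qmin < 0 or qmax > 60:
            raise ValueError(
                f"read {self.id!r}: quality {qmin if qmin < 0 else qmax} outside [0, 60]"
            )
        if qmax > 40:
            warnings.warn(
                f"read {self.id!r}: quality above the Illumina 1.9 range [2, 40]",
                stacklevel=2,
            )


@dataclass
class ReadCluster:
    """A unique read sequence with the multiplicity of the pooled identical reads."""

    representative: Read
    multiplicity: int = 1
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("cluster multiplicity must be >= 1")
        if not self.members:
            self.members = [self.representative.id]

    @property
    def id(self) -> str:
        return self.representative.id

    @property
    def sequence(self) -> str:
        return self.representative.sequence


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: Optional[str] = None
    cog_id: Optional[str] = None
    ko_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid span [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TaxonomyLineage:
    genome_id: str
    ranks: dict

    def taxon(self, rank: str) -> Optional[str]:
        return self.ranks.get(rank)


@dataclass
class AlignmentHit:
    """One query-vs-subject local alignment (internal coordinates)."""

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    alignment_length: int
    identity: float
    bit_score: float
    raw_score: Optional[int] = None
    evalue: Optional[float] = None
    mismatches: int = 0
    gap_opens: int = 0

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if self.bit_score < 0:
            raise ValueError("bit_score must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass
class Thresholds:
    """Every numeric cutoff of the pipeline, in one configurable record."""

    q_min: float = 10.0            # mean-Phred read filter
    rrna_min_bit: float = 54.0     # filter-database removal cutoff
    t_func: float = 74.0           # function-only bin lower bound
    t_family: float = 110.0        # family bin lower bound
    t_genus: float = 148.0         # genus bin lower bound
    blastx_min_bit: float = 40.0   # translated-search salvage cutoff
    cog_evalue_max: float = 1e-6   # COG assignment from protein alignments
    capture_fraction: float = 0.95  # significant-gene selection
    salvage_fraction: float = 0.10  # unassigned-read subsample
    orf_overlap_fraction: float = 0.50  # gene vs intergenic rule
    conf_phylo: float = 0.80       # calibration target, phylogenetic ranks
    conf_cog: float = 0.95         # calibration target, COG
    word_size_pass1: int = 28
    word_size_pass2: int = 11
    calib_n_reads: int = 10000
    calib_read_len: int = 100

    def __post_init__(self) -> None:
        if not (self.t_func < self.t_family < self.t_genus):
            raise ValueError("bin thresholds must satisfy t_func < t_family < t_genus")
        if not (0 < self.capture_fraction <= 1):
            raise ValueError("capture_fraction must be in (0, 1]")
        if not (0 < self.orf_overlap_fraction <= 1):
            raise ValueError("orf_overlap_fraction must be in (0, 1]")
        for name in ("q_min", "rrna_min_bit", "blastx_min_bit", "cog_evalue_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "Thresholds":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class FilterRecord:
    """One sequence of the rRNA/tRNA/phiX/adapter filter database."""

    id: str
    sequence: str
    category: str  # rRNA | tRNA | phiX | adapter
    domain: str    # bacteria | archaea | eukaryota | none

    def __post_init__(self) -> None:
        if self.category not in ("rRNA", "tRNA", "phiX", "adapter"):
            raise ValueError(f"filter record {self.id}: unknown category {self.category!r}")
        if self.category in ("phiX", "adapter") and self.domain != "none":
            raise ValueError(f"filter record {self.id}: {self.category} must have domain 'none'")
        if self.domain not in ("bacteria", "archaea", "eukaryota", "none"):
            raise ValueError(f"filter record {self.id}: unknown domain {self.domain!r}")


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def _open_text(path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_fastq(path, mate: Optional[str] = None) -> Iterator[Read]:
    """Stream 4-line FASTQ records (phred+33, gzip transparently handled).

    Malformed records (length mismatch, truncated file) raise ``ValueError``
    naming the 1-based record index.
    """
    with _open_text(path) as handle:
        record_index = 0
        while True:
            header = handle.readline()
            if not header:
                return
            record_index += 1
            seq = handle.readline().rstrip("\n")
            plus = handle.readline()
            qual = handle.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record {record_index} in {path}")
            if not qual or len(seq) != len(qual):
                raise ValueError(
                    f"FASTQ record {record_index} in {path}: sequence length "
                    f"{len(seq)} != quality length {len(qual)}"
                )
            read_id = header[1:].split()[0]
            qualities = [ord(c) - 33 for c in qual]
            yield Read(id=read_id, sequence=seq.upper(), qualities=qualities, mate=mate)


def write_fastq(reads: Iterable[Read], path) -> int:
    n = 0
    with open(path, "w") as out:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            out.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path) -> dict:
    """FASTA -> ordered ``{record_id: uppercase sequence}``."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(records: dict, path, width: int = 80) -> None:
    with open(path, "w") as out:
        for name, seq in records.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# tabular alignment dialect (12-column, 1-based inclusive)
# ---------------------------------------------------------------------------

def hit_to_table_line(hit: AlignmentHit) -> str:
    if hit.strand == "+":
        sstart, send = hit.subject_start + 1, hit.subject_end
    else:
        sstart, send = hit.subject_end, hit.subject_start + 1
    evalue = hit.evalue if hit.evalue is not None else 0.0
    return "\t".join([
        hit.query_id,
        hit.subject_id,
        f"{hit.identity * 100:.3f}",
        str(hit.alignment_length),
        str(hit.mismatches),
        str(hit.gap_opens),
        str(hit.query_start + 1),
        str(hit.query_end),
        str(sstart),
        str(send),
        f"{evalue:.3g}",
        f"{hit.bit_score:.2f}",
    ])


def write_alignment_table(hits: Iterable[AlignmentHit], path) -> int:
    n = 0
    with open(path, "w") as out:
        for hit in hits:
            out.write(hit_to_table_line(hit) + "\n")
            n += 1
    return n


def read_alignment_table(path) -> Iterator[AlignmentHit]:
    """Parse a 12-column tabular alignment file into internal coordinates."""
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                length = int(fields[3])
                mismatches = int(fields[4])
                gap_opens = int(fields[5])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bit = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if sstart <= send:
                strand, s0, s1 = "+", sstart - 1, send
            else:
                strand, s0, s1 = "-", send - 1, sstart
            yield AlignmentHit(
                query_id=fields[0],
                subject_id=fields[1],
                query_start=qstart - 1,
                query_end=qend,
                subject_start=s0,
                subject_end=s1,
                strand=strand,
                alignment_length=length,
                identity=pident / 100.0,
                bit_score=bit,
                evalue=evalue,
                mismatches=mismatches,
                gap_opens=gap_opens,
            )


# ---------------------------------------------------------------------------
# reference bundle
# ---------------------------------------------------------------------------

class ReferenceBundle:
    """Indexed genomes + gene models + lineages + COG/KO maps.

    Supports position lookup of genes (interval trees per contig),
    genome -> lineage and gene -> COG/KO resolution.  The contig -> genome
    map is derived from the gene table; a contig with no annotated gene is
    assumed to be its own genome (contig_id == genome_id).
    """

    def __init__(
        self,
        contigs: dict,
        genes: Sequence[GeneModel],
        lineages: dict,
        contig_to_genome: Optional[dict] = None,
    ) -> None:
        self.contigs = contigs
        self.genes = {g.gene_id: g for g in genes}
        if len(self.genes) != len(genes):
            raise ValueError("gene_id values must be unique within a reference set")
        self.lineages = lineages
        self.contig_to_genome = dict(contig_to_genome or {})
        self._trees: dict = {}
        for gene in genes:
            if gene.contig_id not in contigs:
                raise ValueError(
                    f"gene {gene.gene_id} references unknown contig {gene.contig_id!r}"
                )
            if gene.end > len(contigs[gene.contig_id]):
                raise ValueError(
                    f"gene {gene.gene_id} extends past the end of contig {gene.contig_id}"
                )
            self.contig_to_genome.setdefault(gene.contig_id, gene.genome_id)
            self._trees.setdefault(gene.contig_id, IntervalTree()).addi(
                gene.start, gene.end, gene
            )
        for contig_id in contigs:
            self.contig_to_genome.setdefault(contig_id, contig_id)
        missing = sorted(
            {g for g in self.contig_to_genome.values() if g not in lineages}
        )
        if missing:
            raise ValueError(f"genomes missing a taxonomy lineage: {missing}")
        for genome_id, lineage in lineages.items():
            if lineage.taxon("genus") is None or lineage.taxon("family") is None:
                raise ValueError(
                    f"lineage for {genome_id} must include at least genus and family"
                )

    @property
    def genome_ids(self) -> list:
        return sorted(self.lineages)

    def genes_overlapping(self, contig_id: str, start: int, end: int) -> list:
        tree = self._trees.get(contig_id)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)), key=lambda g: g.gene_id)

    def lineage_of_contig(self, contig_id: str) -> TaxonomyLineage:
        genome = self.contig_to_genome.get(contig_id)
        if genome is None or genome not in self.lineages:
            raise KeyError(f"no lineage for contig {contig_id!r}")
        return self.lineages[genome]

    def genes_of_genome(self, genome_id: str) -> list:
        return sorted(
            (g for g in self.genes.values() if g.genome_id == genome_id),
            key=lambda g: g.gene_id,
        )


def _read_tsv_rows(path) -> Iterator[list]:
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield line.split("\t")


def load_gene_table(path) -> list:
    """TSV: gene_id genome_id contig_id start end strand [cog_id ko_id product]."""
    genes = []
    for row in _read_tsv_rows(path):
        if row[0] == "gene_id":
            continue
        pad = row + [""] * (9 - len(row))
        genes.append(GeneModel(
            gene_id=pad[0], genome_id=pad[1], contig_id=pad[2],
            start=int(pad[3]), end=int(pad[4]), strand=pad[5],
            cog_id=pad[6] or None, ko_id=pad[7] or None, product=pad[8] or None,
        ))
    return genes


def load_taxonomy_table(path) -> dict:
    """TSV: genome_id species genus family order class phylum (blank = absent)."""
    lineages = {}
    for row in _read_tsv_rows(path):
        if row[0] == "genome_id":
            continue
        pad = row + [""] * (7 - len(row))
        ranks = {r: pad[i + 1] for i, r in enumerate(RANK_ORDER) if pad[i + 1]}
        lineages[pad[0]] = TaxonomyLineage(genome_id=pad[0], ranks=ranks)
    return lineages


def load_two_column_map(path) -> dict:
    return {row[0]: row[1] for row in _read_tsv_rows(path) if len(row) >= 2}


def load_references(
    genome_fasta,
    gene_table,
    taxonomy_table,
    cog_map=None,
    ko_map=None,
) -> ReferenceBundle:
    """Load and cross-validate the reference genome bundle.

    ``cog_map``/``ko_map`` (gene_id -> COG/KO TSVs) override blank columns of
    the gene table when provided.
    """
    contigs = read_fasta(genome_fasta)
    genes = load_gene_table(gene_table)
    lineages = load_taxonomy_table(taxonomy_table)
    cogs = load_two_column_map(cog_map) if cog_map else {}
    kos = load_two_column_map(ko_map) if ko_map else {}
    if cogs or kos:
        genes = [
            replace(g, cog_id=cogs.get(g.gene_id, g.cog_id), ko_id=kos.get(g.gene_id, g.ko_id))
            for g in genes
        ]
    return ReferenceBundle(contigs=contigs, genes=genes, lineages=lineages)


def load_filter_db(fasta_path, meta_path) -> list:
    """Filter FASTA + metadata TSV (record_id, category, domain) -> FilterRecords."""
    sequences = read_fasta(fasta_path)
    meta = {row[0]: (row[1], row[2]) for row in _read_tsv_rows(meta_path)
            if row[0] != "record_id"}
    records = []
    for name, seq in sequences.items():
        if name not in meta:
            raise ValueError(f"filter record {name!r} has no category/domain metadata")
        category, domain = meta[name]
        records.append(FilterRecord(id=name, sequence=seq, category=category, domain=domain))
    return records
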
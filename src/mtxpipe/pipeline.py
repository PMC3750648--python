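"""End-to-end driver: preprocess -> rRNA filter -> two-pass alignment ->
binning -> gene counting -> functional profiling, with a run manifest whose
stage-accounting identities must hold exactly.

Stages communicate through files in the documented text formats, so any
stage can be re-fed from an external tool's output (e.g. real MegaBLAST /
BLASTN tabular files instead of the built-in aligner).  Each stage writes a
marker with a hash of its inputs; reruns with ``resume=True`` reuse stage
outputs whose markers still match.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from . import __version__
from .aligner import GenomeAligner, ScoringScheme
from .assign import (AssignmentRecord, assign_clusters, bin_totals,
                     expand_to_reads, pair_congruence, phylo_profile)
from .genes import build_expression_table, coverage_histogram
from .iokit import (Read, ReadCluster, ReferenceBundle, Thresholds,
                    load_filter_db, load_references, read_fastq,
                    read_alignment_table, write_alignment_table, write_fasta)
from .preprocess import dereplicate, filter_by_quality
from .profiles import cog_category_distribution, export_ipath
from .rrna_filter import run_filter, summarize_removed


@dataclass
class RunManifest:
    """Per-stage read accounting plus the configuration snapshot."""

    n_raw: int = 0
    n_quality_failed: int = 0
    n_quality_passed: int = 0
    n_unique_clusters: int = 0
    sum_multiplicities: int = 0
    rrna_removed_reads_pass1: int = 0
    rrna_removed_reads_pass2: int = 0
    rrna_removed_clusters: int = 0
    n_mrna_clusters: int = 0
    n_mrna_reads: int = 0
    bin_read_totals: dict = field(default_factory=dict)
    gene_assigned_reads: int = 0
    intergenic_reads: int = 0
    n_genes_identified: int = 0
    n_significant_genes: int = 0
    significant_gene_reads: int = 0
    removed_composition: dict = field(default_factory=dict)
    pair_congruence: Optional[dict] = None
    config: dict = field(default_factory=dict)
    seed: int = 0
    version: str = __version__
    backend: str = "builtin"

    def conservation_violations(self) -> list:
        """Every stage-partition identity; empty list = all hold exactly."""
        v = []
        if self.n_raw != self.n_quality_failed + self.n_quality_passed:
            v.append("raw != quality_failed + quality_passed")
        if self.sum_multiplicities != self.n_quality_passed:
            v.append("sum of cluster multiplicities != quality-passed reads")
        if (self.rrna_removed_reads_pass1 + self.rrna_removed_reads_pass2
                + self.n_mrna_reads != self.sum_multiplicities):
            v.append("filter partition does not cover the unique-read total")
        binned = sum(self.bin_read_totals.get(b, 0)
                     for b in ("genus", "family", "function_only", "unassigned"))
        if binned != self.n_mrna_reads:
            v.append("bin totals != mRNA read total")
        coding = sum(self.bin_read_totals.get(b, 0)
                     for b in ("genus", "family", "function_only"))
        if self.gene_assigned_reads + self.intergenic_reads != coding:
            v.append("gene + intergenic reads != genome-assigned reads")
        if self.significant_gene_reads > self.gene_assigned_reads:
            v.append("significant reads exceed gene-assigned reads")
        return v

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")


def _stage_hash(*parts) -> str:
    h = hashlib.sha256()
    for part in parts:
        h.update(repr(part).encode())
    return h.hexdigest()[:16]


def _marker_ok(marker: Path, digest: str, outputs: list) -> bool:
    if not marker.exists():
        return False
    if json.loads(marker.read_text()).get("hash") != digest:
        return False
    return all(Path(p).exists() for p in outputs)


def _write_marker(marker: Path, digest: str) -> None:
    marker.write_text(json.dumps({"hash": digest}) + "\n")


def write_clusters(clusters, fasta_path, counts_path) -> None:
    write_fasta({c.id: c.sequence for c in clusters}, fasta_path)
    with open(counts_path, "w") as out:
        out.write("cluster_id\tmultiplicity\tmembers\n")
        for c in clusters:
            out.write(f"{c.id}\t{c.multiplicity}\t{','.join(c.members)}\n")


def read_clusters(fasta_path, counts_path) -> list:
    from .iokit import read_fasta
    seqs = read_fasta(fasta_path)
    clusters = []
    with open(counts_path) as fh:
        next(fh)
        for line in fh:
            cluster_id, mult, members = line.rstrip("\n").split("\t")
            clusters.append(ReadCluster(
                representative=Read(cluster_id, seqs[cluster_id],
                                    [40] * len(seqs[cluster_id])),
                multiplicity=int(mult), members=members.split(",")))
    return clusters


def write_assignments(records, path) -> None:
    with open(path, "w") as out:
        out.write("cluster_id\tmultiplicity\tbin\tgenome_id\tgenus\tfamily\t"
                  "species\tgene_id\tcog_id\tbit_score\tambiguous\n")
        for r in records:
            bit = f"{r.best_hit.bit_score:.2f}" if r.best_hit else ""
            out.write("\t".join([
                r.cluster_id, str(r.multiplicity), r.bin, r.genome_id or "",
                r.taxon_genus or "", r.taxon_family or "", r.taxon_species or "",
                r.gene_id or "", r.cog_id or "", bit, str(int(r.ambiguous)),
            ]) + "\n")


def run_pipeline(config: dict, resume: bool = False) -> RunManifest:
    """Execute the full pipeline described by ``config``.

    Required keys: ``reads`` (FASTQ path), ``genome_fasta``, ``gene_table``,
    ``taxonomy_table``, ``filter_fasta``, ``filter_meta``, ``outdir``.
    Optional: ``mate_reads`` (right-mate FASTQ; enables the paired-end
    congruence report), ``cog_map``, ``ko_map``, ``thresholds`` (dict of
    overrides), ``seed``, ``alignments`` (precomputed tabular alignment
    file replacing the built-in aligner).  Any stage error aborts with the
    stage name; the partial manifest is written alongside.
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = Thresholds(**config.get("thresholds", {}))
    seed = int(config.get("seed", 0))
    manifest = RunManifest(config={k: str(v) for k, v in config.items()},
                           seed=seed)
    try:
        bundle = load_references(
            config["genome_fasta"], config["gene_table"], config["taxonomy_table"],
            cog_map=config.get("cog_map"), ko_map=config.get("ko_map"))
    except KeyError as exc:
        raise RuntimeError(f"stage load_references: missing config entry {exc}") from exc
    filter_db = load_filter_db(config["filter_fasta"], config["filter_meta"])

    sides = [("", config["reads"])]
    if config.get("mate_reads"):
        sides = [("left_", config["reads"]), ("right_", config["mate_reads"])]

    per_side = {}
    for prefix, reads_path in sides:
        per_side[prefix] = _run_one_side(
            prefix, reads_path, bundle, filter_db, thresholds, config, outdir,
            manifest if prefix in ("", "left_") else None, resume)

    if len(sides) == 2:
        left = per_side["left_"]
        right = per_side["right_"]
        left_reads = expand_to_reads(left["records"], left["clusters"])
        right_reads = expand_to_reads(right["records"], right["clusters"])
        common = set(left_reads) & set(right_reads)
        report = pair_congruence({k: left_reads[k] for k in common},
                                 {k: right_reads[k] for k in common})
        manifest.pair_congruence = {
            "n_pairs_both_assigned": report.n_pairs_both_assigned,
            "n_one_end_only": report.n_one_end_only,
            "same_genus": report.same_genus,
            "same_species": report.same_species,
            "same_gene": report.same_gene,
            "same_cog": report.same_cog,
        }

    violations = manifest.conservation_violations()
    if violations:
        manifest.to_json(outdir / "manifest.json")
        raise AssertionError(f"manifest conservation violated: {violations}")
    manifest.to_json(outdir / "manifest.json")
    side = per_side.get("", per_side.get("left_"))
    (outdir / "report.txt").write_text(
        render_report(manifest, side["profile_total"], side["phylo"]))
    return manifest


def _run_one_side(prefix, reads_path, bundle, filter_db, thresholds, config,
                  outdir: Path, manifest: Optional[RunManifest], resume: bool):
    # --- stage 1: quality filter + dereplication -------------------------
    unique_fasta = outdir / f"{prefix}unique.fasta"
    counts_tsv = outdir / f"{prefix}counts.tsv"
    qc_json = outdir / f"{prefix}qc.json"
    marker = outdir / f"{prefix}preprocess.done.json"
    digest = _stage_hash("preprocess", reads_path, thresholds.q_min)
    if not (resume and _marker_ok(marker, digest, [unique_fasta, counts_tsv, qc_json])):
        reads = read_fastq(reads_path)
        passed, report = filter_by_quality(reads, thresholds.q_min)
        clusters = dereplicate(passed)
        write_clusters(clusters, unique_fasta, counts_tsv)
        qc_json.write_text(json.dumps({
            "n_input": report.n_input,
            "n_quality_failed": report.n_quality_failed,
            "n_passed": report.n_passed,
            "phred_band_counts": report.phred_band_counts}, indent=1) + "\n")
        _write_marker(marker, digest)
    qc = json.loads(qc_json.read_text())
    clusters = read_clusters(unique_fasta, counts_tsv)
    if manifest:
        manifest.n_raw = qc["n_input"]
        manifest.n_quality_failed = qc["n_quality_failed"]
        manifest.n_quality_passed = qc["n_passed"]
        manifest.n_unique_clusters = len(clusters)
        manifest.sum_multiplicities = sum(c.multiplicity for c in clusters)

    # --- stage 2: rRNA/tRNA/phiX/adapter filter --------------------------
    partition = run_filter(clusters, filter_db, thresholds)
    ledger = outdir / f"{prefix}removal_ledger.tsv"
    with open(ledger, "w") as out:
        out.write("cluster_id\tmultiplicity\tpass\tcategory\tdomain\tbit_score\trecord\n")
        for rm in partition.removed:
            bit = f"{rm.bit_score:.2f}" if rm.bit_score is not None else ""
            out.write(f"{rm.cluster.id}\t{rm.cluster.multiplicity}\t{rm.pass_number}\t"
                      f"{rm.category}\t{rm.domain}\t{bit}\t{rm.matched_record or ''}\n")
    mrna_clusters = partition.retained
    write_clusters(mrna_clusters, outdir / f"{prefix}mrna.fasta",
                   outdir / f"{prefix}mrna_counts.tsv")
    if manifest:
        manifest.rrna_removed_reads_pass1 = sum(
            r.cluster.multiplicity for r in partition.removed if r.pass_number == 1)
        manifest.rrna_removed_reads_pass2 = sum(
            r.cluster.multiplicity for r in partition.removed if r.pass_number == 2)
        manifest.rrna_removed_clusters = len(partition.removed)
        manifest.n_mrna_clusters = len(mrna_clusters)
        manifest.n_mrna_reads = sum(c.multiplicity for c in mrna_clusters)
        manifest.removed_composition = summarize_removed(partition)

    # --- stage 3: two-pass genome alignment ------------------------------
    alignments_tsv = outdir / f"{prefix}alignments.tsv"
    if config.get("alignments"):
        hits_by_cluster: dict = {}
        for hit in read_alignment_table(config["alignments"]):
            hits_by_cluster.setdefault(hit.query_id, []).append(hit)
        if manifest:
            manifest.backend = "external"
    else:
        aligner = GenomeAligner(bundle.contigs, thresholds, ScoringScheme())
        result = aligner.two_pass_align(mrna_clusters)
        hits_by_cluster = result.hits_by_cluster
        best_hits = [hits[0] for hits in hits_by_cluster.values() if hits]
        best_hits.sort(key=lambda h: h.query_id)
        write_alignment_table(best_hits, alignments_tsv)

    # --- stage 4: binning + gene classification --------------------------
    records = assign_clusters(mrna_clusters, hits_by_cluster, thresholds, bundle)
    table = build_expression_table(records, bundle, thresholds)
    write_assignments(records, outdir / f"{prefix}assignments.tsv")
    table.to_frame().to_csv(outdir / f"{prefix}expression.tsv", sep="\t", index=False)
    coverage_histogram(table).to_csv(outdir / f"{prefix}coverage_hist.tsv",
                                     sep="\t", index=False)
    if manifest:
        manifest.bin_read_totals = bin_totals(records)
        manifest.gene_assigned_reads = table.gene_assigned_total
        manifest.intergenic_reads = table.intergenic_count
        manifest.n_genes_identified = len(table.counts)
        manifest.n_significant_genes = len(table.significant)
        manifest.significant_gene_reads = sum(
            table.counts[g] for g in table.significant)

    # --- stage 5: functional profiles ------------------------------------
    gene_to_cog = {g.gene_id: g.cog_id for g in bundle.genes.values() if g.cog_id}
    gene_to_ko = {g.gene_id: g.ko_id for g in bundle.genes.values() if g.ko_id}
    cog_to_category = _cog_categories_from_products(bundle)
    profile_total = cog_category_distribution(records, gene_to_cog, cog_to_category,
                                              scope="total", thresholds=thresholds)
    phylo = phylo_profile(records)
    (outdir / f"{prefix}profile_total.tsv").write_text(
        "category\tfraction\n" + "".join(
            f"{k}\t{v:.6f}\n" for k, v in profile_total.category_fractions.items()))
    (outdir / f"{prefix}phylo_profile.tsv").write_text(
        "taxon\tfraction\n" + "".join(f"{k}\t{v:.6f}\n" for k, v in phylo.items()))
    (outdir / f"{prefix}ipath_selection.txt").write_text(
        export_ipath(table, gene_to_ko))

    return {"clusters": clusters, "mrna_clusters": mrna_clusters,
            "records": records, "table": table,
            "profile_total": profile_total, "phylo": phylo}


def _cog_categories_from_products(bundle: ReferenceBundle) -> dict:
    """COG -> category map; synthetic references encode the category in the
    gene product field ("... category X"), real references supply a map."""
    mapping: dict = {}
    for gene in bundle.genes.values():
        if gene.cog_id and gene.product and " category " in gene.product:
            mapping[gene.cog_id] = gene.product.rsplit(" category ", 1)[1]
        elif gene.cog_id:
            mapping.setdefault(gene.cog_id, "S")
    return mapping


def render_report(manifest: RunManifest, profile_total=None, phylo=None) -> str:
    """Human-readable run summary: phylogenetic profile, bin breakdown,
    COG categories and the stage accounting table."""
    lines = ["# mtxpipe run report", ""]
    lines.append("## Phylogenetic profile (genus level, read fractions)")
    if phylo:
        for taxon, frac in phylo.items():
            lines.append(f"  {taxon:<24s} {frac:8.4f}")
    else:
        lines.append("  (no data)")
    lines.append("")
    lines.append("## Read bins (multiplicity-weighted)")
    for b in ("genus", "family", "function_only", "unassigned"):
        lines.append(f"  {b:<16s} {manifest.bin_read_totals.get(b, 0):>10d}")
    lines.append(f"  {'gene-assigned':<16s} {manifest.gene_assigned_reads:>10d}")
    lines.append(f"  {'intergenic':<16s} {manifest.intergenic_reads:>10d}")
    lines.append("")
    lines.append("## COG categories (fractions of category-assigned reads)")
    if profile_total is not None and profile_total.category_fractions:
        for code, frac in profile_total.category_fractions.items():
            lines.append(f"  {code} {frac:8.4f}")
    else:
        lines.append("  (no data)")
    lines.append("")
    lines.append("## Stage accounting")
    lines.append(f"  raw reads            {manifest.n_raw:>10d}")
    lines.append(f"  quality-failed       {manifest.n_quality_failed:>10d}")
    lines.append(f"  unique clusters      {manifest.n_unique_clusters:>10d}")
    lines.append(f"  rRNA removed (p1)    {manifest.rrna_removed_reads_pass1:>10d}")
    lines.append(f"  rRNA removed (p2)    {manifest.rrna_removed_reads_pass2:>10d}")
    lines.append(f"  mRNA reads           {manifest.n_mrna_reads:>10d}")
    lines.append(f"  genes identified     {manifest.n_genes_identified:>10d}")
    lines.append(f"  significant genes    {manifest.n_significant_genes:>10d}")
    violations = manifest.conservation_violations()
    if violations:
        lines.append("")
        lines.append("## WARNING: conservation identities violated")
        for v in violations:
            lines.append(f"  FAILED: {v}")
    return "\n".join(lines) + "\n"
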
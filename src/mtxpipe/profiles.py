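"""COG/KO functional aggregation, normalization, iPath export, comparisons.

Total COG-category profiles use all reads binned at bit >= 74; genus-scoped
profiles are restricted to reads binned at genus level (bit >= 148) for that
genus.  Whole-genome gene complements serve as expression-independent
baseline profiles.  Cross-dataset comparability comes from scaling each
dataset's gene counts to the mean total mRNA read count:

    normalized = count / dataset_total * mean(dataset totals)

so each dataset's normalized total equals the mean total exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

from .assign import AssignmentRecord
from .genes import INTERGENIC, GeneExpressionTable
from .iokit import ReferenceBundle, Thresholds

_POORLY_CHARACTERIZED = {"R", "S"}


def cog_category_table() -> pd.DataFrame:
    """The standard one-letter COG functional category definitions."""
    with resources.files("mtxpipe.data").joinpath("cog_categories.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def known_category_codes() -> set:
    return set(cog_category_table()["code"])


@dataclass
class FunctionalProfile:
    scope: str                                   # "total" | "genus:<name>" | "genome-baseline:<id>"
    category_fractions: dict = field(default_factory=dict)
    category_counts: dict = field(default_factory=dict)
    cog_counts: dict = field(default_factory=dict)
    no_cog_count: int = 0
    total_reads: int = 0


def assign_cog(
    gene_ids: Iterable[str],
    cog_map: Optional[dict] = None,
    protein_hits: Optional[dict] = None,
    evalue_max: float = 1e-6,
) -> dict:
    """gene -> COG resolution.

    A precomputed ``cog_map`` row is used verbatim.  Otherwise the gene's
    best protein alignment (``protein_hits``: gene -> list of (cog_id,
    evalue), best first) assigns its COG when evalue < ``evalue_max``.
    """
    cog_map = cog_map or {}
    protein_hits = protein_hits or {}
    result: dict = {}
    for gene_id in gene_ids:
        if gene_id in cog_map:
            result[gene_id] = cog_map[gene_id]
            continue
        hits = protein_hits.get(gene_id)
        if hits:
            cog_id, ev = hits[0]
            if ev < evalue_max:
                result[gene_id] = cog_id
    return result


def normalize_counts(tables: dict) -> dict:
    """Scale each dataset's gene counts to the mean total across datasets.

    ``tables`` maps dataset name -> {gene: count}.  Returns the same shape
    with float values; a dataset with zero total raises (it cannot be
    scaled).
    """
    if not tables:
        raise ValueError("at least one dataset is required")
    totals = {name: sum(counts.values()) for name, counts in tables.items()}
    for name, total in totals.items():
        if total == 0:
            raise ValueError(f"dataset {name!r} has zero total count")
    mean_total = sum(totals.values()) / len(totals)
    return {
        name: {g: c / totals[name] * mean_total for g, c in counts.items()}
        for name, counts in tables.items()
    }


def cog_category_distribution(
    records: Iterable[AssignmentRecord],
    gene_to_cog: dict,
    cog_to_category: dict,
    scope: str = "total",
    thresholds: Optional[Thresholds] = None,
) -> FunctionalProfile:
    """Multiplicity-weighted COG category profile of gene-assigned reads.

    ``scope="total"`` uses every read binned at bit >= t_func;
    ``scope="genus:<name>"`` restricts to genus-binned reads of that genus.
    Reads on genes without a COG tally as "no COG" (excluded from the
    category fractions' denominator).  Unknown category codes raise.
    """
    thresholds = thresholds or Thresholds()
    valid = known_category_codes()
    profile = FunctionalProfile(scope=scope)
    genus = scope.split(":", 1)[1] if scope.startswith("genus:") else None
    cat_counts: dict = {}
    for record in records:
        if record.gene_id in (None, INTERGENIC):
            continue
        if genus is not None:
            if record.bin != "genus" or record.taxon_genus != genus:
                continue
        elif record.bin not in ("genus", "family", "function_only"):
            continue
        profile.total_reads += record.multiplicity
        cog = gene_to_cog.get(record.gene_id)
        if cog is None:
            profile.no_cog_count += record.multiplicity
            continue
        profile.cog_counts[cog] = profile.cog_counts.get(cog, 0) + record.multiplicity
        category = cog_to_category[cog]
        for code in category:  # multi-letter categories split per code
            if code not in valid:
                raise ValueError(f"unknown COG category code {code!r}")
            cat_counts[code] = cat_counts.get(code, 0) + record.multiplicity
    total = sum(cat_counts.values())
    profile.category_counts = dict(sorted(cat_counts.items()))
    if total:
        profile.category_fractions = {k: v / total for k, v in profile.category_counts.items()}
    return profile


def genome_baseline_profile(
    bundle: ReferenceBundle,
    genome_id: str,
    cog_to_category: dict,
) -> FunctionalProfile:
    """Category fractions of a genome's annotated gene complement.

    Each gene weighs once; genes without a COG are excluded from the
    denominator and reported separately.
    """
    profile = FunctionalProfile(scope=f"genome-baseline:{genome_id}")
    cat_counts: dict = {}
    for gene in bundle.genes_of_genome(genome_id):
        if gene.cog_id is None:
            profile.no_cog_count += 1
            continue
        profile.cog_counts[gene.cog_id] = profile.cog_counts.get(gene.cog_id, 0) + 1
        for code in cog_to_category[gene.cog_id]:
            cat_counts[code] = cat_counts.get(code, 0) + 1
    total = sum(cat_counts.values())
    profile.category_counts = dict(sorted(cat_counts.items()))
    if total:
        profile.category_fractions = {k: v / total for k, v in profile.category_counts.items()}
    return profile


def split_characterized(profile: FunctionalProfile) -> dict:
    """Fraction of category-weighted reads with vs without a known function
    (R and S count as poorly characterized)."""
    known = sum(v for k, v in profile.category_counts.items()
                if k not in _POORLY_CHARACTERIZED)
    poor = sum(v for k, v in profile.category_counts.items()
               if k in _POORLY_CHARACTERIZED)
    total = known + poor
    if total == 0:
        return {"characterized": 0.0, "poorly_characterized": 0.0}
    return {"characterized": known / total, "poorly_characterized": poor / total}


def export_ipath(
    table: GeneExpressionTable,
    gene_to_ko: dict,
    use_normalized: bool = False,
) -> str:
    """iPath selection text: one ``<KO> W<width>`` line per expressed KO.

    Width = log2 of the KO's aggregated multiplicity-weighted read count,
    rounded to 2 decimals.  Raw counts are the default ("read count"
    semantics); ``use_normalized`` switches to the normalized values.
    """
    source = table.normalized if use_normalized else table.counts
    ko_counts: dict = {}
    for gene_id, count in source.items():
        ko = gene_to_ko.get(gene_id)
        if ko is not None and count >= 1:
            ko_counts[ko] = ko_counts.get(ko, 0) + count
    lines = [f"{ko} W{math.log2(count):.2f}" for ko, count in sorted(ko_counts.items())]
    return "\n".join(lines) + ("\n" if lines else "")


@dataclass
class CorrelationReport:
    pairs: dict  # (name_a, name_b) -> (pearson_r, p_value, n_keys)


def compare_datasets(tables: dict, normalize: bool = True) -> CorrelationReport:
    """Pearson r (exact t-transform p, n-2 df) for each dataset pair.

    Counts are compared on the union of keys, absent entries as 0, after
    normalization.  Fewer than 3 keys in the union is an error.
    """
    if len(tables) < 2:
        raise ValueError("at least two datasets are required")
    if normalize:
        tables = normalize_counts(tables)
    names = sorted(tables)
    report = CorrelationReport(pairs={})
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            keys = sorted(set(tables[a]) | set(tables[b]))
            if len(keys) < 3:
                raise ValueError(
                    f"datasets {a!r} and {b!r} share too few keys ({len(keys)} < 3)")
            xs = [tables[a].get(k, 0.0) for k in keys]
            ys = [tables[b].get(k, 0.0) for k in keys]
            r, p = stats.pearsonr(xs, ys)
            report.pairs[(a, b)] = (float(r), float(p), len(keys))
    return report
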
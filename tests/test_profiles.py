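"""Functional profiling: COG assignment/aggregation, normalization, iPath,
cross-dataset correlation."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from mtxpipe.assign import AssignmentRecord
from mtxpipe.genes import GeneExpressionTable
from mtxpipe.iokit import GeneModel, ReferenceBundle, TaxonomyLineage
from mtxpipe.profiles import (assign_cog, cog_category_distribution,
                              cog_category_table, compare_datasets,
                              export_ipath, genome_baseline_profile,
                              normalize_counts, split_characterized)


class TestAssignCog:
    def test_precomputed_map_used_verbatim(self):
        result = assign_cog(["g1"], cog_map={"g1": "COG9"},
                            protein_hits={"g1": [("COG1", 1e-30)]})
        assert result == {"g1": "COG9"}

    def test_evalue_below_cutoff_assigns(self):
        assert assign_cog(["g1"], protein_hits={"g1": [("COG1", 1e-7)]}) == \
            {"g1": "COG1"}

    def test_evalue_above_cutoff_rejects(self):
        assert assign_cog(["g1"], protein_hits={"g1": [("COG1", 1e-5)]}) == {}


class TestNormalize:
    def test_worked_example(self):
        tables = {"A": {"g": 10, "h": 90}, "B": {"g": 300}}
        normalized = normalize_counts(tables)
        # totals {A:100, B:300}, mean 200 -> 10/100*200 = 20
        assert normalized["A"]["g"] == pytest.approx(20.0)

    def test_single_dataset_identity(self):
        tables = {"A": {"g": 10, "h": 90}}
        assert normalize_counts(tables) == {"A": {"g": 10.0, "h": 90.0}}

    def test_equal_totals_identity(self):
        tables = {"A": {"g": 50, "h": 50}, "B": {"x": 100}}
        normalized = normalize_counts(tables)
        assert normalized["A"] == {"g": 50.0, "h": 50.0}
        assert normalized["B"] == {"x": 100.0}

    def test_zero_total_names_dataset(self):
        with pytest.raises(ValueError, match="'B'"):
            normalize_counts({"A": {"g": 1}, "B": {}})

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_normalized_totals_equal_mean_exactly(self, seed):
        rng = random.Random(seed)
        tables = {
            f"d{d}": {f"g{i}": rng.randint(1, 1000)
                      for i in range(rng.randint(1, 20))}
            for d in range(rng.randint(1, 5))}
        normalized = normalize_counts(tables)
        totals = [sum(t.values()) for t in tables.values()]
        mean_total = sum(totals) / len(totals)
        for name in tables:
            assert sum(normalized[name].values()) == pytest.approx(
                mean_total, rel=1e-12)
        # conservation: sum of normalized totals == sum of raw totals
        assert sum(sum(t.values()) for t in normalized.values()) == \
            pytest.approx(sum(totals), rel=1e-12)


def _record(gene, mult, bin="genus", genus="Alpha"):
    rec = AssignmentRecord(cluster_id=f"c_{gene}_{mult}", bin=bin,
                           multiplicity=mult, taxon_genus=genus)
    rec.gene_id = gene
    return rec


class TestCategoryDistribution:
    COG2CAT = {"COG1": "J", "COG2": "G", "COG3": "G"}
    GENE2COG = {"g1": "COG1", "g2": "COG2", "g3": "COG3"}

    def test_single_category(self):
        profile = cog_category_distribution([_record("g1", 10)],
                                            self.GENE2COG, self.COG2CAT)
        assert profile.category_fractions == {"J": 1.0}

    def test_sixty_forty_split(self):
        records = [_record("g2", 60), _record("g1", 40)]
        profile = cog_category_distribution(records, self.GENE2COG, self.COG2CAT)
        assert profile.category_fractions == {"G": 0.6, "J": 0.4}

    def test_no_cog_reads_counted_outside_denominator(self):
        records = [_record("g1", 50), _record("gX", 50)]
        profile = cog_category_distribution(records, self.GENE2COG, self.COG2CAT)
        assert profile.no_cog_count == 50
        assert profile.category_fractions == {"J": 1.0}

    def test_genus_scope_requires_genus_bin(self):
        records = [_record("g1", 10, bin="genus", genus="Alpha"),
                   _record("g2", 90, bin="function_only", genus=None)]
        profile = cog_category_distribution(records, self.GENE2COG, self.COG2CAT,
                                            scope="genus:Alpha")
        assert profile.category_fractions == {"J": 1.0}
        assert profile.total_reads == 10

    def test_genus_scope_with_no_reads_is_empty(self):
        profile = cog_category_distribution([_record("g1", 10, genus="Alpha")],
                                            self.GENE2COG, self.COG2CAT,
                                            scope="genus:Nobody")
        assert profile.category_fractions == {}
        assert profile.total_reads == 0

    def test_unknown_category_code_is_error(self):
        with pytest.raises(ValueError, match="'9'"):
            cog_category_distribution([_record("g1", 1)], {"g1": "COGX"},
                                      {"COGX": "9"})

    def test_category_fractions_sum_to_one(self):
        records = [_record("g1", 7), _record("g2", 3), _record("g3", 5)]
        profile = cog_category_distribution(records, self.GENE2COG, self.COG2CAT)
        assert sum(profile.category_fractions.values()) == pytest.approx(1.0)


class TestGenomeBaseline:
    def _bundle(self, cogs):
        genes = [GeneModel(f"g{i}", "c1", "c1", 10 * i, 10 * i + 5, "+",
                           cog_id=c) for i, c in enumerate(cogs)]
        return ReferenceBundle(
            {"c1": "A" * 200}, genes,
            {"c1": TaxonomyLineage("c1", {"genus": "G", "family": "F"})})

    def test_uniform_single_category(self):
        bundle = self._bundle(["COG1", "COG2"])
        profile = genome_baseline_profile(bundle, "c1",
                                          {"COG1": "G", "COG2": "G"})
        assert profile.category_fractions == {"G": 1.0}

    def test_even_split_and_no_cog_excluded(self):
        bundle = self._bundle(["COG1", "COG2", None])
        profile = genome_baseline_profile(bundle, "c1",
                                          {"COG1": "G", "COG2": "J"})
        assert profile.category_fractions == {"G": 0.5, "J": 0.5}
        assert profile.no_cog_count == 1

    def test_characterized_split_uses_r_and_s(self):
        bundle = self._bundle(["COG1", "COG2"])
        profile = genome_baseline_profile(bundle, "c1",
                                          {"COG1": "G", "COG2": "S"})
        split = split_characterized(profile)
        assert split == {"characterized": 0.5, "poorly_characterized": 0.5}


class TestIPath:
    def _table(self, counts):
        table = GeneExpressionTable()
        table.counts = counts
        return table

    def test_log2_widths(self):
        out = export_ipath(self._table({"g1": 8, "g2": 1}),
                           {"g1": "K00001", "g2": "K00002"})
        assert out == "K00001 W3.00\nK00002 W0.00\n"

    def test_counts_aggregate_over_genes_of_one_ko(self):
        out = export_ipath(self._table({"g1": 3, "g2": 5}),
                           {"g1": "K00001", "g2": "K00001"})
        assert out == "K00001 W3.00\n"  # log2(3+5)

    def test_round_trip_width_recovers_count(self):
        counts = {"g1": 37, "g2": 111}
        out = export_ipath(self._table(counts), {"g1": "K1", "g2": "K2"})
        for line, expected in zip(out.splitlines(), [37, 111]):
            width = float(line.split("W")[1])
            assert 2 ** width == pytest.approx(expected, rel=0.01)

    def test_genes_without_ko_skipped(self):
        assert export_ipath(self._table({"g1": 8}), {}) == ""


class TestCompare:
    def test_self_correlation_is_one(self):
        t = {"g1": 5, "g2": 10, "g3": 1}
        report = compare_datasets({"A": dict(t), "B": dict(t)})
        r, p, n = report.pairs[("A", "B")]
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_constructed_anticorrelation(self):
        xs = {"g1": 1, "g2": 5, "g3": 9, "g4": 2}
        ys = {k: 10 - v for k, v in xs.items()}  # y = c - x -> r = -1
        report = compare_datasets({"A": xs, "B": ys}, normalize=False)
        r, p, _ = report.pairs[("A", "B")]
        assert r == pytest.approx(-1.0)

    def test_independent_tables_low_correlation(self):
        rng = random.Random(44)
        a = {f"g{i}": rng.randint(1, 100) for i in range(500)}
        b = {f"g{i}": rng.randint(1, 100) for i in range(500)}
        r, p, _ = compare_datasets({"A": a, "B": b}).pairs[("A", "B")]
        assert abs(r) < 0.15
        assert p > 1e-4

    def test_too_few_keys_is_error(self):
        with pytest.raises(ValueError, match="too few"):
            compare_datasets({"A": {"g1": 1, "g2": 2}, "B": {"g1": 3, "g2": 1}})

    def test_fewer_than_two_datasets_is_error(self):
        with pytest.raises(ValueError):
            compare_datasets({"A": {"g1": 1}})


class TestCategoryData:
    def test_shipped_table_has_standard_codes(self):
        table = cog_category_table()
        assert {"J", "G", "C", "R", "S"} <= set(table["code"])
        assert table["code"].is_unique
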
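"""Bit-score binning, best-hit selection, profiles, congruence, salvage."""

import pytest

from mtxpipe.assign import (AssignmentRecord, best_hit, bin_read, bin_totals,
                            pair_congruence, phylo_profile, salvage,
                            subsample_unassigned)
from mtxpipe.iokit import AlignmentHit, Read, ReadCluster, Thresholds


def _hit(bits, subject="gA_1", identity=0.99):
    return AlignmentHit(query_id="q", subject_id=subject, query_start=0,
                        query_end=101, subject_start=150, subject_end=251,
                        strand="+", alignment_length=101, identity=identity,
                        bit_score=bits)


def _cluster(cid="c1", mult=1):
    return ReadCluster(Read(cid, "A" * 50 + "C" * 51, [40] * 101),
                       multiplicity=mult)


class TestBestHit:
    def test_highest_bit_wins(self, toy_bundle):
        hit, ambiguous = best_hit([_hit(150), _hit(120, "gB_1")], toy_bundle)
        assert hit.bit_score == 150
        assert not ambiguous

    def test_tie_same_genus_not_ambiguous(self, toy_bundle):
        hit, ambiguous = best_hit([_hit(150, "gA_1"), _hit(150, "gA_1")],
                                  toy_bundle)
        assert not ambiguous

    def test_tie_across_genera_flags_ambiguous(self, toy_bundle):
        hits = sorted([_hit(150, "gB_1"), _hit(150, "gA_1")],
                      key=lambda h: h.subject_id)
        hit, ambiguous = best_hit(hits, toy_bundle)
        assert hit.subject_id == "gA_1"  # lexicographically first subject
        assert ambiguous

    def test_empty_list_sentinel(self, toy_bundle):
        assert best_hit([], toy_bundle) == (None, False)


class TestBinRead:
    @pytest.mark.parametrize("bits,expected_bin", [
        (148.0, "genus"),        # threshold itself is genus (inclusive)
        (147.99, "family"),
        (120.0, "family"),
        (110.0, "family"),
        (109.99, "function_only"),
        (90.0, "function_only"),
        (74.0, "function_only"),
        (73.99, "unassigned"),
        (50.0, "unassigned"),
    ])
    def test_half_open_intervals(self, toy_bundle, thresholds, bits, expected_bin):
        record = bin_read(_cluster(), [_hit(bits)], thresholds, toy_bundle)
        assert record.bin == expected_bin

    def test_genus_bin_carries_lineage_names(self, toy_bundle, thresholds):
        record = bin_read(_cluster(), [_hit(150)], thresholds, toy_bundle)
        assert record.taxon_genus == "Alpha"
        assert record.taxon_family == "Alphaceae"
        assert record.taxon_species == "Alpha one"
        assert record.genome_id == "gA_1"

    def test_family_bin_has_no_genus_name(self, toy_bundle, thresholds):
        record = bin_read(_cluster(), [_hit(120)], thresholds, toy_bundle)
        assert record.taxon_genus is None
        assert record.taxon_family == "Alphaceae"

    def test_no_hit_unassigned(self, toy_bundle, thresholds):
        record = bin_read(_cluster(), [], thresholds, toy_bundle)
        assert record.bin == "unassigned"
        assert record.best_hit is None

    def test_unknown_subject_lineage_is_error(self, toy_bundle, thresholds):
        with pytest.raises(KeyError):
            bin_read(_cluster(), [_hit(150, subject="unknown")],
                     thresholds, toy_bundle)

    def test_raising_genus_cutoff_only_moves_genus_to_family(self, toy_bundle):
        bits_grid = [73.99, 74.0, 90.0, 109.99, 110.0, 147.99, 148.0, 160.0]
        base = Thresholds()
        raised = Thresholds(t_genus=155)
        for bits in bits_grid:
            rec_base = bin_read(_cluster(), [_hit(bits)], base, toy_bundle)
            rec_raised = bin_read(_cluster(), [_hit(bits)], raised, toy_bundle)
            if rec_base.bin in ("function_only", "unassigned"):
                assert rec_raised.bin == rec_base.bin
            elif rec_base.bin == "genus" and bits < 155:
                assert rec_raised.bin == "family"


class TestPhyloProfile:
    def _records(self, spec):
        # spec: list of (bin, genus, multiplicity)
        return [AssignmentRecord(cluster_id=f"c{i}", bin=b, taxon_genus=g,
                                 multiplicity=m)
                for i, (b, g, m) in enumerate(spec)]

    def test_simple_fractions(self):
        records = self._records([("genus", "A", 70), ("genus", "B", 30)])
        assert phylo_profile(records) == {"A": 0.70, "B": 0.30}

    def test_rare_genera_pool_into_other(self):
        records = self._records([("genus", "A", 98), ("genus", "B", 1),
                                 ("genus", "C", 1)])
        profile = phylo_profile(records, min_display_fraction=0.02)
        assert profile == {"A": 0.98, "other": 0.02}

    def test_all_unassigned(self):
        records = self._records([("unassigned", None, 5)])
        assert phylo_profile(records) == {"unclassified": 1.0}

    def test_fractions_sum_to_one_with_family_pool(self):
        records = self._records([("genus", "A", 50), ("family", None, 30),
                                 ("unassigned", None, 20)])
        profile = phylo_profile(records)
        assert profile["family-classified"] == 0.30
        assert sum(profile.values()) == pytest.approx(1.0)


class TestSubsample:
    def _records(self, n):
        return [AssignmentRecord(cluster_id=f"c{i}", bin="unassigned")
                for i in range(n)]

    def test_exact_count(self):
        assert len(subsample_unassigned(self._records(100), 0.1, seed=1)) == 10

    def test_reproducible_for_fixed_seed(self):
        records = self._records(50)
        a = subsample_unassigned(records, 0.2, seed=7)
        b = subsample_unassigned(records, 0.2, seed=7)
        assert [r.cluster_id for r in a] == [r.cluster_id for r in b]

    def test_full_fraction_returns_everything(self):
        records = self._records(17)
        assert len(subsample_unassigned(records, 1.0, seed=3)) == 17

    def test_half_even_rounding(self):
        # 0.1 * 25 = 2.5 -> banker's rounding gives 2
        assert len(subsample_unassigned(self._records(25), 0.1, seed=0)) == 2


class TestPairCongruence:
    def _rec(self, bin="genus", genus="A", species=None, gene=None, cog=None):
        return AssignmentRecord(cluster_id="c", bin=bin, taxon_genus=genus,
                                taxon_species=species, gene_id=gene, cog_id=cog)

    def test_nine_of_ten_same_genus(self):
        left = {f"p{i}": self._rec(genus="A") for i in range(10)}
        right = {f"p{i}": self._rec(genus="A") for i in range(9)}
        right["p9"] = self._rec(genus="B")
        report = pair_congruence(left, right)
        assert report.same_genus == pytest.approx(0.90)
        assert report.n_pairs_both_assigned == 10

    def test_one_end_only_excluded_from_denominator(self):
        left = {"p0": self._rec(), "p1": self._rec()}
        right = {"p0": self._rec(), "p1": self._rec(bin="unassigned", genus=None)}
        report = pair_congruence(left, right)
        assert report.n_pairs_both_assigned == 1
        assert report.n_one_end_only == 1
        assert report.same_genus == 1.0

    def test_gene_and_cog_congruence_tracked(self):
        left = {"p0": self._rec(gene="g1", cog="COG1", species="A sp")}
        right = {"p0": self._rec(gene="g1", cog="COG2", species="A sp")}
        report = pair_congruence(left, right)
        assert report.same_gene == 1.0
        assert report.same_cog == 0.0
        assert report.same_species == 1.0

    def test_unpairable_ids_error_lists_examples(self):
        with pytest.raises(ValueError, match="p1"):
            pair_congruence({"p0": self._rec(), "p1": self._rec()},
                            {"p0": self._rec()})


class TestSalvage:
    PEP1 = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    PEP2 = "WLHGGWFNPDEYKKLAAQMGMSRSAWWNGQHFE"

    @staticmethod
    def _encode(peptide):
        from Bio.Data.CodonTable import unambiguous_dna_by_id
        table = unambiguous_dna_by_id[1].forward_table
        codon_of = {}
        for codon, aa in sorted(table.items()):
            codon_of.setdefault(aa, codon)
        return "".join(codon_of[aa] for aa in peptide)

    def _setup(self):
        records = [AssignmentRecord(cluster_id="r1", bin="unassigned"),
                   AssignmentRecord(cluster_id="r2", bin="unassigned"),
                   AssignmentRecord(cluster_id="r3", bin="unassigned")]
        sequences = {"r1": self._encode(self.PEP1),
                     "r2": self._encode(self.PEP2),
                     "r3": "ACGT" * 25}
        dbs = [("db1", {"p1": self.PEP1}, {"p1": "kinase"}),
               ("db2", {"p2": self.PEP2}, {})]
        return records, sequences, dbs

    def test_iterative_fallback(self):
        records, sequences, dbs = self._setup()
        report = salvage(records, sequences, dbs, min_bit=40)
        assert report.assigned_by_db == {"db1": 1, "db2": 1}
        assert report.annotations["r1"][0] == "db1"  # never tried on db2
        assert report.annotations["r1"][2] == "kinase"
        assert report.annotations["r2"][0] == "db2"
        assert report.n_remaining == 1
        assert report.remaining_fraction == pytest.approx(1 / 3)

    def test_no_database_is_error(self):
        records, sequences, _ = self._setup()
        with pytest.raises(ValueError):
            salvage(records, sequences, [])


class TestBinTotals:
    def test_totals_cover_every_record_once(self):
        records = [AssignmentRecord(cluster_id="a", bin="genus", multiplicity=3),
                   AssignmentRecord(cluster_id="b", bin="unassigned", multiplicity=2)]
        totals = bin_totals(records)
        assert totals["genus"] == 3
        assert totals["unassigned"] == 2
        assert sum(totals.values()) == 5
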
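"""Built-in seed-and-extend aligner vs an independent Smith-Waterman oracle,
bit-score normalisation, and the six-frame translated search."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import oracle_best_bits, pairwise_oracle
from mtxpipe.aligner import (GenomeAligner, ProteinScoringScheme, ScoringScheme,
                             SeedIndex, align, bit_score, encode_dna, evalue,
                             min_raw_for_bit, revcomp, smith_waterman,
                             translated_search)
from mtxpipe.iokit import Read, ReadCluster, Thresholds


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestBitScore:
    def test_zero_raw_unit_k_is_zero_bits(self):
        assert bit_score(0, ScoringScheme(lam=0.625, k_param=1.0)) == 0.0

    def test_published_blastn_style_example(self):
        # (0.625 * 100 - ln 0.41) / ln 2, evaluated independently
        sch = ScoringScheme(lam=0.625, k_param=0.41)
        assert bit_score(100, sch) == pytest.approx(91.4547, abs=1e-3)

    def test_threshold_inversion(self):
        sch = ScoringScheme(lam=0.625, k_param=0.41)
        raw = min_raw_for_bit(148, sch)
        assert raw == 163  # derived by inverting the formula, both neighbours checked
        assert bit_score(raw, sch) >= 148 > bit_score(raw - 1, sch)

    def test_strictly_monotone(self, scheme):
        bits = [bit_score(s, scheme) for s in range(0, 200, 7)]
        assert all(b2 > b1 for b1, b2 in zip(bits, bits[1:]))

    def test_evalue_decreases_with_score(self, scheme):
        assert evalue(100, scheme, 100, 10000) < evalue(50, scheme, 100, 10000)


class TestAlign:
    def test_exact_substring_hit(self, scheme):
        rng = random.Random(5)
        genome = _random_seq(rng, 600)
        index = SeedIndex({"g": genome}, 28)
        hit = align(genome[200:301], index, scheme, min_bit=50)[0]
        assert hit.identity == 1.0
        assert hit.alignment_length == 101
        assert (hit.query_start, hit.query_end) == (0, 101)
        assert (hit.subject_start, hit.subject_end) == (200, 301)
        assert hit.strand == "+"

    def test_reverse_complement_strand_symmetry(self, scheme):
        rng = random.Random(6)
        genome = _random_seq(rng, 600)
        index = SeedIndex({"g": genome}, 28)
        fwd = align(genome[200:301], index, scheme)[0]
        rev = align(revcomp(genome[200:301]), index, scheme)[0]
        assert rev.strand == "-"
        assert rev.bit_score == fwd.bit_score
        assert (rev.subject_start, rev.subject_end) == (200, 301)

    def test_query_shorter_than_word_size_empty(self, scheme):
        index = SeedIndex({"g": "ACGT" * 50}, 11)
        assert align("ACGTACG", index, scheme) == []

    def test_no_shared_word_no_hits(self, scheme):
        # subject lacks any T; query is T-rich, so no 11-mer seed exists
        index = SeedIndex({"g": "ACG" * 100}, 11)
        assert align("T" * 40 + "ACGACG" + "T" * 40, index, scheme) == []

    def test_deterministic_ordering(self, scheme):
        rng = random.Random(7)
        genome = _random_seq(rng, 400)
        subjects = {"b": genome, "a": genome}  # identical -> tie on bits
        index = SeedIndex(subjects, 11)
        hits = align(genome[50:151], index, scheme)
        assert [h.subject_id for h in hits[:2]] == ["a", "b"]  # lexicographic tie-break

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None)
    def test_best_raw_matches_full_smith_waterman(self, seed):
        """Seeded random instances with a guaranteed planted 11-mer: the
        seeded heuristic must equal the exhaustive DP oracle."""
        scheme = ScoringScheme()
        rng = random.Random(seed)
        subject = _random_seq(rng, rng.randint(60, 300))
        core_start = rng.randint(0, len(subject) - 20)
        core = subject[core_start:core_start + rng.randint(15, 60)]
        query = (_random_seq(rng, rng.randint(0, 30)) + core
                 + _random_seq(rng, rng.randint(0, 30)))[:300]
        index = SeedIndex({"s": subject}, 11)
        hits = align(query, index, scheme, min_bit=0)
        assert hits, "planted seed must produce a hit"
        oracle = pairwise_oracle(scheme)
        expected = max(oracle.score(query, subject),
                       oracle.score(revcomp(query), subject))
        assert hits[0].raw_score == expected

    def test_score_monotone_under_matching_extension(self, scheme):
        rng = random.Random(8)
        subject = _random_seq(rng, 200)
        query = subject[50:120]
        index = SeedIndex({"s": subject}, 11)
        base = align(query, index, scheme)[0].raw_score
        extended = align(subject[50:140], index, scheme)[0].raw_score
        assert extended >= base


class TestTwoPass:
    def test_perfect_match_resolved_in_pass_one(self, scheme, thresholds):
        rng = random.Random(9)
        genome = _random_seq(rng, 2000)
        aligner = GenomeAligner({"g": genome}, thresholds, scheme)
        cluster = ReadCluster(Read("c1", genome[500:601], [40] * 101))
        result = aligner.two_pass_align([cluster])
        assert result.pass_by_cluster["c1"] == 1
        assert result.best("c1").bit_score >= thresholds.t_genus

    def test_diverged_read_rescued_by_sensitive_pass(self, scheme, thresholds):
        """A read too diverged for 28-mer seeding but holding an 11-mer seed
        is recovered in pass 2; the brute-force oracle confirms the score."""
        rng = random.Random(10)
        genome = _random_seq(rng, 2000)
        read = list(genome[500:601])
        for pos in range(20, 101, 24):  # break every possible 28-mer
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        read = "".join(read)
        aligner = GenomeAligner({"g": genome}, thresholds, scheme)
        cluster = ReadCluster(Read("c1", read, [40] * 101))
        result = aligner.two_pass_align([cluster])
        assert result.pass_by_cluster["c1"] == 2
        best = result.best("c1")
        assert best is not None
        assert best.bit_score == pytest.approx(
            oracle_best_bits(read, [genome], scheme), abs=1e-9)

    def test_unmatched_cluster_has_empty_hits(self, scheme, thresholds):
        aligner = GenomeAligner({"g": "ACG" * 600}, thresholds, scheme)
        cluster = ReadCluster(Read("c1", "T" * 101, [40] * 101))
        result = aligner.two_pass_align([cluster])
        assert result.hits_by_cluster["c1"] == []
        assert result.best("c1") is None


class TestTranslatedSearch:
    PEPTIDE = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"  # 33 aa

    @staticmethod
    def _encode(peptide):
        from Bio.Data.CodonTable import unambiguous_dna_by_id
        table = unambiguous_dna_by_id[1].forward_table
        codon_of = {}
        for codon, aa in sorted(table.items()):
            codon_of.setdefault(aa, codon)
        return "".join(codon_of[aa] for aa in peptide)

    def test_exact_encoding_hits_frame_one(self):
        nt = self._encode(self.PEPTIDE)
        hit = translated_search(nt, {"p1": self.PEPTIDE}, min_bit=40)[0]
        assert hit.frame == 1
        assert hit.alignment_length == 33
        assert hit.identity == 1.0

    def test_reverse_complement_negative_frame_same_score(self):
        nt = self._encode(self.PEPTIDE)
        fwd = translated_search(nt, {"p1": self.PEPTIDE}, min_bit=40)[0]
        rev = translated_search(revcomp(nt), {"p1": self.PEPTIDE}, min_bit=40)[0]
        assert rev.frame < 0
        assert rev.bit_score == fwd.bit_score

    def test_random_sequence_below_cutoff_both_routes(self):
        """No >=40-bit hit for an unrelated sequence; verified frame-by-frame
        with the independent protein DP oracle."""
        rng = random.Random(11)
        nt = _random_seq(rng, 90)
        db = {"p1": "WWWWWCCCCCHHHHHMMMMMWWWWW"}
        assert translated_search(nt, db, min_bit=40) == []
        # oracle: exhaustive six-frame scores stay below 40 bits
        from Bio.Align import substitution_matrices
        from mtxpipe.aligner import six_frame_segments
        sch = ProteinScoringScheme()
        oracle = pairwise_oracle(ScoringScheme())  # reconfigure for protein below
        oracle.substitution_matrix = substitution_matrices.load("BLOSUM62")
        oracle.open_gap_score = sch.gap_open
        oracle.extend_gap_score = sch.gap_extend
        best = 0.0
        for _, segment in six_frame_segments(nt):
            if len(segment) >= 4:
                best = max(best, oracle.score(segment, db["p1"]))
        assert (sch.lam * best - math.log(sch.k_param)) / math.log(2) < 40

    def test_empty_db_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            translated_search("ACGTACGTACGT", {})
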
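"""Shared fixtures: toy references, independent alignment oracle, small
synthetic communities."""

from __future__ import annotations

import math

import pytest
from Bio import Align
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mtxpipe.aligner import ScoringScheme
from mtxpipe.iokit import GeneModel, ReferenceBundle, TaxonomyLineage, Thresholds


def pairwise_oracle(scheme: ScoringScheme):
    """Independent full Smith-Waterman scorer (Biopython, C implementation).

    Same scoring model as the built-in aligner: a gap of length L costs
    ``gap_open + (L-1) * gap_extend``.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scheme.match_reward
    aligner.mismatch_score = scheme.mismatch_penalty
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def oracle_best_bits(query: str, subjects, scheme: ScoringScheme) -> float:
    """Best bit score over subjects and both strands, via the oracle."""
    from mtxpipe.aligner import revcomp

    aligner = pairwise_oracle(scheme)
    best = 0.0
    for subject in subjects:
        for q in (query, revcomp(query)):
            best = max(best, float(aligner.score(q, subject)))
    if best <= 0:
        return 0.0
    return (scheme.lam * best - math.log(scheme.k_param)) / math.log(2)


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme()


@pytest.fixture(scope="session")
def thresholds() -> Thresholds:
    return Thresholds()


def make_toy_bundle() -> ReferenceBundle:
    """Two genera, one genome each; deterministic sequences with two genes
    per genome at known coordinates."""
    import numpy as np

    rng = np.random.default_rng(99)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    def seq(n):
        return rng.choice(bases, size=n).tobytes().decode()

    contigs = {"gA_1": seq(2000), "gB_1": seq(2000)}
    genes = [
        GeneModel("gA_1_g001", "gA_1", "gA_1", 100, 600, "+", cog_id="COG0001",
                  ko_id="K00001"),
        GeneModel("gA_1_g002", "gA_1", "gA_1", 800, 1400, "-", cog_id="COG0002"),
        GeneModel("gB_1_g001", "gB_1", "gB_1", 100, 600, "+", cog_id="COG0001"),
        GeneModel("gB_1_g002", "gB_1", "gB_1", 800, 1400, "-", cog_id="COG0003",
                  ko_id="K00003"),
    ]
    lineages = {
        "gA_1": TaxonomyLineage("gA_1", {"species": "Alpha one", "genus": "Alpha",
                                         "family": "Alphaceae"}),
        "gB_1": TaxonomyLineage("gB_1", {"species": "Beta one", "genus": "Beta",
                                         "family": "Betaceae"}),
    }
    return ReferenceBundle(contigs=contigs, genes=genes, lineages=lineages)


@pytest.fixture(scope="session")
def toy_bundle() -> ReferenceBundle:
    return make_toy_bundle()


@pytest.fixture(scope="session")
def small_community():
    """3-genus community at reduced read count, single-end, shared by tests."""
    from mtxpipe.simdata import CommunitySpec, generate_community

    return generate_community(CommunitySpec(n_reads=3000, seed=11))
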
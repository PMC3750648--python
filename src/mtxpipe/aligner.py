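"""Seed-and-extend local nucleotide aligner with Karlin-Altschul bit scores.

This is the pipeline's built-in alignment backend: exact ``word_size``-mer
seeds located through a hash index, grouped by diagonal, and extended by a
full affine-gap Smith-Waterman over a generous subject window around the
seeds.  A large word size (28) gives the fast first pass; a small word size
(11) gives the sensitive second pass for reads the first pass could not
place.  Raw scores are normalised to bits,

    bits = (lambda * S - ln K) / ln 2,

so cutoffs are comparable across scoring schemes.  Gap scoring convention:
a gap of length L scores ``gap_open + (L - 1) * gap_extend``.

Production runs may instead import tabular alignment files from an external
aligner (see :func:`mtxpipe.iokit.read_alignment_table`); the two-pass logic
is identical either way.

A rudimentary six-frame translated search against a protein database (used
by the unassigned-read salvage step) shares the same DP kernel with a
BLOSUM62 substitution table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from numba import njit

from .iokit import AlignmentHit, ReadCluster, Thresholds

_DNA_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_CODE = {aa: i for i, aa in enumerate(_AA_ALPHABET)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_dna(seq: str) -> np.ndarray:
    return np.fromiter((_DNA_CODE.get(c, 4) for c in seq), dtype=np.uint8, count=len(seq))


def encode_protein(seq: str) -> np.ndarray:
    return np.fromiter((_AA_CODE.get(c, 22) for c in seq), dtype=np.uint8, count=len(seq))


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring plus the Karlin-Altschul parameters normalising it.

    Defaults: match +1 / mismatch -2 with the published *ungapped*
    Karlin-Altschul values for that ratio (lambda = 1.33, K = 0.621),
    reused as stated approximations for the mildly gapped alignments
    produced here.  Under these defaults a perfect 101-nt match scores
    ~195 bits, a ~15%-diverged one ~110 bits, so the genus/family/function
    cutoffs (148/110/74) partition realistic read alignments.  All five
    values are configurable and recorded in result headers.
    """

    match_reward: int = 1
    mismatch_penalty: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 1.33
    k_param: float = 0.621

    def __post_init__(self) -> None:
        if self.match_reward <= 0 or self.lam <= 0 or self.k_param <= 0:
            raise ValueError("match_reward, lambda and K must be positive")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")

    def substitution_matrix(self) -> np.ndarray:
        mat = np.full((5, 5), self.mismatch_penalty, dtype=np.int32)
        np.fill_diagonal(mat, self.match_reward)
        mat[4, :] = self.mismatch_penalty  # N never rewards
        mat[:, 4] = self.mismatch_penalty
        return mat

    def header(self) -> str:
        return (f"# scheme match={self.match_reward} mismatch={self.mismatch_penalty} "
                f"gap_open={self.gap_open} gap_extend={self.gap_extend} "
                f"lambda={self.lam} K={self.k_param}")


@dataclass(frozen=True)
class ProteinScoringScheme:
    """BLOSUM62 scoring with gapped Karlin-Altschul parameters (11/1 gaps)."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = -11
    gap_extend: int = -1
    lam: float = 0.267
    k_param: float = 0.041

    def substitution_matrix(self) -> np.ndarray:
        blosum = substitution_matrices.load(self.matrix_name)
        n = len(_AA_ALPHABET)
        mat = np.zeros((n, n), dtype=np.int32)
        for i, a in enumerate(_AA_ALPHABET):
            for j, b in enumerate(_AA_ALPHABET):
                mat[i, j] = int(blosum[a][b])
        return mat


def bit_score(raw_score: float, scheme) -> float:
    """Karlin-Altschul normalisation: (lambda*S - ln K) / ln 2."""
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    return (scheme.lam * raw_score - math.log(scheme.k_param)) / math.log(2)


def min_raw_for_bit(bits: float, scheme) -> int:
    """Smallest integer raw score whose bit score reaches ``bits``."""
    exact = (bits * math.log(2) + math.log(scheme.k_param)) / scheme.lam
    raw = math.ceil(exact)
    while bit_score(raw, scheme) < bits:  # guard float edge
        raw += 1
    while raw > 0 and bit_score(raw - 1, scheme) >= bits:
        raw -= 1
    return raw


def evalue(raw_score: float, scheme, m: int, n: int) -> float:
    """K * m * n * exp(-lambda * S); reported for information only."""
    return scheme.k_param * m * n * math.exp(-scheme.lam * raw_score)


# ---------------------------------------------------------------------------
# DP kernel (affine-gap local alignment with traceback)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sw_traceback(q, s, submat, gap_open, gap_extend):  # pragma: no cover - numba
    n, m = len(q), len(s)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -(10 ** 8), dtype=np.int32)  # gap in query
    F = np.full((n + 1, m + 1), -(10 ** 8), dtype=np.int32)  # gap in subject
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 open, 1 extend
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                ptr_e[i, j] = 1
            else:
                E[i, j] = e_open
                ptr_e[i, j] = 0
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                ptr_f[i, j] = 1
            else:
                F[i, j] = f_open
                ptr_f[i, j] = 0
            diag = H[i - 1, j - 1] + submat[q[i - 1], s[j - 1]]
            h = np.int32(0)
            p = np.uint8(0)
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptr_h[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0, 0, 0
    # traceback
    i, j = bi, bj
    matches = 0
    mismatches = 0
    gap_opens = 0
    aln_len = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                aln_len += 1
                if q[i - 1] == s[j - 1]:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            aln_len += 1
            p = ptr_e[i, j]
            j -= 1
            if p == 0:
                gap_opens += 1
                state = 0
        else:
            aln_len += 1
            p = ptr_f[i, j]
            i -= 1
            if p == 0:
                gap_opens += 1
                state = 0
    return int(best), i, bi, j, bj, matches, mismatches, gap_opens, aln_len


def smith_waterman(query_codes, subject_codes, submat, gap_open, gap_extend):
    """Best local alignment of two encoded sequences.

    Returns ``(raw_score, q_start, q_end, s_start, s_end, matches,
    mismatches, gap_opens, alignment_length)``; raw_score 0 means no
    positive-scoring alignment exists.
    """
    return _sw_traceback(
        np.ascontiguousarray(query_codes),
        np.ascontiguousarray(subject_codes),
        np.ascontiguousarray(submat),
        np.int32(gap_open),
        np.int32(gap_extend),
    )


# ---------------------------------------------------------------------------
# seed index
# ---------------------------------------------------------------------------

class SeedIndex:
    """Hash index of all ``word_size``-mers of a reference sequence set.

    Homopolymer words (a single repeated base) are skipped as seeds — a
    minimal low-complexity guard.
    """

    def __init__(self, subjects: dict, word_size: int) -> None:
        if word_size < 4:
            raise ValueError("word_size must be >= 4")
        self.word_size = word_size
        self.names = list(subjects)
        self.sequences = {name: subjects[name] for name in self.names}
        self.codes = {name: encode_dna(subjects[name]) for name in self.names}
        self.index: dict = {}
        for name in self.names:
            seq = subjects[name]
            for pos in range(len(seq) - word_size + 1):
                word = seq[pos:pos + word_size]
                if word[0] * word_size == word:
                    continue
                self.index.setdefault(word, []).append((name, pos))

    def seeds(self, query: str):
        w = self.word_size
        hits = self.index
        out = []
        for qpos in range(len(query) - w + 1):
            found = hits.get(query[qpos:qpos + w])
            if found:
                for name, spos in found:
                    out.append((name, spos - qpos))
        return out


def _merge_windows(diags: list, qlen: int, subj_len: int, pad: int) -> list:
    """Cluster seed diagonals into merged subject windows."""
    diags = sorted(set(diags))
    windows = []
    start = max(0, diags[0] - pad)
    end = min(subj_len, diags[0] + qlen + pad)
    for d in diags[1:]:
        w_start = max(0, d - pad)
        w_end = min(subj_len, d + qlen + pad)
        if w_start <= end:
            end = max(end, w_end)
        else:
            windows.append((start, end))
            start, end = w_start, w_end
    windows.append((start, end))
    return windows


def align(
    query: str,
    index: SeedIndex,
    scheme: ScoringScheme,
    min_bit: float = 0.0,
    query_id: str = "query",
    pad: Optional[int] = None,
) -> list:
    """Seed-and-extend local alignment of ``query`` against an indexed reference.

    Both strands are searched; hits with bit score >= ``min_bit`` are
    returned sorted by bit descending (ties: identity descending, then
    subject id, strand, position — fully deterministic).  A query shorter
    than the word size yields an empty result.  ``pad`` is the window
    margin added around the seed diagonals before DP (default: the query
    length, generous enough to contain any local alignment through a seed).
    """
    qlen = len(query)
    if qlen < index.word_size:
        return []
    if pad is None:
        pad = qlen
    submat = scheme.substitution_matrix()
    db_len = sum(len(c) for c in index.codes.values())
    hits = []
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        seeds = index.seeds(qseq)
        if not seeds:
            continue
        by_subject: dict = {}
        for name, diag in seeds:
            by_subject.setdefault(name, []).append(diag)
        qcodes = encode_dna(qseq)
        for name in sorted(by_subject):
            scodes = index.codes[name]
            for w_start, w_end in _merge_windows(by_subject[name], qlen, len(scodes), pad):
                (raw, qs, qe, ss, se, nmatch, nmis, ngap, alen) = smith_waterman(
                    qcodes, scodes[w_start:w_end], submat,
                    scheme.gap_open, scheme.gap_extend,
                )
                if raw <= 0:
                    continue
                bits = bit_score(raw, scheme)
                if bits < min_bit:
                    continue
                if strand == "+":
                    q0, q1 = qs, qe
                else:
                    q0, q1 = qlen - qe, qlen - qs
                hits.append(AlignmentHit(
                    query_id=query_id,
                    subject_id=name,
                    query_start=q0,
                    query_end=q1,
                    subject_start=w_start + ss,
                    subject_end=w_start + se,
                    strand=strand,
                    alignment_length=alen,
                    identity=nmatch / alen,
                    raw_score=raw,
                    bit_score=bits,
                    evalue=evalue(raw, scheme, qlen, db_len),
                    mismatches=nmis,
                    gap_opens=ngap,
                ))
    hits.sort(key=lambda h: (-h.bit_score, -h.identity, h.subject_id, h.strand,
                             h.subject_start))
    return hits


# ---------------------------------------------------------------------------
# two-pass alignment
# ---------------------------------------------------------------------------

@dataclass
class TwoPassResult:
    hits_by_cluster: dict
    pass_by_cluster: dict  # cluster_id -> 1 | 2

    def best(self, cluster_id: str):
        hits = self.hits_by_cluster.get(cluster_id)
        return hits[0] if hits else None


class GenomeAligner:
    """Two-pass aligner against a reference genome set.

    Pass 1 uses the large word size for fast exact seeding; clusters with no
    hit, or whose best bit score falls below the function threshold, are
    re-queried with the small word size.  The final hit list for a
    re-queried cluster is the pass-2 result.
    """

    def __init__(self, contigs: dict, thresholds: Optional[Thresholds] = None,
                 scheme: Optional[ScoringScheme] = None,
                 min_bit_floor: float = 40.0) -> None:
        self.thresholds = thresholds or Thresholds()
        self.scheme = scheme or ScoringScheme()
        self.min_bit_floor = min_bit_floor
        self._contigs = contigs
        self._index1 = SeedIndex(contigs, self.thresholds.word_size_pass1)
        self._index2: Optional[SeedIndex] = None

    @property
    def index_pass2(self) -> SeedIndex:
        if self._index2 is None:
            self._index2 = SeedIndex(self._contigs, self.thresholds.word_size_pass2)
        return self._index2

    def two_pass_align(self, clusters: Iterable[ReadCluster],
                       pad: Optional[int] = 32) -> TwoPassResult:
        hits_by_cluster: dict = {}
        pass_by_cluster: dict = {}
        requery: list = []
        for cluster in clusters:
            hits = align(cluster.sequence, self._index1, self.scheme,
                         min_bit=self.min_bit_floor, query_id=cluster.id, pad=pad)
            if hits and hits[0].bit_score >= self.thresholds.t_func:
                hits_by_cluster[cluster.id] = hits
                pass_by_cluster[cluster.id] = 1
            else:
                requery.append(cluster)
        for cluster in requery:
            hits = align(cluster.sequence, self.index_pass2, self.scheme,
                         min_bit=self.min_bit_floor, query_id=cluster.id, pad=pad)
            hits_by_cluster[cluster.id] = hits
            pass_by_cluster[cluster.id] = 2
        return TwoPassResult(hits_by_cluster, pass_by_cluster)


# ---------------------------------------------------------------------------
# six-frame translated search
# ---------------------------------------------------------------------------

@dataclass
class ProteinHit:
    query_id: str
    subject_id: str
    frame: int  # +1..+3 / -1..-3
    raw_score: int
    bit_score: float
    identity: float
    alignment_length: int


def six_frame_segments(query: str):
    """Yield ``(frame, aa_segment)`` for all six frames, split at stop codons."""
    for strand, seq in ((1, query), (-1, revcomp(query))):
        for offset in range(3):
            sub = seq[offset:]
            sub = sub[:len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate())
            frame = strand * (offset + 1)
            for segment in aa.split("*"):
                if segment:
                    yield frame, segment


def translated_search(
    query: str,
    protein_db: dict,
    scheme_aa: Optional[ProteinScoringScheme] = None,
    min_bit: float = 40.0,
    query_id: str = "query",
) -> list:
    """Best protein hits of the six-frame translation of ``query``.

    Exhaustive DP of every stop-free frame segment against every database
    protein — intended for the small salvage databases of this pipeline,
    not for genome-scale protein search.
    """
    if not protein_db:
        raise ValueError("protein database is empty")
    scheme_aa = scheme_aa or ProteinScoringScheme()
    submat = scheme_aa.substitution_matrix()
    encoded_db = {name: encode_protein(seq) for name, seq in protein_db.items()}
    hits = []
    for frame, segment in six_frame_segments(query):
        if len(segment) < 4:
            continue
        seg_codes = encode_protein(segment)
        for name in sorted(encoded_db):
            raw, qs, qe, ss, se, nmatch, nmis, ngap, alen = smith_waterman(
                seg_codes, encoded_db[name], submat,
                scheme_aa.gap_open, scheme_aa.gap_extend,
            )
            if raw <= 0:
                continue
            bits = bit_score(raw, scheme_aa)
            if bits >= min_bit:
                hits.append(ProteinHit(
                    query_id=query_id, subject_id=name, frame=frame,
                    raw_score=raw, bit_score=bits,
                    identity=nmatch / alen, alignment_length=alen,
                ))
    hits.sort(key=lambda h: (-h.bit_score, -h.identity, h.subject_id, h.frame))
    return hits
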
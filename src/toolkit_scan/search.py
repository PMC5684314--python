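"""Desk-scale translated homology search.

A full Smith-Waterman replaces the seeded heuristics of production search
tools: inputs here are small enough that exactness is affordable, and exact
scores make the statistics testable.  Expectation values follow the
Karlin-Altschul formula E = K * m * n * exp(-lambda * S) with the published
gapped BLOSUM62 (open 11, extend 1) calibration constants; the paper-scale
tools rely on the same defaults.

Protein queries are aligned against all six frame translations of each
nucleotide subject ("tblastn-style"); stop codons receive a prohibitively
negative score so no alignment crosses a stop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from . import _sw
from .orf import Contig, six_frame_translate

#: Substitution score assigned to any column involving a stop symbol.
STOP_SCORE = -(10**6)


@lru_cache(maxsize=8)
def _encoded_matrix(name: str) -> tuple[np.ndarray, np.ndarray, int]:
    """(ASCII char -> index lookup, index x index score matrix, stop index)."""
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    k = len(alphabet)
    sub = np.zeros((k, k), np.int64)
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            if a == "*" or b == "*":
                sub[i, j] = STOP_SCORE
            else:
                sub[i, j] = int(mat[a, b])
    lookup = np.full(128, alphabet.index("X") if "X" in alphabet else 0, np.int8)
    for i, a in enumerate(alphabet):
        lookup[ord(a)] = i
        lookup[ord(a.lower())] = i
    stop_idx = alphabet.index("*") if "*" in alphabet else -1
    return lookup, sub, stop_idx


def encode_protein(seq: str, matrix_name: str = "BLOSUM62") -> np.ndarray:
    """Encode an amino-acid string as matrix indices (unknowns -> X)."""
    lookup, _, _ = _encoded_matrix(matrix_name)
    raw = np.frombuffer(seq.encode("ascii"), np.uint8)
    if raw.size and raw.max() >= 128:
        raise ValueError("non-ASCII residue in protein sequence")
    return lookup[raw]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring plus Karlin-Altschul calibration.

    Defaults are the gapped BLOSUM62 / open 11 / extend 1 constants
    (lambda = 0.267, K = 0.041).
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_K <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")

    def bit_score(self, raw_score: int) -> float:
        return (self.karlin_lambda * raw_score - math.log(self.karlin_K)) / math.log(2)


@dataclass(frozen=True)
class LocalAlignment:
    """Result of one optimal local alignment (spans half-open)."""

    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    n_identical: int
    n_aligned_cols: int

    @property
    def identity_frac(self) -> float:
        """Identity over aligned residue-residue columns (gaps excluded)."""
        if self.n_aligned_cols == 0:
            return 0.0
        return self.n_identical / self.n_aligned_cols


@dataclass(frozen=True)
class Hit:
    """One scored alignment of a protein query against a subject.

    ``frame`` is +-1..3 for translated (nucleotide) subjects and 0 for
    protein subjects; subject spans are amino-acid coordinates within the
    searched frame translation (or the protein itself).
    """

    query_id: str
    subject_id: str
    frame: int
    raw_score: int
    bit_score: float
    evalue: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identity_frac: float
    query_coverage: float
    aln_len: int = 0

    def sort_key(self):
        return (-self.bit_score, self.evalue, self.subject_id, self.frame)


def local_align(a: str, b: str, scheme: ScoringScheme | None = None) -> LocalAlignment:
    """Optimal affine-gap local alignment of two amino-acid strings."""
    if not a or not b:
        raise ValueError("local_align requires two non-empty sequences")
    scheme = scheme or ScoringScheme()
    qa = encode_protein(a, scheme.matrix)
    sb = encode_protein(b, scheme.matrix)
    _, sub, stop_idx = _encoded_matrix(scheme.matrix)
    res = _sw.sw_affine(qa, sb, sub, scheme.gap_open, scheme.gap_extend, stop_idx)
    return LocalAlignment(*res)


def local_align_score(a: str, b: str, scheme: ScoringScheme | None = None) -> int:
    """Best local alignment score only (linear memory, no traceback)."""
    if not a or not b:
        raise ValueError("local_align_score requires two non-empty sequences")
    scheme = scheme or ScoringScheme()
    qa = encode_protein(a, scheme.matrix)
    sb = encode_protein(b, scheme.matrix)
    _, sub, stop_idx = _encoded_matrix(scheme.matrix)
    return _sw.sw_score(qa, sb, sub, scheme.gap_open, scheme.gap_extend, stop_idx)


class TranslatedDb:
    """Six-frame translations of an assembly, computed once and reused.

    Building the database up front amortizes translation cost across the
    many queries of a completeness run or pathway audit.
    """

    def __init__(self, contigs: Iterable[Contig]):
        self.contigs: dict[str, Contig] = {}
        self.frames: list[tuple[str, dict[int, str]]] = []
        for c in contigs:
            if c.id in self.contigs:
                raise ValueError(f"duplicate contig id {c.id!r}")
            self.contigs[c.id] = c
            self.frames.append((c.id, six_frame_translate(c)))
        self.db_len = sum(len(aa) for _, fr in self.frames for aa in fr.values())

    def __len__(self) -> int:
        return len(self.contigs)


def score_to_evalue(
    raw_score: int, query_len: int, db_len: int, scheme: ScoringScheme | None = None
) -> float:
    """Karlin-Altschul expectation: E = K * m * n * exp(-lambda * S)."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    scheme = scheme or ScoringScheme()
    # exp underflows around S ~ 6000 in float64; work in log space.
    log_e = (
        math.log(scheme.karlin_K)
        + math.log(query_len)
        + math.log(db_len)
        - scheme.karlin_lambda * raw_score
    )
    if log_e < -745.0:
        return 0.0
    return math.exp(log_e)


def _make_hit(
    query_id: str,
    subject_id: str,
    frame: int,
    aln: LocalAlignment,
    query_len: int,
    db_len: int,
    scheme: ScoringScheme,
) -> Hit:
    return Hit(
        query_id=query_id,
        subject_id=subject_id,
        frame=frame,
        raw_score=aln.score,
        bit_score=scheme.bit_score(aln.score),
        evalue=score_to_evalue(aln.score, query_len, db_len, scheme),
        q_start=aln.q_start,
        q_end=aln.q_end,
        s_start=aln.s_start,
        s_end=aln.s_end,
        identity_frac=aln.identity_frac,
        query_coverage=(aln.q_end - aln.q_start) / query_len,
        aln_len=max(aln.q_end - aln.q_start, aln.s_end - aln.s_start),
    )


def translated_search(
    query: str,
    subjects: Iterable[Contig] | TranslatedDb,
    evalue_max: float = 1.0,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
) -> list[Hit]:
    """Align a protein query against all six frames of each contig.

    Retains the best alignment per (contig, frame) with E <= evalue_max,
    ranked by bit score descending, then E ascending, then subject id.
    A score-only pass filters each frame first; the full traceback runs
    only for alignments that can pass the E-value cutoff.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    scheme = scheme or ScoringScheme()
    if not query:
        raise ValueError("empty query")
    db = subjects if isinstance(subjects, TranslatedDb) else TranslatedDb(subjects)
    if db.db_len == 0:
        return []
    hits: list[Hit] = []
    for contig_id, frames in db.frames:
        for frame, aa in frames.items():
            if not aa:
                continue
            score = local_align_score(query, aa, scheme)
            if score <= 0:
                continue
            if score_to_evalue(score, len(query), db.db_len, scheme) > evalue_max:
                continue
            aln = local_align(query, aa, scheme)
            hits.append(
                _make_hit(query_id, contig_id, frame, aln, len(query), db.db_len, scheme)
            )
    hits.sort(key=Hit.sort_key)
    return hits


def protein_search(
    query: str,
    subjects: Mapping[str, str],
    evalue_max: float = 1.0,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
) -> list[Hit]:
    """Protein-vs-protein search with the same statistics and ranking."""
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    scheme = scheme or ScoringScheme()
    if not query:
        raise ValueError("empty query")
    db_len = sum(len(s) for s in subjects.values())
    if db_len == 0:
        return []
    hits: list[Hit] = []
    for sid, sseq in subjects.items():
        if not sseq:
            continue
        score = local_align_score(query, sseq, scheme)
        if score <= 0:
            continue
        if score_to_evalue(score, len(query), db_len, scheme) > evalue_max:
            continue
        aln = local_align(query, sseq, scheme)
        hits.append(_make_hit(query_id, sid, 0, aln, len(query), db_len, scheme))
    hits.sort(key=Hit.sort_key)
    return hits


def best_hit(hits: Sequence[Hit]) -> Hit | None:
    """First hit of a ranked list, or None."""
    return hits[0] if hits else None
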
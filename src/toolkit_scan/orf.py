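"""Six-frame translation and longest-ORF extraction.

Assembled transcripts are strand-agnostic and frequently 5'-truncated, so an
"ORF" here is the longest stop-free translated stretch over all six reading
frames: stop-to-stop reading, an initiator methionine is not required, and
frame ends count as boundaries.  Coordinates are always reported on the
forward strand, 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

NUCLEOTIDES = frozenset("ACGTN")

#: Frame labels in tie-break priority order.
FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class Contig:
    """A nucleotide assembly record (uppercase A/C/G/T/N)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        bad = set(seq) - NUCLEOTIDES
        if bad:
            raise ValueError(
                f"contig {self.id!r}: invalid nucleotide(s) {sorted(bad)!r}"
            )
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class OrfRecord:
    """The longest stop-free translated stretch of a contig.

    ``nt_start``/``nt_end`` are forward-strand coordinates of the codon span;
    ``frame`` is +1/+2/+3 (forward offsets 0/1/2) or -1/-2/-3 (the same
    offsets on the reverse complement).
    """

    contig_id: str
    frame: int
    nt_start: int
    nt_end: int
    aa_seq: str

    @property
    def aa_len(self) -> int:
        return len(self.aa_seq)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _translate_frame(seq: str, offset: int) -> str:
    """Translate one frame, dropping the trailing partial codon.

    Codons containing N translate to X; stops render as ``*``.
    """
    usable = len(seq) - offset
    if usable < 3:
        return ""
    end = offset + 3 * (usable // 3)
    return str(Seq(seq[offset:end]).translate())


def six_frame_translate(contig: Contig) -> dict[int, str]:
    """Translate all six frames of a contig.

    Returns a mapping from frame label (+1..+3, -1..-3) to the amino-acid
    string of that frame.
    """
    fwd = contig.seq
    rev = revcomp(fwd)
    out: dict[int, str] = {}
    for off in range(3):
        out[off + 1] = _translate_frame(fwd, off)
        out[-(off + 1)] = _translate_frame(rev, off)
    return out


def _stop_free_runs(aa: str):
    """Yield (aa_start, aa_end) half-open spans of stop-free stretches."""
    start = None
    for i, c in enumerate(aa):
        if c == "*":
            if start is not None:
                yield start, i
                start = None
        elif start is None:
            start = i
    if start is not None:
        yield start, len(aa)


def frame_orfs(contig: Contig) -> list[OrfRecord]:
    """The longest stop-free stretch of each reading frame.

    Up to six records (frames with no stop-free stretch are skipped),
    ordered longest first, ties by frame order +1,+2,+3,-1,-2,-3 then by
    smaller forward-strand ``nt_start``.  The head of this list is the
    candidate a reciprocal search validates first; later entries matter
    when a chance antisense stretch happens to outrun the true coding
    frame.
    """
    L = len(contig.seq)
    frames = six_frame_translate(contig)
    records: list[tuple[tuple[int, int, int], OrfRecord]] = []
    for rank, frame in enumerate(FRAMES):
        aa = frames[frame]
        off = abs(frame) - 1
        best: tuple[tuple[int, int, int], OrfRecord] | None = None
        for a0, a1 in _stop_free_runs(aa):
            if frame > 0:
                nt0, nt1 = off + 3 * a0, off + 3 * a1
            else:
                nt0, nt1 = L - (off + 3 * a1), L - (off + 3 * a0)
            key = (-(a1 - a0), rank, nt0)
            if best is None or key < best[0]:
                best = (key, OrfRecord(contig.id, frame, nt0, nt1, aa[a0:a1]))
        if best is not None:
            records.append(best)
    records.sort(key=lambda r: r[0])
    return [rec for _, rec in records]


def orf_at(contig: Contig, frame: int, nt_start: int, nt_end: int) -> OrfRecord | None:
    """The maximal stop-free stretch of ``frame`` overlapping a codon span.

    ``nt_start``/``nt_end`` are forward-strand coordinates (e.g. of a
    translated-search hit); since no alignment crosses a stop, a hit span
    lies within exactly one maximal stretch of its frame.
    """
    if frame not in FRAMES:
        raise ValueError(f"invalid frame {frame}")
    L = len(contig.seq)
    off = abs(frame) - 1
    aa = six_frame_translate(contig)[frame]
    for a0, a1 in _stop_free_runs(aa):
        if frame > 0:
            s0, s1 = off + 3 * a0, off + 3 * a1
        else:
            s0, s1 = L - (off + 3 * a1), L - (off + 3 * a0)
        if s0 < nt_end and nt_start < s1:
            return OrfRecord(contig.id, frame, s0, s1, aa[a0:a1])
    return None


def hit_nt_span(frame: int, s_start: int, s_end: int, contig_len: int) -> tuple[int, int]:
    """Map an aa span within a frame translation to forward-strand nt coords."""
    off = abs(frame) - 1
    if frame > 0:
        return off + 3 * s_start, off + 3 * s_end
    return contig_len - (off + 3 * s_end), contig_len - (off + 3 * s_start)


def longest_orf(contig: Contig) -> OrfRecord:
    """Longest stop-free amino-acid stretch over all six frames.

    Ties break by frame order +1,+2,+3,-1,-2,-3 then by smaller forward-strand
    ``nt_start``.  A contig shorter than one codon yields a zero-length record.
    """
    orfs = frame_orfs(contig)
    if not orfs:
        return OrfRecord(contig.id, 1, 0, 0, "")
    return orfs[0]
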
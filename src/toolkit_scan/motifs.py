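"""Rule-based protein motif detection.

The rules implemented here are the short, alignment-derived diagnostics used
to audit signaling proteins: the furin RXXR proprotein-convertase cleavage
site, the cysteine-spacing classifier that separates TGFbeta-like from
BMP-like ligands at the prodomain/mature junction, the Dvl-binding KTXXXW
motif of Frizzled cytoplasmic tails, the C-terminal PDZ-binding tripeptide
(S/T-x-V/L), and conserved-cysteine column fingerprints in alignments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

RXXR_RE = re.compile(r"(?=(R..R))")
#: Placeholder catenin-binding peptide audited on TCF in synthetic panels.
CTNNB_BD_PEPTIDE = "WSKMST"
CTNNB_BD_RE = re.compile(CTNNB_BD_PEPTIDE)
CXNCC_TEMPLATE = r"C.{{{nmin},{nmax}}}CC"
KTXXXW_RE = re.compile(r"KT...W")
TXXXW_RE = re.compile(r"T...W")
PDZ_TERM_RE = re.compile(r"[ST].[VL]$")

#: Residues scanned at a receptor C-terminus for the Dvl-binding motif
#: (cytoplasmic-tail surrogate).
DVL_TAIL_WINDOW = 80


@dataclass(frozen=True)
class MotifCall:
    seq_id: str
    motif_id: str
    start: int
    end: int
    matched: str


@dataclass(frozen=True)
class ClassifierParams:
    """Junction-window classifier settings.

    ``n_min``..``n_max`` is the admissible spacer of the C-Xn-CC motif;
    ``junction_window`` is how many residues after the last RXXR site are
    scanned for junction cysteines.
    """

    n_min: int = 6
    n_max: int = 8
    junction_window: int = 25

    def __post_init__(self) -> None:
        if not 0 < self.n_min <= self.n_max:
            raise ValueError("need 0 < n_min <= n_max")
        if self.junction_window < self.n_max + 3:
            raise ValueError("junction_window must cover the full motif")


@dataclass(frozen=True)
class LigandCall:
    """TGFbeta-superfamily subclass assignment with its motif evidence."""

    seq_id: str
    subclass: str  # TGFB_LIKE | BMP_LIKE | UNCLASSIFIED | NO_CLEAVAGE_SITE
    cleavage_span: tuple[int, int] | None
    window_cysteines: int
    motif_span: tuple[int, int] | None


def find_rxxr(seq: str, seq_id: str = "seq") -> list[MotifCall]:
    """All (possibly overlapping) R-x-x-R matches, left to right."""
    calls = []
    for m in RXXR_RE.finditer(seq):
        s = m.start()
        calls.append(MotifCall(seq_id, "RXXR", s, s + 4, seq[s : s + 4]))
    return calls


def classify_tgfb_ligand(
    seq: str, params: ClassifierParams | None = None, seq_id: str = "seq"
) -> LigandCall:
    """Assign a TGFbeta-superfamily subclass from junction cysteines.

    The most C-terminal RXXR is taken as the cleavage site; the window
    immediately downstream is scanned.  A C-X{n_min..n_max}-C-C motif marks
    a TGFbeta-like ligand, exactly one window cysteine a BMP-like one;
    anything else is unclassified, and without any RXXR no call is made.
    """
    params = params or ClassifierParams()
    sites = find_rxxr(seq, seq_id)
    if not sites:
        return LigandCall(seq_id, "NO_CLEAVAGE_SITE", None, 0, None)
    site = sites[-1]
    w0 = site.end
    window = seq[w0 : w0 + params.junction_window]
    pat = re.compile(CXNCC_TEMPLATE.format(nmin=params.n_min, nmax=params.n_max))
    m = pat.search(window)
    if m:
        return LigandCall(
            seq_id,
            "TGFB_LIKE",
            (site.start, site.end),
            window.count("C"),
            (w0 + m.start(), w0 + m.end()),
        )
    n_cys = window.count("C")
    if n_cys == 1:
        return LigandCall(seq_id, "BMP_LIKE", (site.start, site.end), 1, None)
    return LigandCall(seq_id, "UNCLASSIFIED", (site.start, site.end), n_cys, None)


def find_dvl_binding_motif(seq: str, tail_window: int = DVL_TAIL_WINDOW) -> str:
    """Dvl-binding motif state in the C-terminal tail: FULL, PARTIAL or ABSENT.

    FULL requires K-T-x-x-x-W; PARTIAL is T-x-x-x-W without the preceding
    lysine (the degenerate form seen in divergent frizzleds).
    """
    tail = seq[-tail_window:]
    if KTXXXW_RE.search(tail):
        return "FULL"
    for m in TXXXW_RE.finditer(tail):
        if m.start() == 0 or tail[m.start() - 1] != "K":
            return "PARTIAL"
    return "ABSENT"


def check_pdz_terminus(seq: str) -> bool:
    """True iff the final three residues are S/T, anything, V/L."""
    if len(seq) < 3:
        return False
    return bool(PDZ_TERM_RE.search(seq))


def conserved_cysteine_columns(
    alignment: Sequence[str], min_frac: float
) -> list[int]:
    """Columns whose cysteine fraction (gap-excluded denominator) >= min_frac."""
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    rows = list(alignment)
    if not rows:
        return []
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment: rows differ in length")
    out = []
    for j in range(width):
        col = [r[j] for r in rows if r[j] != "-"]
        if col and sum(c == "C" for c in col) / len(col) >= min_frac:
            out.append(j)
    return out
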
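"""Per-species pathway audit: presence / absence / degeneracy verdicts.

Each pathway component is searched for with a permissive translated search
(default E <= 1.0, so even highly divergent candidates are retrieved), the
best candidate is validated by a reciprocal search against a labelled
reference panel, and the component's diagnostic short motifs are then
evaluated on the candidate ORF.  A component with a validated hit but a
missing required motif is reported present-but-degenerate — the motif-level
surrogate for domain degeneracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .motifs import (
    CTNNB_BD_RE,
    check_pdz_terminus,
    classify_tgfb_ligand,
    find_dvl_binding_motif,
    find_rxxr,
)
from .orf import Contig, OrfRecord, hit_nt_span, longest_orf, orf_at
from .search import (
    Hit,
    ScoringScheme,
    TranslatedDb,
    best_hit,
    protein_search,
    translated_search,
)

PRESENT = "PRESENT"
PRESENT_DEGENERATE = "PRESENT_DEGENERATE"
ABSENT = "ABSENT"

_GLYPH = {PRESENT: "●", PRESENT_DEGENERATE: "◐", ABSENT: "○"}


def motif_present(motif_id: str, seq: str) -> bool:
    """Evaluate one required-motif rule on a candidate protein."""
    if motif_id == "KTXXXW":
        return find_dvl_binding_motif(seq) == "FULL"
    if motif_id == "PDZ_TERM":
        return check_pdz_terminus(seq)
    if motif_id == "RXXR":
        return bool(find_rxxr(seq))
    if motif_id == "CXNCC":
        return classify_tgfb_ligand(seq).subclass == "TGFB_LIKE"
    if motif_id == "CTNNB_BD":
        return bool(CTNNB_BD_RE.search(seq))
    raise ValueError(f"unknown motif id {motif_id!r}")


@dataclass(frozen=True)
class ComponentDef:
    """One pathway component to audit: query, pathway, motif requirements."""

    id: str
    pathway: str
    query: str  # protein sequence
    required_motifs: tuple[str, ...] = ()
    evalue: float = 1.0  # permissive, to retrieve divergent candidates

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("component E-value threshold must be positive")
        if not self.query:
            raise ValueError(f"component {self.id!r} has an empty query")


@dataclass(frozen=True)
class ComponentStatus:
    species: str
    component_id: str
    pathway: str
    status: str  # PRESENT | PRESENT_DEGENERATE | ABSENT
    hit: Hit | None = None
    orf: OrfRecord | None = None
    missing_motifs: tuple[str, ...] = ()
    evidence_tier: str = "motif"  # degeneracy evidence is motif-level only


def audit_component(
    cdef: ComponentDef,
    assembly: Iterable[Contig],
    panel: Mapping[str, tuple[str, str]],
    scheme: ScoringScheme | None = None,
    species: str = "sample",
    reverse_evalue: float = 1.0,
) -> ComponentStatus:
    """Audit one component against one assembly.

    ``panel`` maps reference id -> (protein, family label); the candidate's
    reverse best hit must carry the component's family label (the component
    id itself for the builtin panel) for the component to count as found.
    """
    scheme = scheme or ScoringScheme()
    db = assembly if isinstance(assembly, TranslatedDb) else TranslatedDb(assembly)
    fwd = translated_search(
        cdef.query, db, evalue_max=cdef.evalue, scheme=scheme, query_id=cdef.id
    )
    top = best_hit(fwd)
    if top is None:
        return ComponentStatus(species, cdef.id, cdef.pathway, ABSENT)
    panel_proteins = {pid: seq for pid, (seq, _) in panel.items()}
    # candidate ORFs: the stop-free stretch the forward hit sits in, then
    # the contig's longest ORF — raw length alone can pick a chance
    # antisense stretch over the true coding frame
    contig = db.contigs[top.subject_id]
    span = hit_nt_span(top.frame, top.s_start, top.s_end, len(contig.seq))
    candidates = [orf_at(contig, top.frame, *span)]
    full = longest_orf(contig)
    if full != candidates[0]:
        candidates.append(full)
    last_orf = None
    for orf in candidates:
        if orf is None or not orf.aa_seq:
            continue
        last_orf = orf
        rev = protein_search(
            orf.aa_seq,
            panel_proteins,
            evalue_max=reverse_evalue,
            scheme=scheme,
            query_id=cdef.id,
        )
        rtop = best_hit(rev)
        if rtop is not None and panel[rtop.subject_id][1] == cdef.id:
            missing = tuple(
                m for m in cdef.required_motifs if not motif_present(m, orf.aa_seq)
            )
            status = PRESENT_DEGENERATE if missing else PRESENT
            return ComponentStatus(
                species, cdef.id, cdef.pathway, status, hit=top, orf=orf,
                missing_motifs=missing,
            )
    return ComponentStatus(species, cdef.id, cdef.pathway, ABSENT, hit=top, orf=last_orf)


def audit_components(
    defs: Sequence[ComponentDef],
    assembly: Iterable[Contig],
    panel: Mapping[str, tuple[str, str]],
    scheme: ScoringScheme | None = None,
    species: str = "sample",
) -> list[ComponentStatus]:
    db = assembly if isinstance(assembly, TranslatedDb) else TranslatedDb(assembly)
    return [audit_component(d, db, panel, scheme, species) for d in defs]


def builtin_component_defs() -> list[ComponentDef]:
    """Component definitions and reciprocal panel from the synthetic roster."""
    from .synth import builtin_component_panel

    panel = builtin_component_panel()
    return [
        ComponentDef(c.id, c.pathway, c.seq, c.required_motifs) for c in panel.values()
    ]


def builtin_reverse_panel() -> dict[str, tuple[str, str]]:
    """id -> (protein, family label) mapping for the synthetic roster."""
    from .synth import builtin_component_panel

    return {c.id: (c.seq, c.id) for c in builtin_component_panel().values()}


def build_presence_matrix(statuses: Sequence[ComponentStatus]) -> pd.DataFrame:
    """Species x component table of presence glyphs.

    Cells are filled (PRESENT), half-filled (PRESENT_DEGENERATE) or open
    (ABSENT) circles; columns are ordered by pathway then component id.
    """
    seen = set()
    for s in statuses:
        key = (s.species, s.component_id)
        if key in seen:
            raise ValueError(f"duplicate status for {key}")
        seen.add(key)
    if not statuses:
        return pd.DataFrame()
    cols = sorted({(s.pathway, s.component_id) for s in statuses})
    col_ids = [c for _, c in cols]
    species = sorted({s.species for s in statuses})
    mat = pd.DataFrame(index=species, columns=col_ids, dtype=object)
    for s in statuses:
        mat.loc[s.species, s.component_id] = _GLYPH[s.status]
    return mat


def count_family_members(
    family_hits: Mapping[str, Sequence[Hit]],
    ligand_calls: Mapping[str, object] | None = None,
    ligand_family: str = "ligands",
) -> dict[str, int]:
    """Distinct-transcript counts per family, with ligand subclass tallies.

    ``family_hits`` maps a family name to the hits its queries produced;
    transcripts hit by several queries of one family count once (dedup by
    contig id).  ``ligand_calls`` maps contig id -> LigandCall for the
    ligand family's candidates.
    """
    counts: dict[str, int] = {}
    for family, hits in family_hits.items():
        counts[family] = len({h.subject_id for h in hits})
    if ligand_calls is not None:
        tally = {"TGFB_LIKE": 0, "BMP_LIKE": 0, "UNCLASSIFIED": 0, "NO_CLEAVAGE_SITE": 0}
        for call in ligand_calls.values():
            tally[call.subclass] += 1
        counts["tgfb_like"] = tally["TGFB_LIKE"]
        counts["bmp_like"] = tally["BMP_LIKE"]
        counts["unclassified"] = tally["UNCLASSIFIED"] + tally["NO_CLEAVAGE_SITE"]
    return counts


def classify_ligand_contigs(
    queries: Mapping[str, str],
    assembly: Iterable[Contig],
    evalue_max: float = 1.0,
    scheme: ScoringScheme | None = None,
):
    """Find ligand-like transcripts and classify each candidate's ORF.

    Returns (hits, {contig_id: LigandCall}) — one call per distinct contig,
    classified on its longest ORF.
    """
    scheme = scheme or ScoringScheme()
    db = assembly if isinstance(assembly, TranslatedDb) else TranslatedDb(assembly)
    by_id = db.contigs
    all_hits: list[Hit] = []
    for qid, qseq in queries.items():
        all_hits.extend(
            translated_search(qseq, db, evalue_max=evalue_max, scheme=scheme, query_id=qid)
        )
    calls = {}
    for cid in sorted({h.subject_id for h in all_hits}):
        orf = longest_orf(by_id[cid])
        calls[cid] = classify_tgfb_ligand(orf.aa_seq, seq_id=cid)
    return all_hits, calls
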
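"""Seeded synthetic transcriptomes with a planted-truth manifest.

Every downstream stage (search, CEG completeness, motif scanning, pathway
audit) is exercised against assemblies whose content is known exactly:
divergent orthologs of reference proteins are planted inside random UTR
flanks on random strands, TGFbeta-superfamily ligand architectures are
planted with controlled junction cysteine patterns, pathway components can
be selectively dropped (gene loss) or motif-knocked-out (domain
degeneracy), and unrelated decoy contigs provide the null background.

Nothing here models sequencing reads, assembly error, isoforms or
expression; contigs are clean transcript surrogates so that detection
logic, not assembly noise, is what gets tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .motifs import CTNNB_BD_PEPTIDE
from .orf import Contig, revcomp

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Residues used for synthetic protein backbones.  C, K, M, R, S, T and W are
#: excluded so that every cysteine pattern, furin site and short linear motif
#: in a synthetic protein is one that was planted deliberately.
SCAFFOLD_AA = "ADEFGHILNPQVY"

LIGAND_SUBCLASSES = ("TGFB_LIKE", "BMP_LIKE", "NEITHER")

DECOY = "DECOY"

_STOP_CODONS = ("TAA", "TAG", "TGA")


def _codon_choices() -> dict[str, tuple[str, ...]]:
    by_aa: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(codons)) for aa, codons in by_aa.items()}


_CODONS = _codon_choices()


def _positive_substitutions() -> dict[str, tuple[str, ...]]:
    """BLOSUM62-positive replacement sets (fallback: best-scoring non-self)."""
    mat = substitution_matrices.load("BLOSUM62")
    table: dict[str, tuple[str, ...]] = {}
    for a in AA20:
        pos = [b for b in AA20 if b != a and mat[a, b] > 0]
        if not pos:
            best = max(mat[a, b] for b in AA20 if b != a)
            pos = [b for b in AA20 if b != a and mat[a, b] == best]
        table[a] = tuple(pos)
    return table


_POSITIVE_SUBS = _positive_substitutions()


def mutate_protein(
    seq: str,
    target_identity: float,
    seed: int,
    protected: Iterable[tuple[int, int]] = (),
) -> str:
    """Introduce BLOSUM62-biased substitutions down to a target identity.

    Exactly round((1 - target_identity) * len(seq)) positions are replaced,
    each by a positive-scoring (homology-preserving) partner residue, so the
    realized identity equals the target up to rounding.  Half-open spans in
    ``protected`` are never mutated (used to keep planted motifs intact).
    """
    if not seq:
        raise ValueError("cannot mutate an empty sequence")
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    n_mut = round((1 - target_identity) * len(seq))
    if n_mut == 0:
        return seq
    shielded = set()
    for a, b in protected:
        shielded.update(range(a, b))
    eligible = [i for i in range(len(seq)) if i not in shielded and seq[i] in _POSITIVE_SUBS]
    rng = np.random.default_rng(seed)
    n_mut = min(n_mut, len(eligible))
    positions = rng.choice(len(eligible), size=n_mut, replace=False)
    out = list(seq)
    for p in sorted(int(i) for i in positions):
        i = eligible[p]
        choices = _POSITIVE_SUBS[out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


#: Robinson & Robinson background amino-acid frequencies — the composition
#: for which the published gapped BLOSUM62 Karlin-Altschul constants hold;
#: used to draw realistic null sequences for E-value calibration checks.
ROBINSON_FREQUENCIES = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

_RR_LETTERS = "".join(ROBINSON_FREQUENCIES)
_RR_P = np.array(list(ROBINSON_FREQUENCIES.values()))
_RR_P = _RR_P / _RR_P.sum()


def random_background_protein(rng: np.random.Generator, length: int) -> str:
    """Null protein drawn i.i.d. from the Robinson-Robinson composition."""
    idx = rng.choice(len(_RR_LETTERS), size=length, p=_RR_P)
    return "".join(_RR_LETTERS[int(i)] for i in idx)


def _random_protein(rng: np.random.Generator, length: int, alphabet: str = SCAFFOLD_AA) -> str:
    idx = rng.integers(len(alphabet), size=length)
    return "".join(alphabet[int(i)] for i in idx)


def _random_nt(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(4, size=length)
    return "".join("ACGT"[int(i)] for i in idx)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Reverse-translate with uniform choice among synonymous codons."""
    codons = []
    for aa in protein:
        try:
            options = _CODONS[aa]
        except KeyError:
            raise ValueError(f"cannot reverse-translate residue {aa!r}") from None
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


def _make_mature_scaffold() -> str:
    """Fixed 100-aa mature-domain stand-in carrying a 7-cysteine knot layout."""
    rng = np.random.default_rng(762031)
    body = list(_random_protein(rng, 100))
    for pos in (5, 35, 39, 68, 69, 83, 97):
        body[pos] = "C"
    return "".join(body)


MATURE_SCAFFOLD = _make_mature_scaffold()

#: Width of the prodomain/mature junction region emitted after the cleavage
#: site; matches the default classifier window.
JUNCTION_LEN = 25

CLEAVAGE_SITE = "RAKR"


def make_tgfb_ligand(subclass: str, seed: int) -> str:
    """Emit a synthetic TGFbeta-superfamily preproprotein.

    Layout: Met + cysteine-free prodomain, a single RXXR furin site, a
    25-residue junction whose cysteine content encodes the subclass
    (C-X{6..8}-C-C for TGFB_LIKE, exactly one cysteine for BMP_LIKE, none
    for NEITHER), then a fixed 7-cysteine mature scaffold.
    """
    if subclass not in LIGAND_SUBCLASSES:
        raise ValueError(f"unknown ligand subclass {subclass!r}")
    rng = np.random.default_rng(seed)
    prodomain = "M" + _random_protein(rng, int(rng.integers(90, 140)))
    junction = list(_random_protein(rng, JUNCTION_LEN))
    if subclass == "TGFB_LIKE":
        n = int(rng.integers(6, 9))  # spacer length 6..8
        start = int(rng.integers(0, JUNCTION_LEN - (n + 3) + 1))
        junction[start] = "C"
        junction[start + n + 1] = "C"
        junction[start + n + 2] = "C"
    elif subclass == "BMP_LIKE":
        junction[int(rng.integers(JUNCTION_LEN))] = "C"
    return prodomain + CLEAVAGE_SITE + "".join(junction) + MATURE_SCAFFOLD


def toy_ceg_reference(n_genes: int = 12, seed: int = 20_240_501):
    """Deterministic synthetic core-gene reference (protein + CDS pairs).

    A desk-scale stand-in for a core-eukaryotic-gene set: unrelated random
    proteins long enough for unambiguous reciprocal search.  Returns
    (proteins, cds) keyed by "CEG001".."CEGnnn".
    """
    rng = np.random.default_rng(seed)
    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    for i in range(n_genes):
        gid = f"CEG{i + 1:03d}"
        prot = "M" + _random_protein(rng, int(rng.integers(180, 261)), AA20.replace("C", ""))
        proteins[gid] = prot
        cds[gid] = reverse_translate(prot, rng)
    return proteins, cds


# ---------------------------------------------------------------------------
# Synthetic pathway-component panel
# ---------------------------------------------------------------------------

#: (component id, pathway, required motif ids)
COMPONENT_ROSTER: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("wnt", "WNT", ()),
    ("wls", "WNT", ()),
    ("dvl", "WNT", ()),
    ("fzdA", "WNT", ("KTXXXW",)),
    ("fzdB", "WNT", ("KTXXXW",)),
    ("porc", "WNT", ()),
    ("lrp", "WNT", ()),
    ("gsk3", "WNT", ()),
    ("axin", "WNT", ()),
    ("apc", "WNT", ()),
    ("bcat", "WNT", ("PDZ_TERM",)),
    ("tcf", "WNT", ("CTNNB_BD",)),
    ("groucho", "WNT", ()),
    ("delta", "NOTCH", ()),
    ("notch", "NOTCH", ()),
    ("furin", "NOTCH", ()),
    ("adam10_17", "NOTCH", ()),
    ("psen", "NOTCH", ()),
    ("pen2", "NOTCH", ()),
    ("aph1", "NOTCH", ()),
    ("ncstn", "NOTCH", ()),
    ("suh", "NOTCH", ()),
    ("ncor", "NOTCH", ()),
    ("tgfb_ligand", "TGFB", ()),
    ("tgfbr1", "TGFB", ()),
    ("tgfbr2", "TGFB", ()),
    ("smad1_5", "TGFB", ()),
    ("smad2_3", "TGFB", ()),
    ("smad4", "TGFB", ()),
)


@dataclass(frozen=True)
class PanelComponent:
    """One synthetic pathway component: sequence plus planted motif spans."""

    id: str
    pathway: str
    seq: str
    required_motifs: tuple[str, ...]
    motif_spans: Mapping[str, tuple[int, int]]


def builtin_component_panel(seed: int = 48_112) -> dict[str, PanelComponent]:
    """Deterministic synthetic component roster for the three pathways.

    Each component is an unrelated backbone protein; components whose audit
    involves a short linear motif carry it at its biologically expected
    position (Dvl-binding KTXXXW in the frizzled cytoplasmic tail, a
    C-terminal PDZ-binding tripeptide on beta-catenin, a placeholder
    catenin-binding peptide in TCF).
    """
    rng = np.random.default_rng(seed)
    panel: dict[str, PanelComponent] = {}
    for comp_id, pathway, required in COMPONENT_ROSTER:
        length = int(rng.integers(180, 241))
        body = list("M" + _random_protein(rng, length))
        spans: dict[str, tuple[int, int]] = {}
        if comp_id in ("fzdA", "fzdB"):
            pos = len(body) - 40
            motif = "KT" + _random_protein(rng, 3) + "W"
            body[pos : pos + 6] = motif
            spans["KTXXXW"] = (pos, pos + 6)
        if comp_id == "bcat":
            body[-3:] = "TKV"
            spans["PDZ_TERM"] = (len(body) - 3, len(body))
        if comp_id == "tcf":
            pos = 60
            body[pos : pos + len(CTNNB_BD_PEPTIDE)] = CTNNB_BD_PEPTIDE
            spans["CTNNB_BD"] = (pos, pos + len(CTNNB_BD_PEPTIDE))
        seq = "".join(body)
        if comp_id == "tgfb_ligand":
            seq = make_tgfb_ligand("TGFB_LIKE", int(rng.integers(2**31)))
            # keep the diagnostic architecture intact under divergence
            site = seq.rfind(CLEAVAGE_SITE)
            spans["RXXR"] = (site, site + 4)
            spans["CXNCC"] = (site + 4, site + 4 + JUNCTION_LEN)
        panel[comp_id] = PanelComponent(comp_id, pathway, seq, required, spans)
    return panel


# ---------------------------------------------------------------------------
# Transcriptome generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedGene:
    ref_id: str
    identity: float = 1.0
    fragmented: bool = False


@dataclass(frozen=True)
class ManifestEntry:
    ref_id: str  # reference/component/ligand id, or DECOY
    strand: str  # '+' or '-'
    cds_start: int  # 0-based half-open, forward-strand coords; stop excluded
    cds_end: int
    labels: tuple[str, ...] = ()


@dataclass
class TruthManifest:
    entries: dict[str, ManifestEntry] = field(default_factory=dict)

    def contigs_for(self, ref_id: str) -> list[str]:
        return [cid for cid, e in self.entries.items() if e.ref_id == ref_id]

    def labels(self, contig_id: str) -> tuple[str, ...]:
        return self.entries[contig_id].labels


@dataclass(frozen=True)
class SynthSpec:
    """Everything needed to regenerate one synthetic assembly byte-for-byte."""

    seed: int = 0
    n_decoys: int = 0
    decoy_len_range: tuple[int, int] = (300, 1200)
    utr_len_range: tuple[int, int] = (30, 300)
    planted_genes: tuple[PlantedGene, ...] = ()
    reference_proteins: Mapping[str, str] = field(default_factory=dict)
    ligand_plants: tuple[str, ...] = ()
    component_ids: tuple[str, ...] = ()
    dropped_components: frozenset = frozenset()
    motif_knockouts: frozenset = frozenset()  # of (component_id, motif_id)
    component_identity: float = 0.85

    def __post_init__(self) -> None:
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be non-negative")
        for lo, hi in (self.decoy_len_range, self.utr_len_range):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")
        for pg in self.planted_genes:
            if not 0 < pg.identity <= 1:
                raise ValueError(f"target identity for {pg.ref_id} not in (0, 1]")
            if pg.ref_id not in self.reference_proteins:
                raise ValueError(f"planted gene {pg.ref_id!r} has no reference protein")
        for label in self.ligand_plants:
            if label not in LIGAND_SUBCLASSES:
                raise ValueError(f"unknown ligand subclass {label!r}")
        if not 0 < self.component_identity <= 1:
            raise ValueError("component_identity must be in (0, 1]")


def _knockout(seq: str, spans: Mapping[str, tuple[int, int]], motifs: set[str]) -> str:
    out = list(seq)
    for motif in motifs:
        a, b = spans[motif]
        out[a:b] = "G" * (b - a)
    return "".join(out)


class _Builder:
    def __init__(self, spec: SynthSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.contigs: list[Contig] = []
        self.manifest = TruthManifest()

    def _next_id(self) -> str:
        return f"tig{len(self.contigs):05d}"

    def _utr(self) -> str:
        lo, hi = self.spec.utr_len_range
        return _random_nt(self.rng, int(self.rng.integers(lo, hi + 1)))

    def _emit_cds(self, protein: str, ref_id: str, labels: tuple[str, ...], with_stop: bool = True):
        cds = reverse_translate(protein, self.rng)
        stop = _STOP_CODONS[int(self.rng.integers(3))] if with_stop else ""
        utr5, utr3 = self._utr(), self._utr()
        construct = utr5 + cds + stop + utr3
        strand = "+" if self.rng.random() < 0.5 else "-"
        s, e = len(utr5), len(utr5) + len(cds)
        if strand == "-":
            L = len(construct)
            construct = revcomp(construct)
            s, e = L - e, L - s
        cid = self._next_id()
        self.contigs.append(Contig(cid, construct))
        self.manifest.entries[cid] = ManifestEntry(ref_id, strand, s, e, labels)

    def plant_protein(
        self,
        protein: str,
        ref_id: str,
        labels: tuple[str, ...] = (),
        fragmented: bool = False,
    ) -> None:
        if not fragmented:
            self._emit_cds(protein, ref_id, labels)
            return
        # split at a uniform random codon boundary; the stop travels with part 2
        k = int(self.rng.integers(1, len(protein)))
        self._emit_cds(protein[:k], ref_id, labels + ("FRAGMENT_1",), with_stop=False)
        self._emit_cds(protein[k:], ref_id, labels + ("FRAGMENT_2",))

    def decoy(self) -> None:
        lo, hi = self.spec.decoy_len_range
        seq = _random_nt(self.rng, int(self.rng.integers(lo, hi + 1)))
        cid = self._next_id()
        self.contigs.append(Contig(cid, seq))
        self.manifest.entries[cid] = ManifestEntry(DECOY, "+", 0, 0, ())


def generate_transcriptome(spec: SynthSpec) -> tuple[list[Contig], TruthManifest]:
    """Build a synthetic assembly and its ground-truth manifest.

    Emission order: planted reference genes, pathway components (minus
    dropped ones, motif knockouts applied), ligand plants, decoys — all
    drawn from one seeded generator so identical specs give byte-identical
    output.
    """
    b = _Builder(spec)
    for pg in spec.planted_genes:
        prot = spec.reference_proteins[pg.ref_id]
        if pg.identity < 1.0:
            prot = mutate_protein(prot, pg.identity, int(b.rng.integers(2**31)))
        b.plant_protein(prot, pg.ref_id, fragmented=pg.fragmented)

    if spec.component_ids:
        panel = builtin_component_panel()
        knockouts: dict[str, set[str]] = {}
        for comp_id, motif_id in spec.motif_knockouts:
            knockouts.setdefault(comp_id, set()).add(motif_id)
        for comp_id in spec.component_ids:
            if comp_id in spec.dropped_components:
                continue
            comp = panel[comp_id]
            seq = comp.seq
            labels: tuple[str, ...] = ()
            if comp_id in knockouts:
                seq = _knockout(seq, comp.motif_spans, knockouts[comp_id])
                labels = tuple(f"KO:{m}" for m in sorted(knockouts[comp_id]))
            if spec.component_identity < 1.0:
                protected = tuple(comp.motif_spans.values())
                seq = mutate_protein(
                    seq,
                    spec.component_identity,
                    int(b.rng.integers(2**31)),
                    protected=protected,
                )
            b.plant_protein(seq, comp_id, labels)

    for i, label in enumerate(spec.ligand_plants):
        seq = make_tgfb_ligand(label, int(b.rng.integers(2**31)))
        b.plant_protein(seq, f"ligand{i + 1:02d}", (label,))

    for _ in range(spec.n_decoys):
        b.decoy()
    return b.contigs, b.manifest


def manifest_protein(contig: Contig, entry: ManifestEntry) -> str:
    """Translate the manifest CDS span on the recorded strand."""
    from Bio.Seq import Seq

    nt = contig.seq[entry.cds_start : entry.cds_end]
    if entry.strand == "-":
        nt = revcomp(nt)
    return str(Seq(nt).translate())


def glass_sponge_spec(
    seed: int,
    full_knockouts: bool = False,
    n_decoys: int = 5,
    component_identity: float = 0.85,
) -> SynthSpec:
    """Study scenario: a syncytial-sponge-like assembly.

    Wnt pathway genes wnt, wls, dvl and fzdA are absent; the Dvl-binding
    KTXXXW motif is knocked out of fzdB; Notch and TGFbeta components are
    intact.  With ``full_knockouts`` the beta-catenin PDZ-binding terminus
    and the TCF catenin-binding peptide are knocked out as well.  Ligand
    plants mirror the observed tally: one TGFbeta-like, three BMP-like and
    one unclassifiable.
    """
    knockouts = {("fzdB", "KTXXXW")}
    if full_knockouts:
        knockouts |= {("bcat", "PDZ_TERM"), ("tcf", "CTNNB_BD")}
    return SynthSpec(
        seed=seed,
        n_decoys=n_decoys,
        component_ids=tuple(c for c, _, _ in COMPONENT_ROSTER),
        dropped_components=frozenset({"wnt", "wls", "dvl", "fzdA"}),
        motif_knockouts=frozenset(knockouts),
        ligand_plants=("TGFB_LIKE", "BMP_LIKE", "BMP_LIKE", "BMP_LIKE", "NEITHER"),
        component_identity=component_identity,
    )
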
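# Methods

This note records the models and procedures `toolkit-scan` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate
about real transcriptomes.

## Translated homology search

The search core is a full Smith–Waterman local alignment with affine gaps
rather than a seeded heuristic: inputs at the scale this package targets
(dozens of queries against thousands of contigs) make exactness affordable,
and exact scores are what allow the aligner to be validated against
brute-force oracles. Scoring defaults are BLOSUM62 with gap open 11 and gap
extend 1 (a gap of length *k* costs 11 + *k*), the scheme for which
published gapped Karlin–Altschul constants exist.

Protein queries are aligned against all six frame translations of each
contig ("tblastn-style"). Stop codons translate to `*` and are excluded
from alignments in the strict sense: the substitution score of any column
involving a stop is a large negative number, *and* gap moves that would
consume a stop position are forbidden in the DP recurrence. Without the
second rule a plain affine DP can skip a stop with a ~12-point query gap,
which silently merges two reading-frame fragments into one alignment.

Expectation values use `E = K·m·n·exp(−λS)` with λ = 0.267 and K = 0.041
(the published gapped BLOSUM62 11/1 calibration), where *m* is the query
length and *n* the summed length of all frame translations (or all subject
proteins). Both constants are fields of `ScoringScheme` and can be
overridden. Two deliberate simplifications: no composition-based score
adjustment and no finite-size ("effective length") correction. The formula
is therefore asymptotic; its accuracy is checked empirically by the null
calibration (below). A reported E-value of "0.0" in the literature is a
display artifact of floating-point underflow, operationalized here as
E ≤ 1e-180.

**Null calibration.** Queries and decoy residues for the calibration check
are drawn i.i.d. from the Robinson–Robinson background amino-acid
frequencies — the composition for which the published λ and K are defined —
with query length 300 aa, a typical protein length and the scale at which
the asymptotic formula applies (for 100-aa queries, edge effects make the
uncorrected formula conservative by several fold). The measured mean count
of E ≤ 1 hits per query against ~10⁶ aa of decoy is within a factor of
three of the theoretical expectation of one.

## ORF extraction

An "ORF" is the longest stop-free translated stretch, stop-to-stop, with
frame ends counting as boundaries and no initiator-Met requirement:
assembled transcripts are arbitrarily 5′-truncated, and demanding ATG would
discard valid partial CDS. Codons containing N translate to X, and X does
not terminate a stretch (conservative retention). Coordinates are reported
on the forward strand, 0-based half-open; ties break by frame order
+1, +2, +3, −1, −2, −3, then by smaller start coordinate.

**Candidate-ORF choice in reciprocal protocols.** The globally longest
stop-free stretch of a transcript is *usually* the coding region, but not
always: reverse complements of coding sequence are stop-poor, so a chance
antisense stretch can outrun the true frame — with the short (~200 aa)
synthetic genes used here this happens in roughly 1–3% of plants, and it
occurs in real transcripts too. Both reciprocal protocols therefore
validate first the stop-free stretch that *contains the forward hit* (well
defined, because alignments cannot cross stops, so a hit span lies within
exactly one maximal stretch of its frame), and fall back to the globally
longest ORF. Nothing else is tried: restricting candidates to these two
keeps specificity identical to the longest-ORF-only protocol, because every
candidate must still pass the reverse search. Exhaustively walking all six
per-frame ORFs was tried and rejected — at the audit's permissive reverse
threshold it lets junk ORFs validate genuinely absent components.

## CEG reciprocal-best-hit completeness

Per core gene: forward translated search at E ≤ 1e-5; the best-hit contig
becomes the candidate (`max_candidates` allows considering further distinct
contigs, for fragmented assemblies); the candidate ORF is searched back
against the *entire* reference protein set at E ≤ 1e-5. Verdicts:

- `RECOVERED_DIRECT` — reverse best hit is the original gene;
- `RECOVERED_INPARALOG` — reverse best hit is a different reference gene
  with query coverage > 0.99 and E ≤ 1e-180, restricted by default to the
  gene's in-paralog group (`rescue="grouped"`); `rescue="any"` accepts any
  reference gene meeting the coverage/E-value predicates, since the two
  readings of "a similar reference sequence" are both defensible;
- `MISSING` otherwise.

Completeness is `100 × recovered / total`. The reverse step is
protein-vs-protein rather than protein-vs-CDS: identical in intent, and it
avoids re-deriving frames for sequences whose protein form is known.

In-paralog groups are single-linkage clusters over the pairwise global
identity matrix (Needleman–Wunsch via Biopython, BLOSUM62 11/1, identity =
identical columns / alignment length), threshold 0.95 by default. The
threshold is a package choice — identity matrices in the literature are
used alongside trees without a stated cutoff — and is exposed in the API.

The bundled reference is a deterministic *synthetic* 12-gene toy set
(`data/toy_cegs_*.fasta`, regenerable from `toy_ceg_reference()`): unrelated
random proteins of 180–260 aa with cysteine excluded from their alphabet so
that cysteine-motif rules never fire on them by accident. Real CEG sets are
supplied by the user as FASTA; rebuilding the canonical 248-gene human set
requires external downloads and is out of scope for the test suite.

## TGFβ-superfamily ligand classification

The classifier encodes the junction-cysteine rule: locate the **last**
(most C-terminal) RXXR — furin sites precede the mature domain in the
C-terminal third of preproproteins — and scan a fixed window immediately
downstream (default 25 aa; the mature-peptide start is an
alignment-level concept a rule engine cannot assume, so a window stands in
for "between the cleavage site and the mature peptide"). `C-X{n}-C-C` with
n ∈ [6, 8] ⇒ `TGFB_LIKE`; exactly one window cysteine ⇒ `BMP_LIKE`;
otherwise `UNCLASSIFIED`; no RXXR anywhere ⇒ `NO_CLEAVAGE_SITE`. Window
width and spacer bounds are `ClassifierParams` fields. The spacer pattern
is `C[^C]`-free by construction in the generator but the matcher itself
allows any residue as spacer (`C.{6,8}CC`); whether boundary cysteines
should count as spacer is not decidable from the published rule, and the
window formulation makes the choice explicit.

Other motif rules: Dvl-binding `KTXXXW` searched in the C-terminal 80
residues (a cytoplasmic-tail surrogate; `PARTIAL` means `TxxxW` without the
preceding lysine, the degenerate form observed in divergent frizzleds);
PDZ-binding terminus = final tripeptide `[ST].[VL]`; conserved-cysteine
columns of an alignment use gap-excluded denominators so partial sequences
do not dilute conservation.

## Pathway audit

Components are searched at the permissive default E ≤ 1.0 (to retrieve
highly divergent candidates), reciprocally validated against a labelled
panel (`id|family` FASTA; the best reverse partner must carry the
component's family label), and then scored against their required motifs:
`PRESENT`, `PRESENT_DEGENERATE` (validated hit, ≥1 required motif missing),
`ABSENT`. Degeneracy evidence is motif-level only — profile/HMM domain
analysis is delegated to external annotators — and statuses carry an
explicit `evidence_tier="motif"` marker so that motif-level calls are never
silently conflated with domain-level ones. The presence matrix is a pure
function of statuses: one row per species, columns ordered by pathway then
component id, glyphs ●/◐/○.

Family counts deduplicate by contig id (one transcript hit by several
queries of a family counts once) and carry subclass tallies for ligands.

## Synthetic-data generator

The generator emulates exactly the features the pipeline must detect:

- **Planted orthologs**: reference proteins are mutated to a target
  identity by replacing `round((1−t)·len)` positions with BLOSUM62-positive
  partners (homology-preserving divergence; realized identity equals the
  target up to rounding), reverse-translated with uniform synonymous-codon
  choice (no codon-usage model is needed to exercise search), given a stop
  codon and random 30–300 nt UTR flanks, and placed on a random strand.
- **Ligand plants**: Met + cysteine-free prodomain (90–140 aa), single
  `RAKR` site, 25-aa junction whose cysteine content encodes the subclass,
  then a fixed 100-aa mature scaffold carrying a 7-cysteine knot layout.
- **Component plants**: a fixed 29-component roster across Wnt, Notch and
  TGFβ. Backbones are drawn from a restricted alphabet (no C, K, M, R, S,
  T, W) so every motif present is one that was planted; diagnostic motifs
  sit at their biologically expected positions. Components are planted at
  85% identity by default with motif spans protected from mutation;
  knockouts scramble the span to glycines. Dropped components are simply
  not emitted.
- **Decoys**: i.i.d. uniform nucleotides, which keeps their expected
  alignment statistics at the null.
- **Fragmented plants** split the CDS at a uniform random codon boundary
  across two contigs, emulating assembly incompleteness.

Everything derives from one seeded generator in a fixed emission order, so
an identical spec yields byte-identical FASTA and manifest. The truth
manifest records, per contig, the planted reference id (or `DECOY`),
strand, CDS coordinates (stop codon excluded) and labels (ligand subclass,
knockouts, fragment parts).

What the generator does **not** model: sequencing reads and their error
profiles, chimeric or misassembled contigs, splice isoforms, expression
levels, codon bias, or realistic UTR composition. Passing the planted-truth
tests therefore demonstrates that the *decision logic* is correct under
clean inputs with known answers; it does not certify recall on noisy real
assemblies, where fragmentation and contamination dominate.

## Scenario used for the headline check

`glass_sponge_spec(seed)` builds the study condition: all 29 components
except {wnt, wls, dvl, fzdA}, the KTXXXW motif knocked out of fzdB
(optionally also bcat's PDZ terminus and tcf's catenin-binding placeholder
peptide), ligand plants of one TGFβ-like, three BMP-like and one
unclassifiable architecture, five decoys. The acceptance check requires the
audit matrix to read exactly: those four Wnt genes `ABSENT`, fzdB
`PRESENT_DEGENERATE` missing only KTXXXW, and every Notch/TGFβ component
`PRESENT`, across 20 seeds.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for a single CPU: 12-gene
reference, assemblies of 12–35 contigs, 1000 oracle alignment pairs
(length ≤ 12, six-letter alphabet), 500 oracle contigs (≤ 300 nt), 50
seeds for divergent-plant recovery, 100 decoy-only seeds, 20 scenario
seeds, and ~10⁶ aa of decoy for the null calibration. The alignment kernel
is JIT-compiled (numba) with a score-only linear-memory pass first and full
traceback only for alignments that can pass the E-value cutoff.

Degenerate inputs: empty assemblies give 0% completeness with every gene
`MISSING`; an empty length list has no N50 (error), an empty assembly
reports `n50 = None`; contigs shorter than one codon yield zero-length ORF
records; sequences with letters outside A/C/G/T/N are rejected at ingest.
N50 uses "cumulative sum ≥ half" at the boundary (the dominant convention;
values are convention-sensitive at ties). N50 is *not* monotone under
lengthening an arbitrary contig (growing a short contig raises the
half-total threshold without joining the covering set); only growing the
longest contig is guaranteed weakly monotone, and the tests pin both facts.

## Known limitations

- E-values are asymptotic Karlin–Altschul, without composition adjustment
  or length correction; absolute values for short queries are conservative
  relative to production search tools, so numerical E-values will differ
  from published runs even where verdicts agree.
- In-paralog detection is identity-threshold single linkage; no
  phylogenetic confirmation.
- Degeneracy calls are short-motif-based only; missing domains detectable
  only by profile methods are out of scope.
- The reciprocal protocols examine one candidate contig per gene by
  default; heavily fragmented assemblies need `max_candidates > 1` and
  still lose genes whose fragments individually fail coverage predicates —
  which is precisely the real-world effect the fragmentation option exists
  to emulate.
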
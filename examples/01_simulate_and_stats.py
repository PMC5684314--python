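"""Generate a synthetic transcriptome and summarize it.

Builds an assembly with twelve planted core genes and a handful of decoy
contigs, then prints the standard assembly statistics.
"""

from toolkit_scan.stats import transcriptome_stats
from toolkit_scan.synth import PlantedGene, SynthSpec, generate_transcriptome, toy_ceg_reference

proteins, _ = toy_ceg_reference()
spec = SynthSpec(
    seed=42,
    n_decoys=6,
    planted_genes=tuple(PlantedGene(g, identity=0.85) for g in proteins),
    reference_proteins=proteins,
)
contigs, manifest = generate_transcriptome(spec)

st = transcriptome_stats(contigs)
print(f"contigs:  {st.n_contigs}")
print(f"total bp: {st.total_bp}")
print(f"N50:      {st.n50}")
n_planted = sum(e.ref_id != "DECOY" for e in manifest.entries.values())
print(f"planted ortholog contigs: {n_planted}, decoys: {st.n_contigs - n_planted}")
# N50 is the contig length at which the longest contigs cover half the
# assembly; planted contigs carry a mutated coding sequence inside random
# UTR flanks on a random strand, decoys are uniform random nucleotides.
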
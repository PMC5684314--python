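"""Classify TGFbeta-superfamily ligands from junction cysteine patterns.

The rule: find the last furin cleavage site (RXXR), scan the 25 residues
after it; a C-X{6..8}-C-C motif marks a TGFbeta-like ligand, exactly one
cysteine a BMP-like one.  We generate one ligand of each architecture and
one edge case with an out-of-range spacer.
"""

from toolkit_scan.motifs import classify_tgfb_ligand
from toolkit_scan.synth import make_tgfb_ligand

for label in ("TGFB_LIKE", "BMP_LIKE", "NEITHER"):
    seq = make_tgfb_ligand(label, seed=11)
    call = classify_tgfb_ligand(seq, seq_id=label.lower())
    print(
        f"planted {label:<10} -> {call.subclass:<16} "
        f"cleavage at {call.cleavage_span}, window cysteines: {call.window_cysteines}"
    )

# spacer of 9 residues: one too many, so the motif is rejected
edge = "MAEVLDNQGH" + "RAKR" + "AA" + "C" + "A" * 9 + "CC" + "AAAA"
print(f"spacer n=9          -> {classify_tgfb_ligand(edge).subclass}")
# NEITHER plants carry a cleavage site but no junction cysteines at all,
# which is why they come back UNCLASSIFIED rather than NO_CLEAVAGE_SITE.
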
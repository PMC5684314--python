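"""Synthetic transcriptome generation and planted ground truth."""

from __future__ import annotations

import pytest
from Bio.Align import substitution_matrices
from scipy.stats import binomtest

from toolkit_scan.io import write_fasta
from toolkit_scan.motifs import classify_tgfb_ligand
from toolkit_scan.synth import (
    DECOY,
    JUNCTION_LEN,
    PlantedGene,
    SynthSpec,
    builtin_component_panel,
    generate_transcriptome,
    glass_sponge_spec,
    make_tgfb_ligand,
    manifest_protein,
    mutate_protein,
    toy_ceg_reference,
)


class TestMutateProtein:
    def test_identity_one_returns_input(self):
        assert mutate_protein("MKVLL", 1.0, seed=3) == "MKVLL"

    def test_realized_identity_matches_target(self):
        seq = "ACDEFGHIKL" * 10
        out = mutate_protein(seq, 0.8, seed=1)
        matches = sum(a == b for a, b in zip(seq, out))
        assert len(out) == 100
        assert 78 <= matches <= 82

    def test_single_residue_degenerate_case(self):
        out = mutate_protein("M", 0.5, seed=1)
        assert len(out) == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mutate_protein("", 0.5, seed=1)

    def test_invalid_identity_rejected(self):
        with pytest.raises(ValueError):
            mutate_protein("MKV", 0.0, seed=1)

    def test_substitutions_are_blosum_positive(self):
        mat = substitution_matrices.load("BLOSUM62")
        seq = "ACDEFGHIKLMNPQRSTVWY" * 10
        out = mutate_protein(seq, 0.5, seed=9)
        for a, b in zip(seq, out):
            if a != b:
                assert mat[a, b] > 0 or mat[a, b] == max(
                    mat[a, c] for c in "ACDEFGHIKLMNPQRSTVWY" if c != a
                )

    def test_protected_spans_untouched(self):
        seq = "ACDEFGHIKL" * 20
        out = mutate_protein(seq, 0.5, seed=2, protected=[(50, 60)])
        assert out[50:60] == seq[50:60]


class TestMakeLigand:
    def test_planted_subclasses_classify_by_construction(self):
        for seed in range(50):
            for label, expected in [
                ("TGFB_LIKE", "TGFB_LIKE"),
                ("BMP_LIKE", "BMP_LIKE"),
                ("NEITHER", "UNCLASSIFIED"),
            ]:
                seq = make_tgfb_ligand(label, seed)
                assert classify_tgfb_ligand(seq).subclass == expected

    def test_single_rxxr_site(self):
        from toolkit_scan.motifs import find_rxxr

        for seed in (1, 7, 23):
            assert len(find_rxxr(make_tgfb_ligand("BMP_LIKE", seed))) == 1

    def test_bmp_junction_has_exactly_one_cysteine(self):
        seq = make_tgfb_ligand("BMP_LIKE", 7)
        site = seq.rfind("RAKR") + 4
        assert seq[site : site + JUNCTION_LEN].count("C") == 1

    def test_unknown_subclass_rejected(self):
        with pytest.raises(ValueError):
            make_tgfb_ligand("SMAD", 1)


class TestGenerateTranscriptome:
    def test_decoys_only(self):
        contigs, manifest = generate_transcriptome(SynthSpec(seed=1, n_decoys=5))
        assert len(contigs) == 5
        assert all(e.ref_id == DECOY for e in manifest.entries.values())

    def test_round_trip_at_identity_one(self, toy_reference):
        proteins = toy_reference.proteins
        spec = SynthSpec(
            seed=11,
            planted_genes=tuple(PlantedGene(g, 1.0) for g in list(proteins)[:10]),
            reference_proteins=proteins,
        )
        contigs, manifest = generate_transcriptome(spec)
        assert len(contigs) == 10
        by_id = {c.id: c for c in contigs}
        for cid, entry in manifest.entries.items():
            assert manifest_protein(by_id[cid], entry) == proteins[entry.ref_id]

    def test_manifest_coordinates_within_bounds(self):
        spec = glass_sponge_spec(seed=2)
        contigs, manifest = generate_transcriptome(spec)
        by_id = {c.id: c for c in contigs}
        for cid, e in manifest.entries.items():
            assert 0 <= e.cds_start <= e.cds_end <= len(by_id[cid])

    def test_dropped_components_not_emitted(self):
        spec = glass_sponge_spec(seed=4)
        _, manifest = generate_transcriptome(spec)
        refs = {e.ref_id for e in manifest.entries.values()}
        assert refs.isdisjoint({"wnt", "wls", "dvl", "fzdA"})
        assert {"apc", "axin", "bcat", "fzdB", "tcf", "gsk3"} <= refs

    def test_motif_knockouts_labelled(self):
        _, manifest = generate_transcriptome(glass_sponge_spec(seed=4))
        ko = [e for e in manifest.entries.values() if e.ref_id == "fzdB"]
        assert len(ko) == 1 and ko[0].labels == ("KO:KTXXXW",)

    def test_fragmented_plant_splits_protein(self, toy_reference):
        proteins = toy_reference.proteins
        gid = next(iter(proteins))
        spec = SynthSpec(
            seed=6,
            planted_genes=(PlantedGene(gid, 1.0, fragmented=True),),
            reference_proteins=proteins,
        )
        contigs, manifest = generate_transcriptome(spec)
        assert len(contigs) == 2
        by_id = {c.id: c for c in contigs}
        parts = {e.labels[-1]: manifest_protein(by_id[cid], e) for cid, e in manifest.entries.items()}
        assert parts["FRAGMENT_1"] + parts["FRAGMENT_2"] == proteins[gid]

    def test_determinism_byte_identical(self, tmp_path, toy_reference):
        proteins = toy_reference.proteins
        spec = SynthSpec(
            seed=13,
            n_decoys=4,
            planted_genes=(PlantedGene(next(iter(proteins)), 0.8),),
            reference_proteins=proteins,
        )
        paths = []
        for run in (1, 2):
            contigs, _ = generate_transcriptome(spec)
            p = tmp_path / f"run{run}.fasta"
            write_fasta(contigs, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]
        contigs_other, _ = generate_transcriptome(
            SynthSpec(
                seed=14,
                n_decoys=4,
                planted_genes=(PlantedGene(next(iter(proteins)), 0.8),),
                reference_proteins=proteins,
            )
        )
        assert [c.seq for c in contigs_other] != [c.seq for c in contigs]

    def test_strand_balance_over_many_plants(self):
        proteins = {"g": "M" + "AVLDE" * 8}
        strands = []
        for seed in range(250):
            spec = SynthSpec(
                seed=seed,
                planted_genes=tuple(PlantedGene("g") for _ in range(4)),
                reference_proteins=proteins,
            )
            _, manifest = generate_transcriptome(spec)
            strands.extend(e.strand for e in manifest.entries.values())
        n_plus = sum(s == "+" for s in strands)
        assert binomtest(n_plus, len(strands), 0.5).pvalue > 0.01

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SynthSpec(n_decoys=-1)
        with pytest.raises(ValueError):
            SynthSpec(planted_genes=(PlantedGene("missing"),))
        with pytest.raises(ValueError):
            SynthSpec(ligand_plants=("WNT_LIKE",))


def test_toy_reference_is_deterministic_and_bundled(toy_reference):
    proteins, cds = toy_ceg_reference()
    assert proteins == toy_reference.proteins
    assert len(proteins) == 12
    from toolkit_scan.ceg import load_toy_reference

    bundled = load_toy_reference()
    assert bundled.proteins == proteins
    assert bundled.cds == cds


def test_component_panel_motifs_in_place():
    panel = builtin_component_panel()
    assert len(panel) == 29
    fzdB = panel["fzdB"]
    a, b = fzdB.motif_spans["KTXXXW"]
    assert fzdB.seq[a] == "K" and fzdB.seq[b - 1] == "W"
    assert len(fzdB.seq) - a <= 80  # inside the cytoplasmic-tail window
    assert panel["bcat"].seq.endswith("TKV")
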
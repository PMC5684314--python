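"""File formats: FASTA in/out, truth manifests, tabular hit exports."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .orf import Contig, OrfRecord
from .search import Hit
from .synth import ManifestEntry, TruthManifest

MANIFEST_COLUMNS = ("contig_id", "ref_id", "strand", "cds_start", "cds_end", "labels")


from contextlib import contextmanager


@contextmanager
def _writable(target):
    """Accept either a path or an open file-like object."""
    if hasattr(target, "write"):
        yield target
    else:
        with open(target, "w") as fh:
            yield fh


def read_fasta_contigs(path) -> list[Contig]:
    return [Contig(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def read_fasta_proteins(path) -> dict[str, str]:
    return {r.id: str(r.seq).rstrip("*") for r in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str] | Contig], path, width: int = 60) -> None:
    """Write FASTA wrapped at ``width`` columns (byte-stable output)."""
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.seq) if isinstance(rec, Contig) else rec
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_manifest(manifest: TruthManifest, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for cid, e in manifest.entries.items():
            labels = ",".join(e.labels) if e.labels else "."
            fh.write(f"{cid}\t{e.ref_id}\t{e.strand}\t{e.cds_start}\t{e.cds_end}\t{labels}\n")


def read_manifest(path) -> TruthManifest:
    manifest = TruthManifest()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("contig_id"):
                continue
            cid, ref, strand, s, e, labels = line.rstrip("\n").split("\t")
            lab = () if labels == "." else tuple(labels.split(","))
            manifest.entries[cid] = ManifestEntry(ref, strand, int(s), int(e), lab)
    return manifest


def write_orf_table(orfs: Iterable[OrfRecord], path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("contig_id\tframe\tnt_start\tnt_end\taa_len\taa_seq\n")
        for o in orfs:
            fh.write(f"{o.contig_id}\t{o.frame:+d}\t{o.nt_start}\t{o.nt_end}\t{o.aa_len}\t{o.aa_seq}\n")


def write_hit_table(hits: Iterable[Hit], path, header_lines: Sequence[str] = ()) -> None:
    """12-column tabular export (1-based inclusive coordinates, the de facto
    standard for alignment hit tables; everything in-memory stays 0-based)."""
    with _writable(path) as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for h in hits:
            mism = round((1 - h.identity_frac) * h.aln_len)
            fields = (
                h.query_id,
                h.subject_id,
                f"{100 * h.identity_frac:.2f}",
                h.aln_len,
                mism,
                0,
                h.q_start + 1,
                h.q_end,
                h.s_start + 1,
                h.s_end,
                f"{h.evalue:.2e}",
                f"{h.bit_score:.1f}",
            )
            fh.write("\t".join(str(f) for f in fields) + "\n")


def write_json(obj, path, header: Mapping | None = None) -> None:
    payload = dict(obj)
    if header:
        payload = {"_provenance": dict(header), **payload}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")


def params_hash(params: Mapping) -> str:
    blob = json.dumps({k: repr(v) for k, v in sorted(params.items())}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
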
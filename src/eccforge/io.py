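"""Reading and writing the pipeline's on-disk formats.

Conventions: BED on disk is 0-based half-open; GFF3 is 1-based closed.
Gene models are written as `gene` records with `five_prime_UTR` / `CDS` /
`three_prime_UTR` children sharing the gene's ID in their Parent
attribute.  Track features go to BED6 plus extra columns
kind/class1/superfamily/subfamily[/monomer_length]; loci go to BED6 with
name = locus_id and score = supporting read count.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .caller import EccLocus
from .sim.genome import GeneModel, TrackFeature


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    with Fasta(str(path), as_raw=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fastq(reads: dict[str, str], path, quality: int = 20) -> None:
    records = []
    for read_id, seq in reads.items():
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")}


def write_genes_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write("\t".join(map(str, [
                g.chrom, "eccforge", "gene", g.start + 1, g.end, ".",
                g.strand, ".", f"ID={g.gene_id}"])) + "\n")
            for kind, ivs in (("five_prime_UTR", g.utr5), ("CDS", g.cds_exons),
                              ("three_prime_UTR", g.utr3)):
                for s, e in ivs:
                    fh.write("\t".join(map(str, [
                        g.chrom, "eccforge", kind, s + 1, e, ".", g.strand,
                        ".", f"Parent={g.gene_id}"])) + "\n")


def read_genes_gff3(path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _, kind, start, end, _, strand, _, attrs = \
                line.rstrip("\n").split("\t")[:9]
            start, end = int(start) - 1, int(end)
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if kind == "gene":
                gid = fields["ID"]
                genes[gid] = GeneModel(gid, chrom, start, end, strand)
            else:
                parent = fields.get("Parent")
                if parent not in genes:
                    continue
                target = {"five_prime_UTR": "utr5", "CDS": "cds_exons",
                          "three_prime_UTR": "utr3"}.get(kind)
                if target:
                    getattr(genes[parent], target).append((start, end))
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start))


_TRACK_COLS = ["chrom", "start", "end", "feature_id", "score", "strand",
               "kind", "class1", "superfamily", "subfamily", "monomer_length"]


def write_tracks_bed(tracks: list[TrackFeature], path) -> None:
    rows = [[t.chrom, t.start, t.end, t.feature_id, 0, t.strand, t.kind,
             t.class1, t.superfamily, t.subfamily,
             t.monomer_length if t.monomer_length is not None else "."]
            for t in tracks]
    pd.DataFrame(rows, columns=_TRACK_COLS).to_csv(
        path, sep="\t", header=False, index=False)


def read_tracks_bed(path) -> list[TrackFeature]:
    frame = pd.read_csv(path, sep="\t", header=None, names=_TRACK_COLS,
                        dtype={"monomer_length": str})
    out = []
    for row in frame.itertuples(index=False):
        mono = None if row.monomer_length in (".", None) else int(float(row.monomer_length))
        out.append(TrackFeature(
            row.feature_id, row.kind, row.chrom, int(row.start), int(row.end),
            row.strand, row.class1,
            "" if pd.isna(row.superfamily) else row.superfamily,
            "" if pd.isna(row.subfamily) else row.subfamily,
            mono))
    return out


def write_loci_bed(loci: list[EccLocus], path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.locus_id}\t{l.n_reads}\t.\n")


def read_loci_bed(path, sample_id: str) -> list[EccLocus]:
    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, score = line.split("\t")[:5]
            loci.append(EccLocus(name, sample_id, chrom, int(start), int(end),
                                 int(score), float("nan")))
    return loci


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")
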
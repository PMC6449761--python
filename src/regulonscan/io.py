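"""Readers and writers for the standard formats the pipeline touches.

GenBank flat files and FASTA go through Biopython; GFF3 is handled as the
9-column tab-separated table it is.  All exported interval files use BED
conventions (0-based half-open); GenBank/GFF3 1-based inclusive coordinates
are converted at this boundary only.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .footprint import RegionAlignment
from .genome import Gene, Genome
from .pwm import Motif
from .regulon import Operon
from .scan import SiteHit

logger = logging.getLogger(__name__)

__all__ = [
    "read_genbank", "write_genbank",
    "read_gff_fasta", "write_gff_fasta",
    "gene_table", "write_gene_table",
    "hits_to_frame", "write_hits_tsv", "write_hits_bed",
    "write_motif_meme", "write_motif_tsv", "read_motif_tsv",
    "write_alignment_fasta", "write_operons_gff",
]


# ---------------------------------------------------------------- genomes ---

def read_genbank(path: str | Path, genome_id: str | None = None) -> Genome:
    """Read sequence and CDS features from a GenBank flat file.

    ``gene_id`` comes from the locus_tag (falling back to protein_id or a
    positional identifier).  Compound (joined) locations are collapsed to
    their outermost span with a warning.
    """
    contigs: dict[str, str] = {}
    genes: list[Gene] = []
    records = list(SeqIO.parse(str(path), "genbank"))
    gid = genome_id or (records[0].id if records else Path(path).stem)
    for rec in records:
        contigs[rec.id] = str(rec.seq).upper()
        for n, feat in enumerate(rec.features):
            if feat.type != "CDS":
                continue
            if len(feat.location.parts) > 1:
                logger.warning("compound CDS location in %s; using outermost span", rec.id)
            tag = feat.qualifiers.get("locus_tag", feat.qualifiers.get("protein_id", [f"cds{n}"]))[0]
            genes.append(Gene(
                gene_id=tag, contig_id=rec.id,
                start=int(feat.location.start), end=int(feat.location.end),
                strand="+" if feat.location.strand >= 0 else "-",
                locus_tag=tag,
                product=feat.qualifiers.get("product", [""])[0],
            ))
    return Genome(gid, contigs, genes)


def write_genbank(genome: Genome, path: str | Path) -> None:
    records = []
    for contig_id, seq in genome.contigs.items():
        rec = SeqRecord(Seq(seq), id=contig_id, name=contig_id[:16],
                        description=genome.genome_id,
                        annotations={"molecule_type": "DNA"})
        for g in genome.genes:
            if g.contig_id != contig_id:
                continue
            loc = FeatureLocation(g.start, g.end, strand=1 if g.strand == "+" else -1)
            rec.features.append(SeqFeature(loc, type="CDS", qualifiers={
                "locus_tag": [g.locus_tag or g.gene_id],
                "product": [g.product or "hypothetical protein"],
            }))
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def read_gff_fasta(gff_path: str | Path, fasta_path: str | Path,
                   genome_id: str | None = None) -> Genome:
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    frame = pd.read_csv(gff_path, sep="\t", comment="#", header=None, names=_GFF_COLS)
    genes = []
    for n, row in enumerate(frame.itertuples(index=False)):
        if row.type != "CDS":
            continue
        attrs = dict(kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv)
        gid = attrs.get("ID", attrs.get("locus_tag", f"cds{n}"))
        genes.append(Gene(gid, str(row.seqid), int(row.start) - 1, int(row.end),
                          str(row.strand), locus_tag=attrs.get("locus_tag", gid),
                          product=attrs.get("product", "")))
    return Genome(genome_id or Path(gff_path).stem, contigs, genes)


def write_gff_fasta(genome: Genome, gff_path: str | Path, fasta_path: str | Path) -> None:
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id};locus_tag={g.locus_tag or g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write("\t".join([g.contig_id, "regulonscan", "CDS", str(g.start + 1),
                                str(g.end), ".", g.strand, "0", attrs]) + "\n")
    SeqIO.write([SeqRecord(Seq(seq), id=cid, description="")
                 for cid, seq in genome.contigs.items()], str(fasta_path), "fasta")


def gene_table(genome: Genome) -> pd.DataFrame:
    return pd.DataFrame(
        [(genome.genome_id, g.contig_id, g.gene_id, g.start, g.end, g.strand)
         for g in genome.genes],
        columns=["genome_id", "contig_id", "gene_id", "start", "end", "strand"])


def write_gene_table(genome: Genome, path: str | Path) -> None:
    gene_table(genome).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- hits ---

def hits_to_frame(hits: list[SiteHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.tf_name, h.genome_id, h.gene_id, h.position, h.strand,
          round(h.score, 6), round(h.score_ratio, 6), h.category, h.clause)
         for h in hits],
        columns=["tf", "genome", "gene", "position", "strand",
                 "score", "ratio", "category", "clause"])


def write_hits_tsv(hits: list[SiteHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def write_hits_bed(hits: list[SiteHit], genome: Genome, motif_length: int,
                   path: str | Path) -> None:
    """BED6 per genome; name = tf, score rescaled to 0-1000 by ratio."""
    rows = []
    for h in hits:
        if h.genome_id != genome.genome_id:
            continue
        gene = genome.gene(h.gene_id)
        if gene.strand == "+":
            start = gene.start + h.position
        else:
            start = gene.end - h.position - motif_length
        bed_score = int(max(0, min(1000, round(1000 * h.score_ratio))))
        rows.append((gene.contig_id, start, start + motif_length, h.tf_name,
                     bed_score, h.strand if gene.strand == "+" else
                     ("-" if h.strand == "+" else "+")))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


# ----------------------------------------------------------------- motifs ---

def write_motif_meme(motif: Motif, path: str | Path) -> None:
    """MEME minimal motif format (letter-probability matrix)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motif.background
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        fh.write(f"MOTIF {motif.tf_name} {motif.consensus}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {motif.length}\n")
        for j in range(motif.length):
            fh.write(" ".join(f"{motif.frequencies[i, j]:.6f}" for i in range(4)) + "\n")


def write_motif_tsv(motif: Motif, path: str | Path) -> None:
    frame = pd.DataFrame(motif.frequencies.T, columns=list("ACGT"))
    frame.insert(0, "position", range(1, motif.length + 1))
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_motif_tsv(path: str | Path, tf_name: str, background=None,
                   pseudocount: float = 0.5, palindromic: bool = False) -> Motif:
    import numpy as np

    from .pwm import _as_background, _finalize  # shared construction path

    frame = pd.read_csv(path, sep="\t")
    freqs = frame[list("ACGT")].to_numpy().T
    freqs = freqs / freqs.sum(axis=0, keepdims=True)
    bg = _as_background(background)
    motif = _finalize(tf_name, np.asarray(freqs, dtype=float), bg, pseudocount, False)
    if palindromic:
        from .pwm import symmetrize
        motif = symmetrize(motif)
    return motif


# ------------------------------------------------------- alignments, operons ---

def write_alignment_fasta(alignment: RegionAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for genome_id, row in alignment.rows.items():
            fh.write(f">{genome_id} {alignment.group_id}\n{row}\n")


def write_operons_gff(operons: list[Operon], genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, op in enumerate(operons):
            genes = [genome.gene(g) for g in op.gene_ids]
            start = min(g.start for g in genes)
            end = max(g.end for g in genes)
            attrs = f"ID=operon{i};genes={','.join(op.gene_ids)};leader={op.leader}"
            fh.write("\t".join([op.contig_id, "regulonscan", "operon", str(start + 1),
                                str(end), ".", op.strand, ".", attrs]) + "\n")
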
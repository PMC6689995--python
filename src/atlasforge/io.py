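"""Readers and writers for the file formats the pipeline exchanges.

FASTA/FASTQ go through Biopython, GTF reading through gffutils, tables
through pandas.  All writers produce plain text so outputs diff cleanly.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import HomologyAlignment, TranscriptModel

HOMOLOGY_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gaps",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "sgenus", "sdescription", "qlen",
]


# ---------------------------------------------------------------- sequences

def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq_pair(read_pairs: Iterable, path_r1, path_r2) -> None:
    """read_pairs: iterable of (read_id, mate1_seq, mate2_seq)."""
    r1, r2 = [], []
    for rid, m1, m2 in read_pairs:
        r1.append(_fastq_record(rid + "/1", m1))
        r2.append(_fastq_record(rid + "/2", m2))
    SeqIO.write(r1, str(path_r1), "fastq")
    SeqIO.write(r2, str(path_r2), "fastq")


def _fastq_record(rid: str, seq: str) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=rid, description="")
    rec.letter_annotations["phred_quality"] = [40] * len(seq)
    return rec


def read_fastq_pair(path_r1, path_r2) -> list:
    out = []
    for a, b in zip(SeqIO.parse(str(path_r1), "fastq"), SeqIO.parse(str(path_r2), "fastq")):
        rid = a.id[:-2] if a.id.endswith("/1") else a.id
        out.append((rid, str(a.seq).upper(), str(b.seq).upper()))
    return out


# ---------------------------------------------------------------------- GTF

def write_gtf(models: Iterable[TranscriptModel], path) -> None:
    """1-based inclusive GTF; gene bounds span the full transcript extent."""
    models = list(models)
    by_gene: dict = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    lines = []
    for gene_id in sorted(by_gene):
        ms = by_gene[gene_id]
        chrom, strand = ms[0].chrom, ms[0].strand
        g_start = min(m.start for m in ms)
        g_end = max(m.end for m in ms)
        lines.append(_gtf_line(chrom, "gene", g_start, g_end, strand,
                               f'gene_id "{gene_id}"; gene_biotype "{ms[0].biotype}";'))
        for m in sorted(ms, key=lambda x: x.transcript_id):
            attrs = (f'gene_id "{gene_id}"; transcript_id "{m.transcript_id}"; '
                     f'biotype "{m.biotype}";')
            lines.append(_gtf_line(m.chrom, "transcript", m.start, m.end, m.strand, attrs))
            for i, (s, e) in enumerate(m.exons, start=1):
                ex_attrs = attrs + f' exon_number "{i}";'
                lines.append(_gtf_line(m.chrom, "exon", s, e, m.strand, ex_attrs))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _gtf_line(chrom, feature, start, end, strand, attrs) -> str:
    return "\t".join([chrom, "atlasforge", feature, str(start), str(end),
                      ".", strand, ".", attrs])


def read_gtf(path) -> list:
    """Parse transcript models from a GTF via gffutils (in-memory db)."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    models = []
    for tr in db.features_of_type("transcript"):
        exons = sorted(
            ((ex.start, ex.end) for ex in db.children(tr, featuretype="exon")),
            key=lambda x: x[0],
        )
        biotype = (tr.attributes.get("biotype") or ["protein_coding"])[0]
        models.append(TranscriptModel(
            transcript_id=tr.attributes["transcript_id"][0],
            gene_id=tr.attributes["gene_id"][0],
            chrom=tr.seqid, strand=tr.strand,
            exons=tuple(exons), biotype=biotype,
        ))
    models.sort(key=lambda m: m.transcript_id)
    return models


# ------------------------------------------------------------------- tables

def write_homology_table(alignments: Iterable[HomologyAlignment], path) -> None:
    rows = []
    for a in alignments:
        rows.append({
            "qseqid": a.query_id, "sseqid": a.subject_id, "pident": a.pident,
            "length": a.align_length, "mismatch": 0, "gaps": a.gap_count,
            "qstart": 1, "qend": min(a.align_length, a.query_length),
            "sstart": 1, "send": a.align_length, "evalue": a.evalue,
            "bitscore": round(2.0 * a.align_length, 1),
            "sgenus": a.subject_genus, "sdescription": a.subject_description,
            "qlen": a.query_length,
        })
    pd.DataFrame(rows, columns=HOMOLOGY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_homology_table(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        HomologyAlignment(
            query_id=str(r.qseqid), subject_id=str(r.sseqid),
            subject_genus=str(r.sgenus), subject_description=str(r.sdescription),
            pident=float(r.pident), align_length=int(r.length),
            gap_count=int(r.gaps), evalue=float(r.evalue),
            query_length=int(r.qlen),
        )
        for r in df.itertuples()
    ]


def write_matrix(df: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.6f")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def ensure_outdir(outdir, force: bool = False, expected: Iterable[str] = ()) -> None:
    os.makedirs(outdir, exist_ok=True)
    if not force:
        clashes = [f for f in expected if os.path.exists(os.path.join(outdir, f))]
        if clashes:
            raise FileExistsError(
                f"output files already exist in {outdir}: {clashes}; pass force=True to overwrite"
            )
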
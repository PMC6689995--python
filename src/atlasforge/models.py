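"""Core domain containers shared across the pipeline.

The pipeline operates on four kinds of objects: transcript models anchored
to a genome, expression matrices with sample metadata, blast-tabular
homology records, and (downstream) cluster assignments.  Everything tabular
is a pandas DataFrame; sequences are plain uppercase strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

VALID_BIOTYPES = ("protein_coding", "lncRNA", "other")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's exon structure on a genome.

    Exons are (start, end) pairs in 1-based inclusive genomic coordinates,
    non-overlapping and sorted by start regardless of strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in VALID_BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise ValueError("a transcript model needs at least one exon")
        for s, e in exons:
            if s > e or s < 1:
                raise ValueError(f"bad exon ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError("exons must be sorted by start and non-overlapping")
        object.__setattr__(self, "exons", exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exon_sequences(self, genome: Mapping[str, str]) -> list:
        """Genomic (+ strand) sequence of each exon, in genomic order."""
        chrom_seq = genome[self.chrom]
        out = []
        for s, e in self.exons:
            if e > len(chrom_seq):
                raise ValueError(
                    f"exon ({s}, {e}) of {self.transcript_id} exceeds "
                    f"chromosome {self.chrom} length {len(chrom_seq)}"
                )
            out.append(chrom_seq[s - 1 : e])
        return out

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Mature transcript sequence (5'→3' on the transcript strand)."""
        joined = "".join(self.exon_sequences(genome))
        return reverse_complement(joined) if self.strand == "-" else joined


@dataclass
class ExpressionMatrix:
    """Gene (or transcript) × sample TPM values plus sample metadata.

    ``data`` rows are features, columns are samples; ``metadata`` is indexed
    by sample id and carries at least a ``tissue`` column.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        missing = [s for s in self.data.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        if "tissue" not in self.metadata.columns:
            raise ValueError("metadata must carry a 'tissue' column")

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    @property
    def genes(self) -> list:
        return list(self.data.index)

    def tissue_of(self, sample: str) -> str:
        return self.metadata.loc[sample, "tissue"]

    @property
    def tissues(self) -> list:
        """Tissue labels in metadata (first-appearance) order."""
        seen, out = set(), []
        for s in self.metadata.index:
            t = self.metadata.loc[s, "tissue"]
            if t not in seen:
                seen.add(t)
                out.append(t)
        return out


@dataclass(frozen=True)
class HomologyAlignment:
    """One blast-tabular record, extended with subject genus/description."""

    query_id: str
    subject_id: str
    subject_genus: str
    subject_description: str
    pident: float
    align_length: int
    gap_count: int
    evalue: float
    query_length: int

    def __post_init__(self):
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"pident out of range: {self.pident}")
        if self.align_length < 0 or self.gap_count < 0:
            raise ValueError("align_length and gap_count must be non-negative")
        if self.query_length < 1:
            raise ValueError("query_length must be >= 1")


@dataclass
class ClusterAssignment:
    """A partition of genes into size-ordered numbered clusters.

    ``clusters[i]`` is cluster i+1; clusters are non-increasing in size with
    ties broken by smallest member id.  ``small`` holds genes whose raw
    cluster fell below ``min_cluster_size``.
    """

    clusters: list
    small: frozenset
    inflation: float
    min_cluster_size: int
    converged: bool = True

    def membership(self) -> pd.Series:
        """gene → 1-based cluster number (small/unclustered genes omitted)."""
        rows = {}
        for i, cl in enumerate(self.clusters, start=1):
            for g in cl:
                rows[g] = i
        return pd.Series(rows, dtype=int).sort_index()

    @property
    def sizes(self) -> list:
        return [len(c) for c in self.clusters]

    def all_genes(self) -> frozenset:
        out = set(self.small)
        for c in self.clusters:
            out |= set(c)
        return frozenset(out)
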
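"""Retention of candidate novel transcript models as protein-coding.

Two gates, both must pass:

* ORF chain — for every exon, the longest open reading frame across all six
  frames of the exon's genomic sequence; the chain passes iff (a) every
  exon's longest ORF lies on one and the same strand, (b) the 3'-most ORF is
  terminated by a stop codon rather than by the exon end, (c) no internal
  exon's ORF is stop-terminated before its exon ends, and (d) the peptide
  concatenated from the translated ORFs is at least 50 amino acids.

* Homology — each candidate needs ≥ 5 valid blast alignments, at least one
  of them to a ruminant genus.  A valid alignment has identity ≥ 90%, an
  aligned length that is both ≥ 90% of the query peptide and ≥ 50 aa, no
  gaps, and a description free of the low-confidence vocabulary
  ("low quality", "hypothetical", "unnamed", "uncharacterized", "putative");
  rows above the e-value ceiling (1e-25) are dropped before the criteria.

An ORF here is a maximal stop-free stretch in a reading frame; no start
codon is required (internal exons of genuine CDS need not begin with ATG),
but ``require_start_codon=True`` restricts runs to begin at ATG.  Ties on
length prefer the model's annotated strand, then frame 0/1/2, then the
leftmost start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .models import HomologyAlignment, TranscriptModel, reverse_complement

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
RUMINANT_GENERA = frozenset(
    {"Bison", "Bos", "Camelus", "Capra", "Ovis", "Pantholops", "Vicugna"}
)
FORBIDDEN_DESCRIPTION_WORDS = (
    "low quality", "hypothetical", "unnamed", "uncharacterized", "putative",
)
# third-party annotations have no operational marker in blast output; the
# TPA prefix is the closest deterministic proxy and the list is configurable
DEFAULT_EXTRA_FORBIDDEN = ("tpa:",)

ORF_FAILURE_CODES = ("a_strand", "b_terminal_stop", "c_internal_stop", "d_min_length")
HOMOLOGY_FAILURE_CODES = ("too_few_alignments", "no_ruminant_genus")


@dataclass(frozen=True)
class ExonOrf:
    """The longest ORF of one exon.

    ``start``/``end`` are 0-based half-open offsets into the exon's
    genomic-plus-strand sequence read along ``strand``; ``peptide`` is its
    translation.  An exon too short to hold a codon yields an empty ORF
    with ``strand=None``.
    """

    exon_index: int
    strand: Optional[str]
    start: int
    end: int
    has_terminal_stop: bool
    internal_stop: bool
    peptide: str

    @property
    def n_codons(self) -> int:
        return (self.end - self.start) // 3


@dataclass
class OrfChain:
    """Per-exon longest ORFs in transcript 5'→3' order, plus the peptide."""

    transcript_id: str
    per_exon: list
    peptide: str


@dataclass
class ValidationDecision:
    transcript_id: str
    retained: bool
    orf_failures: frozenset
    homology_failures: frozenset

    def __post_init__(self):
        expected = not self.orf_failures and not self.homology_failures
        if self.retained != expected:
            raise ValueError("retained flag inconsistent with failure sets")


# -------------------------------------------------------------- ORF engine

def _longest_run_in_frame(codons: Sequence[str], require_start_codon: bool):
    """(start_codon_idx, n_codons, terminated_by_stop) of the longest run."""
    best = (0, 0, False)
    run_start, run_len = None, 0
    for i, c in enumerate(codons + ["TAA"]):  # sentinel stop flushes the last run
        is_stop = c in STOP_CODONS
        if not is_stop:
            if run_start is None:
                if not require_start_codon or c == "ATG":
                    run_start, run_len = i, 1
            else:
                run_len += 1
        if is_stop or i == len(codons):
            if run_start is not None and run_len > best[1]:
                best = (run_start, run_len, is_stop and i < len(codons))
            run_start, run_len = None, 0
    return best


def longest_orf_in_exon(exon_seq: str, exon_index: int, model_strand: str,
                        require_start_codon: bool = False) -> ExonOrf:
    """Scan all six frames of one exon for its longest stop-free stretch."""
    exon_seq = exon_seq.upper()
    if len(exon_seq) < 3:
        return ExonOrf(exon_index, None, 0, 0, False, False, "")
    strand_order = ("+", "-") if model_strand == "+" else ("-", "+")
    best = None  # (n_codons, strand_rank, frame, start, terminated)
    for s_rank, strand in enumerate(strand_order):
        seq = exon_seq if strand == "+" else reverse_complement(exon_seq)
        for f in range(3):
            codons = [seq[i : i + 3] for i in range(f, len(seq) - 2, 3)]
            start, n, terminated = _longest_run_in_frame(codons, require_start_codon)
            if n == 0:
                continue
            key = (-n, s_rank, f, start)
            if best is None or key < best[0]:
                best = (key, strand, f, start, n, terminated)
    if best is None:
        return ExonOrf(exon_index, None, 0, 0, False, False, "")
    _, strand, f, start_codon, n, terminated = best
    nt_start = f + 3 * start_codon
    nt_end = nt_start + 3 * n
    seq = exon_seq if strand == "+" else reverse_complement(exon_seq)
    peptide = str(Seq(seq[nt_start:nt_end]).translate())
    return ExonOrf(
        exon_index=exon_index, strand=strand, start=nt_start, end=nt_end,
        has_terminal_stop=terminated, internal_stop=terminated, peptide=peptide,
    )


def longest_orfs_per_exon(model: TranscriptModel, genome: Mapping[str, str],
                          require_start_codon: bool = False) -> OrfChain:
    """The per-exon longest-ORF decomposition of a candidate model.

    Exons are visited in transcript 5'→3' order (reverse genomic order on
    the '-' strand) and the concatenated peptide follows that order.
    """
    exon_seqs = model.exon_sequences(genome)  # genomic order, + strand
    order = range(len(exon_seqs)) if model.strand == "+" else range(len(exon_seqs) - 1, -1, -1)
    per_exon = [
        longest_orf_in_exon(exon_seqs[i], i, model.strand, require_start_codon)
        for i in order
    ]
    peptide = "".join(o.peptide for o in per_exon)
    return OrfChain(transcript_id=model.transcript_id, per_exon=per_exon, peptide=peptide)


def validate_orf_chain(chain: OrfChain, min_peptide_length: int = 50):
    """Apply the four chain criteria; returns (passed, failure-code set)."""
    if not chain.per_exon:
        raise ValueError("empty ORF chain")
    failures = set()
    strands = {o.strand for o in chain.per_exon if o.strand is not None}
    if len(strands) > 1:
        failures.add("a_strand")
    if not chain.per_exon[-1].has_terminal_stop:
        failures.add("b_terminal_stop")
    if any(o.internal_stop for o in chain.per_exon[:-1]):
        failures.add("c_internal_stop")
    if len(chain.peptide) < min_peptide_length:
        failures.add("d_min_length")
    return (not failures), frozenset(failures)


# ---------------------------------------------------------- homology filter

def alignment_failures(aln: HomologyAlignment,
                       forbidden_words: Sequence[str] = FORBIDDEN_DESCRIPTION_WORDS
                       + DEFAULT_EXTRA_FORBIDDEN,
                       min_pident: float = 90.0, min_coverage: float = 0.9,
                       min_length: int = 50) -> frozenset:
    """Per-record criterion violations (empty set means the record is valid)."""
    failures = set()
    if aln.pident < min_pident:
        failures.add("identity")
    if aln.align_length < min_coverage * aln.query_length:
        failures.add("coverage")
    if aln.align_length < min_length:
        failures.add("min_length")
    if aln.gap_count != 0:
        failures.add("gaps")
    desc = aln.subject_description.lower()
    if any(w in desc for w in forbidden_words):
        failures.add("forbidden_description")
    return frozenset(failures)


def filter_homology(alignments: Iterable[HomologyAlignment],
                    genus_whitelist: frozenset = RUMINANT_GENERA,
                    min_alignments: int = 5, evalue_max: float = 1e-25,
                    forbidden_words: Sequence[str] = FORBIDDEN_DESCRIPTION_WORDS
                    + DEFAULT_EXTRA_FORBIDDEN,
                    min_pident: float = 90.0, min_coverage: float = 0.9,
                    min_length: int = 50) -> dict:
    """query_id → (retained, failure-code set).

    Rows above the e-value ceiling are dropped first; a query is retained
    iff it has ≥ ``min_alignments`` valid records and at least one valid
    record from a whitelisted genus.
    """
    by_query: dict = {}
    for a in alignments:
        if a.evalue > evalue_max:
            continue
        by_query.setdefault(a.query_id, []).append(a)
    out = {}
    for qid, rows in by_query.items():
        valid = [
            a for a in rows
            if not alignment_failures(a, forbidden_words, min_pident, min_coverage, min_length)
        ]
        failures = set()
        if len(valid) < min_alignments:
            failures.add("too_few_alignments")
        if not any(a.subject_genus in genus_whitelist for a in valid):
            failures.add("no_ruminant_genus")
        out[qid] = (not failures, frozenset(failures))
    return out


# -------------------------------------------------------------- composition

def annotate_novel_models(models: Sequence[TranscriptModel], genome: Mapping[str, str],
                          alignments: Iterable[HomologyAlignment],
                          genus_whitelist: frozenset = RUMINANT_GENERA,
                          min_peptide_length: int = 50, min_alignments: int = 5,
                          require_start_codon: bool = False, **filter_kwargs):
    """Retain candidates passing both gates; report every decision.

    Returns ``(retained_models, decisions)`` where ``decisions`` has one
    :class:`ValidationDecision` per candidate, listing all failure reasons.
    Candidates without any alignment record fail homology with
    ``too_few_alignments``.
    """
    homology = filter_homology(
        alignments, genus_whitelist=genus_whitelist,
        min_alignments=min_alignments, **filter_kwargs,
    )
    retained, decisions = [], []
    for m in models:
        chain = longest_orfs_per_exon(m, genome, require_start_codon)
        _, orf_failures = validate_orf_chain(chain, min_peptide_length)
        if m.transcript_id in homology:
            _, hom_failures = homology[m.transcript_id]
        else:
            hom_failures = frozenset({"too_few_alignments"})
        ok = not orf_failures and not hom_failures
        decisions.append(ValidationDecision(
            transcript_id=m.transcript_id, retained=ok,
            orf_failures=orf_failures, homology_failures=hom_failures,
        ))
        if ok:
            retained.append(m)
    return retained, decisions
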
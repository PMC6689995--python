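"""Simplified pseudoalignment quantifier.

A k-mer index over a transcript set assigns read pairs to
transcript-compatibility equivalence classes; an EM over those classes
produces estimated counts and TPM.  This is a deliberately small stand-in
for the contract of a production pseudoaligner (equivalence-class counts →
EM → TPM): no de Bruijn graph skipping, no bootstraps.

The library protocol is stranded: mate 1 is transcript-sense, so the index
stores forward k-mers, mate 1 is queried as-is and mate 2 is
reverse-complemented at query time.  ``stranded=False`` queries both
orientations of the pair and unions the results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .models import reverse_complement

UNASSIGNED_NO_MATCH = "no_match"
UNASSIGNED_TOO_SHORT = "too_short"


@dataclass
class PseudoIndex:
    k: int
    kmer_map: dict                  # k-mer → frozenset of transcript ids
    transcript_lengths: dict        # transcript → spliced length (nt)
    effective_lengths: dict         # transcript → positive real (nt)
    unindexable: frozenset = frozenset()

    @property
    def transcripts(self) -> list:
        return sorted(self.transcript_lengths)


@dataclass
class EquivalenceClassCounts:
    """Read-pair counts per transcript-compatibility class."""

    classes: dict                   # frozenset of transcript ids → count
    unassigned: dict                # read id → reason code
    total_pairs: int

    def __post_init__(self):
        if frozenset() in self.classes:
            raise ValueError("equivalence classes may not be keyed by the empty set")
        assigned = sum(self.classes.values())
        if assigned + len(self.unassigned) != self.total_pairs:
            raise ValueError("read conservation violated: assigned + unassigned != total")

    @property
    def n_assigned(self) -> int:
        return sum(self.classes.values())


@dataclass
class AbundanceTable:
    """Per-transcript estimated counts and TPM, plus EM diagnostics."""

    transcripts: pd.DataFrame       # index tid; length, eff_length, est_counts, tpm
    log_likelihoods: list
    n_iterations: int
    converged: bool

    @property
    def tpm(self) -> pd.Series:
        return self.transcripts["tpm"]

    @property
    def est_counts(self) -> pd.Series:
        return self.transcripts["est_counts"]


def _kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" not in km:
            yield km


def build_index(transcripts: Mapping[str, str], k: int = 31,
                fragment_length_mean: float = 200.0) -> PseudoIndex:
    """Forward k-mer index over a transcript set.

    k must be odd and within [11, 31]; k-mers containing N are skipped.
    Transcripts shorter than k are flagged unindexable (with a warning) and
    contribute no k-mers.  Effective length is
    ``max(length − fragment_length_mean + 1, 1)``.
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    if k % 2 == 0 or not (11 <= k <= 31):
        raise ValueError(f"k must be odd and within [11, 31], got {k}")
    kmer_map: dict = {}
    lengths: dict = {}
    eff: dict = {}
    unindexable = set()
    for tid in sorted(transcripts):
        seq = transcripts[tid].upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(f"transcript {tid} contains non-ACGTN characters")
        lengths[tid] = len(seq)
        eff[tid] = max(len(seq) - fragment_length_mean + 1.0, 1.0)
        if len(seq) < k:
            unindexable.add(tid)
            continue
        for km in _kmers(seq, k):
            kmer_map.setdefault(km, set()).add(tid)
    if unindexable:
        warnings.warn(
            f"{len(unindexable)} transcript(s) shorter than k={k} are unindexable"
        )
    kmer_map = {km: frozenset(v) for km, v in kmer_map.items()}
    return PseudoIndex(k=k, kmer_map=kmer_map, transcript_lengths=lengths,
                       effective_lengths=eff, unindexable=frozenset(unindexable))


def _compat(index: PseudoIndex, *seqs: str):
    """Intersection of indexed k-mer hit sets over the given sequences."""
    result = None
    for seq in seqs:
        for km in _kmers(seq, index.k):
            hits = index.kmer_map.get(km)
            if hits is None:
                continue  # k-mers absent from the index are ignored
            result = hits if result is None else result & hits
            if not result:
                return frozenset()
    return result if result is not None else frozenset()


def pseudoalign(index: PseudoIndex, read_pairs: Iterable,
                stranded: bool = True) -> EquivalenceClassCounts:
    """Assign read pairs to transcript-compatibility equivalence classes.

    A pair's compatibility set is the intersection of the per-k-mer hit
    sets over both mates (mate 2 reverse-complemented under the stranded
    protocol).  Pairs with an empty final set are recorded unassigned with
    a reason code; reads shorter than k get a distinct code.
    """
    classes: dict = {}
    unassigned: dict = {}
    total = 0
    for rid, m1, m2 in read_pairs:
        total += 1
        if len(m1) < index.k or len(m2) < index.k:
            unassigned[rid] = UNASSIGNED_TOO_SHORT
            continue
        m1, m2 = m1.upper(), m2.upper()
        if stranded:
            compat = _compat(index, m1, reverse_complement(m2))
        else:
            fwd = _compat(index, m1, reverse_complement(m2))
            rev = _compat(index, reverse_complement(m1), m2)
            compat = fwd | rev
        if compat:
            classes[compat] = classes.get(compat, 0) + 1
        else:
            unassigned[rid] = UNASSIGNED_NO_MATCH
    return EquivalenceClassCounts(classes=classes, unassigned=unassigned, total_pairs=total)


def em_abundances(ecs: EquivalenceClassCounts, index: PseudoIndex,
                  tol: float = 1e-8, max_iter: int = 1000) -> AbundanceTable:
    """EM over equivalence classes.

    E-step: each class count is split over its member transcripts
    proportionally to α_t / eff_len_t; M-step: α is replaced by the summed
    fractional assignments.  Iterates until the maximum change in α,
    relative to the total assigned count (so the stopping rule is invariant
    to rescaling all class counts), drops below ``tol`` or ``max_iter`` is
    reached.  TPM_t = (α_t/eff_t) / Σ_u (α_u/eff_u) × 1e6.

    The recorded per-iteration log-likelihood is that of the class
    multinomial, Σ_c n_c·log(Σ_{t∈c} α_t/eff_t) − N·log N (the normaliser
    Σ_t α_t stays equal to N throughout); it is non-decreasing.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    tids = index.transcripts
    tindex = {t: i for i, t in enumerate(tids)}
    n_t = len(tids)
    eff = np.array([index.effective_lengths[t] for t in tids])

    members = []
    counts = []
    for cls, n in sorted(ecs.classes.items(), key=lambda kv: sorted(kv[0])):
        idx = np.array([tindex[t] for t in sorted(cls)], dtype=int)
        members.append(idx)
        counts.append(float(n))
    counts = np.array(counts)
    total = counts.sum() if len(counts) else 0.0

    if total == 0.0:
        warnings.warn("no assigned reads; abundance table is all zero")
        df = pd.DataFrame({
            "length": [index.transcript_lengths[t] for t in tids],
            "eff_length": eff, "est_counts": 0.0, "tpm": 0.0,
        }, index=pd.Index(tids, name="transcript_id"))
        return AbundanceTable(df, [], 0, True)

    alpha = np.full(n_t, total / n_t)
    lls = []
    converged = False
    n_iter = 0
    log_n = float(total * np.log(total))
    for n_iter in range(1, max_iter + 1):
        dens = alpha / eff
        ll = -log_n
        new_alpha = np.zeros(n_t)
        for idx, n in zip(members, counts):
            w = dens[idx]
            s = w.sum()
            if s > 0:
                new_alpha[idx] += n * (w / s)
                ll += n * np.log(s)
        lls.append(ll)
        delta = np.max(np.abs(new_alpha - alpha)) / total
        alpha = new_alpha
        if delta < tol:
            converged = True
            break

    dens = alpha / eff
    tpm = dens / dens.sum() * 1e6 if dens.sum() > 0 else dens
    df = pd.DataFrame({
        "length": [index.transcript_lengths[t] for t in tids],
        "eff_length": eff, "est_counts": alpha, "tpm": tpm,
    }, index=pd.Index(tids, name="transcript_id"))
    return AbundanceTable(df, lls, n_iter, converged)


def summarize_to_genes(table: AbundanceTable, gene_map: Mapping[str, str]) -> pd.Series:
    """Gene TPM = sum of member transcript TPM."""
    unmapped = [t for t in table.transcripts.index if t not in gene_map]
    if unmapped:
        raise ValueError(f"transcripts without a gene mapping: {unmapped}")
    genes = pd.Series({t: gene_map[t] for t in table.transcripts.index})
    out = table.tpm.groupby(genes).sum()
    out.index.name = "gene_id"
    return out


def abundance_dataframe(table: AbundanceTable, gene_map: Mapping[str, str]) -> pd.DataFrame:
    """Kallisto-style output table: transcript_id, gene_id, lengths, counts, TPM."""
    df = table.transcripts.copy()
    df.insert(0, "gene_id", [gene_map.get(t, "") for t in df.index])
    return df
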
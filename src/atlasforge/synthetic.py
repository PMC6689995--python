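"""Synthetic inputs for every pipeline stage.

The generator emulates a small tissue expression atlas: a toy genome with
multi-exon transcript models, per-tissue expression with planted
co-expression modules (tissue-restricted modules, housekeeping genes and
unstructured noise genes), stranded paired-end reads, and blast-tabular
homology tables with engineered pass/fail records.

Protein-coding genes are written into the genome with coding-like exon
content (stop-free codons on the annotated strand, a stop codon closing the
3'-most exon) so that their transcript models satisfy the per-exon
longest-ORF retention criteria by construction; helper functions produce
deliberately broken variants for negative tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import ExpressionMatrix, HomologyAlignment, TranscriptModel, reverse_complement

DEFAULT_TISSUES = (
    "cortex", "cerebellum", "liver", "kidney", "spleen",
    "lung", "heart", "muscle", "rumen", "ileum",
)

RUMINANT_GENERA = frozenset(
    {"Bison", "Bos", "Camelus", "Capra", "Ovis", "Pantholops", "Vicugna"}
)

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

HOMOLOGY_SCENARIOS = (
    "all_pass", "identity", "coverage", "min_length",
    "gaps", "forbidden_description", "genus", "too_few",
)


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module: genes sharing a tissue profile."""

    module_id: str
    n_genes: int
    active_tissues: tuple
    mean_active_tpm: float = 500.0
    mean_inactive_tpm: float = 1.0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("module needs at least one gene")
        if self.mean_active_tpm < 0 or self.mean_inactive_tpm < 0:
            raise ValueError("TPM means must be non-negative")


def default_modules(tissues: Sequence[str]) -> tuple:
    """Three 25-gene modules active in disjoint pairs of tissues."""
    if len(tissues) < 6:
        raise ValueError("default modules need at least 6 tissues")
    return (
        ModuleSpec("mod_a", 25, tuple(tissues[0:2])),
        ModuleSpec("mod_b", 25, tuple(tissues[2:4])),
        ModuleSpec("mod_c", 25, tuple(tissues[-2:])),
    )


@dataclass
class SyntheticDesign:
    """Parameters of one synthetic atlas study.

    Defaults describe the benchmark condition used throughout the test
    suite: 300 genes over 10 tissues with two replicates each, three
    25-gene modules active in disjoint tissue pairs, 10% housekeeping
    genes, and 10% multiplicative log-normal replicate noise.
    """

    n_genes: int = 300
    n_tissues: int = 10
    replicates_per_tissue: int = 2
    modules: Optional[tuple] = None
    housekeeping_fraction: float = 0.1
    noise_sd_log: float = 0.1
    seed: int = 0
    tissues: Optional[tuple] = None
    transcripts_per_gene: int = 1
    housekeeping_mean_tpm: float = 100.0
    noise_gene_median_tpm: float = 10.0
    noise_gene_profile_sd: float = 1.5
    lncrna_fraction: float = 0.10
    other_biotype_fraction: float = 0.05

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.replicates_per_tissue < 1:
            raise ValueError("replicates_per_tissue must be >= 1")
        if not (0.0 <= self.housekeeping_fraction <= 1.0):
            raise ValueError("housekeeping_fraction must lie in [0, 1]")
        if self.noise_sd_log < 0:
            raise ValueError("noise_sd_log must be >= 0")
        if self.tissues is None:
            base = list(DEFAULT_TISSUES[: self.n_tissues])
            base += [f"tissue{i:02d}" for i in range(len(base) + 1, self.n_tissues + 1)]
            self.tissues = tuple(base)
        if len(self.tissues) != self.n_tissues:
            raise ValueError("tissue panel size must equal n_tissues")
        if self.modules is None:
            self.modules = default_modules(self.tissues) if self.n_tissues >= 6 else ()
        n_module_genes = sum(m.n_genes for m in self.modules)
        if n_module_genes > self.n_genes:
            raise ValueError("module gene counts exceed n_genes")
        if self.housekeeping_mean_tpm < 0:
            raise ValueError("TPM means must be non-negative")

    # ------------------------------------------------------------- layout
    def gene_ids(self) -> list:
        return [f"gene{i:04d}" for i in range(1, self.n_genes + 1)]

    def assign_roles(self) -> pd.DataFrame:
        """Deterministic gene → (role, module_id, biotype) table.

        Module genes come first (in module order), then housekeeping genes,
        then noise genes; a leading slice of the noise genes is labelled
        lncRNA / other so all three biotypes occur.
        """
        genes = self.gene_ids()
        roles, module_ids, biotypes = [], [], []
        cursor = 0
        for m in self.modules:
            for _ in range(m.n_genes):
                roles.append("module")
                module_ids.append(m.module_id)
                biotypes.append("protein_coding")
                cursor += 1
        n_hk = int(round(self.housekeeping_fraction * self.n_genes))
        n_hk = min(n_hk, self.n_genes - cursor)
        for _ in range(n_hk):
            roles.append("housekeeping")
            module_ids.append("")
            biotypes.append("protein_coding")
            cursor += 1
        n_noise = self.n_genes - cursor
        n_lnc = int(round(self.lncrna_fraction * n_noise))
        n_other = int(round(self.other_biotype_fraction * n_noise))
        for j in range(n_noise):
            roles.append("noise")
            module_ids.append("")
            if j < n_lnc:
                biotypes.append("lncRNA")
            elif j < n_lnc + n_other:
                biotypes.append("other")
            else:
                biotypes.append("protein_coding")
        return pd.DataFrame(
            {"role": roles, "module_id": module_ids, "biotype": biotypes},
            index=pd.Index(genes, name="gene_id"),
        )

    def sample_ids(self) -> list:
        return [
            f"{t}_r{j + 1}"
            for t in self.tissues
            for j in range(self.replicates_per_tissue)
        ]

    def sample_metadata(self) -> pd.DataFrame:
        rows = []
        for t in self.tissues:
            for j in range(self.replicates_per_tissue):
                rows.append({
                    "sample_id": f"{t}_r{j + 1}",
                    "tissue": t,
                    "animal": f"animal{j + 1}",
                    "sex": "F" if j % 2 == 0 else "M",
                    "library_type": "mRNA-Seq",
                })
        return pd.DataFrame(rows).set_index("sample_id")


# ------------------------------------------------------------------ genome

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _longest_runs(seq: str) -> dict:
    """Longest stop-free codon run per (strand, frame); local checker only."""
    out = {}
    for strand in ("+", "-"):
        s = seq if strand == "+" else reverse_complement(seq)
        for f in range(3):
            best = run = 0
            for i in range(f, len(s) - 2, 3):
                if s[i : i + 3] in STOP_CODONS:
                    run = 0
                else:
                    run += 1
                    best = max(best, run)
            out[(strand, f)] = best
    return out


def _random_nonstop(rng: np.random.Generator, n_codons: int) -> list:
    return [_NONSTOP_CODONS[k] for k in rng.integers(0, len(_NONSTOP_CODONS), n_codons)]


def _coding_exon_blocks(rng: np.random.Generator, lengths: Sequence[int]) -> list:
    """Transcript-sense exon sequences: stop-free codons, final codon a stop.

    For internal exons the full-span frame-0 run is maximal by length, so the
    annotated-strand preference in the ORF scanner settles any tie.  The final
    exon's frame-0 run is one codon shorter than full span (the stop), so we
    redraw it until the opposite strand's frame 0 cannot beat it on length.
    """
    blocks = []
    for i, ln in enumerate(lengths):
        assert ln % 3 == 0
        n_codons = ln // 3
        if i < len(lengths) - 1:
            blocks.append("".join(_random_nonstop(rng, n_codons)))
            continue
        while True:
            codons = _random_nonstop(rng, n_codons)
            codons[-1] = STOP_CODONS[rng.integers(0, 3)]
            block = "".join(codons)
            if _longest_runs(block)[("-", 0)] <= n_codons - 1:
                blocks.append(block)
                break
    return blocks


def generate_genome_and_models(design: SyntheticDesign):
    """Build a toy genome and the transcript models living on it.

    Returns ``(genome, models)`` where ``genome`` maps chromosome name to
    sequence.  Protein-coding genes carry planted coding exon content (see
    module docstring); exon lengths are multiples of 3 so the full-exon
    reading frame is strictly the longest ORF on the annotated strand.
    """
    rng = np.random.default_rng([design.seed, 0])
    roles = design.assign_roles()
    genes = design.gene_ids()
    genes_per_chrom = 50
    chrom_parts: dict = {}
    chrom_cursor: dict = {}
    models: list = []
    serial = 0

    for gi, gene_id in enumerate(genes):
        chrom = f"chr{gi // genes_per_chrom + 1}"
        parts = chrom_parts.setdefault(chrom, [])
        cursor = chrom_cursor.get(chrom, 0)

        if gi == 0:
            strand = "+"
        elif gi == 1:
            strand = "-"
        else:
            strand = "+" if rng.random() < 0.5 else "-"
        biotype = roles.loc[gene_id, "biotype"]

        n_exons = int(rng.integers(2, 5))
        exon_lengths = [int(rng.integers(50, 134)) * 3 for _ in range(n_exons)]
        intron_lengths = [int(rng.integers(60, 201)) for _ in range(n_exons - 1)]
        gap = int(rng.integers(100, 301))

        if biotype == "protein_coding":
            # transcript order is reverse genomic order on '-' strand
            tx_lengths = exon_lengths if strand == "+" else exon_lengths[::-1]
            tx_blocks = _coding_exon_blocks(rng, tx_lengths)
            genomic_blocks = (
                tx_blocks if strand == "+" else [reverse_complement(b) for b in tx_blocks[::-1]]
            )
        else:
            genomic_blocks = [_random_seq(rng, ln) for ln in exon_lengths]

        parts.append(_random_seq(rng, gap))
        cursor += gap
        exon_coords = []
        for i, block in enumerate(genomic_blocks):
            exon_coords.append((cursor + 1, cursor + len(block)))
            parts.append(block)
            cursor += len(block)
            if i < n_exons - 1:
                parts.append(_random_seq(rng, intron_lengths[i]))
                cursor += intron_lengths[i]
        chrom_cursor[chrom] = cursor

        for j in range(design.transcripts_per_gene):
            serial += 1
            tid = f"rna{serial:04d}"
            if j == 0 or n_exons < 3:
                exons = tuple(exon_coords)
            else:
                skip = 1 + (j - 1) % (n_exons - 2)  # drop an internal exon
                exons = tuple(e for i, e in enumerate(exon_coords) if i != skip)
            models.append(TranscriptModel(
                transcript_id=tid, gene_id=gene_id, chrom=chrom,
                strand=strand, exons=exons, biotype=biotype,
            ))

    genome = {c: "".join(parts) for c, parts in chrom_parts.items()}
    for m in models:
        assert m.end <= len(genome[m.chrom])
    return genome, models


# -------------------------------------------------------------- expression

def simulate_expression(design: SyntheticDesign,
                        models: Optional[Sequence[TranscriptModel]] = None):
    """True per-sample gene TPM with planted module structure.

    Returns ``(ExpressionMatrix, truth)`` where ``truth`` is the gene role
    table from :meth:`SyntheticDesign.assign_roles`.  Every sample column is
    normalised to sum to 1e6.  Replicate noise is multiplicative log-normal
    with standard deviation ``noise_sd_log`` on the natural-log scale.
    ``models=None`` skips the design/model consistency check for
    expression-only studies that never touch sequence.
    """
    panel = set(design.tissues)
    for m in design.modules:
        missing = [t for t in m.active_tissues if t not in panel]
        if missing:
            raise ValueError(f"module {m.module_id} names unknown tissues: {missing}")
    genes = design.gene_ids()
    if models is not None:
        model_genes = {m.gene_id for m in models}
        if not model_genes.issuperset(genes):
            raise ValueError("models do not cover the design's genes")

    truth = design.assign_roles()
    rng = np.random.default_rng([design.seed, 1])
    n_g, n_t = design.n_genes, design.n_tissues
    means = np.empty((n_g, n_t))
    mod_by_id = {m.module_id: m for m in design.modules}
    active_mask = {
        mid: np.array([t in mod_by_id[mid].active_tissues for t in design.tissues])
        for mid in mod_by_id
    }
    for i, g in enumerate(genes):
        role = truth.loc[g, "role"]
        if role == "module":
            m = mod_by_id[truth.loc[g, "module_id"]]
            means[i] = np.where(active_mask[m.module_id], m.mean_active_tpm, m.mean_inactive_tpm)
        elif role == "housekeeping":
            means[i] = design.housekeeping_mean_tpm
        else:
            means[i] = np.exp(rng.normal(
                math.log(design.noise_gene_median_tpm),
                design.noise_gene_profile_sd, size=n_t,
            ))

    cols = {}
    for ti, t in enumerate(design.tissues):
        for j in range(design.replicates_per_tissue):
            vals = means[:, ti].copy()
            if design.noise_sd_log > 0:
                vals = vals * np.exp(rng.normal(0.0, design.noise_sd_log, size=n_g))
            cols[f"{t}_r{j + 1}"] = vals
    data = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    totals = data.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("a sample has zero total expression; check TPM means")
    data = data / totals * 1e6
    return ExpressionMatrix(data=data, metadata=design.sample_metadata()), truth


def split_gene_tpm_to_transcripts(gene_tpm: pd.Series, models: Sequence[TranscriptModel]) -> pd.Series:
    """Divide each gene's TPM equally among its transcripts."""
    per_gene: dict = {}
    for m in models:
        per_gene.setdefault(m.gene_id, []).append(m.transcript_id)
    rows = {}
    for g, tids in per_gene.items():
        share = float(gene_tpm.get(g, 0.0)) / len(tids)
        for tid in tids:
            rows[tid] = share
    return pd.Series(rows).sort_index()


# ------------------------------------------------------------------- reads

def simulate_reads(transcripts: Mapping[str, str], abundances: Mapping[str, float],
                   n_pairs: int, read_len: int = 125, error_rate: float = 0.0,
                   seed: int = 0, fragment_length: int = 200) -> list:
    """Stranded paired-end reads: mate 1 is transcript-sense.

    Fragments are drawn per transcript with probability proportional to
    abundance × number of distinct fragment start positions; mate 2 is the
    reverse complement of the fragment's 3' end.  Read ids encode the source
    transcript and fragment start (``read000001|rna0001|pos37``).
    Returns a list of ``(read_id, mate1, mate2)`` tuples in a deterministic
    shuffled order.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    missing = [t for t in transcripts if t not in abundances]
    if missing:
        raise ValueError(f"abundances missing for transcripts: {missing[:5]}")
    tids = sorted(t for t in transcripts if abundances[t] > 0)
    if not tids:
        raise ValueError("all abundances are zero")
    for t in tids:
        if len(transcripts[t]) < read_len:
            raise ValueError(f"transcript {t} shorter than read length {read_len}")

    rng = np.random.default_rng(seed)
    frag_lens = {t: min(fragment_length, len(transcripts[t])) for t in tids}
    weights = np.array([
        abundances[t] * max(len(transcripts[t]) - frag_lens[t] + 1, 1) for t in tids
    ], dtype=float)
    counts = rng.multinomial(n_pairs, weights / weights.sum())

    pairs = []
    serial = 0
    for t, c in zip(tids, counts):
        seq = transcripts[t]
        fl = frag_lens[t]
        starts = rng.integers(0, len(seq) - fl + 1, size=c)
        for s in starts:
            serial += 1
            frag = seq[s : s + fl]
            m1 = frag[:read_len]
            m2 = reverse_complement(frag)[:read_len]
            if error_rate > 0:
                m1 = _mutate(rng, m1, error_rate)
                m2 = _mutate(rng, m2, error_rate)
            pairs.append((f"read{serial:06d}|{t}|pos{s}", m1, m2))
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        cur = arr[i].decode()
        alt = [b for b in "ACGT" if b != cur]
        arr[i] = alt[rng.integers(0, 3)].encode()
    return arr.tobytes().decode()


# ---------------------------------------------------------------- homology

_CLEAN_DESCRIPTIONS = (
    "myosin heavy chain 7", "cytochrome c oxidase subunit 5A",
    "solute carrier family 2 member 1", "keratin 5",
    "peptidoglycan recognition protein 3", "heat shock protein beta-1",
)
_FORBIDDEN_WORDS = ("low quality", "hypothetical", "unnamed", "uncharacterized", "putative")
_NON_RUMINANT_GENERA = ("Sus", "Equus", "Homo", "Mus", "Canis")


@dataclass
class HomologySimulation:
    alignments: list
    query_truth: pd.DataFrame  # index query_id; columns retained, failure
    record_labels: list        # per alignment: "pass" or the violated criterion


def _passing_record(rng, qid, qlen, genus) -> HomologyAlignment:
    lo = max(50, math.ceil(0.9 * qlen))
    return HomologyAlignment(
        query_id=qid,
        subject_id=f"XP_{rng.integers(10**6, 10**7)}",
        subject_genus=genus,
        subject_description=str(rng.choice(_CLEAN_DESCRIPTIONS)),
        pident=float(np.round(rng.uniform(90.5, 99.9), 1)),
        align_length=int(rng.integers(lo, qlen + 1)),
        gap_count=0,
        evalue=float(10.0 ** rng.uniform(-60, -26)),
        query_length=qlen,
    )


def _feasible_scenarios(qlen: int) -> list:
    out = ["all_pass", "identity", "gaps", "forbidden_description", "genus", "too_few"]
    if qlen >= 57:
        out.append("coverage")
    if 50 <= qlen <= 54:
        out.append("min_length")
    return out


def simulate_homology_table(queries: Sequence, scenario: str, seed: int = 0,
                            genus_whitelist: frozenset = RUMINANT_GENERA) -> HomologySimulation:
    """Blast-like alignment tables with engineered pass/fail records.

    ``queries`` is a list of ``(query_id, peptide_length)``.  Each failure
    scenario violates exactly one named criterion in one record (or, for
    ``genus``/``too_few``, at the query level); ``mixed`` draws a feasible
    scenario per query.  Ground-truth retention labels are emitted alongside.
    """
    if scenario not in HOMOLOGY_SCENARIOS + ("mixed",):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    whitelist = sorted(genus_whitelist)
    alignments, labels, truth_rows = [], [], []

    for qid, qlen in queries:
        qlen = int(qlen)
        if qlen < 1:
            raise ValueError("peptide lengths must be >= 1")
        sc = scenario
        if sc == "mixed":
            sc = str(rng.choice(_feasible_scenarios(qlen)))
        if qlen < 50:
            raise ValueError(
                f"query {qid} is {qlen} aa; no alignment can satisfy the "
                "length criteria for such a short peptide"
            )
        if sc == "coverage" and qlen < 57:
            raise ValueError("'coverage' needs query length >= 57 aa")
        if sc == "min_length" and not (50 <= qlen <= 54):
            raise ValueError("'min_length' needs query length in [50, 54] aa")

        n_records = 4 if sc == "too_few" else 5
        genera = [whitelist[int(rng.integers(0, len(whitelist)))] for _ in range(n_records)]
        genera[0] = "Bos"
        if sc == "genus":
            genera = [str(rng.choice(_NON_RUMINANT_GENERA)) for _ in range(n_records)]
        records = [_passing_record(rng, qid, qlen, g) for g in genera]
        rec_labels = ["pass"] * n_records

        if sc in ("identity", "coverage", "min_length", "gaps", "forbidden_description"):
            k = int(rng.integers(0, n_records))
            r = records[k]
            kw = dict(
                query_id=r.query_id, subject_id=r.subject_id,
                subject_genus=r.subject_genus,
                subject_description=r.subject_description,
                pident=r.pident, align_length=r.align_length,
                gap_count=r.gap_count, evalue=r.evalue, query_length=r.query_length,
            )
            if sc == "identity":
                kw["pident"] = float(np.round(rng.uniform(50.0, 89.4), 1))
            elif sc == "coverage":
                kw["align_length"] = int(rng.integers(50, math.ceil(0.9 * qlen)))
            elif sc == "min_length":
                kw["align_length"] = int(rng.integers(math.ceil(0.9 * qlen), 50))
            elif sc == "gaps":
                kw["gap_count"] = int(rng.integers(1, 4))
            else:
                word = str(rng.choice(_FORBIDDEN_WORDS))
                kw["subject_description"] = f"{word} protein LOC{rng.integers(10**5, 10**6)}"
            records[k] = HomologyAlignment(**kw)
            rec_labels[k] = sc

        if sc == "all_pass":
            retained, failure = True, ""
        elif sc == "genus":
            retained, failure = False, "no_ruminant_genus"
        else:
            retained, failure = False, "too_few_alignments"
        truth_rows.append({"query_id": qid, "retained": retained,
                           "failure": failure, "scenario": sc})
        alignments.extend(records)
        labels.extend(rec_labels)

    truth = pd.DataFrame(truth_rows).set_index("query_id")
    return HomologySimulation(alignments=alignments, query_truth=truth, record_labels=labels)


# --------------------------------------------------- ORF-scenario candidates

def plant_orf_candidate(scenario: str, seed: int = 0, n_exons: int = 3, strand: str = "+",
                        chrom: str = "chrN", offset: int = 0):
    """A candidate transcript model plus the genome slice it lives on.

    ``scenario`` is one of ``pass``, ``strand`` (one internal exon's longest
    ORF on the opposite strand), ``no_terminal_stop`` (last ORF runs off the
    exon end), ``internal_stop`` (an internal exon's ORF is stop-terminated
    early) or ``short_peptide``.  Returns ``(model, chrom_seq)`` with exon
    coordinates shifted by ``offset`` into the chromosome sequence.
    """
    if scenario not in ("pass", "strand", "no_terminal_stop", "internal_stop", "short_peptide"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if n_exons < 2:
        raise ValueError("scenario candidates need at least 2 exons")
    rng = np.random.default_rng(seed)
    if scenario == "short_peptide":
        lengths = [48] * n_exons  # 16 codons/exon → peptide well under 50 aa
    else:
        lengths = [int(rng.integers(60, 100)) * 3 for _ in range(n_exons)]
    blocks = _coding_exon_blocks(rng, lengths)  # transcript order
    k = n_exons // 2  # the internal exon that failure scenarios corrupt

    if scenario == "no_terminal_stop":
        # last exon runs open to its end: criterion b alone fails
        blocks[-1] = "".join(_random_nonstop(rng, lengths[-1] // 3))
    elif scenario == "internal_stop":
        # an internal exon's longest ORF ends at a stop before the exon end;
        # redraw until no other frame can match or beat that run
        m = lengths[k] // 3
        while True:
            codons = _random_nonstop(rng, m)
            codons[m - 3] = STOP_CODONS[rng.integers(0, 3)]
            block = "".join(codons)
            runs = _longest_runs(block)
            if runs[("+", 0)] == m - 3 and all(
                r < m - 3 for key, r in runs.items() if key != ("+", 0)
            ):
                blocks[k] = block
                break
    elif scenario == "strand":
        # an internal exon whose longest ORF sits on the opposite strand;
        # redraw until the sense-strand frames are all strictly shorter
        m = lengths[k] // 3
        while True:
            block = reverse_complement("".join(_random_nonstop(rng, m)))
            runs = _longest_runs(block)
            if all(runs[("+", f)] <= m - 1 for f in range(3)):
                blocks[k] = block
                break

    genomic_blocks = blocks if strand == "+" else [reverse_complement(b) for b in blocks[::-1]]
    introns = [_random_seq(rng, int(rng.integers(60, 150))) for _ in range(n_exons - 1)]
    parts, exons, cursor = [], [], offset
    for i, block in enumerate(genomic_blocks):
        exons.append((cursor + 1, cursor + len(block)))
        parts.append(block)
        cursor += len(block)
        if i < n_exons - 1:
            parts.append(introns[i])
            cursor += len(introns[i])
    seq = _random_seq(rng, offset) + "".join(parts) if offset else "".join(parts)
    model = TranscriptModel(
        transcript_id=f"cand_{scenario}_{seed}", gene_id=f"gcand_{scenario}_{seed}",
        chrom=chrom, strand=strand, exons=tuple(exons), biotype="protein_coding",
    )
    return model, seq


# ------------------------------------------------------- multipass test-bed

@dataclass
class MultipassStudy:
    """A complete synthetic input set for the three-pass workflow.

    Two expressed genes are withheld from the draft annotation (their models
    become validated novel candidates, alongside two engineered rejects),
    two genes are silenced to exercise all-zero removal, and two transcripts
    carry external low-quality flags.
    """

    design: SyntheticDesign
    genome: dict
    draft_models: list
    candidate_models: list
    alignments: list
    homology_truth: pd.DataFrame
    low_quality_ids: frozenset
    samples: dict
    metadata: pd.DataFrame
    expression: ExpressionMatrix        # truth, gene level
    gene_truth: pd.DataFrame
    withheld_novel_ids: frozenset       # candidates that must be retained
    silenced_gene_ids: frozenset


def simulate_multipass_study(seed: int = 0, n_pairs_per_sample: int = 5000) -> MultipassStudy:
    """Build the default toy study for multi-pass quantification.

    30 genes over 6 tissues (2 replicates): three 6-gene modules active in
    disjoint tissue pairs, 3 housekeeping genes, 9 noise genes.  Withheld
    novel genes are module members (well above the noise floor) so their
    recovery in the third pass is unambiguous.
    """
    tissues = DEFAULT_TISSUES[:6]
    modules = (
        ModuleSpec("mod_a", 6, tuple(tissues[0:2])),
        ModuleSpec("mod_b", 6, tuple(tissues[2:4])),
        ModuleSpec("mod_c", 6, tuple(tissues[4:6])),
    )
    design = SyntheticDesign(n_genes=30, n_tissues=6, replicates_per_tissue=2,
                             modules=modules, tissues=tissues, seed=seed)
    genome, models = generate_genome_and_models(design)
    expr, truth = simulate_expression(design, models)

    silenced = ("gene0029", "gene0030")
    expr.data.loc[list(silenced)] = 0.0
    expr.data = expr.data / expr.data.sum(axis=0) * 1e6

    withheld_genes = ("gene0006", "gene0012")  # one mod_a, one mod_b member
    withheld = [m for m in models if m.gene_id in withheld_genes]
    draft = [m for m in models if m.gene_id not in withheld_genes]
    low_quality = frozenset(
        m.transcript_id for m in draft if m.gene_id in ("gene0022", "gene0023")
    )

    # engineered rejects: a broken ORF chain, and a homology failure
    orf_fail, seq1 = plant_orf_candidate("internal_stop", seed=seed + 50, chrom="chrX1")
    hom_fail, seq2 = plant_orf_candidate("pass", seed=seed + 51, chrom="chrX2")
    genome = dict(genome)
    genome["chrX1"] = seq1
    genome["chrX2"] = seq2
    candidates = withheld + [orf_fail, hom_fail]

    def qlen(m):
        return m.spliced_length // 3 - 1

    sims = [
        simulate_homology_table([(m.transcript_id, qlen(m))], "all_pass", seed=seed + 60 + i)
        for i, m in enumerate(withheld + [orf_fail])
    ]
    sims.append(simulate_homology_table([(hom_fail.transcript_id, qlen(hom_fail))],
                                        "gaps", seed=seed + 70))
    alignments = [a for s in sims for a in s.alignments]
    homology_truth = pd.concat([s.query_truth for s in sims])

    seqs = {m.transcript_id: m.spliced_sequence(genome) for m in models}
    samples = {}
    for i, sample in enumerate(expr.samples):
        tx = split_gene_tpm_to_transcripts(expr.data[sample], models)
        samples[sample] = simulate_reads(
            seqs, tx.to_dict(), n_pairs=n_pairs_per_sample, seed=seed + 1000 + i,
        )

    return MultipassStudy(
        design=design, genome=genome, draft_models=draft,
        candidate_models=candidates, alignments=alignments,
        homology_truth=homology_truth, low_quality_ids=low_quality,
        samples=samples, metadata=expr.metadata, expression=expr,
        gene_truth=truth,
        withheld_novel_ids=frozenset(m.transcript_id for m in withheld),
        silenced_gene_ids=frozenset(silenced),
    )
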
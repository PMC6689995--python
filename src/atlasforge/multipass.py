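"""Multi-pass quantification with index revision.

Pass 1 quantifies every sample against the draft transcript set.  The index
is then revised — transcripts with TPM exactly 0 in all samples are dropped,
externally flagged low-quality transcripts are dropped, and validated novel
models are added — and quantification is repeated.  The full flow is:

    pass 1 → revise (all-zero + low-quality) → pass 2
           → validate candidate novel models → revise (add retained) → pass 3

Every revision is logged with a reason (``all_zero``, ``low_quality_flag``
or ``novel_validated``) so the final transcript set is reproducible from the
draft set plus the log.  Low-quality flags are treated as data: the upstream
judgement that a reference transcript is a poor prediction cannot be
recomputed here, so callers supply the id list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .models import ExpressionMatrix, TranscriptModel
from .quant import build_index, em_abundances, pseudoalign, summarize_to_genes
from .validation import RUMINANT_GENERA, annotate_novel_models

REVISION_REASONS = ("all_zero", "low_quality_flag", "novel_validated")


@dataclass
class QuantConfig:
    k: int = 31
    fragment_length_mean: float = 200.0
    tol: float = 1e-8
    max_iter: int = 1000
    stranded: bool = True


@dataclass
class IndexRevisionPlan:
    drop_all_zero: bool = True
    low_quality_ids: frozenset = frozenset()
    novel_models: tuple = ()
    pass_number: int = 1


@dataclass
class PassResult:
    pass_number: int
    transcript_ids: list
    expression: ExpressionMatrix            # gene-level TPM
    transcript_expression: pd.DataFrame     # transcript-level TPM
    unassigned: dict                        # sample → list of read ids
    revision_log: list = field(default_factory=list)

    @property
    def transcript_set_size(self) -> int:
        return len(self.transcript_ids)


@dataclass
class MultipassResult:
    passes: list
    revision_history: list
    validation_decisions: list = field(default_factory=list)

    @property
    def final(self) -> PassResult:
        return self.passes[-1]


def run_pass(transcript_seqs: Mapping[str, str], gene_map: Mapping[str, str],
             samples: Mapping[str, Sequence], metadata: pd.DataFrame,
             config: QuantConfig = QuantConfig(), pass_number: int = 1) -> PassResult:
    """Quantify every sample independently against one index.

    ``samples`` maps sample id → list of (read_id, mate1, mate2) tuples.
    Samples are quantified with no cross-sample coupling; per-sample
    unassigned read ids are kept for downstream de-novo handling.
    """
    if not transcript_seqs:
        raise ValueError("transcript set is empty")
    if not samples:
        raise ValueError("at least one sample is required")
    index = build_index(transcript_seqs, k=config.k,
                        fragment_length_mean=config.fragment_length_mean)
    tx_cols, gene_cols, unassigned = {}, {}, {}
    for sample in metadata.index:
        if sample not in samples:
            continue
        pairs = samples[sample]
        if not pairs:
            warnings.warn(f"sample {sample} has no reads; emitting a zero column")
            tx_cols[sample] = pd.Series(0.0, index=pd.Index(index.transcripts))
            gene_cols[sample] = summarize_to_genes(
                em_abundances(
                    pseudoalign(index, []), index, config.tol, config.max_iter
                ),
                gene_map,
            )
            unassigned[sample] = []
            continue
        ecs = pseudoalign(index, pairs, stranded=config.stranded)
        table = em_abundances(ecs, index, tol=config.tol, max_iter=config.max_iter)
        tx_cols[sample] = table.tpm
        gene_cols[sample] = summarize_to_genes(table, gene_map)
        unassigned[sample] = sorted(ecs.unassigned)
    tx_expr = pd.DataFrame(tx_cols)
    gene_expr = pd.DataFrame(gene_cols)
    gene_expr.index.name = "gene_id"
    return PassResult(
        pass_number=pass_number,
        transcript_ids=sorted(transcript_seqs),
        expression=ExpressionMatrix(data=gene_expr, metadata=metadata.loc[list(gene_expr.columns)]),
        transcript_expression=tx_expr,
        unassigned=unassigned,
    )


def revise_index(current_ids: Sequence[str], transcript_expression: pd.DataFrame,
                 plan: IndexRevisionPlan):
    """Apply one revision; returns (new id set, revision log).

    Removal reasons: ``all_zero`` (TPM exactly 0 in every sample, when
    ``drop_all_zero``) and ``low_quality_flag``; additions are the plan's
    validated novel models.  Idempotent: re-running on the revised set with
    the same expression changes nothing further.
    """
    current = set(current_ids)
    missing = current - set(transcript_expression.index)
    if missing:
        raise ValueError(f"expression does not cover ids: {sorted(missing)[:5]}")
    unknown_flags = set(plan.low_quality_ids) - current
    if unknown_flags:
        raise ValueError(f"low-quality flags outside the index: {sorted(unknown_flags)[:5]}")
    log = []
    removed = set()
    if plan.drop_all_zero:
        zeros = transcript_expression.loc[sorted(current)]
        all_zero = set(zeros.index[(zeros == 0.0).all(axis=1)])
        for t in sorted(all_zero):
            log.append({"transcript_id": t, "action": "removed", "reason": "all_zero"})
        removed |= all_zero
    for t in sorted(set(plan.low_quality_ids) - removed):
        log.append({"transcript_id": t, "action": "removed", "reason": "low_quality_flag"})
    removed |= set(plan.low_quality_ids)
    surviving = current - removed
    novel_ids = [m.transcript_id for m in plan.novel_models]
    collisions = set(novel_ids) & surviving
    if collisions:
        raise ValueError(f"novel model ids collide with surviving ids: {sorted(collisions)}")
    for t in sorted(novel_ids):
        log.append({"transcript_id": t, "action": "added", "reason": "novel_validated"})
    return surviving | set(novel_ids), log


def replay_revisions(draft_ids: Sequence[str], history: Sequence[dict]) -> set:
    """Reconstruct the final transcript set from the draft set and the log."""
    ids = set(draft_ids)
    for entry in history:
        if entry["action"] == "removed":
            ids.discard(entry["transcript_id"])
        else:
            ids.add(entry["transcript_id"])
    return ids


def run_multipass(genome: Mapping[str, str], draft_models: Sequence[TranscriptModel],
                  candidate_models: Sequence[TranscriptModel], homology_alignments,
                  samples: Mapping[str, Sequence], metadata: pd.DataFrame,
                  low_quality_ids: frozenset = frozenset(),
                  config: QuantConfig = QuantConfig(),
                  genus_whitelist: frozenset = RUMINANT_GENERA) -> MultipassResult:
    """The full three-pass flow on in-memory inputs."""
    draft_seqs = {m.transcript_id: m.spliced_sequence(genome) for m in draft_models}
    gene_map = {m.transcript_id: m.gene_id for m in draft_models}
    gene_map.update({m.transcript_id: m.gene_id for m in candidate_models})
    history = []

    pass1 = run_pass(draft_seqs, gene_map, samples, metadata, config, pass_number=1)

    plan1 = IndexRevisionPlan(drop_all_zero=True,
                              low_quality_ids=frozenset(low_quality_ids), pass_number=1)
    ids2, log1 = revise_index(pass1.transcript_ids, pass1.transcript_expression, plan1)
    history.extend(log1)
    seqs2 = {t: draft_seqs[t] for t in sorted(ids2)}
    pass2 = run_pass(seqs2, gene_map, samples, metadata, config, pass_number=2)
    pass2.revision_log = log1

    retained, decisions = annotate_novel_models(
        candidate_models, genome, homology_alignments, genus_whitelist=genus_whitelist,
    )
    if candidate_models and not retained:
        warnings.warn("validation rejected all candidate novel models; "
                      "third-pass index unchanged beyond the second-pass set")
    plan2 = IndexRevisionPlan(drop_all_zero=False, novel_models=tuple(retained),
                              pass_number=2)
    ids3, log2 = revise_index(pass2.transcript_ids, pass2.transcript_expression, plan2)
    history.extend(log2)
    seqs3 = dict(seqs2)
    seqs3.update({m.transcript_id: m.spliced_sequence(genome) for m in retained})
    pass3 = run_pass(seqs3, gene_map, samples, metadata, config, pass_number=3)
    pass3.revision_log = log2

    return MultipassResult(passes=[pass1, pass2, pass3], revision_history=history,
                           validation_decisions=decisions)
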
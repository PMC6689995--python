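# Methods

This note documents the models and procedures atlasforge implements, the
synthetic study designs its tests run on, and the numerical choices that
were genuinely open.

## Quantification model

The quantifier follows the pseudoalignment contract: reads are assigned to
*transcript-compatibility equivalence classes* rather than aligned at base
level, and an EM distributes class counts over member transcripts.

**Index.** A forward k-mer index (default k = 31; k must be odd, 11–31).
K-mers containing N are skipped. Transcripts shorter than k are flagged
unindexable and warned about. Effective length is
ℓ̃_t = max(ℓ_t − μ_frag + 1, 1) with μ_frag = 200 by default; this is the
number of distinct fragment start positions for a fixed fragment length,
and the floor of 1 avoids division by zero for very short transcripts.

**Strandedness.** The library convention is a stranded dUTP-style protocol:
mate 1 is transcript-sense. The index stores forward k-mers; mate 1 is
queried as-is and mate 2 reverse-complemented. An unstranded mode queries
both orientations of the pair and unions the two compatibility sets.

**Pseudoalignment.** A pair's compatibility set is the intersection of the
hit sets of every indexed k-mer across both mates; k-mers absent from the
index are ignored rather than emptying the set. Pairs with an empty final
set are recorded unassigned (reason `no_match`; pairs shorter than k get
`too_short`) and their ids are kept — in a real workflow these feed de-novo
assembly.

**EM.** With α_t the estimated read count of transcript t, the E-step
splits each class count n_c over members proportionally to α_t/ℓ̃_t and the
M-step replaces α with the summed fractional assignments. In molar
fractions θ_t ∝ α_t/ℓ̃_t this is the EM for the class multinomial with
p_c(θ) = Σ_{t∈c} θ_t / Σ_u θ_u ℓ̃_u, and the recorded log-likelihood
Σ_c n_c log(Σ_{t∈c} α_t/ℓ̃_t) − N log N is non-decreasing (Σ_t α_t = N is
invariant under the update). TPM_t = θ_t · 10⁶. Convergence is declared
when max_t |Δα_t| / N < tol (default 1e-8, max 1000 iterations); measuring
the change relative to the assigned total makes the stopping rule — and
therefore the whole trajectory — exactly invariant to rescaling all class
counts, which the test suite asserts. Gene TPM is the sum of member
transcript TPM.

The deliberate simplifications relative to production pseudoaligners: no
transcript de Bruijn graph or k-mer skipping, no bootstrap resampling, no
fragment-length distribution or bias models. The contract (EC counts → EM →
TPM, unassigned reads captured) is what downstream stages consume.

## Novel-model retention

A candidate transcript model passes the **ORF gate** if:

a. the longest ORF of every exon lies on one and the same strand;
b. the 3'-most exon's ORF is terminated by a stop codon, not by running
   into the exon end;
c. no internal exon's ORF is stop-terminated before its exon ends (the ORF
   must end because the exon does);
d. the peptide concatenated from the translated per-exon ORFs is ≥ 50 aa.

An ORF here is a *maximal stop-free stretch* in one of the six reading
frames of the exon's genomic sequence; no start codon is required, because
internal exons of a genuine CDS need not begin with ATG. A
`require_start_codon` switch restricts ORFs to begin at ATG for users who
prefer the stricter convention. Ties on length are resolved toward the
model's annotated strand, then frame 0/1/2, then the leftmost start; this
keeps decisions deterministic and biases toward the annotation when the
evidence cannot distinguish strands. Criterion (c) is interpreted as: the
chosen ORF of a non-terminal exon must not be followed by an in-frame stop
within the exon (equivalently, it must extend to the exon's last complete
codon). The standard genetic code is used; stops are TAA/TAG/TGA.

The **homology gate** consumes a blast-tabular file extended with subject
genus and description columns (standard outfmt 6 lacks the description text
the criteria need). Rows with e-value > 1e-25 are dropped first. A row is
valid if identity ≥ 90%, aligned length ≥ 90% of the query peptide and
≥ 50 aa, no gaps, and the description contains none of "low quality",
"hypothetical", "unnamed", "uncharacterized", "putative" (plus a
configurable extra list, by default "tpa:" as a deterministic proxy for
third-party annotations). A query is retained iff it has ≥ 5 valid rows of
which at least one is from a ruminant genus
{Bison, Bos, Camelus, Capra, Ovis, Pantholops, Vicugna}. Each HSP row
counts once toward the ≥ 5 requirement; genus is parsed from its own
column, never from free text. Retention is monotone under relaxing any
single threshold, which the suite verifies.

A model is kept only if both gates pass; every decision is reported with
the complete set of violated criteria, not just the first.

## Multi-pass index revision

Low-quality reference transcripts cannot be recomputed from the data (the
upstream judgement involves comparing predicted transcripts to their
source genome), so they enter as an externally supplied id list. All-zero
removal uses TPM exactly 0.0 in every sample — a strict rule, not a small
threshold. The revision log records every id added or removed with one of
three reasons (`all_zero`, `low_quality_flag`, `novel_validated`);
replaying the log over the draft set reproduces the final set exactly, and
revision is idempotent. De-novo assembly of unassigned reads is out of
scope: unassigned read ids are captured per sample and candidate novel
models enter as input.

## Network analysis

Expression is reduced to mean TPM per gene per tissue (tissues ordered as
in the sample metadata); genes whose mean TPM never exceeds 10 in any
tissue are removed (strictly >10). Edges connect gene pairs with Pearson
r ≥ 0.80 computed on tissue-average profiles; the per-sample alternative is
available as an option, but the tissue-average representation is the
primary one. Zero-variance genes have undefined r and are reported
separately as isolated nodes. For lncRNA subsets the convention is the
same pipeline on the subset gene list at r ≥ 0.9 and no expression filter.
No automatic threshold selection is attempted; `threshold_scan` reports
node/edge counts over candidate thresholds so the choice can be made
empirically.

**MCL.** The transition matrix uses edge weights (r values) with self-loops
of weight 1, column-normalised. Iteration alternates expansion (matrix
power 2) and inflation (entry-wise power, default 2.2, followed by column
renormalisation), pruning entries below 1e-5 and renormalising again so
columns remain stochastic to ≤1e-9 throughout (asserted in tests).
Convergence: max entry change < 1e-6, cap 200 iterations (non-convergence
returns the current interpretation with a warning flag). Clusters are read
from the limit matrix's attractor structure: rows with positive diagonal
attract their nonzero columns; attractors attracting each other share a
cluster; a node attracted by several clusters is assigned where its
attractor mass is larger (ties to the earlier cluster). Pruning and
inflation defaults are common MCL practice rather than derived values; the
suite pins behaviour against an independently coded sparse-matrix MCL.
Clusters below 5 members are excluded and survivors renumbered by
non-increasing size, ties broken by smallest member id.

## Summaries

A gene is detected in a tissue when its mean TPM over that tissue's
replicates strictly exceeds 1; breadth is the count of detecting tissues
and is written as the "Expression summary" column of the atlas table.
Cluster profiles are per-tissue means over member genes; the specificity
label lists tissues by descending mean, truncated at depth 5, and a
cluster whose top tissue holds < 25% of the profile mass is labelled
"general". Functional class assignments (housekeeping vs pathway vs
cell-type) are curator judgements and are not automated; only the
mechanical tissue-order label is.

## Synthetic designs

The generator emulates the features the pipeline's correctness depends on,
at a scale where every test runs in seconds.

* **Genome and models.** Genes are laid sequentially on chromosomes (50 per
  chromosome) with 2–4 exons of 150–399 nt (multiples of 3) and introns of
  60–200 nt; both strands occur. Protein-coding genes carry planted coding
  exon content — stop-free codons in frame 0 of the annotated strand, a
  stop codon closing the 3'-most exon, with the final exon redrawn until no
  opposite-strand frame can match the intended ORF on length — so their
  models satisfy the ORF criteria by construction. Scenario helpers emit
  candidates violating exactly one criterion each (wrong-strand exon, open
  terminal ORF, early internal stop, short peptide), with redraw loops
  guaranteeing the planted defect is the decisive one.
* **Expression.** The default design is 300 genes × 10 tissues × 2
  replicates: three 25-gene modules active in disjoint tissue pairs (mean
  500 TPM active, 1 TPM inactive), 10% housekeeping genes (100 TPM
  everywhere), and unstructured noise genes with per-gene log-normal
  tissue profiles (median 10 TPM, σ_log 1.5). Replicate noise is
  multiplicative log-normal, σ = 0.1 on the natural-log scale — positive
  support and a realistic heavy tail for TPM. Columns are normalised to
  10⁶, so planted "expected means" are exact before normalisation and
  proportionally preserved after it.
* **Reads.** Fragments of fixed length 200 are drawn per transcript with
  probability proportional to abundance × number of distinct start
  positions (i.e. effective length), matching the quantifier's
  effective-length convention so that TPM is recovered in expectation;
  mate 1 is the fragment's 5' end on the transcript strand, mate 2 the
  reverse complement of its 3' end; substitution errors at a configurable
  rate; read ids carry the source transcript and fragment start.
* **Homology tables.** Five records per query (four for the
  `too_few` scenario) in blast outfmt-6-plus-genus/description form; each
  failure scenario corrupts exactly one named criterion in one record, and
  truth labels are emitted alongside. Single-violation `min_length`
  records are only constructible for queries of 50–54 aa (shorter queries
  cannot satisfy the criteria at all, longer ones would also fail
  coverage); the generator enforces these feasibility bounds.

What the generator does **not** emulate: realistic error models (indels,
quality calibration), intron-retention artefacts of total-RNA libraries,
fragment-length variability, mappability structure, or between-animal
biological variation beyond log-normal replicate noise. Passing tests
therefore demonstrate the correctness of the bookkeeping, estimators and
rules under clean generative conditions, not robustness to real-data
artefacts.

## Benchmark sizes and statistical formulations

Problem sizes were chosen so the full suite runs in well under a minute of
CPU: quantifier benchmarks use an 80-gene design (three 12-gene modules)
with 20,000 error-free pairs per sample; the three-pass study uses 30
genes × 6 tissues × 2 replicates with 5,000 pairs per sample, two withheld
(module-member) novel genes, two silenced genes and two low-quality flags;
network benchmarks use the 300-gene default design and 60-node planted
graphs. TPM recovery is reported as the mean Spearman correlation over
five seeded replicates: a single 20,000-pair draw leaves genes near 1 TPM
with expected coverage ≪ 1 read, so their ranks are noise and individual
draws fluctuate around the 0.95 mark (observed range ≈ 0.945–0.973); the
mean over replicates is the stable quantity at these study conditions.

## Known limitations

* The pseudoaligner's compatibility sets come from full k-mer
  intersection; unlike graph-based implementations there is no notion of
  contig skipping, so runtime scales with read length × library size.
  Fine at test scale; not a production aligner.
* EM consistency holds under the simulator's generative model; with
  strongly length-heterogeneous transcripts sharing many classes, the
  class-multinomial approximation (which weights members by molar
  fraction, not by fragment mass) can bias shared-count splits.
* MCL cluster reading from the limit matrix follows one of several
  equivalent-in-practice conventions; graphs that converge to genuinely
  overlapping attractor systems are resolved by attractor mass, which may
  differ from other tools' tie handling.
* The `tpa:` keyword is a proxy for "third-party annotation" exclusions;
  there is no deterministic marker for these in blast output.
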
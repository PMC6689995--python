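"""ORF-chain and homology-filter decisions against independent re-implementations."""

import numpy as np
import pytest

from atlasforge.models import HomologyAlignment, TranscriptModel, reverse_complement
from atlasforge.synthetic import plant_orf_candidate, simulate_homology_table
from atlasforge.validation import (
    RUMINANT_GENERA,
    ExonOrf,
    OrfChain,
    annotate_novel_models,
    filter_homology,
    longest_orf_in_exon,
    longest_orfs_per_exon,
    validate_orf_chain,
)

STOPS = {"TAA", "TAG", "TGA"}


# --------------------------------------------------------------- ORF engine

def test_hand_translated_single_exon():
    model = TranscriptModel("t", "g", "c", "+", ((1, 12),))
    genome = {"c": "ATGGCCGCCTAA"}
    # under the ATG-start convention the only ORF is ATG-GCC-GCC + stop
    chain = longest_orfs_per_exon(model, genome, require_start_codon=True)
    assert chain.peptide == "MAA"
    assert chain.per_exon[0].has_terminal_stop
    assert validate_orf_chain(chain, min_peptide_length=3)[0]
    # the default stop-to-stop reading finds the longer open stretch on
    # the reverse strand (TTA-GGC-GGC-CAT, no stop anywhere)
    default = longest_orfs_per_exon(model, genome)
    assert default.per_exon[0].strand == "-"
    assert default.per_exon[0].n_codons == 4
    assert not default.per_exon[0].has_terminal_stop


def test_poly_a_exon_runs_open_to_the_end():
    orf = longest_orf_in_exon("A" * 60, 0, "+")
    assert orf.n_codons == 20
    assert not orf.has_terminal_stop
    assert orf.strand == "+"


def brute_force_longest(seq):
    """Extend from every codon-aligned start in all six frames."""
    best = 0
    for s in (seq, reverse_complement(seq)):
        for f in range(3):
            codons = [s[i:i + 3] for i in range(f, len(s) - 2, 3)]
            for i in range(len(codons)):
                ln = 0
                for j in range(i, len(codons)):
                    if codons[j] in STOPS:
                        break
                    ln += 1
                best = max(best, ln)
    return best


def test_longest_orf_matches_exhaustive_enumeration():
    rng = np.random.default_rng(17)
    for trial in range(50):
        seq = "".join(rng.choice(list("ACGT"), 300))
        orf = longest_orf_in_exon(seq, 0, "+" if trial % 2 else "-")
        assert orf.n_codons == brute_force_longest(seq)


def test_exon_outside_chromosome_rejected():
    model = TranscriptModel("t", "g", "c", "+", ((1, 500),))
    with pytest.raises(ValueError, match="exceeds"):
        longest_orfs_per_exon(model, {"c": "ACGT" * 10})


# --------------------------------------------------------------- rule table

def random_chain(rng):
    n = int(rng.integers(1, 5))
    per_exon = [
        ExonOrf(exon_index=i, strand=str(rng.choice(["+", "-"])),
                start=0, end=3 * int(rng.integers(1, 30)),
                has_terminal_stop=bool(rng.random() < 0.5),
                internal_stop=bool(rng.random() < 0.5), peptide="")
        for i in range(n)
    ]
    peptide = "M" * int(rng.integers(20, 90))
    return OrfChain("t", per_exon, peptide)


def independent_rules(chain):
    """A second reading of the four retention criteria."""
    failures = set()
    strands = [o.strand for o in chain.per_exon]
    for a in strands:
        for b in strands:
            if a != b:
                failures.add("a_strand")
    last = chain.per_exon[-1]
    if last.has_terminal_stop is False:
        failures.add("b_terminal_stop")
    for o in chain.per_exon[:-1]:
        if o.internal_stop:
            failures.add("c_internal_stop")
    if not len(chain.peptide) >= 50:
        failures.add("d_min_length")
    return failures


def test_chain_rules_match_independent_reading():
    rng = np.random.default_rng(23)
    for _ in range(50):
        chain = random_chain(rng)
        ok, failures = validate_orf_chain(chain)
        expected = independent_rules(chain)
        assert set(failures) == expected
        assert ok == (not expected)


def test_chain_boundary_and_strand_examples():
    def exon(strand, terminal, internal=False):
        return ExonOrf(0, strand, 0, 90, terminal, internal, "")

    good = OrfChain("t", [exon("+", False), exon("+", True)], "M" * 60)
    assert validate_orf_chain(good) == (True, frozenset())

    short = OrfChain("t", [exon("+", False), exon("+", True)], "M" * 49)
    assert validate_orf_chain(short)[1] == frozenset({"d_min_length"})

    mixed = OrfChain("t", [exon("+", False), exon("-", True)], "M" * 60)
    assert "a_strand" in validate_orf_chain(mixed)[1]


@pytest.mark.parametrize("scenario,expected", [
    ("pass", frozenset()),
    ("strand", frozenset({"a_strand"})),
    ("no_terminal_stop", frozenset({"b_terminal_stop"})),
    ("internal_stop", frozenset({"c_internal_stop"})),
    ("short_peptide", frozenset({"d_min_length"})),
])
@pytest.mark.parametrize("strand", ["+", "-"])
@pytest.mark.parametrize("seed", [0, 7])
def test_planted_scenarios_fail_their_single_criterion(scenario, expected, strand, seed):
    model, seq = plant_orf_candidate(scenario, seed=seed, strand=strand)
    chain = longest_orfs_per_exon(model, {model.chrom: seq})
    ok, failures = validate_orf_chain(chain)
    assert failures == expected
    assert ok == (not expected)


def test_exon_order_independent_of_insertion_order():
    model, seq = plant_orf_candidate("pass", seed=3)
    chain1 = longest_orfs_per_exon(model, {model.chrom: seq})
    shuffled = TranscriptModel(model.transcript_id, model.gene_id, model.chrom,
                               model.strand, tuple(model.exons), model.biotype)
    chain2 = longest_orfs_per_exon(shuffled, {model.chrom: seq})
    assert chain1.peptide == chain2.peptide


# ----------------------------------------------------------- homology filter

def make_alignment(qid="q", genus="Bos", desc="myosin", pident=95.0,
                   length=58, gaps=0, evalue=1e-40, qlen=60):
    return HomologyAlignment(query_id=qid, subject_id="s", subject_genus=genus,
                             subject_description=desc, pident=pident,
                             align_length=length, gap_count=gaps,
                             evalue=evalue, query_length=qlen)


def test_ruminant_five_alignment_query_is_retained():
    genera = ["Bos", "Ovis", "Capra", "Bos", "Bison"]
    alignments = [make_alignment(genus=g, pident=92 + i, length=55 + i)
                  for i, g in enumerate(genera)]
    result = filter_homology(alignments)
    assert result["q"] == (True, frozenset())


def test_single_hypothetical_description_knocks_out_the_query():
    genera = ["Bos", "Ovis", "Capra", "Bos", "Bison"]
    alignments = [make_alignment(genus=g) for g in genera]
    alignments[2] = make_alignment(genus="Capra", desc="hypothetical protein")
    retained, failures = filter_homology(alignments)["q"]
    assert not retained
    assert failures == frozenset({"too_few_alignments"})


def test_evalue_prefilter_removes_weak_rows_before_criteria():
    alignments = [make_alignment() for _ in range(3)]
    alignments += [make_alignment(evalue=1e-10) for _ in range(2)]
    retained, failures = filter_homology(alignments)["q"]
    assert not retained and "too_few_alignments" in failures


def independent_filter(alignments, min_alignments=5):
    """Brute-force re-implementation of the retention rule."""
    words = ("low quality", "hypothetical", "unnamed", "uncharacterized",
             "putative", "tpa:")
    per_query: dict = {}
    for a in alignments:
        per_query.setdefault(a.query_id, []).append(a)
    out = {}
    for q, rows in per_query.items():
        n_valid, ruminant = 0, False
        for a in rows:
            if a.evalue > 1e-25:
                continue
            ok = (a.pident >= 90 and a.align_length >= 0.9 * a.query_length
                  and a.align_length >= 50 and a.gap_count == 0
                  and not any(w in a.subject_description.lower() for w in words))
            if ok:
                n_valid += 1
                ruminant = ruminant or a.subject_genus in RUMINANT_GENERA
        out[q] = n_valid >= min_alignments and ruminant
    return out


def random_table(rng, n_rows=500, n_queries=40):
    descs = ["myosin", "keratin 5", "hypothetical protein", "putative kinase",
             "low quality protein", "solute carrier"]
    genera = sorted(RUMINANT_GENERA) + ["Sus", "Homo", "Mus"]
    rows = []
    for _ in range(n_rows):
        qlen = int(rng.integers(50, 300))
        rows.append(make_alignment(
            qid=f"q{rng.integers(0, n_queries):02d}",
            genus=str(rng.choice(genera)), desc=str(rng.choice(descs)),
            pident=float(rng.uniform(70, 100)),
            length=int(rng.integers(30, qlen + 1)),
            gaps=int(rng.integers(0, 3)),
            evalue=float(10.0 ** rng.uniform(-60, -10)), qlen=qlen))
    return rows


def test_filter_matches_bruteforce_on_random_tables():
    rng = np.random.default_rng(31)
    table = random_table(rng)
    mine = filter_homology(table)
    oracle = independent_filter(table)
    assert set(mine) == set(oracle)
    for q in oracle:
        assert mine[q][0] == oracle[q], q


def test_relaxing_any_threshold_never_shrinks_retention():
    rng = np.random.default_rng(37)
    table = random_table(rng)
    base = {q for q, (r, _) in filter_homology(table).items() if r}
    relaxed = [
        dict(min_pident=85.0), dict(min_coverage=0.8),
        dict(min_length=40), dict(min_alignments=4),
    ]
    for kwargs in relaxed:
        bigger = {q for q, (r, _) in filter_homology(table, **kwargs).items() if r}
        assert base <= bigger, kwargs


def test_decisions_stable_under_row_permutation():
    rng = np.random.default_rng(41)
    table = random_table(rng, n_rows=200, n_queries=15)
    base = filter_homology(table)
    perm = [table[i] for i in rng.permutation(len(table))]
    assert filter_homology(perm) == base


# -------------------------------------------------------------- composition

def test_retained_set_is_conjunction_of_both_gates():
    genome, models, scenarios = {}, [], []
    orf_cases = ["pass", "internal_stop", "pass", "short_peptide", "pass", "strand"]
    hom_cases = ["all_pass", "all_pass", "gaps", "too_few", "genus", "all_pass"]
    alignments = []
    expected_retained = set()
    for i, (oc, hc) in enumerate(zip(orf_cases, hom_cases)):
        model, seq = plant_orf_candidate(oc, seed=100 + i, chrom=f"chr{i}")
        genome[f"chr{i}"] = seq
        models.append(model)
        qlen = max(model.spliced_length // 3 - 1, 60)
        sim = simulate_homology_table([(model.transcript_id, qlen)], hc, seed=i)
        alignments.extend(sim.alignments)
        if oc == "pass" and hc == "all_pass":
            expected_retained.add(model.transcript_id)
    retained, decisions = annotate_novel_models(models, genome, alignments)
    assert {m.transcript_id for m in retained} == expected_retained
    for d in decisions:
        assert d.retained == (not d.orf_failures and not d.homology_failures)
        if not d.retained:
            assert d.orf_failures or d.homology_failures


def test_candidate_without_alignments_fails_homology_only():
    model, seq = plant_orf_candidate("pass", seed=9)
    retained, decisions = annotate_novel_models([model], {model.chrom: seq}, [])
    assert retained == []
    d = decisions[0]
    assert d.orf_failures == frozenset()
    assert d.homology_failures == frozenset({"too_few_alignments"})
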
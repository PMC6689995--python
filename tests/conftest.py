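import pytest

from atlasforge.synthetic import (
    DEFAULT_TISSUES,
    ModuleSpec,
    SyntheticDesign,
    generate_genome_and_models,
    simulate_expression,
    split_gene_tpm_to_transcripts,
)


def small_design(seed: int = 3, **overrides) -> SyntheticDesign:
    """An 80-gene benchmark design: three 12-gene modules, 10 tissues."""
    T = DEFAULT_TISSUES
    kwargs = dict(
        n_genes=80,
        modules=(
            ModuleSpec("mod_a", 12, tuple(T[0:2])),
            ModuleSpec("mod_b", 12, tuple(T[2:4])),
            ModuleSpec("mod_c", 12, tuple(T[8:10])),
        ),
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticDesign(**kwargs)


@pytest.fixture(scope="session")
def study():
    """One fully generated small study shared by read-level tests."""
    design = small_design()
    genome, models = generate_genome_and_models(design)
    expr, truth = simulate_expression(design, models)
    seqs = {m.transcript_id: m.spliced_sequence(genome) for m in models}
    return {
        "design": design, "genome": genome, "models": models,
        "expression": expr, "truth": truth, "seqs": seqs,
        "gene_map": {m.transcript_id: m.gene_id for m in models},
    }


@pytest.fixture()
def sample_reads(study):
    """Error-free stranded pairs from the first sample's true abundances."""
    expr = study["expression"]
    tx = split_gene_tpm_to_transcripts(expr.data[expr.samples[0]], study["models"])
    from atlasforge.synthetic import simulate_reads

    return simulate_reads(study["seqs"], tx.to_dict(), n_pairs=2000, seed=11)
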
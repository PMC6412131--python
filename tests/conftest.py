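import numpy as np
import pytest

from csckit import CSCTable, GeneSequence, SENSE_CODONS, make_genome


def make_csc(values=None, fill=0.0, n_genes=10, label="fixture"):
    """Full 61-codon CSC table with selected overrides."""
    table = {c: fill for c in SENSE_CODONS}
    if values:
        table.update(values)
    return CSCTable(table, n_genes, label)


@pytest.fixture(scope="session")
def random_csc():
    rng = np.random.default_rng(42)
    return CSCTable(
        {c: float(v) for c, v in zip(SENSE_CODONS, rng.uniform(-0.5, 0.5, 61))},
        n_genes=100,
        dataset_label="random",
    )


@pytest.fixture(scope="session")
def small_genome():
    return make_genome(50, (20, 80), seed=7)


@pytest.fixture
def gene_factory():
    def build(codon_string, gene_id="g1"):
        codons = tuple(codon_string.split())
        return GeneSequence(gene_id, codons, codons[-1] in {"TAA", "TAG", "TGA"})

    return build
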
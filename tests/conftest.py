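import numpy as np
import pytest

from codonbias.codon_model import standard_table
from codonbias.metrics import counts_from_mapping


@pytest.fixture(scope="session")
def table():
    return standard_table()


@pytest.fixture(scope="session")
def pooled_study_counts(table):
    """Genome-wide pooled codon counts of the study chloroplast genome."""
    from codonbias import datasets

    return datasets.pooled_counts(table)


def random_count_table(rng: np.random.Generator, table, mean: float = 5.0):
    """A random codon count table with most families populated."""
    counts = {c: int(rng.poisson(mean)) for c in table.sense_codons}
    return counts_from_mapping(counts, table, scope="random")
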
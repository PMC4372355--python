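import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rootdge.expression import CountLibrary
from rootdge.synthetic_data import CountSimSpec, PlantedDe, gen_counts

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_library(library_id, counts, lengths, gene_ids=None):
    """Small CountLibrary from plain lists."""
    idx = pd.Index(gene_ids or [f"g{i}" for i in range(len(counts))], name="gene_id")
    return CountLibrary(
        library_id=library_id,
        counts=pd.Series(counts, index=idx, dtype=np.int64),
        gene_lengths=pd.Series(lengths, index=idx),
    )


@pytest.fixture(scope="session")
def six_libraries():
    """Six small libraries with three planted DTGs (one per root)."""
    spec = CountSimSpec(
        n_genes=300,
        baseline_mean=500.0,
        planted_de=(
            PlantedDe(0, "PR", -3.0),
            PlantedDe(1, "CR", 3.0),
            PlantedDe(2, "SR", -2.0),
        ),
        seed=11,
    )
    libraries, truth = gen_counts(spec)
    return libraries, truth
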
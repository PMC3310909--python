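import numpy as np
import pytest

from dpmsa import (
    AlphabetSpec,
    CodebookParams,
    RunConfig,
    TOY_AC,
    build_codebook,
    build_pipeline_tables,
    build_reduction_table,
    build_substitution_table,
)


@pytest.fixture(scope="session")
def dna_pipeline():
    """Default DNA codebook, substitution table and reduction table."""
    return build_pipeline_tables(RunConfig())


@pytest.fixture(scope="session")
def dna_codebook(dna_pipeline):
    return dna_pipeline[0]


@pytest.fixture(scope="session")
def dna_table(dna_pipeline):
    return dna_pipeline[1]


@pytest.fixture(scope="session")
def dna_reduction(dna_pipeline):
    return dna_pipeline[2]


@pytest.fixture(scope="session")
def toy_codebook():
    """The 3-dimensional {A, C, gap} worked-example codebook, unfiltered."""
    return build_codebook(TOY_AC, CodebookParams(L=4, apply_filter=False))


def random_simplex_points(rng: np.random.Generator, n: int, D: int) -> np.ndarray:
    """Uniform points on the (D-1)-simplex (Dirichlet(1))."""
    return rng.dirichlet(np.ones(D), size=n)
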
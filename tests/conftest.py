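import numpy as np
import pandas as pd
import pytest

from qstfst import GenotypeTable, PopulationMetadata


@pytest.fixture
def two_pop_genotypes():
    """Two populations of two diploids at one 2-allele locus (hand-countable)."""
    calls = np.array(
        [[[1, 2]], [[1, 1]], [[2, 2]], [[2, 2]]], dtype=np.int64
    )
    return GenotypeTable(
        ["a_1", "a_2", "b_1", "b_2"],
        np.array(["a", "a", "b", "b"], dtype=object),
        ["L01"],
        calls,
    )


@pytest.fixture
def fixed_alternative_genotypes():
    """Two populations each fixed for a different allele: theta = 1."""
    n = 10
    calls = np.concatenate(
        [np.full((n, 1, 2), 1), np.full((n, 1, 2), 2)]
    ).astype(np.int64)
    inds = [f"a_{i}" for i in range(n)] + [f"b_{i}" for i in range(n)]
    pops = np.array(["a"] * n + ["b"] * n, dtype=object)
    return GenotypeTable(inds, pops, ["L01"], calls)


from helpers import small_design  # noqa: E402  (shared design builder)


@pytest.fixture
def small_study():
    """A small simulated phenotype study with its generating truth."""
    from qstfst.synthetic_data import simulate_phenotypes

    d = small_design()
    p, m, truth = simulate_phenotypes(d, seed=11)
    return d, p, m, truth


@pytest.fixture
def toy_metadata():
    return PopulationMetadata(
        pd.DataFrame(
            {
                "population": ["p1", "p2", "p3", "p4", "p5"],
                "subspecies": ["ps"] * 5,
                "latitude": [42.1, 42.5, 42.9, 43.0, 42.3],
                "longitude": [0.8, 1.4, 2.0, 2.5, 1.1],
                "altitude": [61.0, 400.0, 800.0, 1200.0, 1564.0],
            }
        )
    )
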
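import numpy as np
import pytest

from ssrpopgen import GenotypeMatrix, SimulationSpec, simulate


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """Four individuals, two loci, two populations; one missing call."""
    calls = np.array(
        [
            [[150, 150], [200, 204]],
            [[150, 152], [200, 200]],
            [[152, 152], [0, 0]],
            [[150, 152], [204, 204]],
        ]
    )
    return GenotypeMatrix(
        individuals=["i1", "i2", "i3", "i4"],
        loci=["locA", "locB"],
        calls=calls,
        populations=["P1", "P1", "P2", "P2"],
    )


@pytest.fixture(scope="session")
def study_like():
    """Study-sized synthetic dataset: 91 individuals, 5 pops, 13 loci."""
    matrix, truth = simulate(SimulationSpec(seed=20240901))
    return matrix, truth


@pytest.fixture(scope="session")
def two_cluster():
    """Two well-separated synthetic populations (drift 0.3, 50+50)."""
    spec = SimulationSpec(
        n_populations=2, sizes=(50, 50), fst=0.30, fis=0.79, seed=71
    )
    return simulate(spec)
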
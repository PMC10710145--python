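import numpy as np
import pytest

from mvfuse.gwas import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_genotypes():
    """4 subjects x 3 variants, one missing call."""
    counts = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, np.nan, 0.0],
            [2.0, 1.0, 1.0],
            [0.0, 0.0, 1.0],
        ]
    )
    return GenotypeMatrix(
        counts=counts,
        subject_ids=["a", "b", "c", "d"],
        variant_ids=["v1", "v2", "v3"],
        chromosome=np.array([1, 1, 2]),
        position=np.array([100, 200, 50]),
    )
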
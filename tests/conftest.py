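import numpy as np
import pytest

import fourfold as ff


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def uniform_pi():
    return ff.NucleotideDistribution((0.25, 0.25, 0.25, 0.25))


@pytest.fixture(scope="session")
def skewed_pi():
    # the stationary distribution of the packaged reference matrix
    return ff.NucleotideDistribution((0.19, 0.69, 0.05, 0.07))


@pytest.fixture(scope="session")
def acceptance_sm():
    return ff.acceptance_matrix("SM")


@pytest.fixture(scope="session")
def acceptance_sl():
    return ff.acceptance_matrix("SL")


@pytest.fixture(scope="session")
def reference_matrix():
    """The packaged maximum-deviation transition matrix fixture."""
    from importlib import resources

    from fourfold.mutation import read_matrix_tsv

    path = resources.files("fourfold.data") / "max_deviation_matrix.tsv"
    with resources.as_file(path) as p:
        return read_matrix_tsv(p)
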
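import numpy as np
import pytest

from cellmapper import ExpressionMatrix


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples, hand-written values."""
    return ExpressionMatrix(
        gene_ids=np.array(["g1", "g2", "g3"], object),
        sample_ids=np.array(["s1", "s2", "s3", "s4"], object),
        values=np.array([
            [1.0, 2.0, 3.0, 4.0],
            [4.0, 3.0, 2.0, 1.0],
            [0.5, 1.5, 0.5, 1.5],
        ]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160929)


def random_matrix(rng, m, n, prefix="G"):
    return ExpressionMatrix(
        gene_ids=np.array([f"{prefix}{i}" for i in range(m)], object),
        sample_ids=np.array([f"S{j}" for j in range(n)], object),
        values=rng.standard_normal((m, n)),
    )
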
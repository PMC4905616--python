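import numpy as np
import pytest

from mmdpath.io import OmicsBlock, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(20160606)


@pytest.fixture
def small_block():
    return OmicsBlock(
        "toy",
        ["s1", "s2", "s3"],
        ["g1", "g2"],
        np.array([[0.0, 1.0], [1.5, -0.5], [3.0, 2.0]]),
    )


@pytest.fixture
def two_group_block(rng):
    """12 samples x 4 features, first 5 samples shifted."""
    X = rng.standard_normal((12, 4))
    X[:5] += 1.0
    return OmicsBlock(
        "toy", [f"s{i}" for i in range(12)], [f"g{j}" for j in range(4)], X
    )


@pytest.fixture
def two_group_labels():
    return np.array([True] * 5 + [False] * 7)


@pytest.fixture
def gmt_file(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text(
        "catabolism\tdesc\tAOX\tBIEN\tTHIOL\n"
        "dupset\tdesc\tAOX\tAOX\tBIEN\n"
        "emptyset\tdesc\n"
    )
    return p
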
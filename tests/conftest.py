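import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_expression(tmp_path):
    """2-gene x 3-timepoint TSV with one empty cell."""
    p = tmp_path / "toy.tsv"
    p.write_text(
        "gene\t0\t10\t20\n"
        "cla4\t0.1\t-0.3\t0.5\n"
        "ACT1\t\t0.0\t0.2\n"
    )
    return p


@pytest.fixture
def triangle_sif(tmp_path):
    p = tmp_path / "tri.sif"
    p.write_text("A\tpp\tB\nB\tpp\tC\nC\tpp\tA\n")
    return p
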
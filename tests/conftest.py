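import numpy as np
import pytest

from varmod.core_io import Alignment
from varmod.fixtures import make_helix, make_strand_pair


@pytest.fixture(scope="session")
def ideal_helix():
    return make_helix(15)


@pytest.fixture(scope="session")
def strand_pair():
    return make_strand_pair(8)


@pytest.fixture()
def small_alignment():
    # query ACDEF with one invariant column (pos 1) and diverse columns
    return Alignment(
        query_id="q",
        rows=[
            ("q", "ACDEF"),
            ("h1", "AKDGF"),
            ("h2", "AWDEC"),
            ("h3", "AYRE-"),
        ],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
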
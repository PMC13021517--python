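import numpy as np
import pytest

from celldag import Ontology


@pytest.fixture
def chain():
    """C is_a B is_a A; node order (A, B, C)."""
    return Ontology(["A", "B", "C"], [("C", "B"), ("B", "A")])


@pytest.fixture
def diamond():
    """D is_a B, D is_a C, B is_a A, C is_a A (multi-parent)."""
    return Ontology(
        ["A", "B", "C", "D"],
        [("D", "B"), ("D", "C"), ("B", "A"), ("C", "A")],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
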
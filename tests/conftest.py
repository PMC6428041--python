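import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from protgram.grammar import (
    Alphabet,
    NonTerminalInventory,
    build_covering_grammar,
    randomize_theta,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_small_grammar(seed: int, contact: bool = True):
    """Random proper covering grammar over a two-letter alphabet.

    Two lexical and two structural non-terminals: small enough for the
    exhaustive parse-tree enumeration oracle at n <= 6.
    """
    alphabet = Alphabet(("A", "B"))
    nts = NonTerminalInventory(
        lexical=("p", "q"),
        structural=("s", "t"),
        start="s",
        branch_capable=("s", "t"),
        contact_capable=("s", "t") if contact else (),
    )
    g = build_covering_grammar(alphabet, nts)
    return randomize_theta(g, seed)


@pytest.fixture
def small_grammar():
    return make_small_grammar(0)


@pytest.fixture
def toy():
    from protgram.simulate import toy_hairpin_grammar

    return toy_hairpin_grammar()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
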
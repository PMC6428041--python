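import math
import time
import warnings

import numpy as np
import pytest

from oracle import (
    oracle_inside,
    oracle_inside_constrained,
    oracle_skeleton_mass,
    oracle_viterbi,
)
from conftest import make_small_grammar
from protgram.contacts import ContactMap, ShortContactWarning, is_consistent
from protgram.grammar import (
    Alphabet,
    CfcGrammar,
    NonTerminalInventory,
    Rule,
    build_covering_grammar,
    normalize_theta,
    randomize_theta,
)
from protgram.parser import (
    MapCompatibilityError,
    ParseTree,
    from_bracket,
    inside,
    inside_constrained,
    skeleton,
    skeleton_mass,
    to_bracket,
    tree_log_prob,
    viterbi,
)


def tiny_grammar():
    """{s -> t t (1), t -> A (1)} over a one-letter alphabet."""
    rules = (
        Rule("branching", "s", ("t", "t")),
        Rule("lexical", "t", ("A",)),
    )
    nts = NonTerminalInventory(("t",), ("s",), start="s", branch_capable=("s",))
    return CfcGrammar(Alphabet(("A",)), nts, rules, {r: 1.0 for r in rules})


def cmap(n, pairs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ShortContactWarning)
        return ContactMap(n, frozenset(pairs))


class TestInside:
    def test_deterministic_grammar(self):
        g = tiny_grammar()
        assert inside("AA", g) == 1.0
        assert inside("AAA", g) == 0.0

    def test_unknown_symbol_and_empty_sequence(self):
        g = tiny_grammar()
        with pytest.raises(ValueError):
            inside("AZ", g)
        with pytest.raises(ValueError):
            inside("", g)

    def test_matches_enumeration(self):
        for seed in range(5):
            g = make_small_grammar(seed)
            rng = np.random.default_rng(seed)
            for n in (2, 3, 5):
                x = "".join(rng.choice(["A", "B"], size=n))
                expected = oracle_inside(g, x)
                assert inside(x, g) == pytest.approx(expected, rel=1e-11, abs=1e-300)

    def test_probability_mass_bounded_by_one(self):
        # sum over all sequences of all lengths cannot exceed 1 for a proper grammar
        g = make_small_grammar(11)
        total = 0.0
        for n in range(1, 9):
            for bits in range(2**n):
                x = "".join("AB"[(bits >> k) & 1] for k in range(n))
                total += inside(x, g)
        assert total <= 1.0 + 1e-9


class TestInsideConstrained:
    def test_empty_map_equals_unconstrained(self):
        g = make_small_grammar(1)
        x = "ABBA"
        assert inside_constrained(x, ContactMap(4), g) == inside(x, g)

    def test_no_contact_rules_means_zero_mass(self):
        g = make_small_grammar(2, contact=False)
        assert inside_constrained("ABABA", cmap(5, {(1, 5)}), g) == 0.0

    def test_incompatible_map_rejected(self):
        g = make_small_grammar(3)
        with pytest.raises(MapCompatibilityError):
            inside_constrained("ABABAB", cmap(6, {(1, 4), (2, 6)}), g)

    def test_length_mismatch_rejected(self):
        g = make_small_grammar(3)
        with pytest.raises(MapCompatibilityError):
            inside_constrained("ABA", cmap(5, {(1, 5)}), g)

    def test_matches_enumerate_and_filter(self):
        maps = [cmap(6, {(1, 6)}), cmap(6, {(2, 5)}), cmap(6, {(1, 6), (2, 5)})]
        for seed in range(5):
            g = make_small_grammar(seed + 100)
            rng = np.random.default_rng(seed)
            x = "".join(rng.choice(["A", "B"], size=6))
            for m in maps:
                expected = oracle_inside_constrained(g, x, m)
                got = inside_constrained(x, m, g)
                assert got == pytest.approx(expected, rel=1e-11, abs=1e-300)

    def test_separation_two_pair_has_zero_mass(self):
        # no CFC derivation can realize a contact at separation 2
        g = make_small_grammar(8)
        assert inside_constrained("ABABA", cmap(5, {(1, 3)}), g) == 0.0

    def test_monotone_in_map_refinement(self):
        g = make_small_grammar(4)
        x = "ABBABA"
        p0 = inside(x, g)
        p1 = inside_constrained(x, cmap(6, {(1, 6)}), g)
        p2 = inside_constrained(x, cmap(6, {(1, 6), (2, 5)}), g)
        assert 0.0 <= p2 <= p1 <= p0 <= 1.0


class TestSkeletonMass:
    def test_single_skeleton_grammar(self):
        rules = (
            Rule("branching", "s", ("t", "t")),
            Rule("lexical", "t", ("A",)),
            Rule("lexical", "t", ("B",)),
        )
        nts = NonTerminalInventory(("t",), ("s",), start="s", branch_capable=("s",))
        g = CfcGrammar(
            Alphabet(("A", "B")),
            nts,
            rules,
            {rules[0]: 1.0, rules[1]: 0.3, rules[2]: 0.7},
        )
        assert skeleton_mass(2, ContactMap(2), g) == 1.0

    def test_independent_of_lexical_probabilities(self):
        g = make_small_grammar(5)
        m = cmap(5, {(1, 5)})
        v1 = skeleton_mass(5, m, g)
        theta = dict(g.theta)
        lex = [r for r in g.rules if r.kind == "lexical"]
        # reshuffle lexical mass arbitrarily (still proper)
        theta[lex[0]], theta[lex[1]] = theta[lex[1]], theta[lex[0]]
        g2 = g.with_theta(normalize_theta(theta))
        assert skeleton_mass(5, m, g2) == pytest.approx(v1, rel=1e-12)

    def test_equals_sum_of_constrained_insides(self):
        for seed in (0, 1, 2):
            g = make_small_grammar(seed + 40)
            for n, pairs in [(4, set()), (5, {(1, 5)}), (6, {(1, 6), (2, 5)})]:
                m = cmap(n, pairs)
                total = 0.0
                for bits in range(2**n):
                    x = "".join("AB"[(bits >> k) & 1] for k in range(n))
                    total += inside_constrained(x, m, g)
                assert skeleton_mass(n, m, g) == pytest.approx(total, rel=1e-9)


class TestViterbi:
    def test_deterministic_grammar_tree_probability_equals_inside(self):
        g = tiny_grammar()
        tree, p = viterbi("AA", g)
        assert p == inside("AA", g) == 1.0
        assert to_bracket(tree) == "(s (t A) (t A))"

    def test_matches_enumeration_max(self):
        for seed in range(8):
            g = make_small_grammar(seed + 200)
            rng = np.random.default_rng(seed)
            x = "".join(rng.choice(["A", "B"], size=int(rng.integers(2, 7))))
            tree, p = viterbi(x, g)
            assert p == pytest.approx(oracle_viterbi(g, x), rel=1e-11)
            # the returned tree's own derivation probability matches the report
            assert math.exp(tree_log_prob(tree, g)) == pytest.approx(p, rel=1e-11)
            assert tree.yield_string() == x

    def test_constrained_tree_is_consistent(self):
        g = make_small_grammar(6)
        m = cmap(6, {(1, 6)})
        tree, p = viterbi("ABABAB", g, m)
        assert p > 0
        assert is_consistent(skeleton(tree), m, delta=4)
        assert p == pytest.approx(oracle_viterbi(g, "ABABAB", m), rel=1e-11)

    def test_no_parse_returns_none_not_exception(self):
        g = tiny_grammar()
        tree, p = viterbi("AAA", g)
        assert tree is None and p == 0.0
        g2 = make_small_grammar(2, contact=False)
        tree, p = viterbi("ABABA", g2, cmap(5, {(1, 5)}))
        assert tree is None and p == 0.0

    def test_viterbi_bounded_by_inside(self):
        g = make_small_grammar(9)
        x = "ABBAAB"
        _, p = viterbi(x, g)
        assert 0 < p <= inside(x, g) <= 1.0


def test_bracket_round_trip():
    g = make_small_grammar(13)
    tree, _ = viterbi("ABAB", g)
    assert from_bracket(to_bracket(tree)) == tree


def test_runtime_scales_polynomially():
    """Doubling n from 32 to 64 should cost roughly 2^3; allow generous slack."""
    g = randomize_theta(
        build_covering_grammar(Alphabet(), NonTerminalInventory.make(3, 4, contact=True)),
        seed=0,
    )
    rng = np.random.default_rng(0)
    times = {}
    for n in (16, 32, 64):
        x = "".join(rng.choice(list("ACDEFGHIKLMNQPRSTVWY"), size=n))
        inside(x, g)  # warm-up (JIT, cache)
        t0 = time.perf_counter()
        for _ in range(3):
            inside(x, g)
        times[n] = (time.perf_counter() - t0) / 3
    assert times[64] / max(times[32], 1e-9) < 40  # cubic ~8, generous noise margin
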
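import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score

from conftest import make_small_grammar
from protgram.contacts import ContactMap, ShortContactWarning, Ust
from protgram.evaluation import (
    NullModel,
    ScoredSet,
    average_precision,
    cv_split,
    descriptive_metrics,
    ensemble_score,
    null_logprob,
    recall_precision_ap,
    scan,
    score_sequence,
)
from protgram.grammar import (
    Alphabet,
    CfcGrammar,
    NonTerminalInventory,
    Rule,
)
from protgram.parser import NEG_INF, ParseTree, viterbi
from protgram.simulate import toy_hairpin_grammar


def cmap(n, pairs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ShortContactWarning)
        return ContactMap(n, frozenset(pairs))


class TestNullModel:
    def test_uniform_logprob(self):
        null = NullModel.uniform(Alphabet())
        assert null_logprob("ACDEF", null) == pytest.approx(-5 * math.log10(20))

    def test_hand_multiplied_product(self):
        null = NullModel.from_weights({"A": 0.5, "C": 0.3, "D": 0.2})
        assert null_logprob("ACD", null) == pytest.approx(math.log10(0.5 * 0.3 * 0.2))

    def test_default_table_covers_amino_acids_and_sums_to_one(self):
        null = NullModel.default()
        assert set(null.frequencies) == set("ACDEFGHIKLMNQPRSTVWY")
        assert sum(null.frequencies.values()) == pytest.approx(1.0, abs=1e-12)

    def test_score_three_means_thousandfold_ratio(self):
        # grammar assigns probability 1 to "AA"; null assigns 1/1000
        rules = (Rule("branching", "s", ("t", "t")), Rule("lexical", "t", ("A",)))
        nts = NonTerminalInventory(("t",), ("s",), start="s", branch_capable=("s",))
        g = CfcGrammar(Alphabet(("A", "B")), nts, rules, {r: 1.0 for r in rules})
        f = 10 ** (-1.5)
        null = NullModel.from_weights({"A": f, "B": 1 - f})
        assert score_sequence("AA", g, null=null) == pytest.approx(3.0, abs=1e-12)


class TestScoreSequence:
    def test_grammar_factorizing_like_null_scores_zero(self):
        fa, fb = 0.7, 0.3
        rules = (
            Rule("branching", "s", ("t", "t")),
            Rule("lexical", "t", ("A",)),
            Rule("lexical", "t", ("B",)),
        )
        nts = NonTerminalInventory(("t",), ("s",), start="s", branch_capable=("s",))
        g = CfcGrammar(
            Alphabet(("A", "B")), nts, rules, {rules[0]: 1.0, rules[1]: fa, rules[2]: fb}
        )
        null = NullModel.from_weights({"A": fa, "B": fb})
        for x in ("AA", "AB", "BB"):
            assert score_sequence(x, g, null=null) == pytest.approx(0.0, abs=1e-12)

    def test_unparsable_scores_minus_inf(self):
        rules = (Rule("branching", "s", ("t", "t")), Rule("lexical", "t", ("A",)))
        nts = NonTerminalInventory(("t",), ("s",), start="s", branch_capable=("s",))
        g = CfcGrammar(Alphabet(("A", "B")), nts, rules, {r: 1.0 for r in rules})
        null = NullModel.uniform(Alphabet(("A", "B")))
        assert score_sequence("AB", g, null=null) == NEG_INF

    def test_constrained_score_uses_constrained_inside(self):
        g = make_small_grammar(3)
        null = NullModel.uniform(Alphabet(("A", "B")))
        m = cmap(6, {(1, 6)})
        s_free = score_sequence("ABABAB", g, null=null)
        s_con = score_sequence("ABABAB", g, cmap=m, null=null)
        assert s_con <= s_free


class TestEnsemble:
    def test_single_and_identical_grammars(self):
        g = make_small_grammar(4)
        null = NullModel.uniform(Alphabet(("A", "B")))
        s = score_sequence("ABBA", g, null=null)
        assert ensemble_score("ABBA", [g], null) == pytest.approx(s)
        assert ensemble_score("ABBA", [g, g, g], null) == pytest.approx(s)

    def test_two_grammar_mean(self):
        g1, g2 = make_small_grammar(5), make_small_grammar(6)
        null = NullModel.uniform(Alphabet(("A", "B")))
        s1 = score_sequence("ABBA", g1, null=null)
        s2 = score_sequence("ABBA", g2, null=null)
        assert ensemble_score("ABBA", [g1, g2], null) == pytest.approx((s1 + s2) / 2)


class TestAveragePrecision:
    def test_perfect_separation(self):
        assert average_precision([3.0, 2.5], [1.0, 0.5, -1.0]) == 1.0

    def test_positives_ranked_last(self):
        n_neg = 98
        ap = average_precision([0.0, 0.0], np.linspace(1, 2, n_neg))
        assert ap == pytest.approx(2 / (n_neg + 2), rel=1e-9)

    def test_worked_six_item_list(self):
        # descending: P(1.0) N(0.9) P(0.8) N(0.7) N(0.6) P(0.5)
        # recall steps at ranks 1, 3, 6 with precisions 1/1, 2/3, 3/6
        pos, neg = [1.0, 0.8, 0.5], [0.9, 0.7, 0.6]
        expected = (1 / 3) * 1.0 + (1 / 3) * (2 / 3) + (1 / 3) * 0.5
        assert average_precision(pos, neg) == pytest.approx(expected)

    def test_matches_sklearn_on_finite_scores(self, rng):
        for _ in range(20):
            pos = rng.normal(1, 1, size=rng.integers(1, 10))
            neg = rng.normal(0, 1, size=rng.integers(1, 30))
            y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
            s = np.concatenate([pos, neg])
            assert average_precision(pos, neg) == pytest.approx(
                average_precision_score(y, s), rel=1e-9
            )

    def test_handles_minus_inf_scores(self):
        ap = average_precision([1.0, NEG_INF], [0.0, NEG_INF])
        assert 0.0 < ap <= 1.0

    @given(a=st.floats(0.01, 10), b=st.floats(-5, 5))
    def test_invariant_under_monotone_transforms(self, a, b):
        pos, neg = [2.0, 0.5, -1.0], [1.5, 0.0, -0.5, -2.0]
        base = average_precision(pos, neg)
        assert average_precision(
            [a * p + b for p in pos], [a * q + b for q in neg]
        ) == pytest.approx(base, rel=1e-9)

    def test_scored_set_identifiers_must_be_disjoint(self):
        with pytest.raises(ValueError):
            ScoredSet([("x", 1.0)], [("x", 0.0)])

    def test_curve_endpoints(self):
        curve, ap = recall_precision_ap(
            ScoredSet([("p1", 2.0), ("p2", 1.0)], [("n1", 1.5)])
        )
        assert curve[-1][0] == 1.0  # final recall
        assert 0 < ap <= 1


def lex(sym):
    return ParseTree("h", (ParseTree(sym),))


def contact_node(label, left_sym, inner, right_sym):
    return ParseTree(label, (lex(left_sym), inner, lex(right_sym)))


class TestDescriptiveMetrics:
    def hairpin_tree(self):
        """8 leaves; contact rules generate (1,8) and (2,7)."""
        loop = ParseTree(
            "u",
            (
                ParseTree("b", (lex("G"), lex("N"))),
                ParseTree("b", (lex("S"), lex("G"))),
            ),
        )
        return contact_node("s", "V", contact_node("t", "L", loop, "I"), "F")

    def test_exact_match_gives_unit_precision_and_recall(self):
        tree = self.hairpin_tree()
        m = cmap(8, {(1, 8), (2, 7)})
        rep = descriptive_metrics(tree, m, m, delta=4, min_separation=3)
        assert rep.recall_at_delta == 1.0
        assert rep.precision_at_delta == 1.0
        assert rep.ap_over_deltas == 1.0

    def test_cnf_tree_has_zero_recall_at_delta_four(self):
        # without contact rules no separated pair can be within 4 edges
        node = lex("A")
        for k in range(5):
            node = ParseTree("s", (node, lex("A")))
        m = cmap(6, {(1, 5)})
        rep = descriptive_metrics(node, m, m, delta=4, min_separation=3)
        assert rep.recall_at_delta == 0.0
        assert rep.precision_at_delta is None  # no pair predicted at the cutoff

    def test_hand_counted_eight_leaf_example(self):
        tree = self.hairpin_tree()
        training = cmap(8, {(1, 8)})
        full = cmap(8, {(1, 8), (2, 7), (3, 6)})
        rep = descriptive_metrics(tree, training, full, delta=4, min_separation=3)
        assert rep.recall_at_delta == 1.0  # the single training pair is at d=4
        # predicted pairs at d<=4 with separation>=3: (1,8) and (2,7); both true
        assert rep.precision_at_delta == 1.0
        # ranking by distance: d=4 ->{(1,8),(2,7)}: R=2/3,P=1; (3,6) found later
        assert 0.5 < rep.ap_over_deltas < 1.0
        assert rep.local_recall[1] == 1.0
        assert rep.local_ap[2] == 1.0

    def test_empty_reference_reported_as_undefined(self):
        tree = self.hairpin_tree()
        rep = descriptive_metrics(tree, None, ContactMap(8), delta=4)
        assert rep.recall_at_delta is None
        assert rep.ap_over_deltas is None

    def test_recall_nondecreasing_in_delta(self):
        tree = self.hairpin_tree()
        m = cmap(8, {(1, 8), (3, 6)})
        recalls = [
            descriptive_metrics(tree, m, m, delta=d).recall_at_delta for d in (2, 4, 6, 8)
        ]
        assert recalls == sorted(recalls)


class TestScan:
    def test_sequence_shorter_than_window_yields_nothing(self):
        g = toy_hairpin_grammar()
        best, hits = scan("ACD", g, window_min=8, window_max=10, threshold=0.0)
        assert best == [] and hits == []

    def test_single_window_reduces_to_score_sequence(self):
        g = toy_hairpin_grammar()
        x = "LVSSNGYM"
        best, _ = scan(x, g, window_min=8, window_max=8, threshold=math.inf)
        assert len(best) == 1
        assert best[0]["score"] == pytest.approx(score_sequence(x, g))

    def test_infinite_threshold_yields_no_hits(self):
        g = toy_hairpin_grammar()
        _, hits = scan("LVSSNGYMLVSSNGYM", g, window_min=8, window_max=8, threshold=math.inf)
        assert hits == []

    def test_planted_motif_is_located(self, rng):
        g = toy_hairpin_grammar()
        null = NullModel.default()
        syms = list("ACDEFGHIKLMNQPRSTVWY")
        freqs = np.array([null.frequencies[s] for s in syms])
        background = "".join(rng.choice(syms, size=30, p=freqs))
        motif = "LVGGNGVM"  # high-probability hairpin realization
        seq = background[:15] + motif + background[15:]
        best, hits = scan(seq, g, null, window_min=8, window_max=8, threshold=1.0)
        assert hits
        top = max(best, key=lambda r: r["score"])
        assert top["start"] == 16


class TestCvSplit:
    def test_8_items_give_singleton_parts_and_56_combos(self):
        splits = cv_split(8, folds=8, seed=0)
        assert len(splits) == 56
        for train, val, test in splits:
            assert len(train) == 6 and len(val) == 1 and len(test) == 1
            assert set(train) | set(val) | set(test) == set(range(8))
        assert len({(v, t) for _, v, t in splits}) == 56

    def test_partition_is_exact_and_reproducible(self):
        s1 = cv_split(20, seed=4)
        s2 = cv_split(20, seed=4)
        assert s1 == s2
        for train, val, test in s1:
            assert sorted(train + val + test) == list(range(20))

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            cv_split(5, folds=8)
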
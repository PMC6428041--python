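"""Independent brute-force oracles used to validate the chart parser.

These enumerate complete parse trees recursively, entirely bypassing
the CKY implementation: probabilities are plain products over the
derivation, constrained sums filter trees by the tree-geometric
consistency predicate.  Feasible only for tiny grammars and n <= 6.
"""

from __future__ import annotations

import itertools

from protgram.contacts import ContactMap, is_consistent
from protgram.grammar import CfcGrammar
from protgram.parser import ParseTree, skeleton


def enumerate_parses(g: CfcGrammar, x: str):
    """All complete parse trees of ``x`` with their probabilities."""
    lex = set(g.nts.lexical)
    by_lhs: dict[str, list] = {}
    for r in g.rules:
        by_lhs.setdefault(r.lhs, []).append(r)
    memo: dict[tuple[str, int, int], list] = {}

    def parses(sym: str, i: int, j: int):
        if j <= i:
            return []
        key = (sym, i, j)
        if key in memo:
            return memo[key]
        out = []
        if sym in lex:
            if j - i == 1:
                for r in by_lhs.get(sym, []):
                    if r.rhs[0] == x[i]:
                        out.append((ParseTree(sym, (ParseTree(x[i]),)), g.theta[r]))
        else:
            for r in by_lhs.get(sym, []):
                if r.kind == "branching":
                    a, b = r.rhs
                    for k in range(i + 1, j):
                        for ta, pa in parses(a, i, k):
                            for tb, pb in parses(b, k, j):
                                out.append((ParseTree(sym, (ta, tb)), g.theta[r] * pa * pb))
                elif r.kind == "contact" and j - i >= 4:
                    f1, w, f2 = r.rhs
                    for t1, p1 in parses(f1, i, i + 1):
                        for tw, pw in parses(w, i + 1, j - 1):
                            for t2, p2 in parses(f2, j - 1, j):
                                out.append(
                                    (ParseTree(sym, (t1, tw, t2)), g.theta[r] * p1 * pw * p2)
                                )
        memo[key] = out
        return out

    return parses(g.nts.start, 0, len(x))


def oracle_inside(g: CfcGrammar, x: str) -> float:
    return sum(p for _, p in enumerate_parses(g, x))


def oracle_inside_constrained(g: CfcGrammar, x: str, cmap: ContactMap, delta: int = 4) -> float:
    return sum(
        p for t, p in enumerate_parses(g, x) if is_consistent(skeleton(t), cmap, delta)
    )


def oracle_viterbi(g: CfcGrammar, x: str, cmap: ContactMap | None = None, delta: int = 4):
    """Max-probability value over (optionally filtered) enumerated trees."""
    best = 0.0
    for t, p in enumerate_parses(g, x):
        if cmap is not None and not is_consistent(skeleton(t), cmap, delta):
            continue
        if p > best:
            best = p
    return best


def oracle_skeleton_mass(g: CfcGrammar, n: int, cmap: ContactMap | None, delta: int = 4) -> float:
    """Sum over incomplete-tree shapes via enumeration with lexical probs forced to 1.

    Each incomplete tree (leaves = lexical non-terminals) extends to exactly
    one complete tree of any fixed sequence, so enumerating complete trees
    of one dummy sequence under unit lexical probabilities sums the
    structural-rule products exactly once per shape.
    """
    theta1 = {r: (1.0 if r.kind == "lexical" else g.theta[r]) for r in g.rules}
    g1 = g.with_theta(theta1)
    x = g.alphabet.symbols[0] * n
    total = 0.0
    for t, p in enumerate_parses(g1, x):
        if cmap is not None and not is_consistent(skeleton(t), cmap, delta):
            continue
        total += p
    return total
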
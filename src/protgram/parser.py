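"""Probabilistic CKY computations for CFC grammars.

Four quantities are computed by a bottom-up chart parser:

* :func:`inside` -- ``prob(Y_x | G)``, the total probability of all
  parse trees yielding sequence ``x``;
* :func:`inside_constrained` -- ``prob(Y_x^m | G)``, restricted to parse
  trees whose skeleton is consistent with contact map ``m``;
* :func:`skeleton_mass` -- ``prob(U_n^m | G)``, the total probability of
  map-consistent tree shapes over *all* sequences of length ``n``,
  obtained by running the constrained parser with every lexical-rule
  probability set to 1 (the per-position lexical sums telescope to 1 for
  a proper grammar);
* :func:`viterbi` -- an argmax-probability parse tree, optionally
  constrained.

Contact constraints enter through an auxiliary table: span-1 lexical
probabilities of positions involved in contacts are moved out of the
chart into per-contact slices that only a contact rule spanning exactly
that pair can consume, with both flanks drawn from the same slice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .contacts import ContactMap, Ust, is_cf_compatible
from .grammar import CfcGrammar, GrammarError

__all__ = [
    "ParseTree",
    "GrammarKernel",
    "MapCompatibilityError",
    "inside",
    "log_inside",
    "inside_constrained",
    "log_inside_constrained",
    "skeleton_mass",
    "log_skeleton_mass",
    "viterbi",
    "skeleton",
    "tree_log_prob",
    "to_bracket",
    "from_bracket",
]

NEG_INF = float("-inf")


class MapCompatibilityError(ValueError):
    """The contact map is not CF-compatible or does not match the sequence."""


@dataclass(frozen=True)
class ParseTree:
    """Rooted ordered tree; leaves are terminal symbols (no children)."""

    label: str
    children: tuple["ParseTree", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["ParseTree"]:
        if self.is_leaf:
            return [self]
        out: list[ParseTree] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def yield_string(self) -> str:
        return "".join(l.label for l in self.leaves())


def skeleton(tree: ParseTree) -> Ust:
    """Strip non-leaf labels: the unlabeled syntactic tree of a parse tree."""
    if tree.is_leaf:
        return Ust(leaf=tree.label)
    return Ust(children=tuple(skeleton(c) for c in tree.children))


def tree_log_prob(tree: ParseTree, g: CfcGrammar) -> float:
    """Natural-log probability of the derivation encoded by ``tree``."""
    from .grammar import Rule

    total = 0.0
    stack = [tree]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            continue
        if len(node.children) == 1 and node.children[0].is_leaf:
            r = Rule("lexical", node.label, (node.children[0].label,))
        elif len(node.children) == 2:
            r = Rule("branching", node.label, tuple(c.label for c in node.children))
        else:
            r = Rule("contact", node.label, tuple(c.label for c in node.children))
        p = g.theta.get(r)
        if p is None:
            raise GrammarError(f"tree uses rule {r} absent from the grammar")
        if p == 0.0:
            return NEG_INF
        total += math.log(p)
        stack.extend(node.children)
    return total


# ---------------------------------------------------------------------------
# bracketed serialization, e.g. ``(s (h V) (t (l N) (l G)) (h I))``


def to_bracket(tree: ParseTree) -> str:
    if tree.is_leaf:
        return tree.label
    return "(" + " ".join([tree.label] + [to_bracket(c) for c in tree.children]) + ")"


def from_bracket(text: str) -> ParseTree:
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()
    pos = 0

    def parse() -> ParseTree:
        nonlocal pos
        if tokens[pos] == "(":
            pos += 1
            label = tokens[pos]
            pos += 1
            children = []
            while tokens[pos] != ")":
                children.append(parse())
            pos += 1
            return ParseTree(label, tuple(children))
        leaf = ParseTree(tokens[pos])
        pos += 1
        return leaf

    tree = parse()
    if pos != len(tokens):
        raise ValueError("trailing tokens in bracketed tree")
    return tree


# ---------------------------------------------------------------------------
# packed kernel


class GrammarKernel:
    """Packed array representation of a grammar for the CKY kernels.

    Built once per rule set; :meth:`set_theta_vector` swaps probabilities
    in place, which the genetic-algorithm trainer uses to avoid
    rebuilding grammar objects for every individual.
    """

    def __init__(self, g: CfcGrammar):
        self.grammar = g
        self.sym_index = {s: i for i, s in enumerate(g.alphabet.symbols)}
        self.lex_names = g.nts.lexical
        self.struct_names = g.nts.structural
        self.T = len(self.lex_names)
        self.N = len(self.struct_names)
        lex_idx = {v: i for i, v in enumerate(self.lex_names)}
        struct_idx = {v: i for i, v in enumerate(self.struct_names)}
        self.start = struct_idx[g.nts.start]

        def code(sym: str) -> int:
            return lex_idx[sym] if sym in lex_idx else self.T + struct_idx[sym]

        lex_pos, lex_t, lex_s = [], [], []
        b_pos, b_lhs, b_a, b_b = [], [], [], []
        c_pos, c_lhs, c_f1, c_in, c_f2 = [], [], [], [], []
        for pos, r in enumerate(g.rules):
            if r.kind == "lexical":
                lex_pos.append(pos)
                lex_t.append(lex_idx[r.lhs])
                lex_s.append(self.sym_index[r.rhs[0]])
            elif r.kind == "branching":
                b_pos.append(pos)
                b_lhs.append(struct_idx[r.lhs])
                b_a.append(code(r.rhs[0]))
                b_b.append(code(r.rhs[1]))
            else:
                c_pos.append(pos)
                c_lhs.append(struct_idx[r.lhs])
                c_f1.append(lex_idx[r.rhs[0]])
                c_in.append(struct_idx[r.rhs[1]])
                c_f2.append(lex_idx[r.rhs[2]])
        self._lex_pos = np.array(lex_pos, dtype=np.int64)
        self._lex_t = np.array(lex_t, dtype=np.int64)
        self._lex_s = np.array(lex_s, dtype=np.int64)
        self._b_pos = np.array(b_pos, dtype=np.int64)
        self.b_lhs = np.array(b_lhs, dtype=np.int64)
        self.b_a = np.array(b_a, dtype=np.int64)
        self.b_b = np.array(b_b, dtype=np.int64)
        self._c_pos = np.array(c_pos, dtype=np.int64)
        self.c_lhs = np.array(c_lhs, dtype=np.int64)
        self.c_f1 = np.array(c_f1, dtype=np.int64)
        self.c_in = np.array(c_in, dtype=np.int64)
        self.c_f2 = np.array(c_f2, dtype=np.int64)
        self.L = np.zeros((self.T, len(g.alphabet)))
        self.b_p = np.zeros(len(b_pos))
        self.c_p = np.zeros(len(c_pos))
        self.set_theta_vector(g.theta_vector())

    def set_theta_vector(self, w: np.ndarray) -> None:
        self.L[self._lex_t, self._lex_s] = w[self._lex_pos]
        self.b_p[:] = w[self._b_pos]
        self.c_p[:] = w[self._c_pos]

    # -- inputs ------------------------------------------------------

    def encode(self, x: str) -> np.ndarray:
        if len(x) == 0:
            raise ValueError("empty sequence")
        try:
            return np.array([self.sym_index[s] for s in x], dtype=np.int64)
        except KeyError as err:
            raise ValueError(f"symbol {err.args[0]!r} is not in the grammar alphabet") from None

    def _pairs(self, cmap: ContactMap | None, n: int):
        if cmap is None:
            pairs: list[tuple[int, int]] = []
        else:
            if cmap.length != n:
                raise MapCompatibilityError(
                    f"map length {cmap.length} does not match sequence length {n}"
                )
            ok, viol = is_cf_compatible(cmap, min_separation=2)
            if not ok:
                raise MapCompatibilityError(f"contact map is not CF-compatible: {viol}")
            pairs = cmap.sorted_pairs()
        pl = np.array([i - 1 for i, _ in pairs], dtype=np.int64)
        pr = np.array([j - 1 for _, j in pairs], dtype=np.int64)
        return pl, pr

    def _prepare(self, P1: np.ndarray, pl: np.ndarray, pr: np.ndarray):
        """Scale rows by their max and move contact-position rows into C."""
        scale = P1.max(axis=1)
        if np.any(scale == 0.0):
            return None
        P1s = P1 / scale[:, None]
        C = np.zeros((len(pl), 2, self.T))
        P1m = P1s.copy()
        for p in range(len(pl)):
            C[p, 0] = P1s[pl[p]]
            C[p, 1] = P1s[pr[p]]
            P1m[pl[p]] = 0.0
            P1m[pr[p]] = 0.0
        return P1m, C, float(np.log(scale).sum())

    def _kernel_args(self):
        return (
            self.b_lhs,
            self.b_a,
            self.b_b,
            self.b_p,
            self.c_lhs,
            self.c_f1,
            self.c_in,
            self.c_f2,
            self.c_p,
        )

    # -- computations ------------------------------------------------

    def log_inside(self, x: str, cmap: ContactMap | None = None) -> float:
        xi = self.encode(x)
        n = len(xi)
        pl, pr = self._pairs(cmap, n)
        prep = self._prepare(self.L[:, xi].T, pl, pr)
        if prep is None:
            return NEG_INF
        P1m, C, logscale = prep
        P = _kernels.fill_inside(n, self.T, self.N, P1m, C, pl, pr, *self._kernel_args())
        val = P[n, 0, self.T + self.start] if n > 1 else 0.0
        return math.log(val) + logscale if val > 0.0 else NEG_INF

    def log_skeleton_mass(self, n: int, cmap: ContactMap | None = None) -> float:
        if n < 1:
            raise ValueError("length must be positive")
        pl, pr = self._pairs(cmap, n)
        P1 = np.ones((n, self.T))
        P1m, C, _ = self._prepare(P1, pl, pr)  # scale is 1
        P = _kernels.fill_inside(n, self.T, self.N, P1m, C, pl, pr, *self._kernel_args())
        val = P[n, 0, self.T + self.start] if n > 1 else 0.0
        return math.log(val) if val > 0.0 else NEG_INF

    def viterbi(self, x: str, cmap: ContactMap | None = None):
        xi = self.encode(x)
        n = len(xi)
        pl, pr = self._pairs(cmap, n)
        prep = self._prepare(self.L[:, xi].T, pl, pr)
        if prep is None:
            return None, NEG_INF
        P1m, C, logscale = prep
        best, bkind, brule, bsplit = _kernels.fill_viterbi(
            n, self.T, self.N, P1m, C, pl, pr, *self._kernel_args()
        )
        root = self.T + self.start
        if n < 2 or best[n, 0, root] == 0.0:
            return None, NEG_INF
        tree = self._reconstruct(x, best, bkind, brule, bsplit, n, 0, root)
        return tree, math.log(best[n, 0, root]) + logscale

    def _reconstruct(self, x, best, bkind, brule, bsplit, j, i, v) -> ParseTree:
        if v < self.T:
            return ParseTree(self.lex_names[v], (ParseTree(x[i]),))
        kind = bkind[j, i, v]
        r = brule[j, i, v]
        if kind == 0:
            k = bsplit[j, i, v]
            a, b = self.b_a[r], self.b_b[r]
            return ParseTree(
                self.struct_names[v - self.T],
                (
                    self._reconstruct(x, best, bkind, brule, bsplit, k, i, a),
                    self._reconstruct(x, best, bkind, brule, bsplit, j - k, i + k, b),
                ),
            )
        e = i + j - 1
        inner = self._reconstruct(
            x, best, bkind, brule, bsplit, j - 2, i + 1, self.T + self.c_in[r]
        )
        return ParseTree(
            self.struct_names[v - self.T],
            (
                ParseTree(self.lex_names[self.c_f1[r]], (ParseTree(x[i]),)),
                inner,
                ParseTree(self.lex_names[self.c_f2[r]], (ParseTree(x[e]),)),
            ),
        )


def _kernel(g: CfcGrammar) -> GrammarKernel:
    k = getattr(g, "_kernel_cache", None)
    if k is None:
        k = GrammarKernel(g)
        g._kernel_cache = k  # type: ignore[attr-defined]
    return k


# ---------------------------------------------------------------------------
# public operations


def log_inside(x: str, g: CfcGrammar) -> float:
    """Natural log of ``prob(Y_x | G)``; ``-inf`` encodes zero."""
    return _kernel(g).log_inside(x)


def inside(x: str, g: CfcGrammar) -> float:
    """``prob(Y_x | G)``: total probability of all parse trees of ``x``."""
    return math.exp(log_inside(x, g))


def log_inside_constrained(x: str, cmap: ContactMap, g: CfcGrammar) -> float:
    """Natural log of ``prob(Y_x^m | G)``; only map-consistent trees count."""
    return _kernel(g).log_inside(x, cmap)


def inside_constrained(x: str, cmap: ContactMap, g: CfcGrammar) -> float:
    """``prob(Y_x^m | G)``: probability mass of parse trees consistent with ``m``."""
    return math.exp(log_inside_constrained(x, cmap, g))


def log_skeleton_mass(n: int, cmap: ContactMap | None, g: CfcGrammar) -> float:
    """Natural log of ``prob(U_n^m | G)``, independent of lexical probabilities."""
    return _kernel(g).log_skeleton_mass(n, cmap)


def skeleton_mass(n: int, cmap: ContactMap | None, g: CfcGrammar) -> float:
    """``prob(U_n^m | G)``: mass of consistent tree shapes over all length-n sequences."""
    return math.exp(log_skeleton_mass(n, cmap, g))


def viterbi(x: str, g: CfcGrammar, cmap: ContactMap | None = None):
    """Most likely parse tree (optionally map-constrained).

    Returns ``(tree, probability)``; an unparsable input yields
    ``(None, 0.0)`` rather than an exception.
    """
    tree, logp = _kernel(g).viterbi(x, cmap)
    return tree, (math.exp(logp) if logp > NEG_INF else 0.0)
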
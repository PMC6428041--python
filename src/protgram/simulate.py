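"""Generative sampling from CFC grammars and synthetic benchmarks.

Sampling inverts parsing: a derivation is drawn top-down by choosing,
at every non-terminal, one of its rules with probability ``theta``, so
a parse tree is produced with exactly its derivation probability
(conditioned on not exceeding the depth cap).  The contact map of a
sampled tree is the set of residue pairs generated by its contact
rules, which is CF-compatible by construction and consistent with the
tree at the natural threshold ``delta = 4``.

Benchmarks bundle rejection-sampled positives (sequence + contact map)
with background negatives of matching lengths, so that discrimination
experiments measure the structure a grammar has learned rather than
composition alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .contacts import ContactMap, ShortContactWarning
from .estimation import TrainingSample
from .evaluation import NullModel
from .grammar import (
    Alphabet,
    CfcGrammar,
    NonTerminalInventory,
    Rule,
    normalize_theta,
    read_grammar,
    write_grammar,
)
from .parser import ParseTree

__all__ = [
    "DepthOverflowError",
    "SyntheticBenchmark",
    "sample_derivation",
    "map_from_tree",
    "make_benchmark",
    "write_benchmark",
    "load_benchmark",
    "toy_hairpin_grammar",
    "stem_grammar",
]


class DepthOverflowError(RuntimeError):
    """Derivation exceeded the depth cap (the grammar may be divergent)."""


def sample_derivation(g: CfcGrammar, rng, max_depth: int = 50):
    """Draw one ``(sequence, ParseTree)`` from the grammar's distribution.

    ``rng`` is a seed or a :class:`numpy.random.Generator`.  Trees deeper
    than ``max_depth`` raise :class:`DepthOverflowError` so a divergent
    grammar is reported rather than looping forever.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    groups: dict[str, list[Rule]] = {}
    for r in g.rules:
        groups.setdefault(r.lhs, []).append(r)
    probs = {
        lhs: np.array([g.theta[r] for r in rules]) / sum(g.theta[r] for r in rules)
        for lhs, rules in groups.items()
    }

    def expand(sym: str, depth: int) -> ParseTree:
        if depth > max_depth:
            raise DepthOverflowError(f"derivation exceeded max_depth={max_depth}")
        if sym in g.alphabet:
            return ParseTree(sym)
        rules = groups.get(sym)
        if not rules:
            raise ValueError(f"non-terminal {sym!r} has no rules")
        r = rules[rng.choice(len(rules), p=probs[sym])]
        return ParseTree(sym, tuple(expand(s, depth + 1) for s in r.rhs))

    tree = expand(g.nts.start, 0)
    return tree.yield_string(), tree


def map_from_tree(tree: ParseTree) -> ContactMap:
    """Contact map of all residue pairs generated by contact rules of ``tree``.

    A contact node is recognized structurally: three children with
    lexical flanks (unary nodes over a leaf) around an internal middle.
    """
    pairs: list[tuple[int, int]] = []
    pos = 0

    def is_lex(node: ParseTree) -> bool:
        return len(node.children) == 1 and node.children[0].is_leaf

    def walk(node: ParseTree) -> None:
        nonlocal pos
        if node.is_leaf:
            pos += 1
            return
        if len(node.children) == 3 and is_lex(node.children[0]) and is_lex(node.children[2]):
            left = pos + 1
            walk(node.children[0])
            walk(node.children[1])
            walk(node.children[2])
            pairs.append((left, pos))
            return
        for c in node.children:
            walk(c)

    walk(tree)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ShortContactWarning)
        return ContactMap(pos, frozenset(pairs))


@dataclass
class SyntheticBenchmark:
    generator_grammar: CfcGrammar
    positives: TrainingSample
    negatives: list[str]
    metadata: dict = field(default_factory=dict)


def make_benchmark(
    g: CfcGrammar,
    n_pos: int,
    n_neg: int,
    target_length: int | None = None,
    seed: int = 0,
    background: NullModel | None = None,
    max_depth: int = 50,
    max_attempts_per_item: int = 10_000,
) -> SyntheticBenchmark:
    """Sample a benchmark: positives from the grammar, negatives from a unigram.

    Positives are rejection-sampled derivations, optionally filtered to
    an exact ``target_length``; each carries the contact map read off
    its own tree.  Negatives are i.i.d. draws from ``background``
    (default: the Swiss-Prot table restricted to the grammar alphabet)
    with lengths cycled from the positives, or ``target_length`` when no
    positives were requested.
    """
    rng = np.random.default_rng(seed)
    items: list[tuple[str, ContactMap]] = []
    for _ in range(n_pos):
        for attempt in range(max_attempts_per_item):
            try:
                x, tree = sample_derivation(g, rng, max_depth=max_depth)
            except DepthOverflowError:
                continue
            if target_length is None or len(x) == target_length:
                items.append((x, map_from_tree(tree)))
                break
        else:
            raise RuntimeError(
                f"rejection sampling failed: no accepted derivation in "
                f"{max_attempts_per_item} attempts; relax target_length={target_length} "
                f"or check that the grammar reaches that length"
            )
    background = (background or NullModel.default()).restricted(g.alphabet)
    syms = [s for s in g.alphabet]
    freqs = np.array([background.frequencies[s] for s in syms])
    if n_pos:
        lengths = [len(x) for x, _ in items]
    elif target_length is not None:
        lengths = [target_length]
    else:
        raise ValueError("need positives or a target_length to size the negatives")
    negatives = [
        "".join(rng.choice(syms, size=lengths[k % len(lengths)], p=freqs))
        for k in range(n_neg)
    ]
    meta = {
        "seed": seed,
        "n_pos": n_pos,
        "n_neg": n_neg,
        "target_length": target_length,
        "max_depth": max_depth,
    }
    return SyntheticBenchmark(g, TrainingSample(items), negatives, meta)


# ---------------------------------------------------------------------------
# on-disk layout: positives.fasta, maps/pos_###.txt, negatives.fasta,
# generator.grammar, meta.json


def write_benchmark(b: SyntheticBenchmark, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "maps").mkdir(exist_ok=True)
    pos_records = []
    for k, (x, m) in enumerate(b.positives.items, start=1):
        name = f"pos_{k:03d}"
        pos_records.append(SeqRecord(Seq(x), id=name, description=""))
        from .contacts import write_contact_map

        write_contact_map(m, d / "maps" / f"{name}.txt")
    SeqIO.write(pos_records, d / "positives.fasta", "fasta")
    neg_records = [
        SeqRecord(Seq(x), id=f"neg_{k:03d}", description="")
        for k, x in enumerate(b.negatives, start=1)
    ]
    SeqIO.write(neg_records, d / "negatives.fasta", "fasta")
    write_grammar(b.generator_grammar, d / "generator.grammar")
    (d / "meta.json").write_text(json.dumps(b.metadata, indent=2) + "\n")


def load_benchmark(directory) -> SyntheticBenchmark:
    from .contacts import read_contact_map

    d = Path(directory)
    items = []
    for rec in SeqIO.parse(str(d / "positives.fasta"), "fasta"):
        m = read_contact_map(d / "maps" / f"{rec.id}.txt")
        items.append((str(rec.seq), m))
    negatives = [str(rec.seq) for rec in SeqIO.parse(str(d / "negatives.fasta"), "fasta")]
    g = read_grammar(d / "generator.grammar")
    meta = json.loads((d / "meta.json").read_text())
    return SyntheticBenchmark(g, TrainingSample(items), negatives, meta)


# ---------------------------------------------------------------------------
# fixture grammars

# lexical emission profiles (weights; normalized on use)
_HYDROPHOBIC = {"A": 2, "C": 1, "F": 3, "I": 4, "L": 4, "M": 2, "V": 4, "W": 2, "Y": 2}
_LOOP = {"G": 4, "N": 3, "D": 3, "S": 3, "P": 3, "T": 2}


def _lexical_rules(vt: str, profile: dict[str, float] | None, alphabet: Alphabet):
    """Lexical rules for ``vt``; profile weights plus a small floor for coverage."""
    rules = {}
    for a in alphabet:
        w = 1.0 if profile is None else profile.get(a, 0.0) + 0.05
        rules[Rule("lexical", vt, (a,))] = w
    return rules


def toy_hairpin_grammar() -> CfcGrammar:
    """A small beta-hairpin-like grammar used in examples and tests.

    Lexical non-terminals: ``h`` (hydrophobic), ``l`` (loop-friendly),
    ``x`` (any).  Structural: ``s`` (start) and ``t`` generate the
    nested stem via contact rules (``s -> h t h``, ``t -> h u h``),
    ``u`` and ``b`` spell out a four-residue loop region with optional
    unspecific positions.  Every derivation yields 8 residues with the
    two stem pairs (1, 8) and (2, 7) in contact.
    """
    alphabet = Alphabet()
    nts = NonTerminalInventory(
        lexical=("h", "l", "x"),
        structural=("s", "t", "u", "b"),
        start="s",
        branch_capable=("u", "b"),
        contact_capable=("s", "t"),
    )
    weights: dict[Rule, float] = {}
    weights.update(_lexical_rules("h", _HYDROPHOBIC, alphabet))
    weights.update(_lexical_rules("l", _LOOP, alphabet))
    weights.update(_lexical_rules("x", None, alphabet))
    weights[Rule("contact", "s", ("h", "t", "h"))] = 1.0
    weights[Rule("contact", "t", ("h", "u", "h"))] = 1.0
    weights[Rule("branching", "u", ("b", "b"))] = 1.0
    weights[Rule("branching", "b", ("l", "l"))] = 0.8
    weights[Rule("branching", "b", ("l", "x"))] = 0.1
    weights[Rule("branching", "b", ("x", "l"))] = 0.1
    theta = normalize_theta(weights)
    return CfcGrammar(alphabet, nts, tuple(weights), theta)


def stem_grammar(p_extend: float = 0.55) -> CfcGrammar:
    """A stem-loop generator with a geometric number of nested contacts.

    ``s -> h t h`` starts the stem, ``t`` either extends it
    (``t -> h t h`` with probability ``p_extend``) or closes into a
    four-residue loop (``t -> w w``, ``w -> l l``).  Sequence lengths
    are ``2k + 4`` for ``k >= 1`` stem pairs, all nested; the default
    extension probability puts usable mass on motif-sized lengths
    (length 16 = six stem pairs).
    """
    if not 0.0 < p_extend < 1.0:
        raise ValueError("p_extend must be in (0, 1)")
    alphabet = Alphabet()
    nts = NonTerminalInventory(
        lexical=("h", "l"),
        structural=("s", "t", "w"),
        start="s",
        branch_capable=("t", "w"),
        contact_capable=("s", "t"),
    )
    weights: dict[Rule, float] = {}
    weights.update(_lexical_rules("h", _HYDROPHOBIC, alphabet))
    weights.update(_lexical_rules("l", _LOOP, alphabet))
    weights[Rule("contact", "s", ("h", "t", "h"))] = 1.0
    weights[Rule("contact", "t", ("h", "t", "h"))] = p_extend
    weights[Rule("branching", "t", ("w", "w"))] = 1.0 - p_extend
    weights[Rule("branching", "w", ("l", "l"))] = 1.0
    theta = normalize_theta(weights)
    return CfcGrammar(alphabet, nts, tuple(weights), theta)
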
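"""Grammar structures for contact-aware protein grammars.

The central object is :class:`CfcGrammar`, a probabilistic context-free
grammar in *Chomsky Form with Contacts* (CFC).  A CFC grammar partitions
its non-terminals into *lexical* non-terminals ``V_T`` (rewritten only
into single terminal symbols, playing the role of amino-acid emission
profiles) and *structural* non-terminals ``V_N``, and its rules into

* lexical rules      ``R_a = { v_t -> a }``         with ``v_t in V_T, a in Sigma``,
* branching rules    ``R_b = { v -> alpha beta }``  with ``v in V_N, alpha, beta in V_T u V_N``,
* contact rules      ``R_c = { v -> v_t w v_u }``   with ``v, w in V_N, v_t, v_u in V_T``.

A contact rule generates a pair of residues that are in spatial contact:
its two flanking lexical non-terminals sit at the two paired sequence
positions, with the inner structural non-terminal deriving everything in
between.  When ``R_c`` is empty the grammar is in plain Chomsky Normal
Form (CNF).

Probabilities ``theta`` attach one number to every rule; a grammar is
*proper* when, for every non-terminal, the probabilities of the rules
rewriting it sum to one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "Alphabet",
    "NonTerminalInventory",
    "Rule",
    "CfcGrammar",
    "GrammarError",
    "PropernessReport",
    "build_covering_grammar",
    "validate_properness",
    "normalize_theta",
    "randomize_theta",
    "read_grammar",
    "write_grammar",
]

#: The 20 standard amino-acid one-letter codes (default terminal alphabet).
AMINO_ACIDS = "ACDEFGHIKLMNQPRSTVWY"


class GrammarError(ValueError):
    """Raised for structurally invalid grammars or grammar files."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered set of single-character terminal symbols."""

    symbols: tuple[str, ...] = tuple(AMINO_ACIDS)

    def __post_init__(self) -> None:
        if not self.symbols:
            raise GrammarError("alphabet must be non-empty")
        if any(len(s) != 1 for s in self.symbols):
            raise GrammarError("alphabet symbols must be single characters")
        if len(set(self.symbols)) != len(self.symbols):
            raise GrammarError("alphabet symbols must be unique")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __contains__(self, s: str) -> bool:
        return s in self.symbols

    def index(self, s: str) -> int:
        return self.symbols.index(s)


@dataclass(frozen=True)
class NonTerminalInventory:
    """Names of lexical and structural non-terminals and their capabilities.

    ``branch_capable`` and ``contact_capable`` are the structural
    non-terminals allowed on the left-hand side of branching and contact
    rules respectively.  Their union must cover all structural
    non-terminals (a structural symbol with no rewriting rules could
    never terminate a derivation).
    """

    lexical: tuple[str, ...]
    structural: tuple[str, ...]
    start: str
    branch_capable: tuple[str, ...]
    contact_capable: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.lexical:
            raise GrammarError("at least one lexical non-terminal is required")
        names = self.lexical + self.structural
        if len(set(names)) != len(names):
            raise GrammarError("lexical and structural non-terminal names must be disjoint and unique")
        if self.start not in self.structural:
            raise GrammarError(f"start symbol {self.start!r} must be a structural non-terminal")
        for v in self.branch_capable:
            if v not in self.structural:
                raise GrammarError(f"branch-capable symbol {v!r} is not structural")
        for v in self.contact_capable:
            if v not in self.structural:
                raise GrammarError(f"contact-capable symbol {v!r} is not structural")
        covered = set(self.branch_capable) | set(self.contact_capable)
        if covered != set(self.structural):
            missing = set(self.structural) - covered
            raise GrammarError(
                f"structural non-terminals {sorted(missing)} are neither branch- nor contact-capable"
            )

    @classmethod
    def make(
        cls,
        n_lexical: int = 3,
        n_structural: int = 4,
        *,
        contact: bool = True,
        branch: bool = True,
    ) -> "NonTerminalInventory":
        """Auto-named inventory ``lex1.. / nt1..`` with uniform capabilities."""
        lexical = tuple(f"lex{i + 1}" for i in range(n_lexical))
        structural = tuple(f"nt{i + 1}" for i in range(n_structural))
        return cls(
            lexical=lexical,
            structural=structural,
            start=structural[0],
            branch_capable=structural if branch else (),
            contact_capable=structural if contact else (),
        )

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.lexical + self.structural


@dataclass(frozen=True)
class Rule:
    """One rewriting rule; ``kind`` is 'lexical', 'branching' or 'contact'."""

    kind: str
    lhs: str
    rhs: tuple[str, ...]

    def __post_init__(self) -> None:
        arity = {"lexical": 1, "branching": 2, "contact": 3}
        if self.kind not in arity:
            raise GrammarError(f"unknown rule kind {self.kind!r}")
        if len(self.rhs) != arity[self.kind]:
            raise GrammarError(f"{self.kind} rule {self.lhs} -> {' '.join(self.rhs)} has wrong arity")

    def __str__(self) -> str:
        return f"{self.lhs} -> {' '.join(self.rhs)}"


@dataclass
class CfcGrammar:
    """A probabilistic grammar in Chomsky Form with Contacts.

    ``theta`` maps each rule to its probability.  The constructor checks
    structural well-formedness (symbols exist, rule patterns are legal);
    properness is checked separately by :func:`validate_properness`.
    """

    alphabet: Alphabet
    nts: NonTerminalInventory
    rules: tuple[Rule, ...]
    theta: dict[Rule, float]

    def __post_init__(self) -> None:
        self.rules = tuple(self.rules)
        lex = set(self.nts.lexical)
        struct = set(self.nts.structural)
        if lex & set(self.alphabet.symbols) or struct & set(self.alphabet.symbols):
            raise GrammarError("non-terminal names must be disjoint from the alphabet")
        for r in self.rules:
            if r.kind == "lexical":
                if r.lhs not in lex:
                    raise GrammarError(f"lexical rule lhs {r.lhs!r} is not a lexical non-terminal")
                if r.rhs[0] not in self.alphabet:
                    raise GrammarError(f"unknown terminal {r.rhs[0]!r} in rule {r}")
            elif r.kind == "branching":
                if r.lhs not in self.nts.branch_capable:
                    raise GrammarError(f"{r.lhs!r} is not branch-capable (rule {r})")
                for s in r.rhs:
                    if s not in lex and s not in struct:
                        raise GrammarError(f"unknown symbol {s!r} in rule {r}")
            else:  # contact
                if r.lhs not in self.nts.contact_capable:
                    raise GrammarError(f"{r.lhs!r} is not contact-capable (rule {r})")
                f1, inner, f2 = r.rhs
                if f1 not in lex or f2 not in lex or inner not in struct:
                    raise GrammarError(
                        f"contact rule {r} must match the pattern V_T V_N V_T"
                    )
            if r not in self.theta:
                raise GrammarError(f"rule {r} has no probability")
        if len(set(self.rules)) != len(self.rules):
            raise GrammarError("duplicate rules")

    # -- convenience -------------------------------------------------

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @property
    def is_cnf(self) -> bool:
        """CNF is the special case of CFC with no contact rules."""
        return not any(r.kind == "contact" for r in self.rules)

    def rules_of_kind(self, kind: str) -> tuple[Rule, ...]:
        return tuple(r for r in self.rules if r.kind == kind)

    def lhs_groups(self) -> dict[str, list[Rule]]:
        groups: dict[str, list[Rule]] = {}
        for r in self.rules:
            groups.setdefault(r.lhs, []).append(r)
        return groups

    def theta_vector(self) -> np.ndarray:
        """Rule probabilities in rule-list order."""
        return np.array([self.theta[r] for r in self.rules], dtype=float)

    def with_theta(self, theta: dict[Rule, float] | np.ndarray) -> "CfcGrammar":
        """A new grammar sharing this rule set with different probabilities."""
        if isinstance(theta, np.ndarray):
            if theta.shape != (len(self.rules),):
                raise GrammarError("theta vector length does not match the rule set")
            theta = dict(zip(self.rules, (float(t) for t in theta)))
        return CfcGrammar(self.alphabet, self.nts, self.rules, dict(theta))


# ---------------------------------------------------------------------------
# construction


def build_covering_grammar(
    alphabet: Alphabet | None = None,
    nts: NonTerminalInventory | None = None,
) -> CfcGrammar:
    """Build the covering grammar of all allowed symbol combinations.

    The rule set contains every lexical rule ``V_T x Sigma``, every
    branching rule ``branch_capable x (V_N u V_T)^2`` and every contact
    rule ``contact_capable x V_T x V_N x V_T``; probabilities are
    initialized uniformly per left-hand side.  Rule counts therefore obey
    ``|R_a| = |V_T|*|Sigma|``, ``|R_b| = |branch|*(|V_N|+|V_T|)^2`` and
    ``|R_c| = |contact|*|V_T|^2*|V_N|``.
    """
    alphabet = alphabet or Alphabet()
    nts = nts or NonTerminalInventory.make()
    rules: list[Rule] = []
    for vt in nts.lexical:
        for a in alphabet:
            rules.append(Rule("lexical", vt, (a,)))
    symbols = nts.lexical + nts.structural
    for v in nts.structural:
        if v in nts.branch_capable:
            for a in symbols:
                for b in symbols:
                    rules.append(Rule("branching", v, (a, b)))
        if v in nts.contact_capable:
            for f1 in nts.lexical:
                for w in nts.structural:
                    for f2 in nts.lexical:
                        rules.append(Rule("contact", v, (f1, w, f2)))
    theta = normalize_theta({r: 1.0 for r in rules})
    return CfcGrammar(alphabet, nts, tuple(rules), theta)


def normalize_theta(weights: dict[Rule, float]) -> dict[Rule, float]:
    """Project non-negative rule weights onto per-lhs probability simplices.

    Raises :class:`GrammarError` if any weight is negative or if all
    weights of one left-hand side are zero.
    """
    sums: dict[str, float] = {}
    for r, w in weights.items():
        if w < 0:
            raise GrammarError(f"negative weight for rule {r}")
        sums[r.lhs] = sums.get(r.lhs, 0.0) + w
    for lhs, s in sums.items():
        if s == 0.0:
            raise GrammarError(f"all rule weights for non-terminal {lhs!r} are zero")
    return {r: w / sums[r.lhs] for r, w in weights.items()}


def randomize_theta(g: CfcGrammar, seed: int) -> CfcGrammar:
    """A copy of ``g`` with proper probabilities drawn at random (seeded)."""
    rng = np.random.default_rng(seed)
    weights = {r: float(w) for r, w in zip(g.rules, rng.exponential(1.0, size=g.n_rules))}
    return g.with_theta(normalize_theta(weights))


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class PropernessReport:
    sums: dict[str, float]
    violations: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_properness(g: CfcGrammar, tol: float = 1e-9) -> PropernessReport:
    """Report every non-terminal whose outgoing probabilities do not sum to 1."""
    sums: dict[str, float] = {}
    for r in g.rules:
        sums[r.lhs] = sums.get(r.lhs, 0.0) + g.theta[r]
    violations = tuple(lhs for lhs, s in sums.items() if abs(s - 1.0) > tol)
    return PropernessReport(sums=sums, violations=violations)


# ---------------------------------------------------------------------------
# file format
#
# One rule per line: ``LHS -> RHS1 [RHS2 [RHS3]] <tab> probability`` with
# ``#`` comments and header lines declaring the inventories, e.g.::
#
#     alphabet: ACDEFGHIKLMNQPRSTVWY
#     lexical: lex1 lex2 lex3
#     structural: nt1 nt2 nt3 nt4
#     start: nt1
#     branch: nt1 nt2 nt3 nt4
#     contact: nt1 nt2 nt3 nt4
#     lex1 -> A	0.05


def write_grammar(g: CfcGrammar, path) -> None:
    with open(path, "w") as fh:
        fh.write("alphabet: " + "".join(g.alphabet.symbols) + "\n")
        fh.write("lexical: " + " ".join(g.nts.lexical) + "\n")
        fh.write("structural: " + " ".join(g.nts.structural) + "\n")
        fh.write("start: " + g.nts.start + "\n")
        fh.write("branch: " + " ".join(g.nts.branch_capable) + "\n")
        fh.write("contact: " + " ".join(g.nts.contact_capable) + "\n")
        for r in g.rules:
            fh.write(f"{r.lhs} -> {' '.join(r.rhs)}\t{g.theta[r]:.12g}\n")


def read_grammar(path, on_improper: str = "error", tol: float = 1e-9) -> CfcGrammar:
    """Read a grammar file.

    Rules written without a probability column get uniform probabilities
    per left-hand side.  Non-proper probabilities are a hard error by
    default; pass ``on_improper='renormalize'`` to repair them instead.
    """
    if on_improper not in ("error", "renormalize"):
        raise ValueError("on_improper must be 'error' or 'renormalize'")
    headers: dict[str, str] = {}
    rule_lines: list[tuple[str, tuple[str, ...], float | None]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key = line.split(":", 1)[0].strip().lower()
            if ":" in line and key in ("alphabet", "lexical", "structural", "start", "branch", "contact"):
                headers[key] = line.split(":", 1)[1].strip()
                continue
            if "->" not in line:
                raise GrammarError(f"{path}:{lineno}: not a header nor a rule: {raw.strip()!r}")
            lhs_part, rhs_part = line.split("->", 1)
            lhs = lhs_part.strip()
            fields = rhs_part.split("\t")
            prob: float | None = None
            if len(fields) > 1 and fields[-1].strip():
                prob = float(fields[-1])
                rhs_text = "\t".join(fields[:-1])
            else:
                rhs_text = fields[0]
                toks = rhs_text.split()
                # allow whitespace-separated probability as a convenience
                if len(toks) > 1:
                    try:
                        prob = float(toks[-1])
                        toks = toks[:-1]
                        rhs_text = " ".join(toks)
                    except ValueError:
                        pass
            rhs = tuple(rhs_text.split())
            if not rhs:
                raise GrammarError(f"{path}:{lineno}: empty right-hand side")
            rule_lines.append((lhs, rhs, prob))
    for required in ("alphabet", "lexical", "structural", "start"):
        if required not in headers:
            raise GrammarError(f"{path}: missing {required}: header")
    alphabet = Alphabet(tuple(headers["alphabet"].replace(" ", "")))
    structural = tuple(headers["structural"].split())
    nts = NonTerminalInventory(
        lexical=tuple(headers["lexical"].split()),
        structural=structural,
        start=headers["start"],
        branch_capable=tuple(headers.get("branch", headers["structural"]).split()),
        contact_capable=tuple(headers.get("contact", "").split()),
    )
    lex = set(nts.lexical)
    struct = set(nts.structural)
    rules: list[Rule] = []
    probs: dict[Rule, float | None] = {}
    for lhs, rhs, prob in rule_lines:
        if lhs in lex:
            kind = "lexical"
        elif lhs in struct:
            if len(rhs) == 2:
                kind = "branching"
            elif len(rhs) == 3:
                kind = "contact"
            else:
                raise GrammarError(f"structural rule {lhs} -> {' '.join(rhs)} must have 2 or 3 rhs symbols")
        else:
            raise GrammarError(f"unknown left-hand side {lhs!r}")
        r = Rule(kind, lhs, rhs)
        rules.append(r)
        probs[r] = prob
    # fill in missing probabilities uniformly per lhs
    by_lhs: dict[str, list[Rule]] = {}
    for r in rules:
        by_lhs.setdefault(r.lhs, []).append(r)
    theta: dict[Rule, float] = {}
    for lhs, group in by_lhs.items():
        given = [probs[r] for r in group]
        if all(p is None for p in given):
            for r in group:
                theta[r] = 1.0 / len(group)
        elif any(p is None for p in given):
            raise GrammarError(f"non-terminal {lhs!r} mixes rules with and without probabilities")
        else:
            for r in group:
                theta[r] = float(probs[r])  # type: ignore[arg-type]
    g = CfcGrammar(alphabet, nts, tuple(rules), theta)
    report = validate_properness(g, tol=tol)
    if not report.ok:
        if on_improper == "error":
            raise GrammarError(
                f"{path}: probabilities do not sum to 1 for: {', '.join(report.violations)}"
            )
        g = g.with_theta(normalize_theta({r: g.theta[r] for r in g.rules}))
    return g
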
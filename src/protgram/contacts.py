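"""Contact maps, syntactic-tree skeletons, and their consistency.

A *contact map* marks residue pairs that are close in the protein's
spatial structure.  A map is *CF-compatible* when no two contacts cross
or overlap (nesting is allowed), so that a single context-free parse
tree can realize all of them.  A tree skeleton (unlabeled syntactic
tree, :class:`Ust`) is *consistent* with a map when every contact pair's
leaf-to-leaf path in the tree has at most ``delta`` edges; ``delta = 4``
is the natural threshold for CFC grammars, where the two residues of a
contact rule sit exactly four edges apart (leaf - lexical parent -
contact node - lexical parent - leaf).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ContactMap",
    "Ust",
    "ShortContactWarning",
    "is_cf_compatible",
    "contacts_from_coordinates",
    "extract_cf_compatible_subset",
    "leaf_distance_matrix",
    "is_consistent",
    "enumerate_cnf_skeletons",
    "read_contact_map",
    "write_contact_map",
]


class ShortContactWarning(UserWarning):
    """A contact at sequence separation 2 can never be realized by a CFC tree."""


@dataclass(frozen=True)
class ContactMap:
    """A partial, symmetric contact map stored as 1-based pairs with i < j."""

    length: int
    pairs: frozenset[tuple[int, int]] = frozenset()

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("contact map length must be positive")
        norm = set()
        for i, j in self.pairs:
            if i == j:
                raise ValueError(f"self-contact ({i},{j}) is not allowed")
            i, j = (i, j) if i < j else (j, i)
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair ({i},{j}) out of range for length {self.length}")
            norm.add((i, j))
        object.__setattr__(self, "pairs", frozenset(norm))
        short = [(i, j) for i, j in norm if j - i == 2]
        if short:
            warnings.warn(
                f"contacts at sequence separation 2 cannot be generated by any CFC "
                f"derivation (inner non-terminal yields >= 2 residues): {sorted(short)}",
                ShortContactWarning,
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.pairs)

    def sorted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pairs)

    def to_matrix(self) -> np.ndarray:
        m = np.zeros((self.length, self.length), dtype=bool)
        for i, j in self.pairs:
            m[i - 1, j - 1] = m[j - 1, i - 1] = True
        return m


def write_contact_map(cmap: ContactMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"length {cmap.length}\n")
        for i, j in cmap.sorted_pairs():
            fh.write(f"{i} {j}\n")


def read_contact_map(path) -> ContactMap:
    """Read a pair-list file: a ``length n`` header then 1-based ``i j`` lines."""
    length = None
    pairs = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            toks = line.split()
            if toks[0].lower() == "length":
                length = int(toks[1])
            else:
                if len(toks) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 'i j'")
                pairs.add((int(toks[0]), int(toks[1])))
    if length is None:
        raise ValueError(f"{path}: missing 'length n' header")
    return ContactMap(length, frozenset(pairs))


# ---------------------------------------------------------------------------
# compatibility


def _violates(p: tuple[int, int], q: tuple[int, int]) -> bool:
    """True if q crosses or overlaps p (exactly one endpoint of q inside [p])."""
    i, j = p
    k, l = q
    return (i <= k <= j) != (i <= l <= j)


def is_cf_compatible(cmap: ContactMap, min_separation: int = 2):
    """Check that no two contacts cross or overlap and all satisfy the separation.

    Returns ``(ok, violations)`` where violations is a list of offending
    pair-pairs (for crossings) and single pairs (for separation).
    """
    pairs = cmap.sorted_pairs()
    violations: list[tuple] = []
    for i, j in pairs:
        if j - i < min_separation:
            violations.append(((i, j),))
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            if _violates(pairs[a], pairs[b]) or _violates(pairs[b], pairs[a]):
                violations.append((pairs[a], pairs[b]))
    return (not violations), violations


def contacts_from_coordinates(
    coords: np.ndarray,
    tau: float = 8.0,
    min_sequence_separation: int = 3,
) -> ContactMap:
    """Derive a full contact map from per-residue coordinates.

    A pair ``(i, j)`` is in contact when the Euclidean distance between
    the representative coordinates is strictly below ``tau`` (default
    8 Angstrom) and ``j - i >= min_sequence_separation`` (default 3).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coordinates must be an (n, 3) array")
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least two residues")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    d = squareform(pdist(coords))
    pairs = set()
    for i in range(n):
        for j in range(i + 1, n):
            if j - i >= min_sequence_separation and d[i, j] < tau:
                pairs.add((i + 1, j + 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ShortContactWarning)
        return ContactMap(n, frozenset(pairs))


def extract_cf_compatible_subset(full: ContactMap, min_separation: int = 2) -> ContactMap:
    """Maximum-cardinality non-crossing, non-overlapping subset of a map.

    Interval dynamic programming in the style of the Nussinov maximum
    non-crossing pairing algorithm: ``best(i, j)`` is the largest number
    of mutually compatible contacts realizable inside positions
    ``i..j``; position ``i`` is either left unpaired or paired with some
    ``j'`` via an input contact, which isolates the inside and the
    outside of ``(i, j')``.
    """
    candidates = {p for p in full.pairs if p[1] - p[0] >= min_separation}
    partners: dict[int, list[int]] = {}
    for i, j in candidates:
        partners.setdefault(i, []).append(j)
    n = full.length
    best: dict[tuple[int, int], int] = {}

    def solve(i: int, j: int) -> int:
        if i >= j:
            return 0
        key = (i, j)
        if key in best:
            return best[key]
        score = solve(i + 1, j)
        for jp in partners.get(i, ()):
            if jp <= j:
                cand = 1 + solve(i + 1, jp - 1) + solve(jp + 1, j)
                if cand > score:
                    score = cand
        best[key] = score
        return score

    def traceback(i: int, j: int, out: set) -> None:
        while i < j:
            score = solve(i, j)
            if score == solve(i + 1, j):
                i += 1
                continue
            # deterministic choice: smallest partner achieving the optimum
            for jp in sorted(partners.get(i, ())):
                if jp <= j and 1 + solve(i + 1, jp - 1) + solve(jp + 1, j) == score:
                    out.add((i, jp))
                    traceback(i + 1, jp - 1, out)
                    i = jp + 1
                    break
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failed")

    chosen: set[tuple[int, int]] = set()
    traceback(1, n, chosen)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ShortContactWarning)
        return ContactMap(n, frozenset(chosen))


# ---------------------------------------------------------------------------
# unlabeled syntactic trees


@dataclass(frozen=True)
class Ust:
    """Unlabeled syntactic tree: internal nodes anonymous, leaves labeled.

    A leaf carries its terminal symbol in ``leaf``; internal nodes have
    one or more children and ``leaf is None``.
    """

    children: tuple["Ust", ...] = ()
    leaf: str | None = None

    def __post_init__(self) -> None:
        if self.leaf is None and not self.children:
            raise ValueError("internal Ust nodes must have at least one child")
        if self.leaf is not None and self.children:
            raise ValueError("leaf nodes cannot have children")

    @property
    def is_leaf(self) -> bool:
        return self.leaf is not None

    def leaves(self) -> list["Ust"]:
        if self.is_leaf:
            return [self]
        out: list[Ust] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def yield_string(self) -> str:
        return "".join(l.leaf for l in self.leaves())  # type: ignore[misc]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())


def leaf_distance_matrix(u: Ust) -> np.ndarray:
    """Matrix of shortest-path edge counts between the leaves of ``u``.

    Computed from root-to-leaf paths: ``d(i, j) = depth_i + depth_j -
    2 * depth(lca)`` where the lowest common ancestor is found as the
    longest common prefix of the two paths.
    """
    paths: list[tuple[int, ...]] = []

    def walk(node: Ust, prefix: tuple[int, ...]) -> None:
        if node.is_leaf:
            paths.append(prefix)
            return
        for idx, c in enumerate(node.children):
            walk(c, prefix + (idx,))

    walk(u, ())
    n = len(paths)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[i], paths[j]
            common = 0
            for a, b in zip(pi, pj):
                if a != b:
                    break
                common += 1
            dist = (len(pi) - common) + (len(pj) - common)
            d[i, j] = d[j, i] = dist
    return d


def is_consistent(u: Ust, cmap: ContactMap, delta: int = 4) -> bool:
    """True iff every contact pair is within ``delta`` edges in the tree.

    The predicate is ``d_u(i, j) <= delta``; with the default
    ``delta = 4`` this means the pair is generated by a contact rule
    (or, for adjacent residues, by one branching rule).
    """
    leaves = u.leaves()
    if len(leaves) != cmap.length:
        raise ValueError(
            f"tree yields {len(leaves)} leaves but the map has length {cmap.length}"
        )
    if not cmap.pairs:
        return True
    d = leaf_distance_matrix(u)
    return all(d[i - 1, j - 1] <= delta for i, j in cmap.pairs)


def enumerate_cnf_skeletons(n: int, labels: str | None = None):
    """Yield every CNF-shaped skeleton over ``n`` leaves.

    Each terminal leaf hangs from a unary lexical-non-terminal node;
    above those, the tree is an arbitrary full binary tree.  For ``n = 1``
    the single skeleton is one lexical node over one leaf (derivable only
    as a subtree, not from the start symbol).
    """
    labels = labels if labels is not None else "x" * n

    def shapes(lo: int, hi: int):
        if hi - lo == 1:
            yield Ust(children=(Ust(leaf=labels[lo]),))
            return
        for k in range(lo + 1, hi):
            for left in shapes(lo, k):
                for right in shapes(k, hi):
                    yield Ust(children=(left, right))

    yield from shapes(0, n)
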
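"""Numba CKY kernels shared by the parser and the trainer.

The charts are computed in linear space after an exact per-position
rescaling: every complete parse tree applies exactly one lexical rule
per sequence position, so dividing the span-1 probabilities of position
``i`` by a constant ``s_i`` divides the probability of every tree by
``prod_i s_i``.  Choosing ``s_i`` as the largest lexical probability at
position ``i`` keeps all chart entries well inside double range for
sequences into the low hundreds of residues; the log of the scale
product is added back at the end.

Contact constraints follow the move-to-C scheme: span-1 probabilities of
positions involved in contacts are moved out of the main chart into a
per-contact table ``C``; ``C`` entries can only be consumed by a contact
rule whose two flanks take the two endpoints of one and the same
contact, so every surviving parse realizes every contact with a contact
rule (leaf-to-leaf distance 4), and nothing else can place a terminal at
a constrained position.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def fill_inside(
    n,
    T,
    N,
    P1,  # (n, T) span-1 lexical probabilities, contact positions zeroed
    C,  # (npairs, 2, T) lexical probabilities reserved for contact endpoints
    pl,  # (npairs,) 0-based left endpoints
    pr,  # (npairs,) 0-based right endpoints
    b_lhs,
    b_a,
    b_b,  # branching rules: lhs (structural index), rhs symbol codes
    b_p,
    c_lhs,
    c_f1,
    c_in,
    c_f2,  # contact rules: lhs, flank lexical indices, inner structural index
    c_p,
):
    """Inside chart P[span, start, symbol]; symbols 0..T-1 lexical, T.. structural."""
    V = T + N
    P = np.zeros((n + 1, n, V))
    for i in range(n):
        for t in range(T):
            P[1, i, t] = P1[i, t]
    for j in range(2, n + 1):
        for i in range(n - j + 1):
            e = i + j - 1
            for r in range(b_lhs.shape[0]):
                a = b_a[r]
                b = b_b[r]
                acc = 0.0
                for k in range(1, j):
                    acc += P[k, i, a] * P[j - k, i + k, b]
                if acc != 0.0:
                    P[j, i, T + b_lhs[r]] += b_p[r] * acc
            if j >= 4:
                pidx = -1
                for p in range(pl.shape[0]):
                    if pl[p] == i and pr[p] == e:
                        pidx = p
                for r in range(c_lhs.shape[0]):
                    inner = P[j - 2, i + 1, T + c_in[r]]
                    if inner == 0.0:
                        continue
                    val = P[1, i, c_f1[r]] * P[1, e, c_f2[r]]
                    if pidx >= 0:
                        val += C[pidx, 0, c_f1[r]] * C[pidx, 1, c_f2[r]]
                    if val != 0.0:
                        P[j, i, T + c_lhs[r]] += c_p[r] * inner * val
    return P


@njit(cache=True)
def fill_viterbi(
    n,
    T,
    N,
    P1,
    C,
    pl,
    pr,
    b_lhs,
    b_a,
    b_b,
    b_p,
    c_lhs,
    c_f1,
    c_in,
    c_f2,
    c_p,
):
    """Max-probability chart plus backpointers.

    Tie-break: branching rules in index order before contact rules, split
    points left to right, strict improvement required -- the first
    optimum encountered wins, which makes trees reproducible.
    Backpointer kind: 0 branching, 1 contact with free flanks, 2 contact
    consuming a C slice (the reconstructed tree is identical for 1 and 2).
    """
    V = T + N
    best = np.zeros((n + 1, n, V))
    bkind = np.full((n + 1, n, V), -1, dtype=np.int32)
    brule = np.full((n + 1, n, V), -1, dtype=np.int32)
    bsplit = np.full((n + 1, n, V), -1, dtype=np.int32)
    for i in range(n):
        for t in range(T):
            best[1, i, t] = P1[i, t]
    for j in range(2, n + 1):
        for i in range(n - j + 1):
            e = i + j - 1
            for r in range(b_lhs.shape[0]):
                a = b_a[r]
                b = b_b[r]
                v = T + b_lhs[r]
                for k in range(1, j):
                    cand = b_p[r] * best[k, i, a] * best[j - k, i + k, b]
                    if cand > best[j, i, v]:
                        best[j, i, v] = cand
                        bkind[j, i, v] = 0
                        brule[j, i, v] = r
                        bsplit[j, i, v] = k
            if j >= 4:
                pidx = -1
                for p in range(pl.shape[0]):
                    if pl[p] == i and pr[p] == e:
                        pidx = p
                for r in range(c_lhs.shape[0]):
                    inner = best[j - 2, i + 1, T + c_in[r]]
                    if inner == 0.0:
                        continue
                    v = T + c_lhs[r]
                    cand = c_p[r] * inner * P1[i, c_f1[r]] * P1[e, c_f2[r]]
                    if cand > best[j, i, v]:
                        best[j, i, v] = cand
                        bkind[j, i, v] = 1
                        brule[j, i, v] = r
                        bsplit[j, i, v] = -1
                    if pidx >= 0:
                        cand = c_p[r] * inner * C[pidx, 0, c_f1[r]] * C[pidx, 1, c_f2[r]]
                        if cand > best[j, i, v]:
                            best[j, i, v] = cand
                            bkind[j, i, v] = 2
                            brule[j, i, v] = r
                            bsplit[j, i, v] = -1
    return best, bkind, brule, bsplit
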
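# protgram

Probabilistic context-free grammars (PCFGs) for families of protein
motifs, estimated with **residue–residue contact maps as syntactic-tree
constraints**.

## Why

Profile HMMs, the workhorse of protein sequence analysis, model the
columns of an alignment independently and cannot express dependencies
between residues that are far apart in the sequence but close in the
folded structure. Context-free grammars can: a nested pair of contacts
maps naturally onto a nested parse-tree structure. The hard part is
*training* such grammars from sequences alone. `protgram` uses partial
contact maps — from solved structures or coevolutionary prediction — to
constrain the set of admissible parse trees during estimation, which
makes the learning problem tractable and yields grammars whose parse
trees track the protein's spatial structure.

## The model

A grammar in **Chomsky Form with Contacts (CFC)** is a PCFG
`⟨Σ, V_T ⊎ V_N, v₀, R, θ⟩` whose rules split into

* lexical rules `R_a = {v_t → a}` (`v_t ∈ V_T`, amino acid `a ∈ Σ`) —
  emission profiles,
* branching rules `R_b = {v → αβ}` (`v ∈ V_N`, `α, β ∈ V_T ∪ V_N`),
* contact rules `R_c = {v → v_t w v_u}` (`v, w ∈ V_N`, `v_t, v_u ∈ V_T`)
  whose two flanking lexical symbols generate a residue pair in spatial
  contact.

With `R_c = ∅` this is ordinary Chomsky Normal Form. A parse-tree
skeleton `u` is *consistent* with a contact map `m` when every contact
pair `(i, j)` satisfies `d_u(i, j) ≤ δ` for the leaf-to-leaf path length
`d_u`; `δ = 4` is the natural CFC threshold — exactly the distance of a
pair generated by a contact rule (in CNF trees the minimum over
separated pairs is 5, so contacts are unreachable).

A contact-constrained CKY chart parser computes, in `O(n³)`,

* `prob(Y_x | G)` — the inside probability of sequence `x`,
* `prob(Y_x^m | G)` — restricted to map-consistent trees,
* `prob(U_n^m | G)` — the total mass of consistent tree shapes over all
  sequences of length `n` (all lexical probabilities set to 1),
* the most likely (Viterbi) parse tree, optionally constrained.

These feed three estimation objectives — constrained maximum likelihood
`ML`, contrastive estimation against the shared-map neighborhood
`CE(m) = Σ_x log prob(U_x^m) − |X| log prob(U_n^m)`, and against each
sequence's own tree space `CE(X) = Σ log [prob(U_x^m)/prob(U_x)]` — all
optimized by a Pittsburgh-style genetic algorithm over the rule
probabilities of a fixed covering rule set. Sequences are scored as
decimal log-odds against a unigram null model of background amino-acid
frequencies (score 3 ⇔ 1,000 times more probable than background).

## Worked example

```python
import protgram as pg

g = pg.toy_hairpin_grammar()          # 8-residue beta-hairpin fixture
x, tree = pg.sample_derivation(g, 42) # draw one (sequence, parse tree)
m = pg.map_from_tree(tree)            # contacts generated by contact rules

print(x)                  # LVSSNGYM
print(m.sorted_pairs())   # [(1, 8), (2, 7)]   nested stem pairs
print(pg.inside(x, g))    # 1.1466183028863213e-07
print(pg.score_sequence(x, g))  # 3.29270976791842  (≈2000x over background)

best, p = pg.viterbi(x, g)
print(pg.to_bracket(best))
# (s (h L) (t (h V) (u (b (l S) (l S)) (b (l N) (l G))) (h Y)) (h M))

from protgram.evaluation import descriptive_metrics
rep = descriptive_metrics(best, m, m, delta=4, min_separation=3)
print(rep.recall_at_delta, rep.precision_at_delta)  # 1.0 1.0
```

The Viterbi tree, derived from the sequence alone, places its two
contact rules exactly on the hairpin's stem pairs, so the tree predicts
both contacts at `δ = 4` with perfect precision and recall.

The same operations are available from the shell via the `protgram`
command (`make-grammar`, `simulate`, `train`, `score`, `parse`, `scan`,
`eval` — see `protgram --help`).

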
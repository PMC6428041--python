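# Methods

## Model

`protgram` models a family of protein motif sequences with a
probabilistic context-free grammar in Chomsky Form with Contacts (CFC).
Non-terminals are split into lexical symbols `V_T`, each of which
rewrites into a single amino acid and thus plays the role of an
emission profile (comparable to a match state of a profile HMM), and
structural symbols `V_N`, which carry the tree topology. Besides the
CNF rule types (lexical `v_t → a`, branching `v → αβ`), CFC adds
ternary *contact rules* `v → v_t w v_u` whose two flanking lexical
symbols generate a pair of residues in spatial contact, with the inner
structural symbol deriving everything between them.

The link between trees and structure is purely geometric: in any CFC
parse tree the two terminals of a contact rule are exactly 4 edges
apart (leaf – lexical parent – contact node – lexical parent – leaf),
while in a CNF tree the minimum leaf-to-leaf distance over pairs at
sequence separation ≥ 3 is 5 (adjacent leaves can reach 4 as siblings
of one branching rule, separated leaves cannot). A skeleton `u` is
therefore declared *consistent* with a contact map `m` when
`d_u(i, j) ≤ δ` for every contact, with the default `δ = 4` meaning
"every contact is generated by a contact rule". The consistency
predicate is implemented non-strictly (`≤ δ`); with the conventional
value `δ = 4` the strict variant would exclude the contact-rule
geometry itself and leave the constrained tree set empty, so the
non-strict reading is the only one under which the constrained parser,
the sampling module and the evaluation metrics agree, and the
enumeration-oracle tests pin this behavior down.

Contact maps are partial, 1-based, and must be *CF-compatible*: no two
contacts may cross or share an endpoint (nesting is fine), and contacts
need sequence separation ≥ 2. Separation-2 contacts are structurally
unrealizable (the inner non-terminal yields at least two residues), so
constructing a map containing one emits a warning; its constrained
probability is exactly 0. `extract_cf_compatible_subset` automates the
choice of a training subset from a full (crossing) map by
maximum-cardinality non-crossing selection, an interval dynamic program
in the style of the Nussinov pairing algorithm, with a deterministic
smallest-partner tie-break.

## Parsing

All four chart quantities (inside, constrained inside, skeleton mass,
Viterbi) come from one bottom-up CKY family. Constraints use an
auxiliary table: the span-1 lexical probabilities of positions involved
in contacts are moved out of the main chart into one slice per contact;
a slice can only be consumed by a contact rule whose flanks sit exactly
on that contact's two endpoints, and the two flanks must come from the
same table (never one free, one reserved). Because a constrained
position's probability is no longer reachable any other way, every
surviving parse realizes every contact with a contact rule — which is
exactly the `d_u ≤ 4` tree set, as the enumerate-and-filter oracle
verifies. The skeleton mass `prob(U_n^m)` — the contrastive
denominator — is the same computation with every lexical probability
set to 1; for a proper grammar the per-position emission sums telescope
to 1, so this equals the sum of constrained inside values over all
`|Σ|^n` sequences (tested exhaustively for `|Σ| = 2, n ≤ 6`).

Numerics: chart arithmetic runs in linear space after an exact
per-position rescaling. Every complete tree uses exactly one lexical
rule per position, so dividing each span-1 row by its maximum divides
every tree's probability by the same constant, which is restored in log
space at the end. This is exact (not an approximation), keeps the
numba kernels branch-free and fast, and holds comfortably within double
range for the motif- and window-scale sequences this package targets
(guaranteed into the low hundreds of residues; the structural-rule
product is the only remaining decay). Viterbi tie-breaks are fixed —
rules in definition order, branching before contact, split points left
to right, strict improvement required — so the reported tree is
reproducible across runs and platforms.

## Estimation

Three objectives are provided, all as mean per-item natural-log values
(means rather than sums so fitness is comparable across sample sizes):
constrained maximum likelihood `ML`; contrastive estimation against the
shared-map neighborhood `CE(m)` (requires equal-length sequences and
one common map; value ≤ 0 since `prob(U_x^m) ≤ prob(U_n^m)`); and
contrastive estimation against each sequence's own tree space `CE(X)`
(≤ 0, exactly 0 when all maps are empty). With empty maps `ML` reduces
to the ordinary sequence log-likelihood.

The trainer is a Pittsburgh-style genetic algorithm: each individual is
a whole grammar, encoded as one non-negative weight per rule and
decoded by per-lhs normalization, so every individual in every
generation is a proper grammar without constrained variation operators.
Defaults: population 100, 500 generations, tournament selection of
size 3, uniform crossover at rate 0.8, per-gene Gaussian mutation at
rate 0.02 with σ = 0.1 applied as a reflected perturbation
(`w ← |w + ε|`, keeping weights non-negative), elitism 2. These
defaults are declared choices of this package, configurable and
recorded in the run metadata. The starting grammar seeds the initial
population, so the returned objective never falls below it, and the
best-so-far trace is non-decreasing. Negative data are never used in
training; they enter only at evaluation time.

## Evaluation

Scores are decimal log-odds against a unigram null model; the shipped
default background table is the Swiss-Prot amino-acid composition
(package data, fully overridable). Discrimination is summarized by the
average precision of the recall–precision curve, computed as the step
sum `Σ (R_k − R_{k−1}) P_k` over descending unique score thresholds;
tied scores share one step, and `−inf` scores (unparsable sequences)
are legal and rank last — the reason AP is implemented in-package, with
scikit-learn serving as an independent cross-check on finite inputs in
the tests. Descriptive metrics rank all residue pairs at separation
≥ 3 by ascending tree distance of the Viterbi skeleton: recall at
`δ = 4` against the training map measures how much of the imposed
constraint the grammar internalized; precision at `δ = 4` and AP over
all distance cutoffs against a full reference map measure fidelity to
the structure. Pairs at equal tree distance share one threshold step
(the per-unique-distance convention; the alternative optimistic /
pessimistic orderings would make AP depend on arbitrary pair order).
Local variants restrict both measures to the pairs involving one
residue. The cross-validation helper implements the 8-fold 6/1/1
train/validation/test scheme with all 56 ordered
(validation, test) part combinations.

Window scanning slides all windows of 20–30 residues (configurable),
scores each with a grammar or an ensemble (arithmetic mean of
per-grammar scores), and reports the best window per start plus
above-threshold hits.

## Synthetic data

Because the original motif collections are built from curated
structural databases, the package ships a first-class generator
instead: top-down sampling from any CFC grammar draws a parse tree with
its derivation probability (depth-capped at 50, with a distinct
overflow signal for divergent grammars), and the contact map of a
sampled tree is read off its contact rules — CF-compatible and
`δ = 4`-consistent by construction. Benchmarks pair rejection-sampled
positives (optionally filtered to an exact length) with i.i.d. unigram
negatives of matching lengths drawn from the null-model background, so
discrimination measures learned structure rather than composition
alone.

Two fixtures are provided. `toy_hairpin_grammar` is an 8-residue
beta-hairpin: lexical symbols `h` (hydrophobic), `l` (loop-friendly),
`x` (unspecific), two nested contact rules for the stem and a
four-residue loop; its rule probabilities are defined here (hairpin
geometry fixed, emissions peaked on hydrophobic/loop residues with a
floor of 0.05 weight per amino acid so no sequence has probability 0).
`stem_grammar(p_extend = 0.55)` generates stems of geometric depth
(`P(k) = p^{k−1}(1 − p)` nested pairs, length `2k + 4`); the default
extension probability puts ~2% of the mass on length 16, making
rejection sampling of motif-sized positives cheap while keeping the
length distribution realistic for short binding-site motifs.

The parameter-recovery experiment trains the full 400-rule covering CFC
grammar (3 lexical, 4 structural non-terminals over the 20 amino acids
— the inventory whose covering counts are 60 lexical, 196 branching,
144 contact rules) on 24 length-16 positives sampled from
`stem_grammar`, with constrained ML, population 100 and 120
generations × 3 seeds. 120 generations is the chosen run size for this
problem (the fitness trace plateaus well before it at ~290k constrained
parses per seed); the package default of 500 remains for real use.
What passing shows: the training machinery can push probability mass
onto contact rules so that unconstrained Viterbi trees reproduce the
imposed contacts (recall ≥ 0.8 at δ = 4) and discrimination improves
over the untrained covering grammar by ≥ 0.2 AP. What it does not
show: performance on real, diverse motif families with crossing
contacts, alignment noise, or length variation — the generator's
positives are cleaner and more homogeneous than curated motif samples.

## Defaults and units

| parameter | default | meaning |
| --- | --- | --- |
| `δ` | 4 edges | tree-distance cutoff for contact consistency |
| `τ` | 8 Å | spatial distance threshold for deriving contacts |
| min. sequence separation | 3 (full maps), 2 (compatibility) | `j − i` lower bound |
| GA | pop 100, 500 gen, cx 0.8, mut 0.02/σ 0.1, elitism 2, tournament 3 | see above |
| scan window | 20–30 residues | sliding-window motif search |
| score base | log₁₀ | score 3 ⇔ 1,000× over background |
| sampling depth cap | 50 | divergence guard |

## Limitations

* Only non-crossing, non-overlapping contact subsets can be imposed;
  crossing contacts must be dropped (`extract_cf_compatible_subset`)
  or handled by training several grammars on tree-decomposed maps.
* The unigram null model does not correct for length or composition
  biases beyond background frequencies; comparing scores across very
  different lengths needs care.
* GA estimation is stochastic and practical up to roughly a thousand
  rules; larger inventories need constrained covering sets.
* The linear-space kernels are exact for the intended sequence scale
  but are not meant for chains of many hundreds of residues.
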
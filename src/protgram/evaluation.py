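"""Scoring against a null model, discrimination and description metrics.

Scores are decimal log-odds: ``score(x) = log10 prob(x | G) - log10
prob(x | null)`` with a unigram null model over background amino-acid
frequencies, so a score of 3 means the sequence is exactly 1,000 times
more probable under the grammar than under the null.

Discriminative performance is summarized by the average precision (AP)
of the recall-precision curve, which is robust to the heavy class
imbalance of motif-search problems.  Descriptive performance measures
how well the leaf distances of a (Viterbi) parse tree reproduce the
protein's contact map: a residue pair is predicted in contact when its
leaf-to-leaf path is short, with the CFC-natural cutoff ``delta = 4``
meaning "generated by a contact rule".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .contacts import ContactMap, leaf_distance_matrix
from .grammar import CfcGrammar
from .parser import NEG_INF, ParseTree, log_inside, log_inside_constrained, skeleton

__all__ = [
    "NullModel",
    "ScoredSet",
    "DescriptiveReport",
    "null_logprob",
    "score_sequence",
    "ensemble_score",
    "recall_precision_ap",
    "average_precision",
    "descriptive_metrics",
    "scan",
    "cv_split",
]

LOG10 = math.log(10.0)


@dataclass(frozen=True)
class NullModel:
    """Unigram null model: independent background frequencies per residue."""

    frequencies: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"null-model frequencies sum to {total}, expected 1")
        if any(f < 0 for f in self.frequencies.values()):
            raise ValueError("negative frequency")

    @classmethod
    def uniform(cls, alphabet) -> "NullModel":
        syms = list(alphabet)
        return cls({s: 1.0 / len(syms) for s in syms})

    @classmethod
    def from_weights(cls, weights: dict[str, float]) -> "NullModel":
        total = sum(weights.values())
        if total <= 0:
            raise ValueError("weights must have positive sum")
        return cls({s: w / total for s, w in weights.items()})

    @classmethod
    def from_file(cls, path) -> "NullModel":
        weights: dict[str, float] = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                sym, val = line.split()
                weights[sym] = float(val)
        return cls.from_weights(weights)

    @classmethod
    def default(cls) -> "NullModel":
        """Swiss-Prot background frequencies shipped with the package."""
        ref = resources.files("protgram").joinpath("data/swissprot_frequencies.tsv")
        weights: dict[str, float] = {}
        for raw in ref.read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if line:
                sym, val = line.split()
                weights[sym] = float(val)
        return cls.from_weights(weights)

    def restricted(self, alphabet) -> "NullModel":
        """Renormalized over the symbols of ``alphabet`` (for small toy alphabets)."""
        return NullModel.from_weights({s: self.frequencies.get(s, 0.0) for s in alphabet})


def null_logprob(x: str, null: NullModel) -> float:
    """Decimal-log probability of ``x`` under the unigram null model."""
    total = 0.0
    for s in x:
        f = null.frequencies.get(s)
        if f is None:
            raise ValueError(f"symbol {s!r} not covered by the null model")
        if f == 0.0:
            return NEG_INF
        total += math.log10(f)
    return total


def score_sequence(
    x: str,
    g: CfcGrammar,
    cmap: ContactMap | None = None,
    null: NullModel | None = None,
) -> float:
    """Decimal log-odds of the grammar over the null model.

    Uses the constrained inside probability when a map is supplied.
    """
    null = null or NullModel.default()
    lp = log_inside_constrained(x, cmap, g) if cmap is not None else log_inside(x, g)
    if lp == NEG_INF:
        return NEG_INF
    return lp / LOG10 - null_logprob(x, null)


def ensemble_score(x, grammars, null: NullModel | None = None, cmap=None) -> float:
    """Arithmetic mean of per-grammar scores; -inf if any member is -inf."""
    if not grammars:
        raise ValueError("need at least one grammar")
    scores = [score_sequence(x, g, cmap, null) for g in grammars]
    if any(s == NEG_INF for s in scores):
        return NEG_INF
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# recall-precision


@dataclass
class ScoredSet:
    positives: list[tuple[str, float]]
    negatives: list[tuple[str, float]]

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.positives] + [i for i, _ in self.negatives]
        if len(set(ids)) != len(ids):
            raise ValueError("identifiers of positives and negatives must be disjoint")


def average_precision(pos_scores, neg_scores) -> float:
    """AP = sum_k (R_k - R_{k-1}) P_k over descending unique score thresholds.

    Ties share one threshold step.  ``-inf`` scores are legal (they rank
    last); implemented here rather than delegated so that non-finite
    scores from unparsable sequences are handled.
    """
    pos_scores = np.asarray(list(pos_scores), dtype=float)
    neg_scores = np.asarray(list(neg_scores), dtype=float)
    if pos_scores.size == 0:
        raise ValueError("need at least one positive")
    scores = np.concatenate([pos_scores, neg_scores])
    labels = np.concatenate([np.ones(pos_scores.size), np.zeros(neg_scores.size)])
    ap = 0.0
    prev_recall = 0.0
    tp = 0.0
    seen = 0.0
    for thr in np.unique(scores)[::-1]:
        at = scores == thr
        tp += labels[at].sum()
        seen += at.sum()
        recall = tp / pos_scores.size
        precision = tp / seen
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return float(ap)


def recall_precision_ap(s: ScoredSet):
    """Recall-precision curve points (descending thresholds) and its AP."""
    pos = [v for _, v in s.positives]
    neg = [v for _, v in s.negatives]
    scores = np.array(pos + neg, dtype=float)
    labels = np.array([1] * len(pos) + [0] * len(neg), dtype=float)
    curve = []
    tp = 0.0
    seen = 0.0
    for thr in np.unique(scores)[::-1]:
        at = scores == thr
        tp += labels[at].sum()
        seen += at.sum()
        curve.append((tp / len(pos), tp / seen))
    return curve, average_precision(pos, neg)


# ---------------------------------------------------------------------------
# descriptive metrics


@dataclass
class DescriptiveReport:
    """Contact-prediction quality of one parse tree.

    ``recall_at_delta`` is measured against the (partial) training map;
    ``precision_at_delta`` and ``ap_over_deltas`` against the full
    reference map, restricted to pairs at sequence separation
    ``>= min_separation``.  ``None`` marks undefined values (empty
    reference, or no predicted pair at the cutoff).
    """

    recall_at_delta: float | None
    precision_at_delta: float | None
    ap_over_deltas: float | None
    local_ap: dict[int, float] = field(default_factory=dict)
    local_recall: dict[int, float] = field(default_factory=dict)
    delta: int = 4
    min_separation: int = 3


def _ap_from_distances(dists, truths) -> float:
    """AP ranking candidate pairs by ascending tree distance, ties grouped."""
    dists = np.asarray(dists)
    truths = np.asarray(truths, dtype=float)
    n_pos = truths.sum()
    ap = 0.0
    prev_recall = 0.0
    tp = 0.0
    seen = 0.0
    for d in np.unique(dists):
        at = dists == d
        tp += truths[at].sum()
        seen += at.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * (tp / seen)
        prev_recall = recall
    return float(ap)


def descriptive_metrics(
    tree: ParseTree,
    training_map: ContactMap | None,
    full_map: ContactMap | None,
    delta: int = 4,
    min_separation: int = 3,
) -> DescriptiveReport:
    """Tree-derived contact prediction versus training and reference maps."""
    u = skeleton(tree)
    d = leaf_distance_matrix(u)
    n = d.shape[0]
    for m, name in ((training_map, "training"), (full_map, "full")):
        if m is not None and m.length != n:
            raise ValueError(f"{name} map length {m.length} does not match tree yield {n}")

    recall = None
    local_recall: dict[int, float] = {}
    if training_map is not None and training_map.pairs:
        hits = [d[i - 1, j - 1] <= delta for i, j in training_map.pairs]
        recall = float(np.mean(hits))
        for k in range(1, n + 1):
            row = [(i, j) for i, j in training_map.pairs if k in (i, j)]
            if row:
                local_recall[k] = float(np.mean([d[i - 1, j - 1] <= delta for i, j in row]))

    precision = None
    ap = None
    local_ap: dict[int, float] = {}
    if full_map is not None and full_map.pairs:
        cand = [
            (i, j)
            for i in range(1, n + 1)
            for j in range(i + 1, n + 1)
            if j - i >= min_separation
        ]
        dists = [d[i - 1, j - 1] for i, j in cand]
        truths = [(i, j) in full_map.pairs for i, j in cand]
        predicted = [t for dd, t in zip(dists, truths) if dd <= delta]
        if predicted:
            precision = float(np.mean(predicted))
        if any(truths):
            ap = _ap_from_distances(dists, truths)
            for k in range(1, n + 1):
                sel = [idx for idx, (i, j) in enumerate(cand) if k in (i, j)]
                if sel and any(truths[idx] for idx in sel):
                    local_ap[k] = _ap_from_distances(
                        [dists[idx] for idx in sel], [truths[idx] for idx in sel]
                    )
    return DescriptiveReport(
        recall_at_delta=recall,
        precision_at_delta=precision,
        ap_over_deltas=ap,
        local_ap=local_ap,
        local_recall=local_recall,
        delta=delta,
        min_separation=min_separation,
    )


# ---------------------------------------------------------------------------
# scanning and cross-validation


def scan(
    sequence: str,
    grammars,
    null: NullModel | None = None,
    window_min: int = 20,
    window_max: int = 30,
    threshold: float = 3.0,
):
    """Slide windows of lengths ``window_min..window_max`` and score each.

    ``grammars`` may be one grammar or a list (ensemble mean score).
    Returns ``(best_per_start, hits)``: for each 1-based start position
    the best (score, window length) over all admissible windows, and the
    subset of starts whose best score reaches ``threshold``.
    """
    if isinstance(grammars, CfcGrammar):
        grammars = [grammars]
    if window_min > window_max:
        raise ValueError("window_min must be <= window_max")
    null = null or NullModel.default()
    n = len(sequence)
    best_per_start = []
    hits = []
    for start in range(1, n + 2 - window_min):
        best = (NEG_INF, None)
        for w in range(window_min, window_max + 1):
            if start - 1 + w > n:
                break
            sub = sequence[start - 1 : start - 1 + w]
            sc = ensemble_score(sub, grammars, null)
            if sc > best[0]:
                best = (sc, w)
        record = {"start": start, "window": best[1], "score": best[0]}
        best_per_start.append(record)
        if best[0] >= threshold:
            hits.append(record)
    return best_per_start, hits


def cv_split(n_items: int, folds: int = 8, seed: int = 0):
    """8-fold scheme: 6 parts train, 1 validation, 1 test; all 56 ordered combos.

    Returns a list of ``(train, validation, test)`` index tuples covering
    every ordered pair of distinct parts as (validation, test).
    """
    if n_items < folds:
        raise ValueError(f"need at least {folds} items for {folds} folds")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n_items)
    parts = [sorted(p.tolist()) for p in np.array_split(idx, folds)]
    splits = []
    for v in range(folds):
        for t in range(folds):
            if v == t:
                continue
            train = sorted(i for p in range(folds) if p not in (v, t) for i in parts[p])
            splits.append((tuple(train), tuple(parts[v]), tuple(parts[t])))
    return splits
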
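"""Training objectives and the Pittsburgh-style genetic algorithm.

Three estimation objectives are provided, all returned as *mean*
per-item natural-log values so that fitness is comparable across sample
sizes:

* ``ML``    -- mean log prob(Y_x^m | G): the contact-constrained
  likelihood; with all-empty maps this is the ordinary sequence
  log-likelihood.
* ``CE_m``  -- contrastive estimation against the shared-map
  neighborhood: mean log prob(U_x^m | G) - log prob(U_n^m | G), where
  the denominator is the skeleton mass of all map-consistent tree
  shapes (requires one contact map shared by every sequence).
* ``CE_X``  -- contrastive estimation against each sequence's own tree
  space: mean log [prob(U_x^m | G) / prob(U_x | G)].

The trainer evolves one weight per rule (a whole grammar per
individual); weights are decoded into a proper grammar by per-lhs
normalization, so every individual of every generation is proper.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactMap, is_cf_compatible
from .grammar import CfcGrammar, normalize_theta
from .parser import NEG_INF, GrammarKernel

__all__ = [
    "TrainingSample",
    "GaConfig",
    "objective_ml",
    "objective_ce_m",
    "objective_ce_x",
    "train_ga",
]


@dataclass
class TrainingSample:
    """Sequences paired with their (CF-compatible) training contact maps."""

    items: list[tuple[str, ContactMap]]
    shared_map: ContactMap | None = None

    def __post_init__(self) -> None:
        for x, m in self.items:
            if m.length != len(x):
                raise ValueError(f"map length {m.length} does not match sequence length {len(x)}")
            ok, viol = is_cf_compatible(m, min_separation=2)
            if not ok:
                raise ValueError(f"training map for {x!r} is not CF-compatible: {viol}")
        if self.shared_map is not None:
            lengths = {len(x) for x, _ in self.items}
            if lengths - {self.shared_map.length}:
                raise ValueError("a shared map requires all sequences to have its length")

    def __len__(self) -> int:
        return len(self.items)

    @classmethod
    def from_sequences(cls, sequences, maps=None, shared_map=None) -> "TrainingSample":
        """Build a sample; ``maps=None`` means empty (unconstrained) maps."""
        items = []
        for idx, x in enumerate(sequences):
            if shared_map is not None:
                m = shared_map
            elif maps is not None:
                m = maps[idx]
            else:
                m = ContactMap(len(x))
            items.append((x, m))
        return cls(items=items, shared_map=shared_map)


@dataclass
class GaConfig:
    population_size: int = 100
    generations: int = 500
    crossover_rate: float = 0.8
    mutation_rate: float = 0.02
    mutation_sigma: float = 0.1
    elitism: int = 2
    tournament_size: int = 3
    seed: int = 0
    objective: str = "ML"  # ML | CE_m | CE_X

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.objective not in ("ML", "CE_m", "CE_X"):
            raise ValueError("objective must be one of ML, CE_m, CE_X")


# ---------------------------------------------------------------------------
# objectives


def _mean(values) -> float:
    values = list(values)
    if any(v == NEG_INF for v in values):
        return NEG_INF
    return float(np.mean(values))


def _obj_ml(kernel: GrammarKernel, sample: TrainingSample) -> float:
    return _mean(kernel.log_inside(x, m if m.pairs else None) for x, m in sample.items)


def _obj_ce_m(kernel: GrammarKernel, sample: TrainingSample) -> float:
    if sample.shared_map is None:
        raise ValueError("CE_m requires a shared contact map")
    m = sample.shared_map
    denom = kernel.log_skeleton_mass(m.length, m)
    if denom == NEG_INF:
        return NEG_INF
    return _mean(kernel.log_inside(x, m) - denom for x, _ in sample.items)


def _obj_ce_x(kernel: GrammarKernel, sample: TrainingSample) -> float:
    vals = []
    for x, m in sample.items:
        num = kernel.log_inside(x, m if m.pairs else None)
        den = kernel.log_inside(x) if m.pairs else num
        if den == NEG_INF:
            warnings.warn(f"sequence {x!r} has zero probability under the grammar")
            return NEG_INF
        vals.append(num - den)
    return _mean(vals)


_OBJECTIVES = {"ML": _obj_ml, "CE_m": _obj_ce_m, "CE_X": _obj_ce_x}


def objective_ml(sample: TrainingSample, g: CfcGrammar) -> float:
    """Mean constrained log-likelihood (1/|S|) sum log prob(Y_x^m | G)."""
    return _obj_ml(GrammarKernel(g), sample)


def objective_ce_m(sample: TrainingSample, g: CfcGrammar) -> float:
    """Mean shared-map contrastive objective; always <= 0 for proper grammars."""
    return _obj_ce_m(GrammarKernel(g), sample)


def objective_ce_x(sample: TrainingSample, g: CfcGrammar) -> float:
    """Mean per-sequence contrastive objective; 0 exactly when all maps are empty."""
    return _obj_ce_x(GrammarKernel(g), sample)


# ---------------------------------------------------------------------------
# genetic algorithm


def _decode(W: np.ndarray, gid: np.ndarray, n_groups: int) -> np.ndarray:
    """Per-lhs simplex normalization of a weight vector (all-zero -> uniform)."""
    sums = np.zeros(n_groups)
    np.add.at(sums, gid, W)
    bad = sums[gid] == 0.0
    if np.any(bad):
        W = W.copy()
        W[bad] = 1.0
        sums = np.zeros(n_groups)
        np.add.at(sums, gid, W)
    return W / sums[gid]


def train_ga(g0: CfcGrammar, sample: TrainingSample, cfg: GaConfig):
    """Evolve rule probabilities; returns ``(best_grammar, trace)``.

    Each chromosome is a vector of non-negative weights, one per rule of
    ``g0``; decoding normalizes per left-hand side so every individual
    is a proper grammar.  ``g0`` itself seeds the initial population, so
    the returned objective is never worse than the starting grammar's.
    ``trace`` holds the best objective after each generation
    (non-decreasing thanks to elitism) with the initial population's
    best at index 0.
    """
    if not sample.items:
        raise ValueError("training sample is empty")
    rng = np.random.default_rng(cfg.seed)
    kernel = GrammarKernel(g0)
    objective = _OBJECTIVES[cfg.objective]

    lhs_names = list(dict.fromkeys(r.lhs for r in g0.rules))
    gid = np.array([lhs_names.index(r.lhs) for r in g0.rules], dtype=np.int64)
    n_groups = len(lhs_names)
    n_rules = g0.n_rules

    def fitness(w: np.ndarray) -> float:
        kernel.set_theta_vector(_decode(w, gid, n_groups))
        return objective(kernel, sample)

    pop = rng.exponential(1.0, size=(cfg.population_size, n_rules))
    pop[0] = g0.theta_vector()
    fit = np.array([fitness(w) for w in pop])
    if np.all(fit == NEG_INF):
        raise ValueError(
            "every individual of the initial population has objective -inf; "
            "check that the grammar can parse the sample under its maps "
            "(e.g. contact rules present, no sequence shorter than 2)"
        )
    trace = [float(fit.max())]

    for _ in range(cfg.generations):
        order = np.argsort(fit)[::-1]
        new_pop = [pop[i].copy() for i in order[: cfg.elitism]]
        while len(new_pop) < cfg.population_size:
            idx = rng.integers(0, cfg.population_size, size=(2, cfg.tournament_size))
            p1 = pop[idx[0][np.argmax(fit[idx[0]])]].copy()
            p2 = pop[idx[1][np.argmax(fit[idx[1]])]].copy()
            if rng.random() < cfg.crossover_rate:
                swap = rng.random(n_rules) < 0.5
                p1[swap], p2[swap] = p2[swap], p1[swap].copy()
            for child in (p1, p2):
                mask = rng.random(n_rules) < cfg.mutation_rate
                if mask.any():
                    child[mask] = np.abs(child[mask] + rng.normal(0.0, cfg.mutation_sigma, mask.sum()))
                if len(new_pop) < cfg.population_size:
                    new_pop.append(child)
        pop = np.array(new_pop)
        fit = np.concatenate([fit[order[: cfg.elitism]], [fitness(w) for w in pop[cfg.elitism :]]])
        trace.append(float(fit.max()))

    best_w = pop[int(np.argmax(fit))]
    theta = _decode(best_w, gid, n_groups)
    best = g0.with_theta(normalize_theta(dict(zip(g0.rules, map(float, theta)))))
    return best, trace
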
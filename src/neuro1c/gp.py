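"""Genetic-programming expression-tree classifier.

Evolves Boolean/arithmetic expression trees over threshold operands —
metabolite z-values against thresholds in control-SD units ({-2, -1, 0, 1, 2})
and SNP allele counts against thresholds in {0, 1, 2}, plus raw allele-count
operands — to separate two subject subgroups.  Fitness is the mean of the two
per-class accuracies penalised 5 percentage points per operand, with a
uniform annealing-style noise term that decays to zero over the first half of
each run; the reported fitness is always noise-free.  The best individual
across repeated independent runs is returned.

Trees are plain nested tuples (hashable, so fitness memoisation is a dict
lookup) and leaves index into a precomputed operand-value matrix, keeping a
single tree evaluation to a handful of vectorised operations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

UNARY_OPS = ("NOT", "NEG")
BINARY_OPS = ("OR", "AND", "ADD", "SUB", "MUL")
METABOLITE_THRESHOLDS = (-2.0, -1.0, 0.0, 1.0, 2.0)
SNP_THRESHOLDS = (0.0, 1.0, 2.0)


class GPError(ValueError):
    pass


@dataclass(frozen=True)
class Operand:
    """A leaf test: ``metabolite_threshold`` and ``snp_threshold`` evaluate
    Boolean ``value >= threshold``; ``snp_count`` is the numeric allele
    count itself."""

    kind: str
    feature: str
    threshold: float | None = None

    def label(self) -> str:
        if self.kind == "snp_count":
            return self.feature
        return f"{self.feature}>={self.threshold:g}"


def enumerate_operands(metabolites: Sequence[str],
                       snps: Sequence[str]) -> list[Operand]:
    """The full operand pool: every metabolite x 5 SD thresholds, every SNP
    x 3 allele-count thresholds, plus one numeric allele-count operand per
    SNP."""
    if not metabolites and not snps:
        raise GPError("empty feature set")
    pool = [Operand("metabolite_threshold", m, t)
            for m in metabolites for t in METABOLITE_THRESHOLDS]
    pool += [Operand("snp_threshold", s, t)
             for s in snps for t in SNP_THRESHOLDS]
    pool += [Operand("snp_count", s) for s in snps]
    return pool


def operand_matrix(pool: Sequence[Operand], features: pd.DataFrame) -> np.ndarray:
    """Evaluate every operand on every subject: (n_operands, n_subjects)
    float matrix, Booleans as 0/1."""
    rows = []
    for op in pool:
        if op.feature not in features.columns:
            raise GPError(f"feature {op.feature!r} missing from data")
        v = features[op.feature].to_numpy(float)
        rows.append(v if op.kind == "snp_count" else (v >= op.threshold).astype(float))
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# Trees: ('L', operand_index) | (unary_op, child) | (binary_op, left, right)
# ---------------------------------------------------------------------------

def evaluate(tree, V: np.ndarray) -> np.ndarray:
    """Numeric evaluation of a tree against the operand matrix.  Logical
    operators read their arguments as Boolean via "> 0" and yield 0/1;
    the caller coerces the root to a class label the same way."""
    tag = tree[0]
    if tag == "L":
        return V[tree[1]]
    if tag == "NOT":
        return 1.0 - (evaluate(tree[1], V) > 0)
    if tag == "NEG":
        return -evaluate(tree[1], V)
    a = evaluate(tree[1], V)
    b = evaluate(tree[2], V)
    if tag == "AND":
        return ((a > 0) & (b > 0)).astype(float)
    if tag == "OR":
        return ((a > 0) | (b > 0)).astype(float)
    if tag == "ADD":
        return a + b
    if tag == "SUB":
        return a - b
    if tag == "MUL":
        return a * b
    raise GPError(f"unknown operator {tag!r}")


def predict(tree, V: np.ndarray) -> np.ndarray:
    """Boolean class prediction: root value coerced by > 0."""
    return evaluate(tree, V) > 0


def operand_count(tree) -> int:
    if tree[0] == "L":
        return 1
    return sum(operand_count(c) for c in tree[1:])


def tree_depth(tree) -> int:
    if tree[0] == "L":
        return 1
    return 1 + max(tree_depth(c) for c in tree[1:])


def serialize(tree, pool: Sequence[Operand]) -> str:
    """Parenthesised prefix form, e.g. ``(AND (NOT snpA>=1) (NOT snpB>=1))``."""
    if tree[0] == "L":
        return pool[tree[1]].label()
    inner = " ".join(serialize(c, pool) for c in tree[1:])
    return f"({tree[0]} {inner})"


def tree_to_json(tree, pool: Sequence[Operand]) -> str:
    def conv(t):
        if t[0] == "L":
            op = pool[t[1]]
            return {"kind": op.kind, "feature": op.feature,
                    "threshold": op.threshold, "comparator": ">="}
        return {"op": t[0], "children": [conv(c) for c in t[1:]]}
    return json.dumps(conv(tree))


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def per_class_accuracy(pred: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    pos = labels
    neg = ~labels
    if pos.sum() == 0 or neg.sum() == 0:
        raise GPError("both classes must be non-empty")
    return (float((pred & pos).sum() / pos.sum()),
            float((~pred & neg).sum() / neg.sum()))


def fitness(tree, V: np.ndarray, labels: np.ndarray,
            penalty: float = 0.05, noise_amp: float = 0.0,
            rng: np.random.Generator | None = None) -> float:
    """Mean per-class accuracy minus ``penalty`` per operand, plus uniform
    [0, noise_amp) selection noise.  The noise-free value (noise_amp = 0) is
    the reported fitness."""
    acc_pos, acc_neg = per_class_accuracy(predict(tree, V), labels)
    f = 0.5 * (acc_pos + acc_neg) - penalty * operand_count(tree)
    if noise_amp > 0:
        f += (rng or np.random.default_rng()).uniform(0.0, noise_amp)
    return f


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------

@dataclass
class GPConfig:
    """Evolution budget and variation rates.

    The study-scale defaults are population 100,000 evolving for 100 steps
    with the best of 10 independent runs kept, a 5-p.p. penalty per operand
    and selection noise decaying linearly from 10 p.p. to zero over the
    first half of each run.  Selection scheme (tournament of 4) and
    crossover/mutation/fresh rates are free choices exposed here;
    ``scaled_down`` gives a small-budget preset for quick experiments.
    """

    population_size: int = 100_000
    generations: int = 100
    runs: int = 10
    operand_penalty: float = 0.05
    noise_max: float = 0.10
    tournament_size: int = 4
    p_crossover: float = 0.6
    p_mutation: float = 0.3
    p_fresh: float = 0.1
    max_depth: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise GPError("population_size must be >= 2")
        if not 0.0 <= self.noise_max <= 1.0 or not 0.0 <= self.operand_penalty <= 1.0:
            raise GPError("penalty and noise must lie in [0, 1]")

    @classmethod
    def scaled_down(cls, **overrides) -> "GPConfig":
        base = dict(population_size=2000, generations=20, runs=3)
        base.update(overrides)
        return cls(**base)


@dataclass
class GPResult:
    """Best individual across runs with its noise-free penalised fitness and
    per-class accuracies (positive class first)."""

    tree: tuple
    expression: str
    fitness: float
    class_accuracies: tuple
    operand_count: int
    run_fitnesses: list = field(default_factory=list)


def _random_tree(rng, n_operands: int, depth: int, p_leaf: float = 0.35) -> tuple:
    if depth <= 1 or rng.random() < p_leaf:
        return ("L", int(rng.integers(n_operands)))
    ops = UNARY_OPS + BINARY_OPS
    op = ops[rng.integers(len(ops))]
    if op in UNARY_OPS:
        return (op, _random_tree(rng, n_operands, depth - 1, p_leaf))
    return (op, _random_tree(rng, n_operands, depth - 1, p_leaf),
            _random_tree(rng, n_operands, depth - 1, p_leaf))


def _nodes(tree, path=()):
    yield path, tree
    if tree[0] != "L":
        for i, c in enumerate(tree[1:], start=1):
            yield from _nodes(c, path + (i,))


def _replace_at(tree, path, sub):
    if not path:
        return sub
    i = path[0]
    return tree[:i] + (_replace_at(tree[i], path[1:], sub),) + tree[i + 1:]


def _mutate(rng, tree, n_operands: int, max_depth: int) -> tuple:
    paths = [p for p, _ in _nodes(tree)]
    path = paths[rng.integers(len(paths))]
    sub = _random_tree(rng, n_operands, max(1, max_depth - len(path)))
    return _replace_at(tree, path, sub)


def _crossover(rng, a, b, max_depth: int) -> tuple:
    pa = [p for p, _ in _nodes(a)]
    pb = [(p, t) for p, t in _nodes(b)]
    path = pa[rng.integers(len(pa))]
    _, donor = pb[rng.integers(len(pb))]
    child = _replace_at(a, path, donor)
    return child if tree_depth(child) <= max_depth else a


def evolve(features: pd.DataFrame, labels, config: GPConfig,
           *, metabolites: Sequence[str] | None = None,
           snps: Sequence[str] | None = None) -> GPResult:
    """Run the full best-of-runs evolution.

    ``features`` holds metabolite z-columns and SNP allele-count columns;
    ``metabolites``/``snps`` name which columns are which (by default
    columns whose name contains "rs" or starts with "snp" are treated as
    SNPs).  ``labels`` is the Boolean positive-class indicator.  Within a
    run, each generation builds a new population by tournament selection
    with crossover / subtree mutation / fresh random individuals; the noise
    amplitude falls linearly from ``noise_max`` to zero at the half-way
    generation.  Deterministic under ``config.seed``.
    """
    labels = np.asarray(labels, bool)
    if metabolites is None or snps is None:
        auto_snps = [c for c in features.columns
                     if "rs" in c.lower() or c.lower().startswith("snp")]
        snps = auto_snps if snps is None else list(snps)
        metabolites = ([c for c in features.columns if c not in snps]
                       if metabolites is None else list(metabolites))
    pool = enumerate_operands(metabolites, snps)
    V = operand_matrix(pool, features)
    n_ops = len(pool)
    penalty = config.operand_penalty

    root_rng = np.random.default_rng(config.seed)
    run_seeds = root_rng.integers(0, 2**31 - 1, config.runs)

    best_tree = None
    best_fit = -np.inf
    run_fits = []
    cache: dict = {}

    def noise_free(tree) -> float:
        f = cache.get(tree)
        if f is None:
            f = fitness(tree, V, labels, penalty, 0.0)
            cache[tree] = f
        return f

    for seed in run_seeds:
        rng = np.random.default_rng(seed)
        population = [_random_tree(rng, n_ops, config.max_depth)
                      for _ in range(config.population_size)]
        run_best, run_best_fit = None, -np.inf
        half = max(config.generations // 2, 1)
        for gen in range(config.generations + 1):
            amp = config.noise_max * max(0.0, 1.0 - gen / half)
            scored = np.empty(len(population))
            for i, t in enumerate(population):
                f = noise_free(t)
                if f > run_best_fit:
                    run_best, run_best_fit = t, f
                scored[i] = f + (rng.uniform(0.0, amp) if amp > 0 else 0.0)
            if gen == config.generations:
                break
            new_pop = []
            k = config.tournament_size

            def select():
                idx = rng.integers(len(population), size=k)
                return population[idx[np.argmax(scored[idx])]]

            for _ in range(config.population_size):
                u = rng.random()
                if u < config.p_crossover:
                    child = _crossover(rng, select(), select(), config.max_depth)
                elif u < config.p_crossover + config.p_mutation:
                    child = _mutate(rng, select(), n_ops, config.max_depth)
                else:
                    child = _random_tree(rng, n_ops, config.max_depth)
                new_pop.append(child)
            population = new_pop
        run_fits.append(run_best_fit)
        if run_best_fit > best_fit:
            best_tree, best_fit = run_best, run_best_fit

    acc = per_class_accuracy(predict(best_tree, V), labels)
    return GPResult(tree=best_tree, expression=serialize(best_tree, pool),
                    fitness=best_fit, class_accuracies=acc,
                    operand_count=operand_count(best_tree),
                    run_fitnesses=run_fits)


def kfold_cv(features: pd.DataFrame, labels, config: GPConfig, k: int = 10,
             *, metabolites: Sequence[str] | None = None,
             snps: Sequence[str] | None = None) -> dict:
    """Stratified k-fold cross-validation of the evolved classifier.

    Each fold evolves on the training portion (fold-specific seed derived
    from the config seed) and is scored on the held-out subjects; returns
    mean held-out per-class accuracies and the per-fold values.
    """
    if k < 2:
        raise GPError("k must be >= 2")
    labels = np.asarray(labels, bool)
    n = len(labels)
    rng = np.random.default_rng(config.seed)
    folds = np.empty(n, int)
    for cls in (True, False):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    per_fold = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        res = evolve(features.loc[train], labels[train], cfg,
                     metabolites=metabolites, snps=snps)
        if metabolites is None or snps is None:
            auto_snps = [c for c in features.columns
                         if "rs" in c.lower() or c.lower().startswith("snp")]
            use_snps = auto_snps if snps is None else list(snps)
            use_mets = ([c for c in features.columns if c not in use_snps]
                        if metabolites is None else list(metabolites))
        else:
            use_snps, use_mets = list(snps), list(metabolites)
        pool = enumerate_operands(use_mets, use_snps)
        Vt = operand_matrix(pool, features.loc[test])
        acc = per_class_accuracy(predict(res.tree, Vt), labels[test])
        per_fold.append(acc)
    per_fold = np.asarray(per_fold)
    return {"per_class_accuracy": tuple(per_fold.mean(axis=0)),
            "per_fold": per_fold.tolist()}
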
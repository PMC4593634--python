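"""Inheritable bi-objective combinatorial genetic algorithm for feature
subset selection with co-optimized RBF-SVM parameters.

The algorithm searches C(n, r) subsets for r growing from ``r_start`` to
``r_end``, inheriting the best size-r solution into the size-(r+1) search.
Recombination uses orthogonal-array crossover: the genes on which two
parents differ are assigned to the columns of a two-level orthogonal array,
every array row is evaluated, and per-gene main effects compose one child
while the best evaluated row provides the other.

Each chromosome carries the n feature bits plus two integer genes encoding
the RBF-SVM parameters ``gamma = 2**g`` and ``C = 2**c`` on the grid
``{-7, ..., 8}``.  Fitness is stratified 10-fold cross-validation accuracy
with folds fixed per run, so fitness is a pure (cached) function of the
chromosome within a run.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._fastsvm import fit_predict_precomputed
from .features.extract import FeatureTable

__all__ = ["Chromosome", "GAConfig", "SolutionSet", "FitnessContext",
           "tournament_select", "oa_crossover", "mutate", "inherit",
           "appearance_score", "run_ibcga"]

log = logging.getLogger(__name__)

EXP_MIN, EXP_MAX = -7, 8  # gamma/C exponent grid: 2**-7 .. 2**8


@dataclass
class Chromosome:
    bits: np.ndarray  # uint8 feature genes
    g: int  # gamma exponent
    c: int  # cost exponent
    fitness: float | None = None

    def copy(self) -> "Chromosome":
        return Chromosome(self.bits.copy(), self.g, self.c, self.fitness)

    @property
    def r(self) -> int:
        return int(self.bits.sum())

    def key(self) -> tuple:
        return (self.bits.tobytes(), self.g, self.c)

    def sort_key(self) -> tuple:
        # deterministic ranking: fitness desc, then fewer features, then lexicographic
        return (-(self.fitness or 0.0), self.r, self.bits.tobytes(), self.g, self.c)


@dataclass
class GAConfig:
    r_start: int = 2
    r_end: int = 30
    n_pop: int = 60
    p_c: float = 0.8
    p_m: float = 0.05
    g_max: int = 60
    n_runs: int = 30
    rng_seed: int = 0
    fitness_folds: int = 10
    lambda_appearance: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.p_c < 1 and 0 < self.p_m < 1):
            raise ValueError("p_c and p_m must lie in (0, 1)")
        if self.r_start < 1 or self.r_end < self.r_start:
            raise ValueError("need 1 <= r_start <= r_end")


class FitnessContext:
    """Precomputed state for fitness evaluation on one table within one run.

    Features are z-scored once on the full candidate table; per-feature
    squared-difference matrices allow O(n^2) assembly of the RBF kernel for
    any subset.  Folds are stratified and fixed at construction.
    """

    def __init__(self, table: FeatureTable, n_folds: int = 10,
                 rng: np.random.Generator | None = None):
        X = table.X.to_numpy(dtype=np.float64)
        self.y = np.asarray(
            (table.labels == sorted(table.labels.unique())[-1]).to_numpy(), dtype=int)
        if len(np.unique(self.y)) < 2:
            raise ValueError("fitness requires both classes")
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        self.D = (Z.T[:, :, None] - Z.T[:, None, :]) ** 2  # (n_feat, N, N)
        self.n_samples = len(self.y)
        n_folds_eff = min(n_folds, self.n_samples)
        if n_folds_eff < n_folds:
            log.warning("reducing folds from %d to %d", n_folds, n_folds_eff)
        self.folds = self._stratified_folds(n_folds_eff, rng or np.random.default_rng(0))
        self.cache: dict = {}
        self.n_evals = 0

    def _stratified_folds(self, k: int, rng: np.random.Generator):
        fold_of = np.empty(self.n_samples, dtype=int)
        pos = 0
        for cls in (0, 1):
            idx = np.flatnonzero(self.y == cls)
            rng.shuffle(idx)
            for i, s in enumerate(idx):
                fold_of[s] = (pos + i) % k
            pos += len(idx)
        return [(np.flatnonzero(fold_of != f), np.flatnonzero(fold_of == f))
                for f in range(k)]

    def fitness(self, chrom: Chromosome) -> float:
        key = chrom.key()
        hit = self.cache.get(key)
        if hit is not None:
            chrom.fitness = hit
            return hit
        if chrom.bits.sum() == 0:
            raise ValueError("chromosome selects no features")
        W = np.tensordot(chrom.bits.astype(np.float64), self.D, axes=1)
        K = np.exp(-(2.0 ** chrom.g) * W)
        C = 2.0 ** chrom.c
        correct = 0
        for tr, te in self.folds:
            if len(te) == 0:
                continue
            pred = fit_predict_precomputed(K[np.ix_(tr, tr)], self.y[tr],
                                           K[np.ix_(te, tr)], C)
            correct += int((pred == self.y[te]).sum())
        acc = correct / self.n_samples
        self.cache[key] = acc
        self.n_evals += 1
        chrom.fitness = acc
        return acc


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def random_chromosome(n: int, r: int, rng: np.random.Generator) -> Chromosome:
    bits = np.zeros(n, dtype=np.uint8)
    bits[rng.choice(n, size=r, replace=False)] = 1
    return Chromosome(bits, int(rng.integers(EXP_MIN, EXP_MAX + 1)),
                      int(rng.integers(EXP_MIN, EXP_MAX + 1)))


def tournament_select(population: list, rng: np.random.Generator,
                      n_winners: int | None = None) -> list:
    """Size-2 tournaments with replacement; the first-drawn wins ties."""
    n_winners = n_winners or len(population)
    pool = []
    for _ in range(n_winners):
        a, b = rng.integers(0, len(population), size=2)
        pa, pb = population[a], population[b]
        pool.append((pa if pa.fitness >= pb.fitness else pb).copy())
    return pool


def _repair_bits(bits: np.ndarray, r: int, rng: np.random.Generator,
                 preference: np.ndarray | None = None) -> np.ndarray:
    """Flip bits until exactly ``r`` ones.  With ``preference`` (higher =
    keep as 1), surplus ones with the lowest preference are dropped and
    deficits are filled from the highest-preference zeros; otherwise flips
    are random."""
    bits = bits.copy()
    ones = np.flatnonzero(bits == 1)
    zeros = np.flatnonzero(bits == 0)
    excess = len(ones) - r
    if excess > 0:
        if preference is not None:
            drop = ones[np.argsort(preference[ones], kind="stable")[:excess]]
        else:
            drop = rng.choice(ones, size=excess, replace=False)
        bits[drop] = 0
    elif excess < 0:
        need = -excess
        if preference is not None:
            add = zeros[np.argsort(-preference[zeros], kind="stable")[:need]]
        else:
            add = rng.choice(zeros, size=need, replace=False)
        bits[add] = 1
    return bits


def _oa_table(n_factors: int) -> np.ndarray:
    """Two-level orthogonal array L_{2^k} with ``n_factors`` columns."""
    k = max(1, math.ceil(math.log2(n_factors + 1)))
    rows = 2**k
    cols = np.arange(1, n_factors + 1)
    i = np.arange(rows)
    # entry = parity of popcount(row & column-id)
    return (np.bitwise_count(i[:, None] & cols[None, :]) & 1).astype(np.uint8)


def oa_crossover(p1: Chromosome, p2: Chromosome, ctx: FitnessContext,
                 rng: np.random.Generator) -> tuple[Chromosome, Chromosome]:
    """Orthogonal-array crossover over the genes on which the parents differ.

    Factors cover the differing feature bits plus the gamma/cost genes when
    they differ.  Every OA row is repaired to the parents' bit count and
    evaluated; per-factor main effects compose child 1, while child 2 is the
    best evaluated row.
    """
    r = p1.r
    diff = np.flatnonzero(p1.bits != p2.bits)
    param_factors = [name for name, a, b in (("g", p1.g, p2.g), ("c", p1.c, p2.c))
                     if a != b]
    d = len(diff) + len(param_factors)
    if d == 0:
        return p1.copy(), p2.copy()
    OA = _oa_table(d)

    def build(levels: np.ndarray, preference: np.ndarray | None) -> Chromosome:
        bits = p1.bits.copy()
        bit_levels = levels[:len(diff)]
        bits[diff[bit_levels == 1]] = p2.bits[diff[bit_levels == 1]]
        bits[diff[bit_levels == 0]] = p1.bits[diff[bit_levels == 0]]
        g, c = p1.g, p1.c
        for f_idx, name in enumerate(param_factors):
            lvl = levels[len(diff) + f_idx]
            if name == "g":
                g = p2.g if lvl else p1.g
            else:
                c = p2.c if lvl else p1.c
        bits = _repair_bits(bits, r, rng, preference)
        return Chromosome(bits, g, c)

    children = []
    fits = np.empty(len(OA))
    for row_idx, levels in enumerate(OA):
        child = build(levels, None)
        fits[row_idx] = ctx.fitness(child)
        children.append(child)

    # per-factor main effects: mean fitness at level 1 minus level 0
    effects = np.array([fits[OA[:, f] == 1].mean() - fits[OA[:, f] == 0].mean()
                        for f in range(d)])
    best_levels = (effects > 0).astype(np.uint8)
    # preference for repair: keep bits whose chosen level carries a strong effect
    pref = np.zeros(len(p1.bits))
    for f, pos in enumerate(diff):
        target = p2.bits[pos] if best_levels[f] else p1.bits[pos]
        pref[pos] = abs(effects[f]) if target == 1 else -abs(effects[f])
    main_child = build(best_levels, pref)
    ctx.fitness(main_child)
    best_row = min(children, key=lambda ch: ch.sort_key())
    return main_child, best_row.copy()


def mutate(chrom: Chromosome, p_m: float, rng: np.random.Generator) -> Chromosome:
    """Swap mutation preserving the bit count; ``p_m = 0`` is the identity.

    One randomly selected 1-gene and 0-gene exchange values; each parameter
    gene moves one grid step (either direction) with probability ``p_m``.
    """
    out = chrom.copy()
    if p_m <= 0:
        return out
    ones = np.flatnonzero(out.bits == 1)
    zeros = np.flatnonzero(out.bits == 0)
    if len(ones) and len(zeros):
        i = rng.choice(ones)
        j = rng.choice(zeros)
        out.bits[i], out.bits[j] = 0, 1
    for attr in ("g", "c"):
        if rng.random() < p_m:
            step = int(rng.choice((-1, 1)))
            setattr(out, attr, int(np.clip(getattr(out, attr) + step, EXP_MIN, EXP_MAX)))
    out.fitness = None
    return out


def inherit(solution: Chromosome, n_pop: int, rng: np.random.Generator) -> list:
    """Population for r+1: copies of the solution, each with one 0->1 flip."""
    zeros = np.flatnonzero(solution.bits == 0)
    if len(zeros) == 0:
        raise ValueError("cannot inherit: all features already selected")
    pop = []
    for _ in range(n_pop):
        child = solution.copy()
        child.bits[rng.choice(zeros)] = 1
        child.fitness = None
        pop.append(child)
    return pop


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def _evolve(population: list, ctx: FitnessContext, config: GAConfig,
            rng: np.random.Generator) -> Chromosome:
    """Run g_max generations at fixed r; returns the best chromosome."""
    for chrom in population:
        ctx.fitness(chrom)
    best = min(population, key=lambda c: c.sort_key()).copy()
    for _ in range(config.g_max):
        pool = tournament_select(population, rng, config.n_pop)
        n_parents = int(round(config.p_c * config.n_pop)) // 2 * 2
        for k in range(0, n_parents, 2):
            c1, c2 = oa_crossover(pool[k], pool[k + 1], ctx, rng)
            pool[k], pool[k + 1] = c1, c2
        # mutation: p_m * n_pop random individuals, elite exempt
        best_idx = int(np.argmin([c.sort_key() for c in pool]))
        n_mut = int(round(config.p_m * config.n_pop))
        candidates = [i for i in range(config.n_pop) if i != best_idx]
        for i in rng.choice(candidates, size=min(n_mut, len(candidates)), replace=False):
            pool[i] = mutate(pool[i], config.p_m, rng)
        for chrom in pool:
            ctx.fitness(chrom)
        gen_best = min(pool, key=lambda c: c.sort_key())
        if gen_best.fitness < best.fitness:  # elitism: best never lost
            worst = int(np.argmin([c.fitness for c in pool]))
            pool[worst] = best.copy()
        else:
            best = gen_best.copy()
        population[:] = pool
    return best


@dataclass
class SolutionSet:
    feature_names: list
    per_run: list  # list (len R) of dict r -> Chromosome
    candidates: list  # best chromosome of each run
    appearance: dict  # run index -> appearance score of its candidate
    robust: Chromosome
    accurate: Chromosome
    counts: dict  # feature name -> selection count across R candidates
    n_evaluations: int
    config: GAConfig

    def selected_names(self, chrom: Chromosome | None = None) -> list:
        chrom = chrom or self.robust
        return [self.feature_names[i] for i in np.flatnonzero(chrom.bits)]

    def to_json(self, path) -> None:
        def enc(ch: Chromosome) -> dict:
            return {"bits": [int(b) for b in ch.bits], "g": ch.g, "c": ch.c,
                    "fitness": ch.fitness,
                    "features": self.selected_names(ch)}
        payload = {
            "feature_names": self.feature_names,
            "per_run": [{str(r): enc(ch) for r, ch in run.items()}
                        for run in self.per_run],
            "candidates": [enc(ch) for ch in self.candidates],
            "appearance": {str(k): v for k, v in self.appearance.items()},
            "robust": enc(self.robust),
            "accurate": enc(self.accurate),
            "counts": self.counts,
            "n_evaluations": self.n_evaluations,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def appearance_score(candidates: list, n_features: int,
                     lam: float = 0.1) -> tuple[np.ndarray, list]:
    """Score = fitness + lam * mean per-feature selection frequency.

    Frequency of a feature is the fraction of the R candidate solutions that
    selected it; a solution's frequency term averages over its features.
    """
    R = len(candidates)
    counts = np.zeros(n_features)
    for ch in candidates:
        counts += ch.bits
    scores = []
    for ch in candidates:
        sel = np.flatnonzero(ch.bits)
        freq = counts[sel].mean() / R if len(sel) else 0.0
        scores.append(ch.fitness + lam * freq)
    return counts, scores


def run_ibcga(table: FeatureTable, config: GAConfig | None = None,
              context_factory=None) -> SolutionSet:
    """Full algorithm: R independent runs, each sweeping r from r_start to
    r_end; returns the most accurate and the robust (appearance-score)
    solutions.  Fully reproducible from ``config.rng_seed``.

    ``context_factory(table, n_folds, rng)`` may replace the default
    :class:`FitnessContext` construction (e.g. to pin CV folds when
    comparing against an exhaustive-search oracle).
    """
    config = config or GAConfig()
    context_factory = context_factory or FitnessContext
    n = len(table.feature_names)
    if config.r_end > n:
        raise ValueError(f"r_end = {config.r_end} exceeds feature count {n}")
    seed_seq = np.random.SeedSequence(config.rng_seed)
    run_seeds = seed_seq.spawn(config.n_runs)
    per_run = []
    candidates = []
    total_evals = 0
    for run_idx in range(config.n_runs):
        rng = np.random.default_rng(run_seeds[run_idx])
        ctx = context_factory(table, config.fitness_folds, rng)
        population = [random_chromosome(n, config.r_start, rng)
                      for _ in range(config.n_pop)]
        solutions: dict[int, Chromosome] = {}
        for r in range(config.r_start, config.r_end + 1):
            best = _evolve(population, ctx, config, rng)
            solutions[r] = best
            if r < config.r_end:
                population = inherit(best, config.n_pop, rng)
        per_run.append(solutions)
        candidates.append(min(solutions.values(), key=lambda c: c.sort_key()).copy())
        total_evals += ctx.n_evals
    counts, scores = appearance_score(candidates, n, config.lambda_appearance)
    order = sorted(range(len(candidates)),
                   key=lambda i: (-scores[i],) + candidates[i].sort_key())
    robust = candidates[order[0]].copy()
    accurate = min(candidates, key=lambda c: c.sort_key()).copy()
    return SolutionSet(
        feature_names=table.feature_names,
        per_run=per_run,
        candidates=candidates,
        appearance={i: scores[i] for i in range(len(scores))},
        robust=robust,
        accurate=accurate,
        counts={table.feature_names[i]: int(counts[i]) for i in range(n)},
        n_evaluations=total_evals,
        config=config,
    )
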
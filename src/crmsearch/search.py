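"""Genetic-algorithm search for K minimally overlapping discriminative modules.

Candidate modules (sets of feature types) evolve under the discriminative
fitness C+/C- (the coverage ratio on the positive vs negative promoter
set, with a half-count correction 1/(2 N-) when a module never occurs on
a negative).  The population is seeded with every feature pair, mutated by
exchanging, adding or deleting one feature or merging two modules, and
truncated elitistically.  Every ``selection_interval`` mutations the best
``pool_size`` modules are candidates for the K-module selection: the
K-subset minimizing the total pairwise support-sequence overlap on the
positive set.  The search stops once the selected K-set is unchanged for
``convergence_rounds`` consecutive selections.

The overlap-minimal selection is exact (subset enumeration with memoized
pairwise overlaps) for pools up to 25 modules and falls back to greedy
forward selection with single-swap refinement for larger pools.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence as TypingSequence

import numpy as np
from scipy import stats as sps

from .core import (CoverageStats, InputError, InstanceIndex, Module,
                   SequenceSet, Support, module_overlap, module_supports)
from .pwm import effective_negative_coverage

__all__ = [
    "GaConfig",
    "SearchState",
    "SearchResult",
    "MultiRunResult",
    "GeneticSearch",
    "run_search",
    "multi_run",
    "select_k_min_overlap",
    "module_pvalue",
    "jaccard_matrix",
]

logger = logging.getLogger(__name__)

#: default mutation operator probabilities
OPERATOR_PROBS = {"exchange": 0.4, "add": 0.2, "delete": 0.2, "merge": 0.2}


@dataclass
class GaConfig:
    """Genetic-algorithm settings.

    The production defaults follow the published procedure (selection every
    10^6 mutations, convergence after 100 unchanged rounds); the
    ``scaled()`` profile (10^3 mutations per round, 10 rounds) keeps desk
    runs and the test suite fast.
    """

    k: int = 5
    population_size: int = 200
    selection_interval: int = 10 ** 6
    convergence_rounds: int = 100
    max_features: int = 6
    pool_size: int = 20
    max_rounds: int = 500
    operator_probs: dict = field(default_factory=lambda: dict(OPERATOR_PROBS))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.pool_size < self.k:
            raise InputError("require k >= 1 and pool_size >= k")
        for name in ("population_size", "selection_interval",
                     "convergence_rounds", "max_features", "max_rounds"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be positive")

    @classmethod
    def scaled(cls, **kw) -> "GaConfig":
        """Desk-scale profile: 10^3 mutations per round, 10 unchanged rounds."""
        kw.setdefault("selection_interval", 1000)
        kw.setdefault("convergence_rounds", 10)
        kw.setdefault("max_rounds", 200)
        return cls(**kw)


@dataclass
class SearchState:
    """Mutable GA state: population, current selection, counters."""

    population: list[frozenset[str]] = field(default_factory=list)
    selected: tuple[tuple[str, ...], ...] = ()
    rounds_unchanged: int = 0
    mutations_done: int = 0
    log: list[dict] = field(default_factory=list)


@dataclass
class SearchResult:
    """Outcome of one GA run: the K selected modules plus the round trace."""

    modules: list[Module]
    state: SearchState
    config: GaConfig
    converged: bool

    @property
    def selected_feature_sets(self) -> list[frozenset[str]]:
        return [m.features for m in self.modules]


@dataclass
class MultiRunResult:
    """Concatenation of R independent runs (R x K modules before dedup)."""

    runs: list[SearchResult]
    modules: list[Module]           # all R*K modules, run order
    unique_modules: list[Module]    # deduplicated by feature set
    feature_jaccard: np.ndarray     # over unique modules' feature sets
    support_jaccard: np.ndarray     # over unique modules' support bp

    @property
    def n_before_dedup(self) -> int:
        return len(self.modules)


def module_pvalue(n_pos_covered: int, n_pos: int, rate_rand: float,
                  n_rand: Optional[int] = None) -> float:
    """Binomial tail probability of the observed positive-set coverage.

    P(X >= n_pos_covered) with n_pos trials and per-sequence success
    probability equal to the module's presence rate on the random set
    (half-count corrected when zero and the random set size is known).
    """
    if not (0 <= n_pos_covered <= n_pos):
        raise InputError("invalid coverage count")
    p = rate_rand
    if p <= 0:
        if n_rand is None:
            p = 0.0
        else:
            p = 1.0 / (2 * n_rand)
    if n_pos_covered == 0:
        return 1.0
    return float(sps.binom.sf(n_pos_covered - 1, n_pos, p))


def jaccard_matrix(sets: TypingSequence[frozenset]) -> np.ndarray:
    n = len(sets)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            out[i, j] = out[j, i] = (len(sets[i] & sets[j]) / union) if union else 1.0
    return out


def _support_jaccard(sup1: dict[str, Support], sup2: dict[str, Support]) -> float:
    inter = module_overlap(sup1, sup2)
    len1 = sum(s.length for s in sup1.values())
    len2 = sum(s.length for s in sup2.values())
    union = len1 + len2 - inter
    return inter / union if union else 1.0


def select_k_min_overlap(pool: TypingSequence[Module], k: int
                         ) -> tuple[list[Module], bool]:
    """The K-subset of the pool with minimal total pairwise support overlap.

    Exact subset enumeration for pools up to 25 modules, greedy forward
    selection plus single-swap refinement beyond that.  Ties break toward
    higher summed fitness, then lexicographically smaller feature-id
    tuples.  Returns ``(modules, flagged)`` where ``flagged`` is True when
    the pool held fewer than K modules and was returned whole.
    """
    if len(pool) < k:
        return list(pool), True
    m = len(pool)
    ov = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ov[i, j] = ov[j, i] = module_overlap(pool[i].supports,
                                                 pool[j].supports)
    fitness = np.array([mod.fitness for mod in pool])
    keys = [mod.sorted_features() for mod in pool]

    def subset_key(idx: tuple[int, ...]) -> tuple:
        total = sum(ov[a, b] for a, b in itertools.combinations(idx, 2))
        return (total, -fitness[list(idx)].sum(),
                tuple(sorted(keys[i] for i in idx)))

    if m <= 25:
        best = min(itertools.combinations(range(m), k), key=subset_key)
        return [pool[i] for i in sorted(best)], False

    # greedy forward selection: seed with the highest-fitness module, then
    # repeatedly add the module with minimal added overlap
    order = sorted(range(m), key=lambda i: (-fitness[i], keys[i]))
    chosen = [order[0]]
    while len(chosen) < k:
        cand = min((i for i in order if i not in chosen),
                   key=lambda i: (ov[i, chosen].sum(), -fitness[i], keys[i]))
        chosen.append(cand)
    # single-swap refinement to a local optimum
    improved = True
    while improved:
        improved = False
        current = subset_key(tuple(chosen))
        for out_i in list(chosen):
            for in_i in range(m):
                if in_i in chosen:
                    continue
                trial = tuple(sorted(set(chosen) - {out_i} | {in_i}))
                if subset_key(trial) < current:
                    chosen = list(trial)
                    current = subset_key(tuple(chosen))
                    improved = True
    return [pool[i] for i in sorted(chosen)], False


class GeneticSearch:
    """GA engine over a fixed feature universe with precomputed coverage.

    Presence of each feature on each sequence is precomputed as boolean
    matrices, so evaluating a candidate module is a row-AND.  Support
    intervals (needed only for the K-selection) are computed lazily and
    memoized per feature set.
    """

    def __init__(self, features: Iterable[str], pos: SequenceSet,
                 neg: SequenceSet, index: InstanceIndex,
                 config: Optional[GaConfig] = None,
                 rand: Optional[SequenceSet] = None):
        self.features = sorted(set(features))
        if len(self.features) < 2:
            raise InputError("need at least 2 feature types")
        self.pos, self.neg, self.rand = pos, neg, rand
        self.index = index
        self.config = config or GaConfig()
        self.rng = np.random.default_rng(self.config.rng_seed)

        self._feat_idx = {f: i for i, f in enumerate(self.features)}
        self.p_pos = self._presence(pos)
        self.p_neg = self._presence(neg)
        self.p_rand = self._presence(rand) if rand is not None else None
        if not self.p_pos.any():
            raise InputError("no feature covers any positive sequence")
        self._eval_cache: dict[frozenset[str], tuple[float, float, float]] = {}
        self._support_cache: dict[frozenset[str], dict[str, Support]] = {}

    def _presence(self, sset: SequenceSet) -> np.ndarray:
        mat = np.zeros((len(self.features), sset.N), dtype=bool)
        for fi, f in enumerate(self.features):
            covered = self.index.seqs_with(f)
            for si, seq_id in enumerate(sset.ids):
                mat[fi, si] = seq_id in covered
        return mat

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, feats: frozenset[str]) -> tuple[float, float, float]:
        """(C+, C-, fitness) of a feature set, memoized."""
        cached = self._eval_cache.get(feats)
        if cached is not None:
            return cached
        rows = [self._feat_idx[f] for f in feats]
        c_pos = float(self.p_pos[rows].all(axis=0).mean())
        c_neg = float(self.p_neg[rows].all(axis=0).mean())
        fit = c_pos / effective_negative_coverage(c_neg, self.neg.N)
        self._eval_cache[feats] = (c_pos, c_neg, fit)
        return c_pos, c_neg, fit

    def fitness(self, feats: frozenset[str]) -> float:
        return self.evaluate(feats)[2]

    def supports(self, feats: frozenset[str]) -> dict[str, Support]:
        sup = self._support_cache.get(feats)
        if sup is None:
            sup = module_supports(feats, self.pos, self.index)
            self._support_cache[feats] = sup
        return sup

    def _sort_key(self, feats: frozenset[str]):
        # fitness descending, then parsimony (fewer members), then ids
        return (-self.fitness(feats), len(feats), tuple(sorted(feats)))

    # -- population ---------------------------------------------------------

    def initial_population(self) -> list[frozenset[str]]:
        """All unordered feature pairs, fitness-sorted and truncated."""
        pairs = [frozenset(p) for p in
                 itertools.combinations(self.features, 2)]
        pairs.sort(key=self._sort_key)
        return pairs[: self.config.population_size]

    def _choose_parent(self, population: list[frozenset[str]]) -> frozenset[str]:
        fits = np.array([self.fitness(m) for m in population])
        total = fits.sum()
        if total <= 0:
            i = int(self.rng.integers(0, len(population)))
        else:
            i = int(self.rng.choice(len(population), p=fits / total))
        return population[i]

    def mutate(self, module: frozenset[str],
               population: list[frozenset[str]]) -> frozenset[str]:
        """Apply one mutation operator; impossible operators are resampled."""
        ops = list(self.config.operator_probs)
        probs = np.array([self.config.operator_probs[o] for o in ops])
        probs = probs / probs.sum()
        others = [f for f in self.features if f not in module]
        for _ in range(20):
            op = ops[int(self.rng.choice(len(ops), p=probs))]
            if op == "exchange" and others and len(module) >= 1:
                out = sorted(module)[int(self.rng.integers(0, len(module)))]
                new = module - {out} | {others[int(self.rng.integers(0, len(others)))]}
            elif op == "add" and others and len(module) < self.config.max_features:
                new = module | {others[int(self.rng.integers(0, len(others)))]}
            elif op == "delete" and len(module) > 1:
                out = sorted(module)[int(self.rng.integers(0, len(module)))]
                new = module - {out}
            elif op == "merge" and population:
                partner = self._choose_parent(population)
                new = module | partner
                if len(new) > self.config.max_features:
                    continue
            else:
                continue
            if new != module and 1 <= len(new) <= self.config.max_features:
                return new
        return module

    # -- main loop ----------------------------------------------------------

    def _build_module(self, feats: frozenset[str]) -> Module:
        c_pos, c_neg, fit = self.evaluate(feats)
        stats = CoverageStats(c_pos=c_pos, c_neg=c_neg)
        pval = None
        if self.p_rand is not None:
            rows = [self._feat_idx[f] for f in feats]
            c_rand = float(self.p_rand[rows].all(axis=0).mean())
            stats.c_rand = c_rand
            n_cov = int(round(c_pos * self.pos.N))
            pval = module_pvalue(n_cov, self.pos.N, c_rand, self.rand.N)
        return Module(features=feats, supports=self.supports(feats),
                      stats=stats, fitness=fit, pvalue=pval)

    def _select(self, population: list[frozenset[str]]) -> tuple[list[Module], bool]:
        pool_sets = population[: self.config.pool_size]
        pool = [self._build_module(f) for f in pool_sets]
        return select_k_min_overlap(pool, self.config.k)

    def run(self) -> SearchResult:
        cfg = self.config
        state = SearchState(population=self.initial_population())
        pop = state.population
        pop_set = set(pop)
        prev_selected: Optional[tuple] = None
        converged = False
        rounds = 0
        while rounds < cfg.max_rounds:
            for _ in range(cfg.selection_interval):
                parent = self._choose_parent(pop)
                child = self.mutate(parent, pop)
                state.mutations_done += 1
                if child not in pop_set:
                    pop.append(child)
                    pop.sort(key=self._sort_key)
                    if len(pop) > cfg.population_size:
                        dropped = pop.pop()
                        pop_set.discard(dropped)
                    pop_set.add(child)
            rounds += 1
            selected_modules, flagged = self._select(pop)
            selected_key = tuple(m.sorted_features() for m in selected_modules)
            if selected_key == prev_selected:
                state.rounds_unchanged += 1
            else:
                state.rounds_unchanged = 0
                prev_selected = selected_key
            state.selected = selected_key
            state.log.append({
                "round": rounds,
                "mutations": state.mutations_done,
                "best_fitness": self.fitness(pop[0]),
                "selected": [list(t) for t in selected_key],
                "rounds_unchanged": state.rounds_unchanged,
                "pool_flagged": flagged,
            })
            logger.info("round %d: best fitness %.3g, unchanged %d",
                        rounds, self.fitness(pop[0]), state.rounds_unchanged)
            if state.rounds_unchanged >= cfg.convergence_rounds:
                converged = True
                break
        modules = [self._build_module(frozenset(t)) for t in state.selected]
        state.population = pop
        return SearchResult(modules=modules, state=state, config=cfg,
                            converged=converged)


def run_search(features: Iterable[str], pos: SequenceSet, neg: SequenceSet,
               index: InstanceIndex, config: Optional[GaConfig] = None,
               rand: Optional[SequenceSet] = None) -> SearchResult:
    """One GA run; see :class:`GeneticSearch`."""
    return GeneticSearch(features, pos, neg, index, config=config,
                         rand=rand).run()


def multi_run(features: Iterable[str], pos: SequenceSet, neg: SequenceSet,
              index: InstanceIndex, config: Optional[GaConfig] = None,
              rand: Optional[SequenceSet] = None, runs: int = 4) -> MultiRunResult:
    """R independent GA runs; concatenate, deduplicate, and report similarity.

    Deduplication of identical modules is automatic; grouping of merely
    *similar* modules (OR logic) remains a manual step supported by the
    emitted Jaccard matrices over feature sets and support sequences.
    """
    base = config or GaConfig()
    seeds = np.random.SeedSequence(base.rng_seed).generate_state(runs) % (2 ** 31)
    results = []
    for r in range(runs):
        cfg_r = GaConfig(**{**base.__dict__,
                            "operator_probs": dict(base.operator_probs),
                            "rng_seed": int(seeds[r])})
        results.append(GeneticSearch(features, pos, neg, index,
                                     config=cfg_r, rand=rand).run())
    modules = [m for res in results for m in res.modules]
    unique: dict[frozenset[str], Module] = {}
    for m in modules:
        unique.setdefault(m.features, m)
    uniq = list(unique.values())
    fj = jaccard_matrix([m.features for m in uniq])
    sj = np.eye(len(uniq))
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            sj[i, j] = sj[j, i] = _support_jaccard(uniq[i].supports,
                                                   uniq[j].supports)
    return MultiRunResult(runs=results, modules=modules, unique_modules=uniq,
                          feature_jaccard=fj, support_jaccard=sj)
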
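"""GA fitness, mutation operators, K-selection and the full search loop."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from crmsearch.core import (InputError, InstanceIndex, Module, Support,
                            module_supports)
from crmsearch.search import (GaConfig, GeneticSearch, module_pvalue,
                              multi_run, run_search, select_k_min_overlap)

from conftest import index_of, inst, make_set, random_dna
import oracles


def toy_engine(n_feat=4, n_pos=4, n_neg=6, seed=1, placement=None, **ga_kw):
    """A small engine over fully controllable feature placements.

    placement: dict feature -> {set_label: [(seq_index, start), ...]}.
    Default: feature f_i covers positives 0..i and one negative.
    """
    pos = make_set("positive", [(f"p{i}", "A" * 200) for i in range(n_pos)])
    neg = make_set("negative", [(f"n{i}", "A" * 200) for i in range(n_neg)])
    instances = []
    if placement is None:
        placement = {}
        for fi in range(n_feat):
            placement[f"f{fi}"] = {
                "p": [(j, 10 * fi) for j in range(min(fi + 1, n_pos))],
                "n": [(fi % n_neg, 10 * fi)],
            }
    for fid, where in placement.items():
        for label, entries in where.items():
            for si, start in entries:
                instances.append(inst(f"{label}{si}", start, start + 8, fid))
    idx = index_of(instances)
    ga_kw.setdefault("k", 2)
    ga_kw.setdefault("pool_size", 4)
    ga_kw.setdefault("rng_seed", seed)
    cfg = GaConfig.scaled(**ga_kw)
    return GeneticSearch(sorted(placement), pos, neg, idx, config=cfg)


class TestFitness:
    def test_coverage_ratio(self):
        eng = toy_engine(placement={
            "a": {"p": [(0, 0), (1, 0), (2, 0), (3, 0)], "n": [(0, 0)]},
            "b": {"p": [(0, 20)], "n": []},
        }, n_pos=4, n_neg=10)
        c_pos, c_neg, fit = eng.evaluate(frozenset(["a"]))
        assert (c_pos, c_neg) == (1.0, 0.1)
        assert fit == pytest.approx(10.0)

    def test_zero_positive_coverage(self):
        eng = toy_engine(placement={
            "a": {"p": [], "n": [(0, 0)]},
            "b": {"p": [(0, 0)], "n": []},
        })
        assert eng.fitness(frozenset(["a"])) == 0.0

    def test_half_count_rule_when_never_on_negatives(self):
        eng = toy_engine(placement={
            "a": {"p": [(0, 0), (1, 0)], "n": []},
            "b": {"p": [(0, 20)], "n": []},
        }, n_pos=4, n_neg=115)
        c_pos, c_neg, fit = eng.evaluate(frozenset(["a"]))
        assert c_neg == 0.0
        assert fit == pytest.approx(0.5 / (1 / 230))


class TestInitialPopulation:
    def test_all_pairs_of_32_features(self):
        placement = {f"f{i:02d}": {"p": [(0, i)], "n": []} for i in range(32)}
        eng = toy_engine(placement=placement, n_pos=2,
                         population_size=600)
        pop = eng.initial_population()
        assert len(pop) == 32 * 31 // 2 == 496

    def test_two_features_one_pair(self):
        eng = toy_engine(placement={
            "a": {"p": [(0, 0)], "n": []},
            "b": {"p": [(0, 20)], "n": []},
        })
        assert eng.initial_population() == [frozenset(["a", "b"])]

    def test_pair_fitness_matches_naive_recount(self, rng):
        eng = toy_engine(n_feat=6)
        seq_ids = eng.pos.ids
        for pair in itertools.combinations(eng.features, 2):
            per_feature = {
                f: [(s, i.start, i.end) for s in seq_ids
                    for i in eng.index.instances_on(f, s)]
                for f in pair}
            want_cpos = oracles.brute_module_coverage(per_feature, seq_ids)
            assert eng.evaluate(frozenset(pair))[0] == pytest.approx(want_cpos)

    def test_too_few_features_rejected(self):
        pos = make_set("p", [("p0", "A" * 50)])
        neg = make_set("n", [("n0", "A" * 50)])
        idx = index_of([inst("p0", 0, 8, "only")])
        with pytest.raises(InputError):
            GeneticSearch(["only"], pos, neg, idx)


class TestMutate:
    def test_delete_leaves_single_member(self):
        eng = toy_engine(n_feat=4, operator_probs={"delete": 1.0})
        out = eng.mutate(frozenset(["f0", "f1"]), eng.initial_population())
        assert out in (frozenset(["f0"]), frozenset(["f1"]))

    def test_merge_is_union(self):
        eng = toy_engine(n_feat=3, operator_probs={"merge": 1.0},
                         max_features=6)
        pop = [frozenset(["f1", "f2"])]
        out = eng.mutate(frozenset(["f0", "f1"]), pop)
        assert out == frozenset(["f0", "f1", "f2"])

    def test_many_mutations_respect_size_bounds(self):
        eng = toy_engine(n_feat=8, max_features=4)
        pop = eng.initial_population()
        m = pop[0]
        for _ in range(10_000):
            m = eng.mutate(m, pop)
            assert 1 <= len(m) <= 4


def _mk_module(feats, supports, fitness):
    return Module(features=frozenset(feats),
                  supports={s: Support(seq=s, start=a, end=b)
                            for s, (a, b) in supports.items()},
                  fitness=fitness)


class TestSelectKMinOverlap:
    def test_disjoint_pair_beats_identical_twins(self):
        twin_sup = {"p0": (0, 100)}
        mods = [_mk_module(["a", "b"], twin_sup, 5.0),
                _mk_module(["a", "c"], twin_sup, 4.0),
                _mk_module(["d", "e"], {"p1": (0, 100)}, 1.0)]
        chosen, flagged = select_k_min_overlap(mods, 2)
        assert not flagged
        assert {m.sorted_features() for m in chosen} == {("a", "b"), ("d", "e")}

    def test_all_disjoint_tie_broken_by_fitness(self):
        mods = [_mk_module([f"x{i}"], {f"p{i}": (0, 50)}, float(i))
                for i in range(5)]
        chosen, _ = select_k_min_overlap(mods, 2)
        assert {m.fitness for m in chosen} == {3.0, 4.0}

    def test_small_pool_returned_whole_and_flagged(self):
        mods = [_mk_module(["a"], {"p0": (0, 10)}, 1.0)]
        chosen, flagged = select_k_min_overlap(mods, 3)
        assert flagged and len(chosen) == 1

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(25):
            m = int(rng.integers(6, 12))
            k = int(rng.integers(2, 5))
            mods = []
            for i in range(m):
                sups = {}
                for sid in range(int(rng.integers(1, 4))):
                    a = int(rng.integers(0, 150))
                    sups[f"p{sid}"] = (a, a + int(rng.integers(10, 80)))
                mods.append(_mk_module([f"f{i}"], sups,
                                       float(rng.integers(1, 50))))
            chosen, _ = select_k_min_overlap(mods, k)
            got = {m.sorted_features()[0] for m in chosen}
            want_idx = oracles.brute_select_k(
                [{s: (v.start, v.end) for s, v in m.supports.items()}
                 for m in mods],
                [m.fitness for m in mods],
                [m.sorted_features() for m in mods], k)
            assert got == {f"f{i}" for i in want_idx}

    def test_invariant_to_pool_ordering(self, rng):
        mods = []
        for i in range(8):
            a = int(rng.integers(0, 100))
            mods.append(_mk_module([f"f{i}"], {"p0": (a, a + 40)},
                                   float(rng.integers(1, 9))))
        ref = {m.sorted_features() for m in select_k_min_overlap(mods, 3)[0]}
        for _ in range(5):
            perm = [mods[i] for i in rng.permutation(8)]
            got = {m.sorted_features() for m in select_k_min_overlap(perm, 3)[0]}
            assert got == ref

    def test_greedy_path_reasonable_on_large_pools(self, rng):
        mods = []
        for i in range(30):  # beyond the exact-enumeration limit
            a = int(rng.integers(0, 400))
            mods.append(_mk_module([f"f{i:02d}"], {"p0": (a, a + 50)}, 1.0))
        chosen, flagged = select_k_min_overlap(mods, 4)
        assert not flagged and len(chosen) == 4


class TestModulePvalue:
    def test_closed_form_all_covered(self):
        assert module_pvalue(13, 13, 0.5) == pytest.approx(0.5 ** 13)
        assert module_pvalue(13, 13, 0.5) == pytest.approx(1.22e-4, rel=1e-2)

    def test_zero_coverage_is_one(self):
        assert module_pvalue(0, 13, 0.3) == 1.0

    def test_matches_direct_summation(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 15))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.05, 0.95))
            assert module_pvalue(k, n, p) == pytest.approx(
                oracles.brute_binom_tail(k, n, p))

    def test_half_count_when_absent_from_random_set(self):
        assert module_pvalue(3, 13, 0.0, n_rand=100) == pytest.approx(
            oracles.brute_binom_tail(3, 13, 1 / 200))


class TestRunSearch:
    def test_elitism_best_fitness_never_decreases(self):
        eng = toy_engine(n_feat=6, selection_interval=100,
                         convergence_rounds=3, max_rounds=6)
        res = eng.run()
        best = [rec["best_fitness"] for rec in res.state.log]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_same_seed_bit_identical(self):
        r1 = toy_engine(n_feat=6, seed=7).run()
        r2 = toy_engine(n_feat=6, seed=7).run()
        assert r1.state.selected == r2.state.selected
        assert r1.state.log == r2.state.log
        r3 = toy_engine(n_feat=6, seed=8).run()
        assert r3.state.mutations_done > 0  # different seed still runs

    def test_selected_never_below_best_singleton_fitness(self):
        # a dominant specific feature: the K=1 selection can only match or
        # exceed its fitness, never pick something worse
        placement = {
            "good": {"p": [(i, 0) for i in range(4)], "n": []},
            "meh": {"p": [(0, 50)], "n": [(i, 0) for i in range(6)]},
            "bad": {"p": [(1, 80)], "n": [(i, 20) for i in range(6)]},
        }
        eng = toy_engine(placement=placement, k=1, pool_size=3,
                         selection_interval=200, convergence_rounds=2)
        res = eng.run()
        assert res.modules[0].fitness >= eng.fitness(frozenset(["good"]))

    def test_no_positive_coverage_rejected(self):
        pos = make_set("p", [("p0", "A" * 50)])
        neg = make_set("n", [("n0", "A" * 50)])
        idx = index_of([inst("n0", 0, 8, "a"), inst("n0", 10, 18, "b")])
        with pytest.raises(InputError):
            GeneticSearch(["a", "b"], pos, neg, idx)

    def test_multi_run_counts_and_similarity(self):
        eng_kw = dict(n_feat=6, selection_interval=60, convergence_rounds=2,
                      max_rounds=4, k=2, pool_size=4)
        eng = toy_engine(**eng_kw)
        res = multi_run(eng.features, eng.pos, eng.neg, eng.index,
                        config=eng.config, runs=3)
        assert res.n_before_dedup == 3 * 2
        n = len(res.unique_modules)
        assert res.feature_jaccard.shape == (n, n)
        assert np.allclose(np.diag(res.feature_jaccard), 1.0)
        assert np.allclose(res.feature_jaccard, res.feature_jaccard.T)
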
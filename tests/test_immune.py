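"""Immune-search operators: balance conservation, elitism, determinism,
and recovery of planted cluster structure."""

import numpy as np
import pytest

from ecgmmc.immune import (Antibody, IEMMCConfig, Population, clone_select,
                           evaluate_antibody, hypermutate, init_population,
                           receptor_edit, recursive_multiclass, reselect,
                           run_iemmc)
from ecgmmc.mmc import KernelSpec, kernel_matrix
from ecgmmc.synthetic import gen_cluster_data


@pytest.fixture(scope="module")
def blob_problem():
    X, y = gen_cluster_data(n=30, k=2, separation=6, dims=2, seed=0)
    cfg = IEMMCConfig()
    K = kernel_matrix(X, KernelSpec("rbf", 3.0))
    return X, y, K, cfg


def make_evaluator(K, cfg, balance):
    return lambda a: evaluate_antibody(K, a, cfg, balance)


class TestInitPopulation:
    def test_balance_distance_and_determinism(self, blob_problem):
        X, _, _, cfg = blob_problem
        n = X.shape[0]
        bal = cfg.resolve_balance(n)
        rng = np.random.default_rng(1)
        pop = init_population(n, cfg, rng)
        assert pop.size == cfg.pop_size
        members = pop.members
        for a in members:
            assert abs(int(a.y.sum())) <= bal
        t_s = cfg.resolve_suppression(n)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                yi = members[i].canonical()
                yj = members[j].canonical()
                assert int(np.sum(yi != yj)) > t_s
        pop2 = init_population(n, cfg, np.random.default_rng(1))
        assert all(np.array_equal(a.y, b.y)
                   for a, b in zip(members, pop2.members))

    def test_infeasible_suppression_raises(self):
        cfg = IEMMCConfig(pop_size=20, suppression=7)
        with pytest.raises(RuntimeError, match="suppression"):
            init_population(8, cfg, np.random.default_rng(0))


class TestCloneSelect:
    def test_rank_proportional_copies(self, blob_problem):
        X, _, K, cfg = blob_problem
        bal = cfg.resolve_balance(X.shape[0])
        ev = make_evaluator(K, cfg, bal)
        pop = init_population(X.shape[0], cfg, np.random.default_rng(2))
        for a in pop.members:
            ev(a)
        clones = clone_select(pop, 5)
        assert len(clones) == 5 + 4 + 3 + 2 + 1
        best = min(pop.remainder, key=lambda a: a.J)
        n_best = sum(np.array_equal(c.y, best.y) for c in clones)
        assert n_best >= 5                     # most copies for the best
        parent_keys = {a.key() for a in pop.remainder}
        assert all(c.key() in parent_keys for c in clones)


class TestHypermutate:
    def test_sum_preserved_and_keep_if_better(self, blob_problem):
        X, _, K, cfg = blob_problem
        n = X.shape[0]
        bal = cfg.resolve_balance(n)
        ev = make_evaluator(K, cfg, bal)
        rng = np.random.default_rng(3)
        pop = init_population(n, cfg, rng)
        for a in pop.members:
            ev(a)
        for rank_frac in (0.0, 0.5, 1.0):
            parent = pop.members[0]
            before = int(parent.y.sum())
            child = hypermutate(parent, rank_frac, f_max=3, rng=rng,
                                evaluator=ev)
            assert int(child.y.sum()) == before
            assert child.J <= parent.J + 1e-12

    def test_seeded_determinism(self, blob_problem):
        X, _, K, cfg = blob_problem
        bal = cfg.resolve_balance(X.shape[0])
        ev = make_evaluator(K, cfg, bal)
        y0 = np.resize([1, -1], X.shape[0])
        a = hypermutate(Antibody(y=y0.copy()), 0.5, 3,
                        np.random.default_rng(9), ev)
        b = hypermutate(Antibody(y=y0.copy()), 0.5, 3,
                        np.random.default_rng(9), ev)
        assert np.array_equal(a.y, b.y)

    def test_one_sided_labeling_rejected(self):
        with pytest.raises(ValueError):
            hypermutate(Antibody(y=np.ones(6, dtype=int)), 0.5, 2,
                        np.random.default_rng(0), lambda a: a)


class TestReselectAndEdit:
    def test_elitism_and_size(self, blob_problem):
        X, _, K, cfg = blob_problem
        n = X.shape[0]
        bal = cfg.resolve_balance(n)
        ev = make_evaluator(K, cfg, bal)
        pop = init_population(n, cfg, np.random.default_rng(4))
        for a in pop.members:
            ev(a)
        best_before = min(a.J for a in pop.members)
        cands = [ev(Antibody(y=np.resize([1, -1], n))) for _ in range(3)]
        out = reselect(pop, cands, cfg)
        assert min(a.J for a in out.members) <= best_before
        assert len(out.memory) == cfg.n_memory
        evaluated = {a.key() for a in pop.members + cands}
        assert all(a.key() in evaluated for a in out.memory)

    def test_receptor_edit_replaces_worst_only(self, blob_problem):
        X, _, K, cfg = blob_problem
        n = X.shape[0]
        bal = cfg.resolve_balance(n)
        ev = make_evaluator(K, cfg, bal)
        pop = init_population(n, cfg, np.random.default_rng(5))
        for a in pop.members:
            ev(a)
        pop = reselect(pop, [], cfg)
        rng = np.random.default_rng(6)
        out = receptor_edit(pop, 0.4, rng, n, bal)
        assert out.memory == pop.memory
        n_replace = int(0.4 * len(pop.remainder))
        survivors = {a.key() for a in out.remainder if a.J is not None}
        worst = sorted(pop.remainder, key=lambda a: a.J)[-n_replace:]
        assert all(w.key() not in survivors for w in worst)
        for a in out.remainder:
            if a.J is None:
                assert abs(int(a.y.sum())) <= bal
        same = receptor_edit(pop, 0.0, rng, n, bal)
        assert same.remainder == pop.remainder


class TestEvaluateAntibody:
    def test_correct_labeling_scores_better_than_scrambled(self,
                                                           blob_problem):
        X, y, K, cfg = blob_problem
        bal = X.shape[0]  # unconstrained for this comparison
        good = evaluate_antibody(K, Antibody(y=y.copy()), cfg, bal)
        rng = np.random.default_rng(7)
        bad = evaluate_antibody(K, Antibody(y=rng.permutation(y)), cfg, bal)
        assert good.J < bad.J and good.F > bad.F

    def test_idempotent(self, blob_problem):
        X, y, K, cfg = blob_problem
        bal = cfg.resolve_balance(X.shape[0])
        a = evaluate_antibody(K, Antibody(y=y.copy()), cfg, bal)
        y1, j1 = a.y.copy(), a.J
        a = evaluate_antibody(K, a, cfg, bal)
        assert np.array_equal(a.y, y1) and a.J == j1

    def test_refined_labeling_respects_balance(self, blob_problem):
        X, _, K, cfg = blob_problem
        n = X.shape[0]
        bal = cfg.resolve_balance(n)
        rng = np.random.default_rng(8)
        for _ in range(5):
            y0 = np.resize([1, -1], n)
            rng.shuffle(y0)
            a = evaluate_antibody(K, Antibody(y=y0), cfg, bal)
            assert abs(int(a.y.sum())) <= bal


class TestRunIEMMC:
    def test_recovers_blobs_and_monotone_history(self):
        X, y = gen_cluster_data(n=60, k=2, separation=6, dims=2, seed=4)
        res = run_iemmc(X, IEMMCConfig(), seed=42)
        agree = max(np.mean(res.y == y), np.mean(res.y == -y))
        assert agree == 1.0
        best = [h["best_F"] for h in res.history]
        assert all(b >= a for a, b in zip(best, best[1:]))

    def test_deterministic(self):
        X, _ = gen_cluster_data(n=24, k=2, separation=4, dims=2, seed=2)
        cfg = IEMMCConfig(max_generations=10, stall=3)
        r1 = run_iemmc(X, cfg, seed=5)
        r2 = run_iemmc(X, cfg, seed=5)
        assert np.array_equal(r1.y, r2.y)
        assert r1.history == r2.history

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            run_iemmc(np.zeros((3, 2)), IEMMCConfig())


class TestRecursiveMulticlass:
    def test_base_case_matches_binary(self):
        X, _ = gen_cluster_data(n=24, k=2, separation=6, dims=2, seed=3)
        cfg = IEMMCConfig(max_generations=15, stall=5)
        labels = recursive_multiclass(X, 2, cfg, seed=1)
        res = run_iemmc(X, cfg, seed=1)
        np.testing.assert_array_equal(labels, np.where(res.y < 0, 2, 1))

    def test_five_separated_blobs_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        X, y = gen_cluster_data(n=250, k=5, separation=8, dims=4, seed=0)
        labels = recursive_multiclass(
            X, 5, IEMMCConfig(init="kmeans"), seed=3)
        assert len(set(labels.tolist())) == 5
        assert set(labels.tolist()) == {1, 2, 3, 4, 5}
        assert adjusted_rand_score(y, labels) >= 0.95

    def test_k_validation(self):
        X, _ = gen_cluster_data(n=10, k=2, seed=0)
        with pytest.raises(ValueError):
            recursive_multiclass(X, 1)
        with pytest.raises(ValueError):
            recursive_multiclass(X, 6)
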
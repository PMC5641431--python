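"""MCMC sampler, convergence diagnostics, consensus, stepping stone, BF."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import betaln

from phylogeo.core import ConstraintSet, PartitionScheme, Tree, bipartitions, \
    satisfies
from phylogeo.engine import (
    MarginalLikelihood, McmcConfig, bayes_factor, consensus,
    random_constrained_tree, run_mcmc, sdsf, stepping_stone,
    stepping_stone_generic,
)
from phylogeo.models import SubstitutionModel
from phylogeo.simulate import simulate_sequences, simulate_yule_tree


def quick_cfg(**kw):
    base = dict(generations=2000, sample_interval=20, n_runs=1, n_chains=1,
                seed=0)
    base.update(kw)
    return McmcConfig(**base)


class TestConstrainedTrees:
    def test_random_tree_satisfies_nested_constraints(self, rng):
        taxa = [f"t{i}" for i in range(10)]
        cs = ConstraintSet("c", [frozenset(taxa[:4]), frozenset(taxa[:2]),
                                 frozenset(taxa[5:8])])
        for seed in range(20):
            t = random_constrained_tree(taxa, cs,
                                        np.random.default_rng(seed))
            assert satisfies(t, cs)
            assert sorted(t.leaf_labels()) == sorted(taxa)

    def test_every_sampled_tree_satisfies_constraints(self):
        true = simulate_yule_tree(6, seed=4)
        mat = simulate_sequences(true, PartitionScheme.single(100, model="JC"),
                                 seed=4)
        labs = true.leaf_labels()
        cs = ConstraintSet("c", [frozenset(labs[:3])])
        post = run_mcmc(mat, PartitionScheme.single(100, model="JC"), cs,
                        quick_cfg(generations=1500))
        trees = post.trees
        assert len(trees) > 10
        assert all(satisfies(t, cs) for t in trees)

    def test_fully_constrained_run_fixes_topology(self):
        true = simulate_yule_tree(6, seed=5)
        mat = simulate_sequences(true, PartitionScheme.single(60, model="JC"),
                                 seed=5)
        cs = ConstraintSet.from_tree(true, "fixed")
        post = run_mcmc(mat, PartitionScheme.single(60, model="JC"), cs,
                        quick_cfg(generations=1000))
        target = bipartitions(true)
        for t in post.trees:
            assert bipartitions(t) == target

    def test_infeasible_start_tree_rejected(self):
        true = simulate_yule_tree(6, seed=6)
        mat = simulate_sequences(true, PartitionScheme.single(50, model="JC"),
                                 seed=6)
        labs = sorted(true.leaf_labels())
        other = Tree.from_newick(
            f"(({labs[0]},{labs[2]}),({labs[1]},{labs[3]}),"
            f"({labs[4]},{labs[5]}));")
        cs = ConstraintSet("c", [frozenset([labs[0], labs[1]])])
        with pytest.raises(Exception, match="violates"):
            run_mcmc(mat, PartitionScheme.single(50, model="JC"), cs,
                     quick_cfg(), start_tree=other)


class TestTopologyRecovery:
    def test_six_taxon_jc_recovery(self):
        """Consensus recovers identifiable generating topologies.

        Trees whose shortest internal branch is below 0.05 expected
        substitutions are skipped: with finite alignments such splits are not
        statistically identifiable, so recovery there says nothing about the
        sampler. On resolvable trees >= 90% of seeds must recover the truth.
        """
        def min_internal(t):
            return min((n.length for n in t.postorder()
                        if not n.is_leaf and n is not t.root), default=0.0)

        hits = 0
        used = 0
        seed = 0
        while used < 10:
            true = simulate_yule_tree(6, seed=seed)
            seed += 1
            if min_internal(true) < 0.05:
                continue
            used += 1
            mat = simulate_sequences(
                true, PartitionScheme.single(1000, model="JC"), seed=seed - 1)
            post = run_mcmc(mat, PartitionScheme.single(1000, model="JC"),
                            None, quick_cfg(generations=5000, n_runs=2,
                                            sample_interval=25, n_chains=2,
                                            seed=seed - 1))
            hits += bipartitions(consensus(post)) == bipartitions(true)
        assert hits >= 9

    def test_two_taxon_branch_length_posterior(self):
        # total path length T = t1 + t2 with t1, t2 ~ iid Exp(10):
        # prior T ~ Gamma(2, 1/10); posterior mean from 1-D quadrature
        true = Tree.from_newick("(A:0.08,B:0.08);")
        model = SubstitutionModel()
        mat = simulate_sequences(true, PartitionScheme.single(300, model="JC"),
                                 seed=9)
        k = sum(a != b for a, b in zip(mat.cells[0], mat.cells[1]))
        n = mat.n_chars

        def like(T):
            psame = 0.25 + 0.75 * math.exp(-4 * T / 3)
            pdiff = (1 - psame) / 3
            return (0.25 ** n) * psame ** (n - k) * (3 * pdiff) ** k

        prior = lambda T: 100 * T * math.exp(-10 * T)
        # split the domain so adaptive quadrature cannot miss the sharp peak
        Z = sum(quad(lambda T: prior(T) * like(T), a, b)[0]
                for a, b in [(0, 0.5), (0.5, 5)])
        mean_T = sum(quad(lambda T: T * prior(T) * like(T), a, b)[0]
                     for a, b in [(0, 0.5), (0.5, 5)]) / Z

        cfg = quick_cfg(generations=20000, sample_interval=10, seed=3)
        post = run_mcmc(mat, PartitionScheme.single(300, model="JC"), None,
                        cfg)
        lengths = np.array([t.total_length() for t in post.trees])
        # SE from 10 batch means to account for autocorrelation
        batches = np.array_split(lengths, 10)
        bm = np.array([b.mean() for b in batches])
        se = bm.std(ddof=1) / math.sqrt(len(bm))
        assert abs(lengths.mean() - mean_T) < 3 * max(se, 1e-4)


class TestSdsf:
    def test_identical_runs_zero(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert sdsf([[t.copy() for _ in range(5)],
                     [t.copy() for _ in range(5)]]) == 0.0

    def test_two_point_sd(self):
        t1 = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = Tree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        # run1 always AB|CD, run2 never: population SD of {1, 0} = 0.5;
        # same for the AC|BD split, so the mean is 0.5
        val = sdsf([[t1.copy() for _ in range(4)],
                    [t2.copy() for _ in range(4)]])
        assert val == pytest.approx(0.5)

    def test_hand_built_three_runs(self):
        t_ab = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t_ac = Tree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        runs = [
            [t_ab.copy()] * 8 + [t_ac.copy()] * 2,   # AB|CD at 0.8, AC|BD 0.2
            [t_ab.copy()] * 6 + [t_ac.copy()] * 4,   # 0.6 / 0.4
            [t_ab.copy()] * 10,                      # 1.0 / 0.0
        ]
        freqs_ab = np.array([0.8, 0.6, 1.0])
        freqs_ac = np.array([0.2, 0.4, 0.0])
        expected = np.mean([freqs_ab.std(), freqs_ac.std()])
        assert sdsf(runs) == pytest.approx(expected, abs=1e-12)

    def test_empty_run_error(self):
        with pytest.raises(Exception, match="empty"):
            sdsf([[], [Tree.from_newick("((A,B),(C,D));")]])


class TestConsensus:
    def test_identical_sample(self):
        t = Tree.from_newick("((A:1,B:2):0.5,(C:1,D:1):0.5);")
        cons = consensus([t.copy() for _ in range(10)])
        assert bipartitions(cons) == bipartitions(t)
        for n in cons.postorder():
            if not n.is_leaf and n.support is not None:
                assert n.support == pytest.approx(1.0)

    def test_majority_split_retained(self):
        t1 = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = Tree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        cons = consensus([t1.copy()] * 6 + [t2.copy()] * 4)
        splits = bipartitions(cons)
        assert frozenset("CD") in splits or frozenset("AB") in splits
        sup = [n.support for n in cons.postorder()
               if not n.is_leaf and n.support is not None]
        assert pytest.approx(0.6) in sup

    def test_matches_bruteforce_greedy(self, rng):
        # independent greedy re-implementation over split count dictionaries
        def oracle(trees):
            taxa = frozenset(trees[0].leaf_labels())
            counts = {}
            for t in trees:
                for s in bipartitions(t):
                    counts[s] = counts.get(s, 0) + 1
            chosen = []

            def compatible(a, b):
                return (not (a & b)) or a <= b or b <= a or (a | b) == taxa

            for s, c in sorted(counts.items(),
                               key=lambda kv: (-kv[1], len(kv[0]),
                                               tuple(sorted(kv[0])))):
                if all(compatible(s, o) for o in chosen):
                    chosen.append(s)
            return frozenset(chosen)

        for seed in range(50):
            trees = [simulate_yule_tree(6, seed=seed * 50 + i)
                     for i in range(7)]
            # relabel so all trees share a taxon set
            cons = consensus(trees)
            assert bipartitions(cons) == oracle(trees), seed


class TestSteppingStone:
    def _bernoulli_kernel(self):
        def lnL(th):
            return 7 * math.log(th) + 3 * math.log(1 - th)

        def kernel(th, beta, rng):
            prop = th + 0.3 * (rng.random() - 0.5)
            if not 0 < prop < 1:
                return th
            if math.log(max(rng.random(), 1e-300)) < beta * (lnL(prop) - lnL(th)):
                return prop
            return th

        return lnL, kernel

    def test_conjugate_beta_bernoulli(self):
        lnL, kernel = self._bernoulli_kernel()
        ml = stepping_stone_generic(lnL, kernel, 0.5, steps=50,
                                    n_per_step=300, seed=11)
        exact = betaln(8, 4) - betaln(1, 1)
        assert abs(ml.log_ml - exact) < 3 * ml.se
        assert ml.log_ml == pytest.approx(ml.contributions.sum())
        assert len(ml.contributions) == 50

    def test_step_doubling_stability(self):
        lnL, kernel = self._bernoulli_kernel()
        ml25 = stepping_stone_generic(lnL, kernel, 0.5, steps=25,
                                      n_per_step=300, seed=12)
        ml50 = stepping_stone_generic(lnL, kernel, 0.5, steps=50,
                                      n_per_step=300, seed=13)
        tol = 3 * math.hypot(ml25.se, ml50.se)
        assert abs(ml25.log_ml - ml50.log_ml) < tol

    def test_empty_data_gives_zero(self):
        _, kernel = self._bernoulli_kernel()
        ml = stepping_stone_generic(lambda s: 0.0, kernel, 0.5, steps=10,
                                    n_per_step=50, seed=14)
        assert ml.log_ml == pytest.approx(0.0, abs=1e-12)

    def test_beta_schedule_spacing(self):
        from phylogeo.engine import _beta_schedule
        b = _beta_schedule(50, 0.3)
        assert b[0] == 1.0 and b[-1] == 0.0
        assert np.all(np.diff(b) < 0)
        assert b[25] == pytest.approx((25 / 50) ** (1 / 0.3))

    def test_phylo_ss_single_branch_quadrature(self):
        # fixed 2-taxon topology, JC, free branch lengths: the marginal
        # likelihood is a 2-D integral that collapses to 1-D in T = t1 + t2
        true = Tree.from_newick("(A:0.1,B:0.1);")
        mat = simulate_sequences(true, PartitionScheme.single(80, model="JC"),
                                 seed=21)
        k = sum(a != b for a, b in zip(mat.cells[0], mat.cells[1]))
        n = mat.n_chars

        def like(T):
            psame = 0.25 + 0.75 * math.exp(-4 * T / 3)
            return (0.25 ** n) * psame ** (n - k) * ((1 - psame) / 3) ** k

        prior = lambda T: 100 * T * math.exp(-10 * T)  # Gamma(2, 1/10)
        # split the domain so adaptive quadrature cannot miss the sharp peak
        Z = sum(quad(lambda T: prior(T) * like(T), a, b)[0]
                for a, b in [(0, 0.5), (0.5, 10)])
        exact = math.log(Z)
        cfg = McmcConfig(seed=5, ss_generations_per_step=600, ss_thin=4,
                         sample_interval=100,
                         proposal_weights={"brlen": 1.0})
        ml = stepping_stone(mat, PartitionScheme.single(80, model="JC"),
                            None, steps=30, cfg=cfg)
        assert abs(ml.log_ml - exact) < 3 * max(ml.se, 0.05)


class TestBayesFactor:
    def _ml(self, v, data_id=None):
        return MarginalLikelihood(v, np.array([v]), np.array([1.0, 0.0]), 0.1,
                                  data_id)

    def test_identical_marginals(self):
        bf = bayes_factor(self._ml(-100.0), self._ml(-100.0))
        assert bf.delta_ln == 0.0 and bf.category == "none"

    def test_very_strong_threshold(self):
        bf = bayes_factor(self._ml(-94.0), self._ml(-100.0))
        assert bf.two_delta_ln == pytest.approx(12.0)
        assert bf.category == "very strong"

    @pytest.mark.parametrize("delta,cat", [
        (0.5, "none"), (2.0, "positive"), (4.0, "strong"), (5.5, "very strong")])
    def test_kass_raftery_categories(self, delta, cat):
        bf = bayes_factor(self._ml(delta), self._ml(0.0))
        assert bf.category == cat

    def test_mismatched_data_rejected(self):
        with pytest.raises(Exception, match="different data"):
            bayes_factor(self._ml(-1.0, "d1"), self._ml(-2.0, "d2"))
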
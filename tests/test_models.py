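"""Substitution models, pruning likelihoods, parsimony and BIC selection."""

import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from phylogeo.core import GAP, MISSING, CharacterMatrix, PartitionScheme, Tree
from phylogeo.models import (
    MkModel, SubstitutionModel, bic_select, classify_characters,
    discrete_gamma_rates, fitch_length, loglik, loglik_mkv, p_distance,
    parse_model, rate_categories, transition_probabilities,
)
from phylogeo.simulate import simulate_sequences, simulate_yule_tree

from conftest import brute_force_min_changes


class TestGammaRates:
    def test_single_category_is_one(self):
        assert discrete_gamma_rates(3.7, 1) == pytest.approx([1.0])

    @pytest.mark.parametrize("alpha,k", [(0.2, 4), (0.5, 4), (1.0, 8), (5.0, 3)])
    def test_mean_is_exactly_one(self, alpha, k):
        assert discrete_gamma_rates(alpha, k).mean() == pytest.approx(1.0, abs=1e-12)

    def test_matches_quadrature_oracle(self):
        alpha, k = 0.5, 4
        dist = gamma_dist(a=alpha, scale=1.0 / alpha)
        edges = dist.ppf(np.linspace(0, 1, k + 1))
        expected = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            hi = np.inf if not np.isfinite(hi) else hi
            val, _ = quad(lambda x: x * dist.pdf(x), lo, hi)
            expected.append(val * k)
        got = discrete_gamma_rates(alpha, k)
        assert np.allclose(got, expected, rtol=1e-6)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            discrete_gamma_rates(0.0, 4)


class TestTransitionProbabilities:
    def test_zero_time_identity(self):
        m = SubstitutionModel(family="GTR", freqs=(0.4, 0.3, 0.2, 0.1),
                              rates=(1, 2, 3, 4, 5, 1))
        assert np.allclose(transition_probabilities(m, 0.0), np.eye(4))

    @pytest.mark.parametrize("t", [0.01, 0.3, 1.7])
    def test_jc_closed_form(self, t):
        P = transition_probabilities(SubstitutionModel(), t)
        same = 0.25 + 0.75 * math.exp(-4 * t / 3)
        assert P[0, 0] == pytest.approx(same, abs=1e-12)
        assert P[0, 1] == pytest.approx((1 - same) / 3, abs=1e-12)

    def test_rows_stochastic(self):
        m = SubstitutionModel(family="HKY", freqs=(0.35, 0.15, 0.25, 0.25),
                              kappa=4.0)
        for t in (0.05, 0.8, 3.0):
            P = transition_probabilities(m, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_long_branch_reaches_stationarity(self):
        m = SubstitutionModel(family="GTR", freqs=(0.4, 0.3, 0.2, 0.1),
                              rates=(1, 2, 0.5, 1.5, 3, 1))
        P = transition_probabilities(m, 200.0)
        for row in P:
            assert np.allclose(row, m.stationary(), atol=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probabilities(SubstitutionModel(), -0.1)

    def test_mk_closed_form(self):
        # symmetric r-state model scaled to mean rate one
        r, t = 3, 0.4
        P = transition_probabilities(MkModel(r=r), t)
        same = 1 / r + (r - 1) / r * math.exp(-r * t / (r - 1))
        assert P[0, 0] == pytest.approx(same, abs=1e-12)


def _brute_force_loglik(tree, model, matrix):
    weights, rates = rate_categories(model)
    pi = model.stationary()
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    ns = model.n_states
    total = 0.0
    for j in range(matrix.n_chars):
        col = dict(zip(matrix.taxa, matrix.column(j)))
        site = 0.0
        for wc, r in zip(weights, rates):
            Ps = {id(n): (transition_probabilities(model, r * n.length)
                          if r > 0 else np.eye(ns)) for n in nodes}
            for assign in itertools.product(range(ns), repeat=len(internal)):
                amap = {id(n): a for n, a in zip(internal, assign)}
                p = pi[amap[id(tree.root)]] * wc
                for n in nodes:
                    if n is tree.root:
                        continue
                    pa = amap[id(n.parent)]
                    if n.is_leaf:
                        cell = col[n.label]
                        if cell in (GAP, MISSING):
                            p *= 1.0
                        else:
                            p *= sum(Ps[id(n)][pa, list(matrix.states).index(x)]
                                     for x in cell)
                    else:
                        p *= Ps[id(n)][pa, amap[id(n)]]
                site += p
        total += math.log(site)
    return total


class TestLoglik:
    def test_single_taxon_single_site(self):
        t = Tree.from_newick("A;")
        m = CharacterMatrix(["A"], [[frozenset("A")]], "dna")
        assert loglik(t, SubstitutionModel(), m) == pytest.approx(math.log(0.25))

    def test_two_taxa_jc_closed_form(self):
        t = Tree.from_newick("(A:0.1,B:0.2);")
        m = CharacterMatrix(["A", "B"], [[frozenset("A")], [frozenset("A")]],
                            "dna")
        d = 0.3
        expected = math.log(0.25 * (0.25 + 0.75 * math.exp(-4 * d / 3)))
        assert loglik(t, SubstitutionModel(), m) == pytest.approx(expected,
                                                                  abs=1e-10)

    @pytest.mark.parametrize("spec,kwargs", [
        ("JC", {}),
        ("GTR+G", dict(family="GTR", freqs=(0.3, 0.2, 0.3, 0.2),
                       rates=(1, 2, 0.5, 1.3, 3, 1), alpha=0.7, ncat=3)),
        ("HKY+I", dict(family="HKY", freqs=(0.35, 0.15, 0.25, 0.25),
                       kappa=3.0, p_inv=0.2)),
    ])
    def test_matches_enumeration_oracle(self, spec, kwargs):
        tree = simulate_yule_tree(5, seed=3)
        model = SubstitutionModel(**kwargs)
        mat = simulate_sequences(tree, PartitionScheme.single(8), model, seed=5)
        assert loglik(tree, model, mat) == pytest.approx(
            _brute_force_loglik(tree, model, mat), abs=1e-8)

    def test_missing_and_ambiguous_cells(self):
        tree = simulate_yule_tree(5, seed=7)
        model = SubstitutionModel()
        mat = simulate_sequences(tree, PartitionScheme.single(6), model, seed=8)
        mat.cells[0][0] = MISSING
        mat.cells[1][1] = GAP
        mat.cells[2][2] = frozenset("AG")
        assert loglik(tree, model, mat) == pytest.approx(
            _brute_force_loglik(tree, model, mat), abs=1e-8)

    def test_reroot_invariance(self):
        from phylogeo.engine import _reroot_at
        tree = simulate_yule_tree(6, seed=9)
        model = SubstitutionModel(family="HKY", freqs=(0.3, 0.2, 0.2, 0.3),
                                  kappa=2.5, alpha=0.9, ncat=4)
        mat = simulate_sequences(tree, PartitionScheme.single(30), model,
                                 seed=10)
        base = loglik(tree, model, mat)
        t2 = tree.copy()
        internal = [n for n in t2.postorder() if not n.is_leaf][0]
        _reroot_at(t2, internal)
        assert loglik(t2, model, mat) == pytest.approx(base, abs=1e-9)

    def test_absent_taxon_error(self):
        t = Tree.from_newick("(A:0.1,B:0.2);")
        m = CharacterMatrix(["A", "Z"], [[frozenset("A")], [frozenset("C")]],
                            "dna")
        with pytest.raises(Exception, match="Z"):
            loglik(t, SubstitutionModel(), m)


class TestMkv:
    def _two_taxon_matrix(self):
        return CharacterMatrix(["A", "B"], [[frozenset("0")], [frozenset("1")]],
                               "standard", states=("0", "1"))

    def test_two_taxon_conditional_probability(self):
        t = 0.3
        tree = Tree.from_newick(f"(A:{t / 2},B:{t / 2});")
        m = self._two_taxon_matrix()
        model = MkModel(r=2)
        P = transition_probabilities(model, t)
        num = 0.5 * P[0, 1]
        p_const = 2 * 0.5 * P[0, 0]
        expected = math.log(num / (1 - p_const))
        assert loglik_mkv(tree, model, m) == pytest.approx(expected, abs=1e-10)

    def test_correction_denominator_bounds(self):
        # P(constant) lies strictly inside (0,1) for t > 0, so the Mkv
        # log-likelihood exceeds the unconditioned Mk one on variable data
        tree = Tree.from_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
        m = CharacterMatrix(
            ["A", "B", "C", "D"],
            [[frozenset("0")], [frozenset("0")], [frozenset("1")],
             [frozenset("1")]], "standard", states=("0", "1"))
        mk = MkModel(r=2, variable_coding=False)
        mkv = MkModel(r=2, variable_coding=True)
        assert loglik_mkv(tree, mkv, m) > loglik_mkv(tree, mk, m)

    def test_shrinking_branches_diverges(self):
        # a pattern needing two changes: its conditional probability under
        # "variable" coding vanishes as the tree length goes to zero
        m = CharacterMatrix(
            ["A", "B", "C", "D"],
            [[frozenset("0")], [frozenset("1")], [frozenset("1")],
             [frozenset("0")]], "standard", states=("0", "1"))
        model = MkModel(r=2)
        lls = []
        for t in (0.1, 0.01, 0.001):
            tree = Tree.from_newick(
                f"((A:{t},B:{t}):{t},(C:{t},D:{t}):{t});")
            lls.append(loglik_mkv(tree, model, m))
        assert lls[0] > lls[1] > lls[2]
        assert lls[2] < -5

    def test_too_many_states_rejected(self):
        tree = Tree.from_newick("(A:0.1,B:0.1);")
        m = CharacterMatrix(["A", "B"], [[frozenset("0")], [frozenset("2")]],
                            "standard", states=("0", "1", "2"))
        with pytest.raises(Exception, match="states"):
            loglik_mkv(tree, MkModel(r=2), m)


class TestFitch:
    def test_simple_synapomorphy(self):
        t = Tree.from_newick("((A:0,B:0),(C:0,D:0));")
        col = [frozenset("0"), frozenset("0"), frozenset("1"), frozenset("1")]
        assert fitch_length(t, col, ["A", "B", "C", "D"]) == 1

    def test_constant_zero(self):
        t = Tree.from_newick("((A,B),(C,D));")
        col = [frozenset("0")] * 4
        assert fitch_length(t, col, ["A", "B", "C", "D"]) == 0

    def test_matches_brute_force_on_small_trees(self, rng):
        from conftest import all_unrooted_topologies
        taxa = list("ABCDE")
        trees = all_unrooted_topologies(taxa)[::3]
        for t in trees:
            for _ in range(4):
                col = [frozenset(str(rng.integers(3))) for _ in taxa]
                if rng.random() < 0.3:
                    col[rng.integers(len(col))] = MISSING
                assert fitch_length(t, col, taxa) == \
                    brute_force_min_changes(t, col, taxa)

    def test_polytomy(self):
        t = Tree.from_newick("(A,B,C,D,E);")
        col = [frozenset("0"), frozenset("1"), frozenset("1"), frozenset("0"),
               frozenset("2")]
        assert fitch_length(t, col, list("ABCDE")) == \
            brute_force_min_changes(t, col, list("ABCDE"))


class TestClassifyAndDistance:
    def test_classification(self):
        columns = [
            [frozenset("A"), frozenset("A"), frozenset("A"), frozenset("A")],
            [frozenset("A"), frozenset("A"), frozenset("A"), frozenset("G")],
            [frozenset("A"), frozenset("A"), frozenset("C"), frozenset("C")],
            [frozenset("A"), MISSING, frozenset("C"), frozenset("C")],
        ]
        m = CharacterMatrix(["w", "x", "y", "z"],
                            [list(r) for r in zip(*columns)], "dna")
        assert classify_characters(m) == [
            "constant", "variable-uninformative", "parsimony-informative",
            "variable-uninformative"]

    def test_p_distance(self):
        a = [frozenset(x) for x in "ACGT"]
        b = [frozenset(x) for x in "ACGA"]
        assert p_distance(a, a) == 0.0
        assert p_distance(a, b) == pytest.approx(0.25)
        assert p_distance(a, b, as_percent=True) == pytest.approx(25.0)
        assert p_distance(a, b) == p_distance(b, a)

    def test_p_distance_excludes_gaps(self):
        a = [frozenset("A"), GAP, frozenset("G")]
        b = [frozenset("A"), frozenset("C"), frozenset("C")]
        assert p_distance(a, b) == pytest.approx(0.5)

    def test_p_distance_no_comparable_sites(self):
        with pytest.raises(Exception, match="comparable"):
            p_distance([GAP], [frozenset("A")])


class TestModelParsing:
    def test_case_insensitive_specs(self):
        m = parse_model("gtr+i+g")
        assert m.family == "GTR" and m.p_inv > 0 and m.ncat == 4
        mk = parse_model("Mk+G", n_states=3)
        assert isinstance(mk, MkModel) and mk.r == 3 and mk.ncat == 4

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            parse_model("WAG")


class TestBic:
    def test_parameter_counts(self):
        from phylogeo.models import _free_params
        assert _free_params("GTR+I+G") == 10
        assert _free_params("HKY+I") == 5
        assert _free_params("JC") == 0

    def test_nested_models_never_lose_likelihood(self):
        tree = simulate_yule_tree(6, seed=2)
        model = SubstitutionModel(family="HKY", freqs=(0.3, 0.2, 0.2, 0.3),
                                  kappa=3.0)
        mat = simulate_sequences(tree, PartitionScheme.single(300), model,
                                 seed=3)
        res = bic_select(tree, mat, ["JC", "HKY", "GTR", "HKY+G"])
        tbl = res.table.set_index("model")
        assert tbl.loc["HKY", "lnL"] >= tbl.loc["JC", "lnL"] - 1e-6
        assert tbl.loc["GTR", "lnL"] >= tbl.loc["HKY", "lnL"] - 1e-6
        assert tbl.loc["HKY+G", "lnL"] >= tbl.loc["HKY", "lnL"] - 1e-6

    def test_jc_data_prefers_jc(self):
        wins = 0
        reps = 8
        for rep in range(reps):
            tree = simulate_yule_tree(6, seed=100 + rep)
            mat = simulate_sequences(tree, PartitionScheme.single(200),
                                     SubstitutionModel(), seed=200 + rep)
            res = bic_select(tree, mat, ["JC", "GTR+I+G"])
            wins += res.best == "JC"
        assert wins >= int(0.9 * reps)

    def test_table_export(self, tmp_path):
        tree = simulate_yule_tree(5, seed=4)
        mat = simulate_sequences(tree, PartitionScheme.single(100),
                                 SubstitutionModel(), seed=5)
        res = bic_select(tree, mat, ["JC", "HKY"])
        out = tmp_path / "bic.tsv"
        res.to_tsv(out)
        assert "BIC" in out.read_text().splitlines()[0]
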
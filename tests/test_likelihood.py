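"""Pruning likelihood: equivalence with exhaustive state enumeration,
closed forms, invariances, and the branch-length / shape / EM fitting
machinery."""

import itertools
import math

import numpy as np
import pytest

from streptophylo import substmodels as M
from streptophylo import trees as T
from streptophylo.alignment import Alignment, Alphabet, DAYHOFF6
from streptophylo.composition import DAYHOFF_GROUPS
from streptophylo.likelihood import (
    PatternData, TreeLikelihood, _Engine, _expected_counts,
    _optimize_lengths_inplace, log_likelihood, optimize_branch_lengths,
)
from streptophylo.simulate import SimulationConfig, simulate_alignment
from tests.conftest import random_trees


def enumeration_loglik(aln, tree, model):
    """Oracle: marginalize internal states by explicit enumeration."""
    codes = aln.codes()
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    K = model.K
    G = model.gamma.n_categories
    total = 0.0
    for s in range(aln.length):
        site_like = 0.0
        for c in range(model.n_classes):
            pi = model.profiles[c]
            w = model.weights[c]
            for g in range(G):
                r = model.gamma.rates[g]
                for assign in itertools.product(range(K), repeat=len(internals)):
                    amap = dict(zip((id(n) for n in internals), assign))
                    p = pi[amap[id(tree.root)]]
                    for n in nodes:
                        if n.parent is None:
                            continue
                        parent_state = amap[id(n.parent)]
                        P = model.transition(c, (n.length or 0.0) * r)
                        if n.is_leaf:
                            st = codes[aln.taxa.index(n.name), s]
                            p *= 1.0 if st < 0 else P[parent_state, st]
                        else:
                            p *= P[parent_state, amap[id(n)]]
                    site_like += w * (1.0 / G) * p
        total += math.log(site_like)
    return total


class TestPruningOracle:
    @pytest.mark.parametrize("newick,seqs", [
        ("((A:0.3,B:0.1):0.2,(C:0.5,D:0.05):0.15,E:0.4);",
         {"A": "ABCA", "B": "BB-A", "C": "CDCA", "D": "ADC?", "E": "ABDA"}),
        ("((A:0.2,B:0.4):0.1,C:0.3,D:0.6);",
         {"A": "DAB", "B": "DBA", "C": "ACD", "D": "AXD"}),
        ("(A:0.5,B:0.2,C:0.9);",
         {"A": "AB", "B": "BB", "C": "CA"}),
    ])
    def test_matches_enumeration(self, newick, seqs, toy_mixture, toy_alphabet):
        tree = T.parse_newick(newick)
        aln = Alignment(seqs, toy_alphabet)
        got = log_likelihood(aln, tree, toy_mixture).loglik
        assert got == pytest.approx(enumeration_loglik(aln, tree, toy_mixture),
                                    abs=1e-8)

    def test_three_class_mixture_matches_enumeration(self, toy_alphabet):
        rng = np.random.default_rng(2)
        e = M.ExchangeabilityMatrix.uniform(4)
        classes = [(M.FrequencyProfile(rng.dirichlet(np.ones(4))), w)
                   for w in (0.5, 0.3, 0.2)]
        model = M.SubstitutionMixtureModel(e, classes, M.discrete_gamma(1.2, 2),
                                           toy_alphabet)
        tree = T.parse_newick("((A:0.2,B:0.3):0.1,C:0.4,D:0.25);")
        aln = Alignment({"A": "ABC", "B": "BAC", "C": "DDA", "D": "ACB"},
                        toy_alphabet)
        got = log_likelihood(aln, tree, model).loglik
        assert got == pytest.approx(enumeration_loglik(aln, tree, model), abs=1e-8)

    def test_twenty_state_case(self, lg_model):
        tree = T.parse_newick("((A:0.2,B:0.3):0.1,C:0.4,D:0.25);")
        aln = Alignment({"A": "MK", "B": "ML", "C": "IV", "D": "M-"})
        got = log_likelihood(aln, tree, lg_model).loglik
        assert got == pytest.approx(enumeration_loglik(aln, tree, lg_model),
                                    abs=1e-8)


class TestClosedFormsAndInvariances:
    def test_two_taxon_poisson_grid(self):
        model = M.make_model("poisson", gamma_categories=1)
        for t in [0.05, 0.2, 0.5, 1.0, 2.0]:
            tree = T.parse_newick(f"(X:{t / 2},Y:{t / 2});", deroot=False)
            same = log_likelihood(Alignment({"X": "A", "Y": "A"}), tree, model)
            pred = math.log((1 / 20) * (1 / 20 + (19 / 20) * math.exp(-20 * t / 19)))
            assert same.loglik == pytest.approx(pred, abs=1e-10)
            diff = log_likelihood(Alignment({"X": "A", "Y": "R"}), tree, model)
            pred_d = math.log((1 / 20) * (1 / 20) * (1 - math.exp(-20 * t / 19)))
            assert diff.loglik == pytest.approx(pred_d, abs=1e-10)

    def test_all_gap_column_contributes_zero(self, toy_mixture, toy_alphabet):
        tree = T.parse_newick("((A:0.3,B:0.1):0.2,(C:0.5,D:0.05):0.15,E:0.4);")
        base = Alignment({t: "A" for t in "ABCDE"}, toy_alphabet)
        gapped = Alignment({t: "A-" for t in "ABCDE"}, toy_alphabet)
        r = log_likelihood(gapped, tree, toy_mixture)
        assert r.loglik == pytest.approx(
            log_likelihood(base, tree, toy_mixture).loglik)
        assert r.site_logliks[1] == pytest.approx(0.0, abs=1e-12)

    def test_total_is_sum_of_site_logliks(self, toy_mixture, toy_alignment,
                                          five_taxon_tree):
        r = log_likelihood(toy_alignment, five_taxon_tree, toy_mixture)
        assert r.loglik == pytest.approx(r.site_logliks.sum(), abs=1e-8)

    def test_reroot_invariance(self, toy_mixture, toy_alignment):
        """The pulley principle: the likelihood of a reversible model does
        not depend on where the unrooted tree is written down as rooted."""
        forms = [
            "((A:0.3,B:0.1):0.2,(C:0.5,D:0.05):0.15,E:0.4);",
            "((C:0.5,D:0.05):0.15,E:0.4,(A:0.3,B:0.1):0.2);",
            "(C:0.5,D:0.05,(E:0.4,(A:0.3,B:0.1):0.2):0.15);",
        ]
        vals = [log_likelihood(toy_alignment, T.parse_newick(f), toy_mixture).loglik
                for f in forms]
        assert vals[1] == pytest.approx(vals[0], abs=1e-8)
        assert vals[2] == pytest.approx(vals[0], abs=1e-8)

    def test_class_split_invariance(self, toy_alphabet, toy_alignment,
                                    five_taxon_tree):
        """Splitting a mixture class into two identical halves leaves the
        likelihood unchanged."""
        e = M.ExchangeabilityMatrix.uniform(4)
        f = M.FrequencyProfile(np.array([0.1, 0.2, 0.3, 0.4]))
        one = M.SubstitutionMixtureModel(e, [(f, 1.0)], M.discrete_gamma(0.9, 4),
                                         toy_alphabet)
        two = M.SubstitutionMixtureModel(e, [(f, 0.5), (f, 0.5)],
                                         M.discrete_gamma(0.9, 4), toy_alphabet)
        a = log_likelihood(toy_alignment, five_taxon_tree, one).loglik
        b = log_likelihood(toy_alignment, five_taxon_tree, two).loglik
        assert a == pytest.approx(b, abs=1e-10)

    def test_missing_taxon_error_names_taxon(self, toy_mixture, toy_alphabet):
        tree = T.parse_newick("((A:1,B:1):1,(C:1,D:1));")
        aln = Alignment({"A": "A", "B": "B", "C": "C", "Z": "D"}, toy_alphabet)
        with pytest.raises(Exception, match="Z"):
            log_likelihood(aln, tree, toy_mixture)


class TestDayhoffLumpability:
    def test_uniform_poisson_lumps_onto_groups(self):
        """The 20-state uniform Poisson chain is lumpable onto the six
        Dayhoff groups; the aggregated transition matrix equals the 6-state
        chain with group-size frequencies, after matching the expected
        substitution rate."""
        sizes = np.array([len(v) for v in DAYHOFF_GROUPS.values()])
        K20 = M.make_model("poisson", gamma_categories=1)
        Q20 = K20.rate_matrix(0)
        f6 = M.FrequencyProfile(sizes / 20)
        Q6 = M.build_rate_matrix(M.ExchangeabilityMatrix.uniform(6), f6)
        # rate scale: fraction of 20-state substitutions that change groups
        scale = 1 - (sizes * (sizes - 1)).sum() / (20 * 19)
        groups = np.repeat(np.arange(6), sizes)  # contiguous blocks by size
        # build a block-aggregation of P20 with uniform within-group start
        for t in [0.05, 0.3, 1.0]:
            P20 = M.transition_probabilities(Q20, t, K20.profiles[0])
            agg = np.zeros((6, 6))
            for g in range(6):
                rows = np.nonzero(groups == g)[0]
                for h in range(6):
                    cols = np.nonzero(groups == h)[0]
                    agg[g, h] = P20[np.ix_(rows, cols)].sum() / len(rows)
            P6 = M.transition_probabilities(Q6, t * scale, f6.values)
            assert agg == pytest.approx(P6, abs=1e-10)


class TestFitting:
    def test_optimum_is_fixed_point(self, toy_mixture, toy_alignment,
                                    five_taxon_tree):
        t1, r1 = optimize_branch_lengths(toy_alignment, five_taxon_tree,
                                         toy_mixture, tol=1e-8, max_rounds=30)
        t2, r2 = optimize_branch_lengths(toy_alignment, t1, toy_mixture,
                                         tol=1e-8, max_rounds=5)
        assert r2.loglik == pytest.approx(r1.loglik, abs=1e-4)
        assert r2.loglik >= r1.loglik - 1e-9

    def test_monotone_trace_random_starts(self, toy_mixture, toy_alignment):
        rng = np.random.default_rng(4)
        for _ in range(3):
            lengths = rng.uniform(0.01, 2.0, size=8)
            nwk = (f"((A:{lengths[0]},B:{lengths[1]}):{lengths[2]},"
                   f"(C:{lengths[3]},D:{lengths[4]}):{lengths[5]},E:{lengths[6]});")
            tree = T.parse_newick(nwk)
            eng = _Engine(PatternData(toy_alignment), tree, toy_mixture)
            trace = [eng.loglik()]
            for _ in range(4):
                trace.append(eng.optimize_lengths_pass())
            assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_branch_length_recovery_within_10pct(self, lg_model):
        tree = T.parse_newick(
            "((A:0.2,B:0.15):0.08,(C:0.25,D:0.18):0.06,(E:0.1,F:0.22):0.09);")
        aln, _ = simulate_alignment(SimulationConfig(
            tree=tree, model=lg_model, sites=5000, seed=9))
        fitted, _ = optimize_branch_lengths(aln, tree, lg_model, max_rounds=8)
        true_leaf = {n.name: n.length for n in tree.leaves()}
        est_leaf = {n.name: n.length for n in fitted.leaves()}
        for k, v in true_leaf.items():
            assert abs(est_leaf[k] - v) / v < 0.10

    def test_alpha_recovery_bracket(self, lg_model):
        """Data simulated with alpha=0.5 on a fixed 8-taxon tree; the fitted
        shape lands in [0.4, 0.6] (bracket confirmed by simulation)."""
        trees = random_trees(8, 1, seed=11, mean_length=0.15)
        model = lg_model.with_gamma(0.5)
        aln, _ = simulate_alignment(SimulationConfig(
            tree=trees[0], model=model, sites=6000, seed=4))
        res = TreeLikelihood(aln, trees[0], "lg").fit(max_rounds=3,
                                                      outer_rounds=2)
        assert 0.4 <= res.alpha <= 0.6

    def test_summary_mentions_fit(self, toy_mixture, toy_alignment,
                                  five_taxon_tree):
        tl = TreeLikelihood(toy_alignment, five_taxon_tree, toy_mixture)
        res = tl.fit(max_rounds=2, shape=False)
        text = res.summary()
        assert "log-likelihood" in text and "mixture classes" in text
        assert res.loglik == pytest.approx(res.site_logliks.sum(), abs=1e-6)


class TestExpectedCountsEM:
    def test_estep_matches_quadrature(self, toy_alphabet):
        """Expected substitution counts and occupancy times on a single
        branch agree with direct numerical integration of the conditional
        path expectations."""
        from scipy.integrate import quad
        from scipy.linalg import expm
        e = M.ExchangeabilityMatrix(np.array(
            [[0, 1, 2, 0.5], [1, 0, 1.5, 0.7], [2, 1.5, 0, 1.2],
             [0.5, 0.7, 1.2, 0]]))
        f = M.FrequencyProfile(np.array([0.1, 0.2, 0.3, 0.4]))
        model = M.SubstitutionMixtureModel(e, [(f, 1.0)], M.discrete_gamma(1.0, 1),
                                           toy_alphabet)
        eps = 1e-7
        tree = T.parse_newick(f"(X:0.6,Y:{eps});", deroot=False)
        aln = Alignment({"X": "A", "Y": "C"}, toy_alphabet)
        eng = _Engine(PatternData(aln), tree, model)
        C, Texp = _expected_counts(eng)
        Q = model.rate_matrix(0)
        t = 0.6 + eps
        Pab = expm(Q * t)[2, 0]      # root-side state is C, far side is A

        def en(i, j):
            val = quad(lambda s: expm(Q * s)[2, i] * expm(Q * (t - s))[j, 0],
                       0, t, limit=200)[0]
            return Q[i, j] * val / Pab

        for i in range(4):
            for j in range(4):
                if i != j:
                    assert C[i, j] == pytest.approx(en(i, j), abs=1e-5)
        assert Texp.sum() == pytest.approx(t, abs=1e-9)

    def test_gtr_em_improves_fit_on_skewed_data(self, toy_alphabet):
        rng = np.random.default_rng(3)
        E = np.array([[0, 5, 0.2, 0.2], [5, 0, 0.2, 0.2],
                      [0.2, 0.2, 0, 5], [0.2, 0.2, 5, 0]])
        truth = M.SubstitutionMixtureModel(
            M.ExchangeabilityMatrix(E),
            [(M.FrequencyProfile(np.array([0.3, 0.2, 0.3, 0.2])), 1.0)],
            M.discrete_gamma(1.0, 1), toy_alphabet)
        tree = T.parse_newick("((A:0.3,B:0.2):0.1,C:0.4,D:0.3);")
        aln, _ = simulate_alignment(SimulationConfig(
            tree=tree, model=truth, sites=2000, seed=17))
        pois = TreeLikelihood(aln, tree, M.make_model(
            "poisson", toy_alphabet, gamma_categories=1)).fit(shape=False,
                                                              max_rounds=3)
        gtr = TreeLikelihood(aln, tree, M.make_model(
            "gtr", toy_alphabet, gamma_categories=1)).fit(
            shape=False, exchangeabilities=True, max_rounds=3, outer_rounds=2)
        assert gtr.loglik > pois.loglik + 50
        # recovered exchangeabilities show the simulated A-B / C-D skew
        Efit = gtr.submodel.exchangeabilities.values
        assert Efit[0, 1] > 3 * Efit[0, 2]
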
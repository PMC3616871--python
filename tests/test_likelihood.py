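"""Likelihood engine: closed forms, brute-force oracle, optimization, AIC."""

import itertools
import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from phylomekit import likelihood as lk
from phylomekit import treecore as tc
from phylomekit.seqio import AA_INDEX, AMINO_ACIDS
from phylomekit.synthetic_data import simulate_alignment

from conftest import random_topology, with_random_lengths


def brute_force_loglik(aln, tree, model):
    """Sum over all internal-state assignments (tiny trees only).

    All 20^k assignments of states to the k internal nodes are enumerated as
    an array and the per-assignment probabilities multiplied out explicitly —
    no pruning recursion shared with the implementation under test.
    """
    names = list(aln)
    ncol = len(aln[names[0]])
    internals = list(tree.non_tips(include_self=True))
    k = len(internals)
    idx_of = {id(n): i for i, n in enumerate(internals)}
    assign = np.indices((20,) * k).reshape(k, -1)  # (k, 20^k)
    rates = model.category_rates()
    out = np.zeros(ncol)
    for col in range(ncol):
        site_like = 0.0
        for r in rates:
            prob = model.freqs[assign[idx_of[id(tree)]]].copy()
            for node in tree.traverse(include_self=False):
                P = model.transition_matrix(r * node.length)
                ps = assign[idx_of[id(node.parent)]]
                if node.children:
                    prob *= P[ps, assign[idx_of[id(node)]]]
                else:
                    ch = aln[node.name][col]
                    if ch in AA_INDEX:
                        prob *= P[ps, AA_INDEX[ch]]
                    # gap: sum over child states = row sum = 1
            site_like += prob.sum() / len(rates)
        if model.p_inv > 0:
            chars = {aln[n][col] for n in names if aln[n][col] in AA_INDEX}
            const = (
                model.freqs[AA_INDEX[chars.pop()]] if len(chars) == 1
                else (1.0 if not chars else 0.0)
            )
            site_like = model.p_inv * const + (1 - model.p_inv) * site_like
        out[col] = math.log(site_like)
    return out


class TestModels:
    @pytest.mark.parametrize("name", lk.ALL_MODELS)
    def test_q_normalization_and_stochasticity(self, name):
        m = lk.load_model(name)
        assert np.abs(m.Q.sum(axis=1)).max() < 1e-12
        assert np.dot(m.freqs, np.diag(m.Q)) == pytest.approx(-1.0)
        rng = np.random.default_rng(1)
        for t in rng.uniform(0, 5, size=4):
            P = m.transition_matrix(float(t))
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
            assert (P >= 0).all()

    def test_poisson_closed_form(self):
        m = lk.load_model("Poisson")
        for t in (0.05, 0.7, 2.5):
            p_ii = 1 / 20 + (19 / 20) * math.exp(-20 * t / 19)
            assert m.transition_matrix(t)[3, 3] == pytest.approx(p_ii, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 3.7, 25.0])
    def test_gamma_category_rates_mean_one(self, alpha):
        r = lk.gamma_category_rates(alpha, 4)
        assert r.mean() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(r) > 0).all()

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            lk.load_model("GTR")


class TestNeighborJoining:
    def test_recovers_additive_topology(self, five_taxon_tree):
        names = sorted(tc.leaf_names(five_taxon_tree))
        d = np.zeros((5, 5))
        for i, j in itertools.combinations(range(5), 2):
            a = five_taxon_tree.find(names[i])
            b = five_taxon_tree.find(names[j])
            d[i, j] = d[j, i] = a.distance(b)
        t = lk.nj_tree(DistanceMatrix(d, ids=names))
        assert tc.rf_distance(t, five_taxon_tree) == 0

    def test_three_taxon_closed_form(self):
        # three-point formulas: x = (dAB + dAC - dBC)/2 etc.
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        t = lk.nj_tree(DistanceMatrix(d, ids=["A", "B", "C"]))
        lengths = {n.name: n.length for n in t.traverse() if n.name}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_too_few_taxa_rejected(self):
        d = np.array([[0, 0.3], [0.3, 0]])
        with pytest.raises(ValueError, match="at least 3"):
            lk.nj_tree(DistanceMatrix(d, ids=["A", "B"]))


class TestSiteLikelihoods:
    def test_two_taxon_poisson_closed_form(self):
        m = lk.load_model("Poisson")
        t = tc.parse_newick("(A:0.4,B:0.6);")
        aln = {"A": "AR", "B": "AN"}
        got = lk.site_log_likelihoods(aln, t, m)
        p_ii = 1 / 20 + (19 / 20) * math.exp(-20 / 19)
        p_ij = 1 / 20 - (1 / 20) * math.exp(-20 / 19)
        assert got[0] == pytest.approx(math.log(0.05 * p_ii), abs=1e-10)
        assert got[1] == pytest.approx(math.log(0.05 * p_ij), abs=1e-10)

    def test_uniform_alpha_equals_single_category(self, five_taxon_tree):
        aln = simulate_alignment(five_taxon_tree, 40, "JTT",
                                 rng=np.random.default_rng(2))
        m_inf = lk.load_model("JTT", alpha=math.inf)
        m_uni = lk.load_model("JTT", alpha=None)
        a = lk.site_log_likelihoods(aln, five_taxon_tree, m_inf)
        b = lk.site_log_likelihoods(aln, five_taxon_tree, m_uni)
        assert np.allclose(a, b, atol=0)

    def test_column_permutation_invariance_of_total(self, five_taxon_tree):
        aln = simulate_alignment(five_taxon_tree, 60, "WAG",
                                 rng=np.random.default_rng(3))
        perm = np.random.default_rng(0).permutation(60)
        aln_p = {n: "".join(s[i] for i in perm) for n, s in aln.items()}
        m = lk.load_model("WAG", alpha=0.8)
        assert lk.total_log_likelihood(aln, five_taxon_tree, m) == pytest.approx(
            lk.total_log_likelihood(aln_p, five_taxon_tree, m)
        )

    @pytest.mark.parametrize("model_name", ["Poisson", "JTT"])
    @pytest.mark.parametrize("seed", range(5))
    def test_pruning_equals_brute_force(self, model_name, seed):
        rng = np.random.default_rng(900 + seed)
        n = int(rng.integers(3, 6))
        tree = with_random_lengths(
            random_topology([f"T{i}" for i in range(n)], rng), rng
        )
        aln = {
            f"T{i}": "".join(
                rng.choice(list(AMINO_ACIDS + "-"), size=4)
            )
            for i in range(n)
        }
        model = lk.load_model(model_name, alpha=0.9, p_inv=0.15)
        got = lk.site_log_likelihoods(aln, tree, model)
        want = brute_force_loglik(aln, tree, model)
        assert np.allclose(got, want, atol=1e-8)

    def test_rerooting_invariance(self, five_taxon_tree):
        """Pulley principle: likelihood unchanged under re-rooting."""
        aln = simulate_alignment(five_taxon_tree, 30, "LG",
                                 rng=np.random.default_rng(5))
        m = lk.load_model("LG", alpha=1.2, p_inv=0.1)
        base = lk.total_log_likelihood(aln, five_taxon_tree, m)
        for tip_name in ["A", "C", "E"]:
            rerooted = five_taxon_tree.root_at(
                five_taxon_tree.find(tip_name).parent, branch_attrs=[]
            )
            assert lk.total_log_likelihood(aln, rerooted, m) == pytest.approx(
                base, abs=1e-8
            )

    def test_leaf_mismatch_error(self, five_taxon_tree):
        with pytest.raises(ValueError, match="mismatch"):
            lk.site_log_likelihoods({"A": "AA", "Z": "AA"}, five_taxon_tree,
                                    lk.load_model("Poisson"))


class TestBranchOptimization:
    def test_pairwise_mle_closed_form(self):
        L, d = 500, 120
        aln = {"A": "A" * L, "B": "A" * (L - d) + "R" * d}
        t = tc.parse_newick("(A:0.2,B:0.2);")
        opt = lk.optimize_branch_lengths(t, aln, lk.load_model("Poisson"))
        total = sum(n.length for n in opt.traverse(include_self=False))
        mle = -(19 / 20) * math.log(1 - (20 / 19) * d / L)
        assert total == pytest.approx(mle, abs=1e-6)

    def test_recovers_simulated_lengths(self):
        truth = tc.parse_newick("((A:0.2,B:0.35):0.15,(C:0.1,D:0.4):0.2);")
        aln = simulate_alignment(truth, 10_000, "Poisson", alpha=None,
                                 rng=np.random.default_rng(8))
        start = truth.copy()
        for n in start.traverse(include_self=False):
            n.length = 0.2
        opt = lk.optimize_branch_lengths(start, aln, lk.load_model("Poisson"))
        # the two root-child branches are confounded; compare their sum
        def canonical(tree):
            out = {}
            root_sum = 0.0
            for n in tree.traverse(include_self=False):
                key = frozenset(t.name for t in n.tips(include_self=True))
                if n.parent.is_root():
                    root_sum += n.length
                else:
                    out[key] = n.length
            out["rootpath"] = root_sum
            return out
        want, got = canonical(truth), canonical(opt)
        for key, w in want.items():
            assert got[key] == pytest.approx(w, rel=0.10, abs=0.02)

    def test_fixed_point_at_optimum(self):
        L, d = 400, 80
        aln = {"A": "A" * L, "B": "A" * (L - d) + "R" * d}
        mle = -(19 / 20) * math.log(1 - (20 / 19) * d / L)
        t = tc.parse_newick(f"(A:{mle / 2},B:{mle / 2});")
        m = lk.load_model("Poisson")
        before = lk.total_log_likelihood(aln, t, m)
        opt = lk.optimize_branch_lengths(t, aln, m)
        after = lk.total_log_likelihood(
            {k: aln[k] for k in aln}, opt, m
        )
        assert after >= before - 1e-6


class TestModelSelection:
    def test_single_candidate_returned(self, five_taxon_tree):
        aln = simulate_alignment(five_taxon_tree, 80, "LG",
                                 rng=np.random.default_rng(12))
        best, table = lk.select_model_aic(aln, five_taxon_tree, ["LG"])
        assert best.name == "LG"
        assert len(table) == 1

    def test_empty_candidates_rejected(self, five_taxon_tree):
        with pytest.raises(ValueError):
            lk.select_model_aic({}, five_taxon_tree, [])

    def test_lnl_below_saturated_bound(self, five_taxon_tree):
        aln = simulate_alignment(five_taxon_tree, 60, "WAG",
                                 rng=np.random.default_rng(13))
        best, table = lk.select_model_aic(aln, five_taxon_tree, ["WAG", "JTT"])
        names, cols = list(aln), len(aln["A"])
        bound = 0.0
        for j in range(cols):
            col = [aln[n][j] for n in names]
            counts = {c: col.count(c) for c in set(col)}
            bound += sum(k * math.log(k / len(col)) for k in counts.values())
        assert (table.lnL <= bound + 1e-6).all()


class TestSiteLnlIO:
    def test_round_trip_plain_and_named(self, tmp_path):
        m = np.random.default_rng(0).normal(-3, 1, size=(3, 7))
        plain = tmp_path / "plain.sitelh"
        lk.write_site_lnl_matrix(m, plain)
        back, names = lk.read_site_lnl_matrix(plain)
        assert np.allclose(back, m, atol=1e-7)
        named = tmp_path / "named.sitelh"
        lk.write_site_lnl_matrix(m, named, names=["tA", "tB", "tC"])
        back2, names2 = lk.read_site_lnl_matrix(named)
        assert names2 == ["tA", "tB", "tC"]
        assert np.allclose(back2, m, atol=1e-7)
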
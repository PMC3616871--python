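"""Reconciliation, duplication dating, redundancy merging, lineage rates."""

import itertools

import numpy as np
import pytest

from phylomekit import treecore as tc
from phylomekit.duplications import (
    EventRecord,
    date_duplications,
    lineage_duplication_rates,
    merge_redundant_events,
    reconcile_lca,
)
from phylomekit.orthology import label_events_species_overlap

from conftest import random_topology


def brute_force_min_dup(gene_tree, species_tree):
    """Minimum duplication count over all valid reconciliation maps.

    Enumerates every map M with M(leaf) = its species and M(v) an ancestor-
    or-equal of the LCA of the children's images.  A node is a speciation
    only when it maps exactly onto that LCA and neither child maps to the
    same node (the children's images then lie in distinct child subtrees);
    anything else is a duplication.
    """
    sp_nodes = list(species_tree.traverse(include_self=True))
    name_of = {id(n): n.name for n in sp_nodes}
    parent = {
        n.name: (n.parent.name if n.parent is not None else None)
        for n in sp_nodes
    }
    depth = {}
    for n in species_tree.preorder(include_self=True):
        depth[n.name] = 0 if n.parent is None else depth[n.parent.name] + 1

    def lca(a, b):
        while depth[a] > depth[b]:
            a = parent[a]
        while depth[b] > depth[a]:
            b = parent[b]
        while a != b:
            a, b = parent[a], parent[b]
        return a

    def ancestors_or_self(x):
        out = [x]
        while parent[x] is not None:
            x = parent[x]
            out.append(x)
        return out

    gnodes = list(gene_tree.postorder(include_self=True))
    internals = [n for n in gnodes if n.children]
    leaf_map = {
        id(n): n.name.rsplit("_", 1)[1] for n in gnodes if not n.children
    }
    best = [np.inf]

    def rec(i, assignment, dups):
        if dups >= best[0]:
            return
        if i == len(internals):
            best[0] = dups
            return
        node = internals[i]
        kid_imgs = []
        for c in node.children:
            img = leaf_map.get(id(c)) or assignment[id(c)]
            kid_imgs.append(img)
        low = kid_imgs[0]
        for k in kid_imgs[1:]:
            low = lca(low, k)
        for m in ancestors_or_self(low):
            assignment[id(node)] = m
            is_spec = m == low and all(m != k for k in kid_imgs)
            rec(i + 1, assignment, dups + (0 if is_spec else 1))
        del assignment[id(node)]

    rec(0, {}, 0)
    return int(best[0])


class TestReconcileLCA:
    def test_congruent_trees_zero_duplications(self):
        gt = tc.parse_newick("((A_s1,A_s2),B_s3);")
        sp = tc.parse_newick("((s1,s2),s3);")
        _, ndup = reconcile_lca(gt, sp)
        assert ndup == 0

    def test_cherry_duplication(self):
        gt = tc.parse_newick("((X_s1,Y_s1),B_s2);")
        sp = tc.parse_newick("(s1,s2);")
        mapping, ndup = reconcile_lca(gt, sp)
        assert ndup == 1

    def test_unknown_species_listed(self):
        gt = tc.parse_newick("((A_s1,B_s9),C_s3);")
        sp = tc.parse_newick("((s1,s2),s3);")
        with pytest.raises(ValueError, match="s9"):
            reconcile_lca(gt, sp)

    @pytest.mark.parametrize("seed", range(100))
    def test_equals_brute_force_minimum(self, seed):
        """LCA reconciliation attains the brute-force optimum (<= 6 leaves)."""
        rng = np.random.default_rng(7000 + seed)
        n_sp = int(rng.integers(2, 5))
        sp = random_topology([f"s{i}" for i in range(n_sp)], rng)
        for node in sp.non_tips(include_self=True):
            node.name = None
        sp2 = sp.copy()
        i = 0
        for node in sp2.preorder(include_self=True):
            if node.name is None:
                i += 1
                node.name = f"N{i}"
        n_genes = int(rng.integers(3, 7))
        species = [f"s{rng.integers(0, n_sp)}" for _ in range(n_genes)]
        gt = random_topology(
            [f"g{i}_{s}" for i, s in enumerate(species)], rng
        )
        _, ndup = reconcile_lca(gt, sp2)
        assert ndup == brute_force_min_dup(gt, sp2)


class TestDating:
    sp = tc.parse_newick("((s1,s2)A,s3)R;")

    def date(self, newick):
        labeled = label_events_species_overlap(tc.parse_newick(newick))
        return date_duplications({"t": labeled}, self.sp)

    def test_single_species_duplication_on_terminal_branch(self):
        events = self.date("((X_s1,Y_s1),B_s2);")
        assert [e.lineage for e in events] == ["s1"]

    def test_two_species_duplication_on_internal_branch(self):
        events = self.date("(((A_s1,B_s2),(C_s1,D_s2)),E_s3);")
        assert [e.lineage for e in events] == ["A"]

    def test_root_spanning_duplication_on_root_branch(self):
        events = self.date("(((A_s1,B_s2),E_s3),((C_s1,D_s2),F_s3));")
        assert [e.lineage for e in events] == ["R"]


class TestMerging:
    def ev(self, tree_id, side1, side2, lineage="b"):
        return EventRecord(
            tree_id=tree_id, node_id=0, event_type="duplication",
            side1=frozenset(side1), side2=frozenset(side2), lineage=lineage,
        )

    def test_identical_events_merge(self):
        events = [self.ev("t1", {"x1", "x2"}, {"y1"}),
                  self.ev("t2", {"x1", "x2"}, {"y1"})]
        merged = merge_redundant_events(events)
        assert len(merged) == 1
        assert events[0].group == events[1].group

    def test_disjoint_families_never_merge(self):
        events = [self.ev("t1", {"a1"}, {"a2"}),
                  self.ev("t2", {"b1"}, {"b2"})]
        assert len(merge_redundant_events(events)) == 2

    def test_restriction_rule_merges_partial_views(self):
        # tree2 lacks x2: restricting tree1's event to the common universe
        # makes the two reports identical
        events = [self.ev("t1", {"x1", "x2"}, {"y1"}),
                  self.ev("t2", {"x1"}, {"y1"})]
        universes = {
            "t1": frozenset({"x1", "x2", "y1", "z1"}),
            "t2": frozenset({"x1", "y1", "z1"}),
        }
        merged = merge_redundant_events(events, universes)
        assert len(merged) == 1

    def test_exact_rule_keeps_partial_views_apart(self):
        events = [self.ev("t1", {"x1", "x2"}, {"y1"}),
                  self.ev("t2", {"x1"}, {"y1"})]
        universes = {
            "t1": frozenset({"x1", "x2", "y1"}),
            "t2": frozenset({"x1", "y1"}),
        }
        assert len(merge_redundant_events(events, universes, rule="exact")) == 2

    def test_merging_idempotent(self, simulated_phylome):
        _, _, truth = simulated_phylome
        labeled = {
            f: label_events_species_overlap(t)
            for f, t in truth.gene_trees.items()
        }
        events = date_duplications(labeled, truth.species_tree)
        universes = {
            f: frozenset(l.name for l in t.tips())
            for f, t in truth.gene_trees.items()
        }
        once = merge_redundant_events(events, universes)
        twice = merge_redundant_events(list(once), universes)
        assert len(once) == len(twice)


class TestLineageRates:
    def test_no_duplications_all_zero(self, simulated_phylome):
        _, _, truth = simulated_phylome
        rates = lineage_duplication_rates([], truth.gene_trees, truth.species_tree)
        assert (rates.table.rate.fillna(0) == 0).all()
        assert rates.fraction_trees_with_duplication == 0.0

    def test_rate_arithmetic(self):
        sp = tc.parse_newick("((s1,s2)A,s3)R;")
        trees = {
            f"t{i}": tc.parse_newick(f"((g{i}a_s1,g{i}b_s2),g{i}c_s3);")
            for i in range(10)
        }
        events = [
            EventRecord(tree_id=f"t{i}", node_id=0, event_type="duplication",
                        side1=frozenset({f"g{i}a_s1"}),
                        side2=frozenset({f"g{i}b_s2"}), lineage="A")
            for i in range(5)
        ]
        rates = lineage_duplication_rates(events, trees, sp)
        assert rates.rate("A") == pytest.approx(0.5)

    def test_conservation_of_dated_events(self, simulated_phylome):
        _, _, truth = simulated_phylome
        labeled = {
            f: label_events_species_overlap(t)
            for f, t in truth.gene_trees.items()
        }
        events = date_duplications(labeled, truth.species_tree)
        merged = merge_redundant_events(events)
        rates = lineage_duplication_rates(merged, truth.gene_trees,
                                          truth.species_tree, raw_events=events)
        assert rates.table.duplications.sum() == len(merged)

    def test_zero_informative_branch_flagged_undefined(self):
        sp = tc.parse_newick("((s1,s2)A,s3)R;")
        trees = {"t0": tc.parse_newick("((a_s1,b_s2),c_s3);")}
        # remove s3 from every tree: terminal branch s3 has no informative gene
        trees = {"t0": tc.parse_newick("(a_s1,b_s2);")}
        rates = lineage_duplication_rates([], trees, sp)
        row = rates.table[rates.table.branch_id == "s3"].iloc[0]
        assert row.undefined
        assert np.isnan(row.rate)

    def test_dropout_hides_duplications_on_average(self):
        """Recovered rate under dropout never exceeds the loss-free planted
        rate on average (copies must be seen on both sides to witness an
        event)."""
        from phylomekit.synthetic_data import (
            SimulationConfig, simulate_gene_family, simulate_species_tree,
        )

        cfg_full = SimulationConfig(n_species=6, dup_rate=0.4, loss_rate=0.0,
                                    sampling_prob=1.0, seed=31)
        sp = simulate_species_tree(cfg_full)
        cfg_drop = SimulationConfig(n_species=6, dup_rate=0.4, loss_rate=0.0,
                                    sampling_prob=0.7, seed=31)
        full_means, drop_means = [], []
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            full = [len(simulate_gene_family(sp, cfg_full, f"F{i}", rng)[1])
                    for i in range(30)]
            rng = np.random.default_rng(500 + seed)
            drop = [len(simulate_gene_family(sp, cfg_drop, f"F{i}", rng)[1])
                    for i in range(30)]
            full_means.append(np.mean(full))
            drop_means.append(np.mean(drop))
        assert np.mean(drop_means) <= np.mean(full_means)
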
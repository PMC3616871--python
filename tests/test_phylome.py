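"""Hit filtering, phylome combination, coverage reporting."""

import numpy as np
import pandas as pd
import pytest

from phylomekit import treecore as tc
from phylomekit.phylome import (
    CombinedPhylome,
    HitRecord,
    Phylome,
    combine_phylomes,
    coverage_report,
    filter_homolog_hits,
    read_hit_table,
)


def hit(q, s, e, start, end, qlen=100):
    return HitRecord(query=q, subject=s, evalue=e, qstart=start, qend=end,
                     qlen=qlen)


class TestHitFiltering:
    def test_evalue_threshold(self):
        hits = [hit("q", "a", 1e-4, 1, 80), hit("q", "b", 1e-6, 1, 80)]
        kept = filter_homolog_hits(hits)
        assert [h.subject for h in kept] == ["b"]

    def test_coverage_strictly_greater_than_threshold(self):
        # 31% kept, 29% dropped, 30% exactly dropped (strict >)
        hits = [hit("q", "a", 1e-10, 1, 31), hit("q", "b", 1e-10, 1, 29),
                hit("q", "c", 1e-10, 1, 30)]
        kept = filter_homolog_hits(hits)
        assert [h.subject for h in kept] == ["a"]

    def test_max_hits_keeps_smallest_evalues(self):
        hits = [hit("q", f"s{i:03d}", 1e-10 * (i + 1), 1, 80)
                for i in range(250)]
        kept = filter_homolog_hits(hits)
        assert len(kept) == 200
        assert kept[0].subject == "s000"
        assert max(h.evalue for h in kept) <= 1e-10 * 200

    def test_tie_break_by_subject(self):
        hits = [hit("q", "zzz", 1e-9, 1, 80), hit("q", "aaa", 1e-9, 1, 80)]
        kept = filter_homolog_hits(hits, max_hits=1)
        assert kept[0].subject == "aaa"

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(1)
        hits = [
            hit(f"q{rng.integers(3)}", f"s{i}", float(10.0 ** -rng.integers(3, 12)),
                1, int(rng.integers(10, 100)))
            for i in range(60)
        ]
        once = filter_homolog_hits(hits)
        assert filter_homolog_hits(once) == once
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert sorted(filter_homolog_hits(shuffled), key=str) == sorted(once, key=str)

    def test_seed_genome_preset(self):
        hits = [hit("q", "a", 1e-10, 1, 20)]
        assert filter_homolog_hits(hits) == []
        assert len(filter_homolog_hits(hits, min_query_coverage=0.15)) == 1

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            hit("q", "a", 1e-9, 50, 20)

    def test_hit_table_round_trip(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q1\ts1\t1e-08\t1\t80\t100\nq1\ts2\t2e-03\t5\t60\t100\n")
        hits = read_hit_table(path)
        assert len(hits) == 2
        assert hits[0].coverage == pytest.approx(0.80)


def tiny_phylome(name, seeds_and_leaves):
    trees = {}
    for seed, others in seeds_and_leaves.items():
        leaves = [seed] + list(others)
        nwk = "(" + ",".join(leaves[:2]) + ")" if len(leaves) == 2 else None
        if len(leaves) == 2:
            tree = tc.parse_newick(f"({leaves[0]},{leaves[1]});")
        else:
            inner = f"({leaves[0]},{leaves[1]})"
            for l in leaves[2:]:
                inner = f"({inner},{l})"
            tree = tc.parse_newick(inner + ";")
        trees[seed] = tree
    return Phylome(trees=trees, name=name)


class TestCombinePhylomes:
    def test_primary_wins_fallback_fills(self):
        primary = tiny_phylome("p", {"t1_s1": ["x_s9"], "t2_s1": ["y_s9"]})
        fallback = tiny_phylome("f", {"t2_s1": ["z_s9"], "t3_s1": ["w_s9"]})
        combined = combine_phylomes(primary, [fallback],
                                    {"s1": {"t1_s1", "t2_s1", "t3_s1"}})
        assert combined.provenance["t1_s1"] == "primary"
        assert combined.provenance["t2_s1"] == "primary"
        assert combined.provenance["t3_s1"] == "fallback:f"
        assert combined.coverage_fraction("s1") == 1.0

    def test_empty_fallback_list(self):
        primary = tiny_phylome("p", {"t1_s1": ["x_s9"]})
        combined = combine_phylomes(primary, [], {"s1": {"t1_s1", "t9_s1"}})
        assert combined.uncovered["s1"] == {"t9_s1"}
        assert combined.coverage_fraction("s1") == 0.5

    def test_leaf_level_representation_counts_non_seeds(self):
        primary = tiny_phylome("p", {"t1_s1": ["t5_s1"]})
        combined = combine_phylomes(primary, [], {"s1": {"t5_s1"}})
        assert combined.provenance["t5_s1"] == "primary"
        seed_level = combine_phylomes(primary, [], {"s1": {"t5_s1"}},
                                      representation_level="seed")
        assert "t5_s1" in seed_level.uncovered["s1"]

    @pytest.mark.parametrize("seed", range(50))
    def test_combined_coverage_monotone(self, seed):
        rng = np.random.default_rng(2000 + seed)
        ids = [f"t{i}_s1" for i in range(12)]
        prim_ids = rng.choice(ids, size=int(rng.integers(1, 8)), replace=False)
        fb_ids = rng.choice(ids, size=int(rng.integers(1, 8)), replace=False)
        primary = tiny_phylome("p", {t: ["o_s9"] for t in prim_ids})
        fallback = tiny_phylome("f", {t: ["o_s9"] for t in fb_ids})
        targets = {"s1": set(ids)}
        alone = combine_phylomes(primary, [], targets)
        both = combine_phylomes(primary, [fallback], targets)
        assert both.coverage_fraction("s1") >= alone.coverage_fraction("s1")


class TestCoverageReport:
    def test_coverage_arithmetic(self):
        ph = tiny_phylome("p", {f"t{i}_s1": ["o_s9"] for i in range(6)})
        targets = {"s1": {f"t{i}_s1" for i in range(10)}}
        table = coverage_report(ph, targets)
        assert table.coverage_pct.iloc[0] == pytest.approx(60.0)
        assert table.mean_homologs_per_tree.iloc[0] == pytest.approx(1.0)

    def test_perfect_linear_correlation(self):
        trees = {}
        lengths = []
        for i in range(1, 7):
            seed = f"t{i}_s1"
            others = [f"h{i}{j}_s9" for j in range(i)]
            trees[seed] = None
            lengths.append((seed, i * 100, 100))
        ph = tiny_phylome("p", {
            f"t{i}_s1": [f"h{i}{j}_s9" for j in range(i)] for i in range(1, 7)
        })
        ortho = pd.DataFrame(
            [(f"t{i}_s1", i * 100, 100) for i in range(1, 7)],
            columns=["transcript", "length", "ortholog_length"],
        )
        table = coverage_report(ph, {"s1": set(ph.trees)}, ortholog_lengths=ortho)
        assert table.pearson_r.iloc[0] == pytest.approx(1.0)

    def test_too_few_points_flagged(self):
        ph = tiny_phylome("p", {"t1_s1": ["a_s9"], "t2_s1": ["b_s9"]})
        ortho = pd.DataFrame(
            [("t1_s1", 100, 100), ("t2_s1", 50, 100)],
            columns=["transcript", "length", "ortholog_length"],
        )
        table = coverage_report(ph, {"s1": set(ph.trees)}, ortholog_lengths=ortho)
        assert np.isnan(table.pearson_r.iloc[0])

    def test_truncation_dropout_trend_detected(self):
        """Homolog counts rising with relative transcript length yield a
        positive, significant correlation (mirrors incomplete-assembly bias:
        shorter transcripts find fewer homologs)."""
        rng = np.random.default_rng(9)
        seeds = {}
        rows = []
        for i in range(200):
            rel = float(rng.uniform(0.3, 1.0))
            n_hom = 1 + int(rng.binomial(20, 0.15 + 0.6 * rel))
            seed = f"t{i}_s1"
            seeds[seed] = [f"h{i}x{j}_s9" for j in range(n_hom)]
            rows.append((seed, int(rel * 1000), 1000))
        ph = tiny_phylome("p", seeds)
        ortho = pd.DataFrame(rows, columns=["transcript", "length",
                                            "ortholog_length"])
        table = coverage_report(ph, {"s1": set(seeds)}, ortholog_lengths=ortho)
        assert table.pearson_r.iloc[0] > 0
        assert table.pearson_p.iloc[0] < 0.05

    def test_mean_homologs_consistent_two_ways(self, simulated_phylome):
        _, phylome, truth = simulated_phylome
        seed_sp = next(truth.species_tree.tips()).name
        targets = {seed_sp: set(phylome.trees)}
        table = coverage_report(phylome, targets)
        by_hand = np.mean(
            [t.count(tips=True) - 1 for t in phylome.trees.values()]
        )
        assert table.mean_homologs_per_tree.iloc[0] == pytest.approx(by_hand)
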
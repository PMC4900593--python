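"""Clade/topology enumeration, full and partial split support, reduction."""

import numpy as np
import pytest

from mitopool.simulate import simulate_treeset
from mitopool.treesupport import (
    TreeSample,
    enumerate_clades,
    enumerate_rooted_trees,
    full_split_support,
    partial_split_support,
    reduce_taxa,
    support_table,
    topology_frequencies,
)


def stepwise_addition_topologies(leaves):
    """Independent oracle: grow rooted trees by adding one leaf at a time
    onto every edge (including the root edge) of every partial tree."""
    leaves = sorted(leaves)
    trees = [("leaf", leaves[0])]
    for leaf in leaves[1:]:
        grown = []
        for t in trees:
            grown.extend(_attach_everywhere(t, leaf))
        trees = grown
    return {_canon(t) for t in trees}


def _attach_everywhere(tree, leaf):
    out = [("node", tree, ("leaf", leaf))]  # attach above the root
    if tree[0] == "node":
        _, left, right = tree
        out.extend(("node", l2, right) for l2 in _attach_everywhere(left, leaf))
        out.extend(("node", left, r2) for r2 in _attach_everywhere(right, leaf))
    return out


def _canon(tree):
    """Canonical string with children ordered by smallest leaf label."""
    string, _ = _canon_rec(tree)
    return string


def _canon_rec(tree):
    if tree[0] == "leaf":
        return tree[1], tree[1]
    parts = sorted((_canon_rec(tree[1]), _canon_rec(tree[2])),
                   key=lambda sm: sm[1])
    string = "(" + ",".join(s for s, _ in parts) + ")"
    return string, min(m for _, m in parts)


class TestEnumeration:
    def test_four_taxon_reduction_has_10_clades_and_15_trees(self):
        assert len(enumerate_clades("ABLR")) == 10
        assert len(enumerate_rooted_trees("ABLR")) == 15

    @pytest.mark.parametrize("n,expected", [(3, 3), (5, 25)])
    def test_clade_counts_follow_subset_formula(self, n, expected):
        leaves = [chr(ord("a") + i) for i in range(n)]
        clades = enumerate_clades(leaves)
        assert len(clades) == expected == 2 ** n - n - 2
        assert len(set(clades)) == len(clades)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6, 7])
    def test_rooted_tree_counts_match_double_factorial_and_oracle(self, n):
        leaves = [chr(ord("a") + i) for i in range(n)]
        mine = enumerate_rooted_trees(leaves)
        dfact = 1
        for k in range(3, 2 * n - 2, 2):
            dfact *= k
        assert len(mine) == dfact
        assert len(set(mine)) == len(mine)
        oracle = stepwise_addition_topologies(leaves)
        assert {t.rstrip(";") for t in mine} == oracle

    def test_combinatorial_guard(self):
        with pytest.raises(ValueError):
            enumerate_rooted_trees([f"t{i}" for i in range(10)])


class TestFullSplitSupport:
    def test_degenerate_sample_all_or_nothing(self):
        trees = ["((A,B),(L,R));"] * 1000
        sample = TreeSample(trees=trees)
        support = {c.clade: c.percent for c in full_split_support(sample)}
        assert support[frozenset("AB")] == 100.0
        assert support[frozenset("LR")] == 100.0
        assert support[frozenset("AL")] == 0.0
        freqs = topology_frequencies(sample)
        assert max(freqs.values()) == 100.0
        assert sum(freqs.values()) == 100.0

    def test_simulated_clade_frequency_within_binomial_error(self):
        ts = simulate_treeset("ABLR", {frozenset("AB"): 0.6}, 10_000, seed=42)
        support = {c.clade: c.percent for c in full_split_support(ts)}
        sd = 100 * np.sqrt(0.6 * 0.4 / 10_000)
        assert abs(support[frozenset("AB")] - 60.0) < 3 * sd

    def test_topology_frequencies_partition_unity_and_clade_identity(self):
        """Each clade's support equals the summed frequency of topologies
        containing it (checked exhaustively for n=4)."""
        from mitopool.treesupport import enumerate_rooted_trees_with_clusters

        ts = simulate_treeset(
            "ABLR", {frozenset("ABL"): 0.5, frozenset("AB"): 0.3},
            4000, seed=7,
        )
        freqs = topology_frequencies(ts)
        assert sum(freqs.values()) == pytest.approx(100.0)
        by_nwk = dict(enumerate_rooted_trees_with_clusters("ABLR"))
        support = {c.clade: c.percent for c in full_split_support(ts)}
        for clade, pct in support.items():
            via_topologies = sum(f for nwk, f in freqs.items()
                                 if clade in by_nwk[nwk])
            assert pct == pytest.approx(via_topologies)


class TestPartialSplitSupport:
    def test_direct_full_split_check(self):
        yes = TreeSample(trees=["((A,B),(L,R));"])
        no = TreeSample(trees=["((A,L),(B,R));"])
        assert partial_split_support(yes, "AB").percent == 100.0
        assert partial_split_support(no, "AB").percent == 0.0

    def test_worked_pruning_example(self):
        # ((A,(B,L)),R) pruned to {A,B,L} displays {B,L}, not {A,B}
        s = TreeSample(trees=["((A,(B,L)),R);"])
        assert partial_split_support(s, "AB", within="ABL").percent == 0.0
        assert partial_split_support(s, "BL", within="ABL").percent == 100.0

    def test_agrees_with_brute_force_pruning_on_random_samples(self):
        """Cluster-restriction support must equal prune-and-check with
        dendropy on random 6-leaf samples."""
        import dendropy

        leaves = list("ABCDEF")
        ts = simulate_treeset(leaves, {}, 60, seed=13)
        rng = np.random.default_rng(3)
        for _ in range(12):
            size = rng.integers(3, 6)
            within = sorted(rng.choice(leaves, size=size, replace=False))
            csize = rng.integers(2, len(within))
            clade = sorted(rng.choice(within, size=csize, replace=False))
            if len(clade) == len(within):
                continue
            mine = partial_split_support(ts, clade, within=within).percent

            count = 0
            for nwk in ts.trees:
                tree = dendropy.Tree.get(data=nwk, schema="newick",
                                         rooting="force-rooted")
                keep = [t for t in tree.taxon_namespace
                        if t.label in within]
                pruned = tree.extract_tree_with_taxa(taxa=keep)
                for node in pruned.preorder_internal_node_iter():
                    below = frozenset(l.taxon.label
                                      for l in node.leaf_iter())
                    if below == frozenset(clade):
                        count += 1
                        break
            assert mine == pytest.approx(100.0 * count / ts.n)

    def test_partial_support_never_below_full_support(self):
        """Pruning can only preserve or create displayed splits."""
        rng = np.random.default_rng(5)
        leaves = list("ABCDEF")
        ts = simulate_treeset(leaves, {}, 80, seed=21)
        for _ in range(10):
            clade = sorted(rng.choice(leaves, size=2, replace=False))
            others = [l for l in leaves if l not in clade]
            within = sorted(clade + list(
                rng.choice(others, size=2, replace=False)))
            full = partial_split_support(ts, clade).percent
            partial = partial_split_support(ts, clade, within=within).percent
            assert partial >= full

    def test_relabeling_invariance(self):
        ts = simulate_treeset("ABLR", {frozenset("AB"): 0.7}, 500, seed=9)
        mapping = {"A": "W", "B": "X", "L": "Y", "R": "Z"}
        relabeled = TreeSample(trees=[
            "".join(mapping.get(ch, ch) for ch in nwk) for nwk in ts.trees
        ])
        assert partial_split_support(ts, "AB").percent == \
            partial_split_support(relabeled, "WX").percent


class TestReduceTaxa:
    TREES_GOOD = ["((((A,B),(L1,L2)),R),P);"] * 6 + \
                 ["(((A,(L1,L2)),(B,R)),P);"] * 4

    def test_collapse_and_root_produce_four_taxon_sample(self):
        sample = TreeSample(trees=self.TREES_GOOD, source="toy")
        reduced = reduce_taxa(sample, {"L": ["L1", "L2"]}, root_taxon="P")
        assert reduced.leaves == frozenset("ABLR")
        support = {c.clade: c.percent
                   for c in full_split_support(reduced)}
        assert support[frozenset("AB")] == 60.0
        assert support[frozenset("BR")] == 40.0

    def test_nonmonophyletic_collapse_rejected_with_fraction(self):
        trees = self.TREES_GOOD + ["((((A,L1),(B,L2)),R),P);"]
        with pytest.raises(ValueError, match="9.1%"):
            reduce_taxa(TreeSample(trees=trees), {"L": ["L1", "L2"]},
                        root_taxon="P")

    def test_tolerance_drops_offending_trees(self):
        trees = self.TREES_GOOD + ["((((A,L1),(B,L2)),R),P);"]
        reduced = reduce_taxa(TreeSample(trees=trees), {"L": ["L1", "L2"]},
                              root_taxon="P", tol=0.2)
        assert reduced.n == 10

    def test_identity_collapse_keeps_sample_size(self):
        sample = TreeSample(trees=self.TREES_GOOD)
        reduced = reduce_taxa(sample, {}, root_taxon="P")
        assert reduced.n == sample.n
        assert reduced.leaves == frozenset(["A", "B", "L1", "L2", "R"])


class TestSupportTable:
    def test_degenerate_sample_row(self):
        s = TreeSample(trees=["((A,B),(L,R));"] * 10, source="one")
        df = support_table([s])
        assert df.shape == (1, 10)
        assert df.loc["one", "AB"] == 100.0
        assert df.loc["one", "AL"] == 0.0

    def test_rows_match_configured_mixtures(self):
        s1 = simulate_treeset("ABLR", {frozenset("AB"): 0.8}, 5000,
                              seed=1, source="m80")
        s2 = simulate_treeset("ABLR", {frozenset("AB"): 0.2}, 5000,
                              seed=2, source="m20")
        df = support_table([s1, s2])
        assert df.shape == (2, 10)
        sd = 100 * np.sqrt(0.2 * 0.8 / 5000)
        assert abs(df.loc["m80", "AB"] - 80.0) < 3 * sd + 0.05
        assert abs(df.loc["m20", "AB"] - 20.0) < 3 * sd + 0.05

    def test_leaf_set_mismatch_names_offender(self):
        s1 = TreeSample(trees=["((A,B),(L,R));"], source="good")
        s2 = TreeSample(trees=["((A,B),(L,Z));"], source="bad")
        with pytest.raises(ValueError, match="bad"):
            support_table([s1, s2])

    def test_written_table_renders_zero_as_dash(self, tmp_path):
        from mitopool.treesupport import write_support_table

        s = TreeSample(trees=["((A,B),(L,R));"] * 4, source="one")
        out = tmp_path / "support.tsv"
        write_support_table(support_table([s]), out)
        text = out.read_text()
        assert "100.0" in text and "\t-" in text
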
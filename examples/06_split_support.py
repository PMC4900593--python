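"""Full and partial split support on a reduced four-taxon problem.

Simulates a posterior-like sample of six-leaf trees, roots on the
outgroup, collapses a proven sister pair into one leaf (the reduction that
turns the Seychelles question into a four-taxon problem with 10 possible
clades and 15 rooted topologies), and prints the support table plus a
partial-split query.
"""

from mitopool.simulate import simulate_treeset
from mitopool.treesupport import (
    enumerate_clades,
    enumerate_rooted_trees,
    partial_split_support,
    reduce_taxa,
    support_table,
)

leaves = ["A", "B", "L1", "L2", "R", "P"]
sample = simulate_treeset(
    leaves,
    {frozenset(["L1", "L2"]): 1.0,                       # proven sister pair
     frozenset(["A", "B", "L1", "L2", "R"]): 1.0,        # ingroup vs outgroup P
     frozenset(["A", "B", "L1", "L2"]): 0.7,
     frozenset(["A", "B"]): 0.4},
    n_trees=1000, seed=77, source="BI synthetic",
)
reduced = reduce_taxa(sample, {"L": ["L1", "L2"]}, root_taxon="P")
print(f"reduced to {sorted(reduced.leaves)}: "
      f"{len(enumerate_clades(sorted(reduced.leaves)))} possible clades, "
      f"{len(enumerate_rooted_trees(sorted(reduced.leaves)))} rooted trees")

df = support_table([reduced])
print(df.to_string())

ps = partial_split_support(reduced, ["A", "B"], within=["A", "B", "R"])
print(f"partial split AB within {{A,B,R}}: {ps.percent:.1f}% "
      "(support on trees pruned to the subset, robust to L's position)")
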
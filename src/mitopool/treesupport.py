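"""Frequency-of-occurrence support for full and partial splits in tree sets.

Bayesian posterior samples and bootstrap replicates are collections of trees
on a shared leaf set.  When the biological question reduces to a small number
of taxa (after accepting an outgroup rooting and collapsing clades that are
recovered in every tree), the full space of rooted topologies can be
enumerated and every possible clade scored by how often it occurs in the
sample.  Partial splits — clades defined on a proper subset of the leaves —
are scored on the trees pruned to that subset, which makes support robust to
unstably placed ("rogue") taxa.

Trees are held internally as sets of clusters (the leaf set below each
internal node of the rooted tree); all support computations reduce to set
operations on those clusters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "TreeSample",
    "CladeSupport",
    "enumerate_clades",
    "enumerate_rooted_trees",
    "full_split_support",
    "topology_frequencies",
    "partial_split_support",
    "reduce_taxa",
    "support_table",
]

Clade = frozenset


# ---------------------------------------------------------------------------
# tree containers


def _newick_to_clusters(newick: str) -> tuple[frozenset, frozenset]:
    """Parse one newick string into (leaf set, set of nontrivial clusters).

    The tree is read as rooted as written.  Clusters are the leaf sets below
    internal nodes, excluding singletons and the full leaf set.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    clusters = set()
    for node in tree.preorder_internal_node_iter():
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(below) < len(leaves):
            clusters.add(below)
    return leaves, frozenset(clusters)


def clusters_to_newick(clusters: Iterable[Clade], leaves: Iterable[str]) -> str:
    """Build the canonical newick string of the rooted tree with the given
    clusters.  Children at every node are sorted by their smallest leaf
    label, so equal topologies always produce equal strings."""
    leaves = frozenset(leaves)
    clusters = [frozenset(c) for c in clusters]

    def build(group: frozenset) -> str:
        if len(group) == 1:
            return next(iter(group))
        # maximal proper sub-clusters of this group partition its children
        subs = [c for c in clusters if c < group]
        maximal = [c for c in subs if not any(c < d for d in subs)]
        covered = frozenset().union(*maximal) if maximal else frozenset()
        parts = maximal + [frozenset([l]) for l in group - covered]
        parts.sort(key=lambda p: min(p))
        return "(" + ",".join(build(p) for p in parts) + ")"

    return build(leaves) + ";"


@dataclass
class TreeSample:
    """A collection of rooted trees on a shared leaf set.

    ``trees`` holds newick strings; cluster sets are computed lazily and
    cached.  ``source`` is a free-text analysis label (e.g. ``"BI All"``).
    """

    trees: list[str]
    source: str = ""
    _leaves: frozenset = field(default=None, repr=False)
    _clusters: list[frozenset] = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.trees)

    @property
    def leaves(self) -> frozenset:
        self._ensure_parsed()
        return self._leaves

    def cluster_sets(self) -> list[frozenset]:
        """Per-tree frozensets of nontrivial clusters."""
        self._ensure_parsed()
        return self._clusters

    def _ensure_parsed(self) -> None:
        if self._clusters is not None:
            return
        leaves = None
        clusters = []
        for nwk in self.trees:
            lv, cl = _newick_to_clusters(nwk)
            if leaves is None:
                leaves = lv
            elif lv != leaves:
                raise ValueError(
                    f"tree leaf set {sorted(lv)} differs from {sorted(leaves)}"
                )
            clusters.append(cl)
        if leaves is None:
            raise ValueError("empty tree sample")
        self._leaves = leaves
        self._clusters = clusters

    @classmethod
    def from_newick_file(cls, path, source: str = "") -> "TreeSample":
        with open(path) as fh:
            trees = [line.strip() for line in fh if line.strip()]
        return cls(trees=trees, source=source)

    @classmethod
    def from_nexus_file(cls, path, source: str = "") -> "TreeSample":
        """Read a Nexus trees block (translate tables supported)."""
        tl = dendropy.TreeList.get(path=str(path), schema="nexus")
        trees = [
            t.as_string(schema="newick", suppress_rooting=True).strip() for t in tl
        ]
        return cls(trees=trees, source=source)

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.trees:
                fh.write(t.rstrip("\n") + "\n")

    def subsample(self, m: int, seed: int) -> "TreeSample":
        """Draw ``m`` trees uniformly without replacement (posterior thinning
        is the caller's responsibility)."""
        import numpy as np

        rng = np.random.default_rng(seed)
        idx = rng.choice(len(self.trees), size=m, replace=False)
        return TreeSample(trees=[self.trees[i] for i in idx], source=self.source)


@dataclass(frozen=True)
class CladeSupport:
    clade: Clade
    kind: str  # "full" | "partial"
    percent: float


# ---------------------------------------------------------------------------
# enumeration


def enumerate_clades(leaves: Sequence[str]) -> list[Clade]:
    """All possible nontrivial clades of a rooted tree on ``leaves``:
    every subset of size 2..n-1.  Count is 2**n - n - 2."""
    leaves = sorted(set(leaves))
    if len(leaves) < 2:
        raise ValueError("need at least 2 leaves")
    out = []
    for k in range(2, len(leaves)):
        out.extend(frozenset(c) for c in itertools.combinations(leaves, k))
    return out


def _enumerate_rooted(leaves: frozenset) -> list[frozenset]:
    """All rooted binary topologies on ``leaves`` as frozensets of nontrivial
    clusters (relative to the full input leaf set handled by the caller)."""
    if len(leaves) == 1:
        return [frozenset()]
    items = sorted(leaves)
    anchor = items[0]
    rest = items[1:]
    out = []
    # unordered bipartitions {left, right}: anchor always goes left
    for r in range(0, len(rest)):
        for right_tuple in itertools.combinations(rest, len(rest) - r):
            right = frozenset(right_tuple)
            left = leaves - right
            if not right or not left:
                continue
            for lt in _enumerate_rooted(left):
                for rt in _enumerate_rooted(right):
                    clusters = set(lt) | set(rt)
                    if len(left) > 1:
                        clusters.add(left)
                    if len(right) > 1:
                        clusters.add(right)
                    out.append(frozenset(clusters))
    return out


def enumerate_rooted_trees(leaves: Sequence[str]) -> list[str]:
    """All (2n-3)!! rooted binary labelled topologies on ``leaves``, each as
    a canonical newick string (children sorted by smallest leaf).

    Guarded at n > 9; for four taxa this yields the 15 distinct rooted
    trees (and :func:`enumerate_clades` the 10 possible clades) of the
    reduced caecilian problem.
    """
    leafset = frozenset(leaves)
    if len(leafset) < 2:
        raise ValueError("need at least 2 leaves")
    if len(leafset) > 9:
        raise ValueError("rooted topology enumeration limited to n <= 9")
    seen = {}
    for clusters in _enumerate_rooted(leafset):
        nwk = clusters_to_newick(clusters, leafset)
        seen[nwk] = clusters
    return sorted(seen)


def enumerate_rooted_trees_with_clusters(
    leaves: Sequence[str],
) -> list[tuple[str, frozenset]]:
    """Like :func:`enumerate_rooted_trees` but also returning each topology's
    cluster set (used by the tree-set simulator and topology tallies)."""
    leafset = frozenset(leaves)
    if len(leafset) < 2:
        raise ValueError("need at least 2 leaves")
    if len(leafset) > 9:
        raise ValueError("rooted topology enumeration limited to n <= 9")
    seen = {}
    for clusters in _enumerate_rooted(leafset):
        nwk = clusters_to_newick(clusters, leafset)
        seen[nwk] = clusters
    return sorted(seen.items())


# ---------------------------------------------------------------------------
# support


def full_split_support(sample: TreeSample) -> list[CladeSupport]:
    """Percent of trees containing each possible clade of the full leaf set."""
    cl_sets = sample.cluster_sets()
    n = sample.n
    out = []
    for clade in enumerate_clades(sorted(sample.leaves)):
        count = sum(1 for cl in cl_sets if clade in cl)
        out.append(CladeSupport(clade=clade, kind="full", percent=100.0 * count / n))
    return out


def topology_frequencies(sample: TreeSample) -> dict[str, float]:
    """Percent frequency of every enumerated rooted topology in the sample.

    For fully resolved samples these sum to 100; trees with polytomies match
    no binary topology and dilute all frequencies.
    """
    leaves = sorted(sample.leaves)
    topo = enumerate_rooted_trees_with_clusters(leaves)
    by_clusters = {cl: nwk for nwk, cl in topo}
    counts = {nwk: 0 for nwk, _ in topo}
    for cl in sample.cluster_sets():
        nwk = by_clusters.get(cl)
        if nwk is not None:
            counts[nwk] += 1
    return {nwk: 100.0 * c / sample.n for nwk, c in counts.items()}


def partial_split_support(sample: TreeSample, clade: Iterable[str],
                          within: Iterable[str] | None = None) -> CladeSupport:
    """Support for ``clade`` evaluated on trees pruned to the leaf subset
    ``within`` (default: the full leaf set, i.e. full-split support).

    A pruned rooted tree displays the clade iff some cluster C of the
    original tree satisfies C ∩ within == clade.  Clades on fewer than three
    taxa of the induced problem are trivially displayed and flagged by a
    100.0 result.
    """
    clade = frozenset(clade)
    within = frozenset(within) if within is not None else sample.leaves
    if not clade <= within <= sample.leaves:
        raise ValueError("clade must be a subset of `within`, within the leaf set")
    if not 1 < len(clade) < len(within):
        raise ValueError("clade must be a nontrivial proper subset of `within`")
    kind = "full" if within == sample.leaves else "partial"
    count = 0
    for cl in sample.cluster_sets():
        candidates = set(cl) | {sample.leaves}
        if any(c & within == clade for c in candidates):
            count += 1
    return CladeSupport(clade=clade, kind=kind, percent=100.0 * count / sample.n)


# ---------------------------------------------------------------------------
# taxon reduction


def reduce_taxa(
    sample: TreeSample,
    collapse: Mapping[str, Iterable[str]],
    root_taxon: str,
    tol: float = 0.0,
    drop_root: bool = True,
) -> TreeSample:
    """Root every tree on ``root_taxon`` and collapse each named taxon set to
    a single leaf, producing the reduced problem (e.g. the four-taxon
    {A, B, L, R} frame after accepting the outgroup rooting and merging the
    sister species pair).

    Each collapse set must be monophyletic — appear as a split — in at least
    a fraction ``1 - tol`` of the trees; trees where any set is not a clade
    are dropped.  With the default ``tol=0`` a single non-monophyletic tree
    rejects the reduction, reporting the offending fraction.  The root taxon
    is removed from the reduced leaf set when ``drop_root`` is true (rooted
    clades are read off the ingroup).
    """
    sample._ensure_parsed()
    leaves = sample.leaves
    if root_taxon not in leaves:
        raise ValueError(f"root taxon {root_taxon!r} not in leaf set")
    collapse = {k: frozenset(v) for k, v in collapse.items()}
    for name, members in collapse.items():
        if not members <= leaves:
            raise ValueError(f"collapse set {name!r} not within the leaf set")

    def rooted_side(cluster: frozenset) -> frozenset:
        # side of the split not containing the root taxon
        return cluster if root_taxon not in cluster else leaves - cluster

    kept_newicks = []
    bad = 0
    reduced_leaves = None
    for nwk, cl in zip(sample.trees, sample.cluster_sets()):
        sides = {rooted_side(c) for c in cl}
        sides.discard(frozenset())
        ok = all(
            members in sides or len(members) == 1 for members in collapse.values()
        )
        if not ok:
            bad += 1
            continue
        # relabel: each collapse set becomes one leaf; root taxon dropped
        def relabel(group: frozenset) -> frozenset:
            out = set(group) - ({root_taxon} if drop_root else set())
            for name, members in collapse.items():
                if members <= group:
                    out -= members
                    out.add(name)
                elif members & group:
                    out -= members  # partial overlap only possible above clade
            return frozenset(out)

        new_leaves = relabel(leaves)
        if reduced_leaves is None:
            reduced_leaves = new_leaves
        clusters = set()
        for side in sides:
            g = relabel(side)
            if 1 < len(g) < len(new_leaves):
                clusters.add(g)
        kept_newicks.append(clusters_to_newick(clusters, new_leaves))

    frac_bad = bad / sample.n
    if frac_bad > tol:
        raise ValueError(
            f"collapse sets non-monophyletic in {100 * frac_bad:.1f}% of trees "
            f"(tolerance {100 * tol:.1f}%)"
        )
    return TreeSample(trees=kept_newicks, source=sample.source)


# ---------------------------------------------------------------------------
# reporting


def support_table(samples: Sequence[TreeSample]) -> pd.DataFrame:
    """Matrix of analyses x possible clades, percentages.

    All samples must share one (reduced) leaf set; columns are the
    enumerated clades, labelled by concatenated sorted members.
    """
    if not samples:
        raise ValueError("no samples")
    leaves = samples[0].leaves
    for s in samples[1:]:
        if s.leaves != leaves:
            raise ValueError(
                f"sample {s.source!r} has leaf set {sorted(s.leaves)}, "
                f"expected {sorted(leaves)}"
            )
    clades = enumerate_clades(sorted(leaves))
    cols = ["".join(sorted(c)) for c in clades]
    rows = {}
    for s in samples:
        support = {cs.clade: cs.percent for cs in full_split_support(s)}
        rows[s.source or f"sample{len(rows) + 1}"] = [
            round(support[c], 1) for c in clades
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def write_support_table(df: pd.DataFrame, path) -> None:
    """TSV with zero support rendered as '-' (the printed convention)."""
    out = df.map(lambda v: "-" if v == 0 else f"{v:.1f}")
    out.to_csv(path, sep="\t", index_label="Analysis")
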
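"""Distance-based phylogenetics robust to base-composition heterogeneity.

When lineages drift toward different base compositions, distances derived
from stationary reversible models are inconsistent.  The LogDet/paralinear
distance,

    d(x, y) = -1/4 * [ ln det F  -  1/2 * ln( det Dx * det Dy ) ],

with F the 4x4 joint relative-frequency matrix of aligned site patterns and
Dx, Dy the diagonal marginal-frequency matrices, remains additive under any
general Markov process, stationary or not.  The -1/4 scaling is the 4-state
convention; rescale if comparing against software using another constant.

The module also provides the chi-square test of base-composition
homogeneity across taxa, a neighbor-joining realisation of the
minimum-evolution criterion, and nonparametric bootstrap over alignment
columns feeding :mod:`mitopool.treesupport`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency

from .reduction import ReferenceAlignment
from .treesupport import TreeSample

__all__ = [
    "DistanceMatrix",
    "CompositionTest",
    "logdet_distance",
    "p_distance_matrix",
    "logdet_matrix",
    "composition_chi2",
    "nj_me_tree",
    "bootstrap_trees",
    "UndefinedDistanceError",
]

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


class UndefinedDistanceError(ValueError):
    """Raised when the divergence matrix is singular (e.g. a base entirely
    absent from one sequence) and the LogDet distance is undefined."""


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray
    method: str  # "p" | "logdet"

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape must match taxon count")

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.taxa)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(self.d[i, j]):
                    out.append((self.taxa[i], self.taxa[j]))
        return out

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for name, row in zip(self.taxa, self.d):
                vals = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{name:<12s} {vals}\n")


@dataclass
class CompositionTest:
    table: np.ndarray  # taxa x bases counts (zero-total columns dropped)
    taxa: list[str]
    bases: str
    statistic: float
    df: int
    p_value: float


def _codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _pair_mask(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.isin(x, _ACGT) & np.isin(y, _ACGT)


def logdet_distance(seq_x: str, seq_y: str) -> float:
    """LogDet/paralinear distance between two aligned sequences.

    Gap/N columns are pairwise-deleted.  Zero for identical sequences;
    raises :class:`UndefinedDistanceError` when F is singular or has a
    non-positive determinant (typically a base missing from one sequence).
    """
    x, y = _codes(seq_x), _codes(seq_y)
    if x.shape != y.shape:
        raise ValueError("sequences must be aligned (equal length)")
    mask = _pair_mask(x, y)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no comparable columns after pairwise deletion")
    xi = np.searchsorted(_ACGT, x[mask])
    yi = np.searchsorted(_ACGT, y[mask])
    f = np.zeros((4, 4))
    np.add.at(f, (xi, yi), 1.0)
    f /= n
    fx = f.sum(axis=1)
    fy = f.sum(axis=0)
    det_f = np.linalg.det(f)
    if det_f <= 0 or (fx <= 0).any() or (fy <= 0).any():
        raise UndefinedDistanceError(
            "singular site-pattern matrix; LogDet undefined for this pair"
        )
    return float(-0.25 * (np.log(det_f)
                          - 0.5 * (np.log(fx).sum() + np.log(fy).sum())))


def _matrix(aln: ReferenceAlignment, fn, method: str) -> DistanceMatrix:
    n = len(aln.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = fn(aln.rows[i], aln.rows[j])
            except UndefinedDistanceError:
                d[i, j] = d[j, i] = np.nan
    return DistanceMatrix(taxa=list(aln.taxa), d=d, method=method)


def p_distance_matrix(aln: ReferenceAlignment) -> DistanceMatrix:
    from .reduction import p_distance

    return _matrix(aln, p_distance, "p")


def logdet_matrix(aln: ReferenceAlignment) -> DistanceMatrix:
    return _matrix(aln, logdet_distance, "logdet")


def composition_chi2(aln: ReferenceAlignment) -> CompositionTest:
    """Chi-square homogeneity test of base composition across taxa.

    Counts come from non-gap, non-N sites per taxon; bases absent from the
    entire alignment are dropped with the degrees of freedom adjusted.
    With identical compositions the statistic is 0 and p = 1.
    """
    if len(aln.taxa) < 2:
        raise ValueError("need at least 2 taxa")
    counts = np.zeros((len(aln.taxa), 4))
    for i, row in enumerate(aln.rows):
        codes = _codes(row)
        for k in range(4):
            counts[i, k] = int((codes == _ACGT[k]).sum())
    keep = counts.sum(axis=0) > 0
    bases = "".join(b for b, k in zip("ACGT", keep) if k)
    table = counts[:, keep]
    if (table.sum(axis=1) == 0).any():
        raise ValueError("a taxon has no countable bases")
    expected = (table.sum(axis=1, keepdims=True)
                * table.sum(axis=0, keepdims=True) / table.sum())
    if np.allclose(table, expected):
        stat, p = 0.0, 1.0
        df = (table.shape[0] - 1) * (table.shape[1] - 1)
    else:
        stat, p, df, _ = chi2_contingency(table, correction=False)
    return CompositionTest(table=table, taxa=list(aln.taxa), bases=bases,
                           statistic=float(stat), df=int(df),
                           p_value=float(p))


# ---------------------------------------------------------------------------
# neighbor joining (the standard heuristic for minimum evolution)


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # (child, branch_length)

    def newick(self) -> str:
        def fmt(node, blen):
            if node.label is not None and not node.children:
                core = node.label
            else:
                core = "(" + ",".join(fmt(c, b) for c, b in node.children) + ")"
            return core if blen is None else f"{core}:{blen:.6g}"

        return fmt(self, None) + ";"


def nj_me_tree(dm: DistanceMatrix, seed: int | None = None) -> str:
    """Neighbor-joining tree (newick, unrooted) from a complete matrix.

    On additive matrices NJ reconstructs the generating tree exactly, path
    lengths included.  Ties in the Q criterion are broken by a seeded RNG
    when ``seed`` is given, first-index otherwise.  Undefined entries are
    rejected with the offending pairs listed.
    """
    bad = dm.undefined_pairs()
    if bad:
        raise UndefinedDistanceError(f"undefined distances for pairs: {bad}")
    n = len(dm.taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed) if seed is not None else None
    nodes = [_Node(label=t) for t in dm.taxa]
    d = dm.d.astype(float).copy()
    active = list(range(n))

    if n == 2:
        root = _Node(children=[(nodes[0], d[0, 1] / 2), (nodes[1], d[0, 1] / 2)])
        return root.newick()

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        pick = ties[0] if rng is None else ties[rng.integers(len(ties))]
        i, j = int(pick[0]), int(pick[1])
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        bi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        bj = dij - bi
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        parent = _Node(children=[(nodes[ai], bi), (nodes[aj], bj)])
        # distances from the new node to the rest
        new_d = 0.5 * (d[ai, :] + d[aj, :] - dij)
        d = np.vstack([d, new_d])
        new_col = np.append(new_d, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        new_idx = len(nodes) - 1
        active = [a for a in active if a not in (ai, aj)] + [new_idx]

    a1, a2 = active
    root = _Node(children=[(nodes[a1], max(d[a1, a2], 0.0) / 2),
                           (nodes[a2], max(d[a1, a2], 0.0) / 2)])
    return root.newick()


def bootstrap_trees(
    aln: ReferenceAlignment,
    n_reps: int,
    method: str = "logdet",
    seed: int = 0,
    max_redraws: int = 100,
) -> TreeSample:
    """Nonparametric bootstrap: resample alignment columns with replacement,
    recompute the distance matrix and NJ tree per replicate.

    Replicates whose distance matrix has undefined entries are redrawn (the
    redraw count is reported on the returned sample's ``source``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    builder = logdet_matrix if method == "logdet" else p_distance_matrix
    rng = np.random.default_rng(seed)
    L = aln.length
    trees = []
    redraws = 0
    m = aln.matrix()
    while len(trees) < n_reps:
        cols = rng.integers(0, L, size=L)
        sub = m[:, cols]
        rows = [sub[i].tobytes().decode() for i in range(sub.shape[0])]
        rep = ReferenceAlignment(taxa=list(aln.taxa), rows=rows,
                                 circular=False)
        dm = builder(rep)
        if dm.undefined_pairs():
            redraws += 1
            if redraws > max_redraws:
                raise UndefinedDistanceError(
                    "too many bootstrap replicates with undefined distances"
                )
            continue
        trees.append(nj_me_tree(dm, seed=int(rng.integers(2 ** 31))))
    src = f"{method} bootstrap (n={n_reps}"
    src += f", redraws={redraws})" if redraws else ")"
    return TreeSample(trees=trees, source=src)
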
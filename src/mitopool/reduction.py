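"""Divergence-windowed reduction of non-indexed pooled read data.

When amplicons from hundreds of taxa are pooled on one lane without index
barcodes, reads for the taxa of interest must be fished out by similarity to
a reference alignment of close relatives.  Because divergence varies along
the mitogenome, a single mismatch threshold either loses reads in the fast
regions or drags in contaminants in the slow ones.  The approach here:

1. slide a window along the circular reference alignment and record the
   maximum pairwise p-distance among the reference taxa;
2. partition the alignment into blocks of roughly homogeneous divergence,
   overlapping by at least ``min_overlap`` columns so reads straddling a
   boundary are not lost;
3. per block, build a consensus reference and set the retention threshold to
   the block's maximum divergence plus an allowance;
4. retain every pooled read whose best (either-strand) alignment to a block
   consensus has a mismatch fraction at or below the block threshold.

Coordinates are 0-based, half-open, with circular wrap: a window whose start
exceeds its end crosses the alignment origin.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

import edlib

from ._mapping import affine_local_alignment, passes_constraints, revcomp

__all__ = [
    "ReferenceAlignment",
    "Window",
    "sliding_pdistance_profile",
    "partition_by_divergence",
    "validate_windows",
    "window_consensus",
    "compute_threshold",
    "extract_reads",
    "p_distance",
]

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class ReferenceAlignment:
    """A multiple alignment of reference mitogenomes (rows over ACGT-N)."""

    taxa: list[str]
    rows: list[str]
    circular: bool = True

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path, circular: bool = True) -> "ReferenceAlignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        return cls(taxa=[r.id for r in recs], rows=[str(r.seq) for r in recs],
                   circular=circular)

    def matrix(self) -> np.ndarray:
        """Rows as a byte matrix for vectorised column arithmetic."""
        return np.frombuffer(
            "".join(self.rows).encode(), dtype=np.uint8
        ).reshape(len(self.rows), self.length)

    def rotated(self, k: int) -> "ReferenceAlignment":
        """Move the last ``k`` columns to the front (origin shift)."""
        return ReferenceAlignment(
            taxa=list(self.taxa),
            rows=[r[-k:] + r[:-k] if k else r for r in self.rows],
            circular=self.circular,
        )


@dataclass
class Window:
    """A circular interval on the alignment with its divergence summary."""

    start: int
    end: int  # half-open; end < start means the window wraps the origin
    max_p_distance: float = 0.0
    consensus: str = ""
    threshold: float = 0.0

    def columns(self, length: int) -> np.ndarray:
        if self.end > self.start:
            return np.arange(self.start, self.end)
        return np.concatenate(
            [np.arange(self.start, length), np.arange(0, self.end)]
        )

    def size(self, length: int) -> int:
        return (self.end - self.start) % length or length


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites, pairwise-deleting gap/N columns."""
    x = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    y = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    if x.shape != y.shape:
        raise ValueError("sequences must be aligned (equal length)")
    valid_x = np.isin(x, np.frombuffer(b"ACGT", dtype=np.uint8))
    valid_y = np.isin(y, np.frombuffer(b"ACGT", dtype=np.uint8))
    both = valid_x & valid_y
    n = int(both.sum())
    if n == 0:
        raise ValueError("no comparable columns after pairwise deletion")
    return float((x[both] != y[both]).sum()) / n


def sliding_pdistance_profile(
    aln: ReferenceAlignment, window_len: int, step: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum pairwise p-distance in a sliding window.

    Returns ``(starts, profile)``: for each window start (spaced ``step``
    columns apart; every start on a circular alignment), the maximum over
    all taxon pairs of the window p-distance with pairwise deletion.
    """
    if window_len < 1 or step < 1:
        raise ValueError("window_len and step must be >= 1")
    L = aln.length
    if window_len > L and not aln.circular:
        raise ValueError("window longer than a non-circular alignment")
    m = aln.matrix()
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    valid = np.isin(m, acgt)
    nrows = m.shape[0]

    starts = np.arange(0, L if aln.circular else L - window_len + 1, step)
    profile = np.zeros(len(starts))
    # per-pair cumulative sums over doubled columns handle the wrap
    reps = 2 if aln.circular else 1
    for i in range(nrows):
        for j in range(i + 1, nrows):
            both = (valid[i] & valid[j]).astype(np.int64)
            diff = ((m[i] != m[j]) & (both > 0)).astype(np.int64)
            cb = np.concatenate([[0], np.tile(both, reps).cumsum()])
            cd = np.concatenate([[0], np.tile(diff, reps).cumsum()])
            nb = cb[starts + window_len] - cb[starts]
            nd = cd[starts + window_len] - cd[starts]
            with np.errstate(invalid="ignore", divide="ignore"):
                pd_ = np.where(nb > 0, nd / np.maximum(nb, 1), 0.0)
            np.maximum(profile, pd_, out=profile)
    return starts, profile


def partition_by_divergence(
    starts: np.ndarray,
    profile: np.ndarray,
    circular_length: int,
    min_block: int = 250,
    min_overlap: int = 50,
    max_blocks: int = 16,
    homogeneity_tol: float = 0.05,
    circular: bool = True,
) -> list[Window]:
    """Greedy change-point segmentation of a divergence profile into blocks.

    A new block opens whenever the running within-block range of the profile
    exceeds ``homogeneity_tol`` and the current block has reached
    ``min_block`` columns.  Block boundaries are then widened so every
    consecutive pair (last-to-first included when circular) overlaps by at
    least ``min_overlap`` columns.  Blocks cover the full alignment.
    """
    L = circular_length
    if L <= min_block:
        return [Window(start=0, end=L % L if circular else L)]
    values = np.asarray(profile, dtype=float)
    pos = np.asarray(starts)

    boundaries = [0]
    lo = hi = values[0]
    block_start_idx = 0
    for i in range(1, len(values)):
        lo, hi = min(lo, values[i]), max(hi, values[i])
        span = pos[i] - pos[block_start_idx]
        if hi - lo > homogeneity_tol and span >= min_block:
            boundaries.append(int(pos[i]))
            block_start_idx = i
            lo = hi = values[i]
    if len(boundaries) > max_blocks:
        # merge the shortest adjacent blocks until within budget
        while len(boundaries) > max_blocks:
            spans = [
                (boundaries[(k + 1) % len(boundaries)] - boundaries[k]) % L or L
                for k in range(len(boundaries))
            ]
            k = int(np.argmin(spans[1:]) + 1)  # never drop the origin boundary
            boundaries.pop(k)

    windows = []
    nb = len(boundaries)
    for k in range(nb):
        s = boundaries[k]
        e = boundaries[(k + 1) % nb] if k + 1 < nb or circular else L
        if k + 1 == nb and not circular:
            e = L
        # widen by the overlap on the leading edge (circular wrap allowed)
        s_wide = (s - min_overlap) % L if (circular or s >= min_overlap) else 0
        windows.append(Window(start=s_wide, end=e % L if circular else e))
    if nb == 1:
        windows = [Window(start=0, end=0 if circular else L)]
    return windows


def validate_windows(
    windows: Sequence[Window], min_overlap: int, circular_length: int
) -> dict:
    """Check a window scheme against the overlap-and-coverage contract.

    Returns ``min_consecutive_overlap`` (the smallest circular overlap
    between neighbouring windows, ``None`` for a single all-covering
    window), ``covers_alignment`` and a pass flag.
    """
    if not windows:
        raise ValueError("no windows")
    L = circular_length
    masks = []
    for w in windows:
        mask = np.zeros(L, dtype=bool)
        mask[w.columns(L)] = True
        masks.append(mask)
    union = np.logical_or.reduce(masks)
    covers = bool(union.all())
    if len(windows) == 1:
        return {
            "min_consecutive_overlap": None,
            "covers_alignment": covers,
            "ok": covers,
        }
    order = sorted(range(len(windows)), key=lambda i: windows[i].start)
    overlaps = []
    for k in range(len(order)):
        a = masks[order[k]]
        b = masks[order[(k + 1) % len(order)]]
        overlaps.append(int((a & b).sum()))
    min_ov = min(overlaps)
    return {
        "min_consecutive_overlap": min_ov,
        "covers_alignment": covers,
        "ok": covers and min_ov >= min_overlap,
    }


def window_consensus(aln: ReferenceAlignment, window: Window) -> str:
    """Majority-rule consensus of the window columns, gap-free.

    Ties among bases produce IUPAC ambiguity codes; columns whose majority
    symbol is a gap (or that contain no unambiguous base) are dropped, so
    the consensus can serve directly as a mapping reference.
    """
    cols = window.columns(aln.length)
    out = []
    for c in cols:
        column = [row[c] for row in aln.rows]
        counts = Counter(b for b in column if b in "ACGT")
        gaps = sum(1 for b in column if b == "-")
        if not counts:
            continue
        top = max(counts.values())
        if gaps > top:
            continue
        tied = frozenset(b for b, n in counts.items() if n == top)
        out.append(_IUPAC[tied])
    return "".join(out)


def compute_threshold(
    max_p_distance: float, allowance: float, mode: str = "additive"
) -> float:
    """Per-window read-retention mismatch threshold.

    ``additive`` (default) adds the allowance in percentage points
    (0.22 + 0.10 -> 0.32); ``multiplicative`` scales
    (0.22 * 1.10 -> 0.242).  Capped at 1.
    """
    if not (0 <= max_p_distance <= 1 and 0 <= allowance <= 1):
        raise ValueError("inputs must be fractions in [0, 1]")
    if mode == "additive":
        t = max_p_distance + allowance
    elif mode == "multiplicative":
        t = max_p_distance * (1.0 + allowance)
    else:
        raise ValueError(f"unknown allowance mode {mode!r}")
    return min(t, 1.0)


def annotate_windows(
    aln: ReferenceAlignment,
    windows: Iterable[Window],
    allowance: float = 0.10,
    mode: str = "additive",
) -> list[Window]:
    """Fill in each window's max p-distance, consensus and threshold."""
    out = []
    for w in windows:
        cols = w.columns(aln.length)
        sub_rows = ["".join(row[c] for c in cols) for row in aln.rows]
        dmax = 0.0
        for i in range(len(sub_rows)):
            for j in range(i + 1, len(sub_rows)):
                try:
                    dmax = max(dmax, p_distance(sub_rows[i], sub_rows[j]))
                except ValueError:
                    pass
        out.append(
            Window(
                start=w.start,
                end=w.end,
                max_p_distance=dmax,
                consensus=window_consensus(aln, w),
                threshold=compute_threshold(dmax, allowance, mode),
            )
        )
    return out


def extract_reads(
    pool,
    consensus: str,
    threshold: float,
    max_gap_frac: float = 0.15,
    max_gap_size: int = 50,
    circular: bool = False,
    min_aligned_frac: float = 0.5,
):
    """Subset of pooled reads within the mismatch threshold of a consensus.

    Each read is aligned to the consensus on both strands; it is retained
    iff its best local alignment covers at least ``min_aligned_frac`` of
    the read, has substitution fraction at or below ``threshold`` over the
    aligned columns, and satisfies the gap constraints.  Retained reads
    keep their ids and order.  ``circular=True`` doubles the consensus so
    reads spanning the origin of a whole-circle reference are not lost
    (multi-window schemes achieve the same via the wrap window).

    A fast edit-distance gate rejects reads whose minimum possible
    substitutions + gap bases already exceed the combined budget; survivors
    are scored under affine gap penalties, which keeps substitutions and
    indels distinct the way a mapping assembler does.
    """
    from .simulate import ReadSet

    if not consensus:
        raise ValueError("empty consensus")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    target = consensus + consensus if circular else consensus
    kept = []
    for read in pool.reads:
        budget = int((threshold + max_gap_frac) * len(read.seq)) + 2
        best = None
        for seq in (read.seq, revcomp(read.seq)):
            res = edlib.align(seq, target, mode="HW", k=budget,
                              task="locations")
            ed = res["editDistance"]
            if ed < 0:
                continue
            if best is None or ed < best[0]:
                best = (ed, seq, res["locations"][0])
        if best is None:  # both strands exceeded the budget
            continue
        _, seq, (lo, hi) = best
        pad = max(20, int(0.2 * len(seq)))
        window = target[max(0, lo - pad):hi + 1 + pad]
        stats = affine_local_alignment(seq, window)
        if stats is None:
            continue
        aligned_read = len(read.seq) - stats.query_clip_left \
            - stats.query_clip_right
        if aligned_read < min_aligned_frac * len(read.seq):
            continue
        if passes_constraints(stats, len(read.seq), threshold,
                              max_gap_frac, max_gap_size):
            kept.append(read)
    labels = {r.id: pool.labels[r.id] for r in kept if r.id in pool.labels}
    return ReadSet(reads=kept, labels=labels, platform=pool.platform)
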
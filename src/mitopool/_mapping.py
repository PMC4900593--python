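"""Shared read-to-reference alignment machinery.

Thin layer over edlib: k-mer seeding locates candidate placements, edlib
produces an optimal edit path for the placed slice, and the path is parsed
into substitution / gap statistics so that mismatch and gap constraints can
be enforced separately (mappers in this domain bound them independently).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XID])")

_COMP = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class AlignmentStats:
    ref_start: int          # reference position of first aligned read base
    ref_end: int            # half-open end on the reference
    matches: int
    mismatches: int
    gap_bases: int          # inserted + deleted bases
    max_gap_run: int
    strand: int             # +1 / -1
    cigar: str
    query_clip_left: int    # read bases hanging off the reference start
    query_clip_right: int

    @property
    def aligned_columns(self) -> int:
        return self.matches + self.mismatches

    @property
    def mismatch_frac(self) -> float:
        cols = self.aligned_columns
        return self.mismatches / cols if cols else 1.0

    @property
    def score(self) -> int:
        return self.matches - self.mismatches - self.gap_bases


def _parse_cigar(cigar: str):
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _stats_from_cigar(cigar: str, ref_start: int, strand: int,
                      clip_left: int = 0, clip_right: int = 0) -> AlignmentStats:
    matches = mismatches = gaps = max_run = 0
    ref_len = 0
    for n, op in _parse_cigar(cigar):
        if op == "=":
            matches += n
            ref_len += n
        elif op == "X":
            mismatches += n
            ref_len += n
        elif op == "I":        # insertion relative to the reference
            gaps += n
            max_run = max(max_run, n)
        elif op == "D":
            gaps += n
            ref_len += n
            max_run = max(max_run, n)
    return AlignmentStats(
        ref_start=ref_start, ref_end=ref_start + ref_len,
        matches=matches, mismatches=mismatches, gap_bases=gaps,
        max_gap_run=max_run, strand=strand, cigar=cigar,
        query_clip_left=clip_left, query_clip_right=clip_right,
    )


def align_infix(query: str, target: str, strand: int = 1) -> AlignmentStats | None:
    """Best placement of the whole query inside the target (edlib HW)."""
    if not query or not target:
        return None
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start = res["locations"][0][0]
    return _stats_from_cigar(res["cigar"], start, strand)


def align_global(query: str, target: str, ref_start: int, strand: int,
                 clip_left: int = 0, clip_right: int = 0) -> AlignmentStats:
    """Global (NW) alignment of two slices already placed against each other."""
    res = edlib.align(query, target, mode="NW", task="path")
    return _stats_from_cigar(res["cigar"], ref_start, strand,
                             clip_left, clip_right)


def best_infix_alignment(read: str, ref: str) -> AlignmentStats | None:
    """Best of forward / reverse-complement infix placements of a read."""
    fwd = align_infix(read, ref, strand=1)
    rev = align_infix(revcomp(read), ref, strand=-1)
    candidates = [a for a in (fwd, rev) if a is not None]
    if not candidates:
        return None
    return max(candidates, key=lambda a: a.score)


def passes_constraints(stats: AlignmentStats, read_len: int,
                       max_mismatch_frac: float, max_gap_frac: float,
                       max_gap_size: int) -> bool:
    if stats.mismatch_frac > max_mismatch_frac:
        return False
    if stats.gap_bases > max_gap_frac * read_len:
        return False
    if stats.max_gap_run > max_gap_size:
        return False
    return True


def _affine_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -8
    aligner.extend_gap_score = -3
    return aligner


_AFFINE = None


def affine_local_alignment(query: str, target: str,
                           strand: int = 1) -> AlignmentStats | None:
    """Best local alignment under affine gap penalties (mapper semantics:
    gaps open only where a contiguous indel is genuinely supported, unlike
    a unit-cost edit path which shreds divergent sequence into many small
    gaps).  Unaligned read ends count as clips."""
    global _AFFINE
    if _AFFINE is None:
        _AFFINE = _affine_aligner()
    if not query or not target:
        return None
    try:
        aln = _AFFINE.align(target, query)[0]
    except (IndexError, ValueError):
        return None
    blocks_t, blocks_q = aln.aligned
    if len(blocks_t) == 0:
        return None
    matches = mismatches = gaps = max_run = 0
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(blocks_t, blocks_q):
        if prev_t is not None:
            dt, dq = t0 - prev_t, q0 - prev_q
            gaps += dt + dq
            max_run = max(max_run, dt, dq)
        for a, b in zip(target[t0:t1], query[q0:q1]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
        prev_t, prev_q = t1, q1
    return AlignmentStats(
        ref_start=int(blocks_t[0][0]), ref_end=int(blocks_t[-1][1]),
        matches=matches, mismatches=mismatches, gap_bases=gaps,
        max_gap_run=max_run, strand=strand, cigar="",
        query_clip_left=int(blocks_q[0][0]),
        query_clip_right=len(query) - int(blocks_q[-1][1]),
    )


def best_affine_alignment(read: str, ref: str) -> AlignmentStats | None:
    """Best of forward / reverse-complement affine local placements."""
    fwd = affine_local_alignment(read, ref, strand=1)
    rev = affine_local_alignment(revcomp(read), ref, strand=-1)
    candidates = [a for a in (fwd, rev) if a is not None]
    if not candidates:
        return None
    return max(candidates, key=lambda a: a.score)


class KmerIndex:
    """Exact k-mer index of a reference string, for seeding placements."""

    def __init__(self, ref: str, k: int):
        self.k = k
        self.ref = ref
        index: dict[str, list[int]] = {}
        for i in range(len(ref) - k + 1):
            index.setdefault(ref[i:i + k], []).append(i)
        self._index = index

    def diagonals(self, read: str, stride: int | None = None) -> dict[int, int]:
        """Candidate offsets (ref_pos - read_pos), with seed-hit counts."""
        k = self.k
        stride = stride or max(1, k // 2)
        hits: dict[int, int] = {}
        for q in range(0, max(1, len(read) - k + 1), stride):
            for r in self._index.get(read[q:q + k], ()):
                d = r - q
                hits[d] = hits.get(d, 0) + 1
        return hits
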
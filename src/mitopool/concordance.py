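"""Cross-platform comparison of reconstructions of one specimen.

When the same mitogenome is reconstructed from several platforms, the
sequences are near-identical up to rotation (different linear origins) and
scattered single-base differences.  Homopolymer-miscall chemistry (454,
Ion Torrent) produces *phantom single nucleotides*: bases present in one
platform's reconstruction at columns where the cross-platform consensus has
none.  This module derotates and aligns the reconstructions, counts
phantoms per base (plus focal ``N`` calls and minority insertions that
survived into the specimen consensus), and reports the phantom rate as a
percentage of the reconstructed length, with half-up rounding to the
printed precision.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from ._mapping import align_infix

__all__ = [
    "PhantomReport",
    "align_reconstructions",
    "call_phantoms",
    "phantom_rate",
    "gc_percent",
]


@dataclass
class PhantomReport:
    specimen: str
    platform: str
    counts: dict  # base in {A,C,G,T,N} -> count
    insertions_added: int
    total_bp: int

    @property
    def rate_percent(self) -> float:
        return phantom_rate(self.counts, self.total_bp)


def _derotate(seq: str, anchor: str) -> str:
    """Rotate ``seq`` so it starts where ``anchor``'s first bases occur.

    The probe is searched in the doubled sequence, so any rotation is
    found; returns ``seq`` unchanged when no confident placement exists.
    """
    probe = anchor[: min(300, len(anchor) // 2)]
    st = align_infix(probe, seq + seq)
    if st is None or st.aligned_columns == 0:
        return seq
    if st.matches / st.aligned_columns < 0.75:
        return seq
    k = st.ref_start % len(seq)
    return seq[k:] + seq[:k]


def align_reconstructions(seqs: Sequence[str],
                          min_identity: float = 0.5) -> list[str]:
    """Rotation-aware multiple alignment of near-identical reconstructions.

    All sequences are derotated to the first sequence's origin, then each is
    aligned pairwise against the first and the pairwise gaps merged into a
    common column set (anchor-referenced alignment, the standard shortcut
    for sequences expected to be nearly identical).  Rejects inputs whose
    identity to the anchor falls below ``min_identity``.
    """
    import edlib

    if len(seqs) < 2:
        raise ValueError("need at least 2 reconstructions")
    seqs = [s.upper() for s in seqs]
    anchor = seqs[0]
    others = [_derotate(s, anchor) for s in seqs[1:]]

    # pairwise global alignments to the anchor
    paths = []
    for s in others:
        res = edlib.align(s, anchor, mode="NW", task="path")
        ident = 1.0 - res["editDistance"] / max(len(s), len(anchor))
        if ident < min_identity:
            raise ValueError(
                f"reconstruction identity {ident:.2f} below {min_identity}: "
                "likely a different specimen"
            )
        nice = edlib.getNiceAlignment(res, s, anchor)
        paths.append((nice["query_aligned"], nice["target_aligned"]))

    # merge: number anchor positions; each pairwise alignment contributes
    # insertion slots between anchor positions
    n = len(anchor)
    ins_len = np.zeros(n + 1, dtype=int)  # slot i = before anchor base i
    per_seq = []
    for q, t in paths:
        cols = []  # (slot_or_pos, is_insert, char)
        apos = 0
        for qc, tc in zip(q, t):
            if tc == "-":
                cols.append((apos, True, qc))
            else:
                cols.append((apos, False, qc))
                apos += 1
        per_seq.append(cols)
        run = Counter()
        for slot, is_ins, _ in cols:
            if is_ins:
                run[slot] += 1
        for slot, k in run.items():
            ins_len[slot] = max(ins_len[slot], k)

    # build matrix
    width = n + int(ins_len.sum())
    slot_offset = np.zeros(n + 1, dtype=int)
    acc = 0
    for i in range(n + 1):
        slot_offset[i] = acc + i  # column index where slot i's inserts begin
        acc += ins_len[i]

    def col_of_anchor(i: int) -> int:
        return int(slot_offset[i] + ins_len[i])

    rows = []
    row0 = ["-"] * width
    for i, b in enumerate(anchor):
        row0[col_of_anchor(i)] = b
    rows.append("".join(row0))

    for cols in per_seq:
        row = ["-"] * width
        ins_seen = Counter()
        for slot, is_ins, ch in cols:
            if is_ins:
                row[int(slot_offset[slot]) + ins_seen[slot]] = ch
                ins_seen[slot] += 1
            else:
                row[col_of_anchor(slot)] = ch
        rows.append("".join(row))
    return rows


def call_phantoms(matrix: Sequence[str], platforms: Sequence[str],
                  focal_platform: str, specimen: str = "") -> PhantomReport:
    """Count phantom single nucleotides in the focal platform's row.

    A phantom is a column where the focal row carries a base (or ``N``) and
    a strict majority of the other rows have a gap — the insertion-type
    disagreement characteristic of homopolymer miscalls.  Phantoms whose
    base nevertheless wins the all-rows consensus (support from at least as
    many rows as the gap) are tallied separately as ``insertions_added``.
    ``total_bp`` is the focal reconstruction's ungapped length.
    """
    if len(matrix) != len(platforms):
        raise ValueError("one platform label per row required")
    if len(matrix) < 3:
        raise ValueError("phantom calling needs at least 3 rows")
    try:
        focal_idx = list(platforms).index(focal_platform)
    except ValueError:
        raise ValueError(f"platform {focal_platform!r} not among rows") from None
    focal = matrix[focal_idx]
    others = [matrix[i] for i in range(len(matrix)) if i != focal_idx]
    counts = {b: 0 for b in "ACGTN"}
    insertions_added = 0
    total_bp = sum(1 for c in focal if c != "-")
    for j, fc in enumerate(focal):
        if fc == "-":
            continue
        other_col = [row[j] for row in others]
        gaps = sum(1 for c in other_col if c == "-")
        if gaps * 2 <= len(other_col):
            continue  # no gap majority among the other platforms
        base_support = 1 + sum(1 for c in other_col if c == fc)
        all_gaps = gaps
        if base_support >= all_gaps:
            insertions_added += 1
        else:
            key = fc if fc in counts else "N"
            counts[key] += 1
    return PhantomReport(specimen=specimen, platform=focal_platform,
                         counts=counts, insertions_added=insertions_added,
                         total_bp=total_bp)


def _round_half_up(x: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def phantom_rate(counts: Mapping[str, int], total_bp: int) -> float:
    """Phantom bases as a percent of the reconstructed length (2 dp,
    half-up).  Counts cover A, C, G, T and N; insertion-accepted columns
    are excluded from this total."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    total = sum(int(v) for v in counts.values())
    if total < 0:
        raise ValueError("negative phantom count")
    return _round_half_up(100.0 * total / total_bp, 2)


def gc_percent(seq: str) -> float:
    """G+C as a percent of unambiguous bases (1 dp, half-up); ambiguity
    codes and N are excluded from numerator and denominator.  Invariant
    under rotation and reverse complement."""
    s = seq.upper()
    gc = sum(1 for b in s if b in "GC")
    at = sum(1 for b in s if b in "AT")
    if gc + at == 0:
        raise ValueError("no unambiguous bases")
    return _round_half_up(100.0 * gc / (gc + at), 1)
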
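"""Inverted-repeat (IR) detection in spacer sequences.

A sequence is locally aligned against its own reverse complement by
dynamic programming: two nearby segments that are reverse complements of
each other (a hairpin stem with a loop between the arms) accumulate +3
per complementary pair, −4 per non-complementary pair and −12 per gap
column — the scoring of the classic EMBOSS ``einverted`` tool.  Hits at
or above the score threshold (default 40; short spacer fragments are the
use case the threshold was lowered for) are reported greedily by
descending score as mutually non-overlapping repeats, deterministically
(ties break leftmost).

Input rows may be aligned (gapped); gaps are stripped before scanning and
all reported coordinates can be mapped back into alignment columns for
cross-taxon conservation summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MATCH = 3
MISMATCH = -4
GAP = -12

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ParameterError(ValueError):
    pass


@dataclass
class InvertedRepeat:
    left: tuple[int, int]       # 1-based inclusive on the (ungapped) input
    right: tuple[int, int]
    score: int
    columns: list[tuple[str, str]]   # paired arm columns, '-' marks a gap

    @property
    def loop_length(self) -> int:
        return self.right[0] - self.left[1] - 1

    def positions(self) -> set[int]:
        return (set(range(self.left[0], self.left[1] + 1))
                | set(range(self.right[0], self.right[1] + 1)))


def score_arm_alignment(paired_columns, match: int = MATCH,
                        mismatch: int = MISMATCH,
                        gap_penalty: int = -GAP) -> int:
    """Score paired arm columns: +match per complementary pair, mismatch per
    non-complementary pair, −gap_penalty per gap column."""
    total = 0
    for a, b in paired_columns:
        if a == "-" or b == "-":
            total -= gap_penalty
        elif _COMP.get(a) == b:
            total += match
        else:
            total += mismatch
    return total


def _strip_gaps(seq: str):
    seq = seq.upper()
    kept = [(i + 1, c) for i, c in enumerate(seq) if c not in "-?"]
    ungapped = "".join(c for _, c in kept)
    coord = [i for i, _ in kept]       # ungapped index -> original position
    return ungapped, coord


def _dp_scan(seq: str, threshold: int, max_loop: int, max_arm,
             match: int, mismatch: int, gap_penalty: int):
    """One DP pass; returns the best hit not touching ``banned`` positions,
    or None.  ``seq`` is ungapped uppercase; positions are 0-based here."""
    n = len(seq)
    NEG = -10 ** 9
    # H[i][j]: best arm alignment with left arm ending at i, right arm
    # starting at j (0-based, i < j).  Moves: pair (i-1,j+1)->(i,j), gap on
    # either arm.  L tracks arm-column count to honour max_arm.
    H = np.full((n, n), NEG, dtype=np.int64)
    B = np.zeros((n, n), dtype=np.int8)   # 0 start, 1 pair, 2 gap-left, 3 gap-right
    L = np.zeros((n, n), dtype=np.int32)

    def pair_score(a, b):
        return match if _COMP.get(a) == b else mismatch

    best = None
    for i in range(n):
        for j in range(n - 1, i, -1):
            if seq[i] == "X" or seq[j] == "X":
                continue  # masked by an already-reported hit
            ps = pair_score(seq[i], seq[j])
            start_val = ps
            ext = []
            if i >= 1 and j + 1 < n and H[i - 1, j + 1] > NEG and L[i - 1, j + 1] + 1 <= (max_arm or n):
                ext.append((H[i - 1, j + 1] + ps, 1, L[i - 1, j + 1] + 1))
            if i >= 1 and H[i - 1, j] > NEG and L[i - 1, j] + 1 <= (max_arm or n):
                ext.append((H[i - 1, j] - gap_penalty, 2, L[i - 1, j] + 1))
            if j + 1 < n and H[i, j + 1] > NEG and L[i, j + 1] + 1 <= (max_arm or n):
                ext.append((H[i, j + 1] - gap_penalty, 3, L[i, j + 1] + 1))
            val, move, ln = max(ext, default=(NEG, 0, 1), key=lambda c: c[0])
            if start_val >= val:
                val, move, ln = start_val, 0, 1
            H[i, j], B[i, j], L[i, j] = val, move, ln
            loop = j - i - 1
            if val >= threshold and loop <= max_loop:
                if best is None or val > best[0] or (val == best[0] and (i, j) < (best[1], best[2])):
                    best = (int(val), i, j)
    if best is None:
        return None
    # traceback
    score, i, j = best
    cols = []
    ci, cj = i, j
    left_end, right_start = i, j
    while True:
        move = B[ci, cj]
        if move == 0:
            cols.append((seq[ci], seq[cj]))
            left_start, right_end = ci, cj
            break
        if move == 1:
            cols.append((seq[ci], seq[cj]))
            ci, cj = ci - 1, cj + 1
        elif move == 2:
            cols.append((seq[ci], "-"))
            ci -= 1
        else:
            cols.append(("-", seq[cj]))
            cj += 1
    cols.reverse()
    return InvertedRepeat(left=(left_start + 1, left_end + 1),
                          right=(right_start + 1, right_end + 1),
                          score=score, columns=cols)


def find_inverted_repeats(seq: str, threshold: int = 40, max_arm=None,
                          max_loop: int = 2000, match: int = MATCH,
                          mismatch: int = MISMATCH,
                          gap_penalty: int = -GAP) -> list[InvertedRepeat]:
    """All mutually non-overlapping IRs scoring >= threshold, best first.

    Gapped (aligned) input is accepted: gaps are stripped for the scan and
    coordinates refer to the original (gapped) string.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    ungapped, coord = _strip_gaps(seq)
    if len(ungapped) < 2:
        return []
    hits: list[InvertedRepeat] = []
    work = list(ungapped)
    while True:
        hit = _dp_scan("".join(work), threshold, max_loop, max_arm,
                       match, mismatch, gap_penalty)
        if hit is None:
            break
        hits.append(hit)
        for p in hit.positions():
            work[p - 1] = "X"       # mask so later hits cannot overlap
    # map ungapped coordinates back to the original string
    mapped = []
    for h in hits:
        mapped.append(InvertedRepeat(
            left=(coord[h.left[0] - 1], coord[h.left[1] - 1]),
            right=(coord[h.right[0] - 1], coord[h.right[1] - 1]),
            score=h.score, columns=h.columns))
    return mapped


def ir_footprints(alignment, hits_per_row) -> dict[str, set[int]]:
    """Map each row's IR intervals (coordinates on the row's gapped string,
    as returned by :func:`find_inverted_repeats` on that row) into the set
    of alignment columns they occupy."""
    footprints: dict[str, set[int]] = {}
    ids = set(alignment.ids())
    for rid, hits in hits_per_row.items():
        if rid not in ids:
            raise ValueError(f"row {rid!r} not in alignment")
        cols: set[int] = set()
        for h in hits:
            cols |= h.positions()
        footprints[rid] = cols
    return footprints


def ir_conservation(alignment, hits_per_row, grouping=None) -> pd.DataFrame:
    """Pairwise Jaccard overlap of IR footprints across rows.

    With ``grouping`` (``{row_id: group}``) each pair is tagged
    within/between so clade-level conservation can be summarised.
    """
    fp = ir_footprints(alignment, hits_per_row)
    ids = [i for i in alignment.ids() if i in fp]
    rows = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            sa, sb = fp[ids[a]], fp[ids[b]]
            union = sa | sb
            jac = len(sa & sb) / len(union) if union else 1.0
            row = {"row_a": ids[a], "row_b": ids[b], "jaccard": jac}
            if grouping is not None:
                row["relation"] = ("within" if grouping[ids[a]] == grouping[ids[b]]
                                   else "between")
            rows.append(row)
    return pd.DataFrame(rows)


def annotate_alignment(alignment, hits_per_row) -> str:
    """Text rendering with IR columns marked (``*`` under occupied columns)."""
    fp = ir_footprints(alignment, hits_per_row)
    width = max(len(i) for i in alignment.ids()) + 2
    lines = []
    for rec in alignment.records:
        lines.append(f"{rec.id:<{width}}{rec.seq}")
        marks = "".join("*" if (c + 1) in fp.get(rec.id, ()) else " "
                        for c in range(alignment.length))
        lines.append(f"{'':<{width}}{marks}")
    return "\n".join(lines) + "\n"
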
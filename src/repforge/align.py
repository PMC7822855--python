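"""Local alignment of merged reads to germline segments and V/D/J/C calling.

The aligner is an affine-gap Smith-Waterman: a gap of length *k* costs
``gap_open + (k - 1) * gap_extend``. ``N`` bases score as mismatches against
everything (including ``N``), so an ``N`` can never anchor an alignment.
Among co-optimal alignments the one with the smallest query start, then
smallest reference start, then fewest operations is returned.

The dynamic-programming fill runs through a numba-jitted kernel when numba
is importable and falls back to the identical pure-Python function
otherwise; both paths produce the same matrices.

Segment assignment aligns a merged read against every reference segment of
each gene type and keeps the best hit above a per-gene-type score floor.
D segments are short and match spuriously, so they are only searched in the
window between the V segment's CDR3-anchor projection on the read and the
start of the J hit. Calls must satisfy the read-coordinate ordering
V <= D <= J <= C; violations demote D first, then C. A J hit starting 5'
of the V hit cannot be repaired by demotion and marks the read
unassignable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .germline import GermlineDatabase, GermlineSegment

__all__ = [
    "ScoringScheme",
    "SegmentAlignment",
    "SegmentCalls",
    "DEFAULT_THRESHOLDS",
    "smith_waterman",
    "migrate_boundary",
    "assign_segments",
    "call_isotype",
]

_NEG = -(10**8)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _CODE[_c] = _i
    _CODE[_c + 32] = _i  # lowercase


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores; defaults favour ungapped matches (gaps are rare in
    amplicon repertoire reads, which carry substitutions, not indels)."""

    match: int = 2
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("mismatch and gap penalties must be <= 0")


@dataclass(frozen=True)
class SegmentAlignment:
    """A local alignment of a read (query) against one germline segment."""

    segment_id: str
    score: int
    query_interval: tuple[int, int]  # 0-based half-open, read coordinates
    ref_interval: tuple[int, int]  # 0-based half-open, segment coordinates
    operations: tuple[tuple[str, int], ...]  # (op in {M, I, D}, run length)
    mismatch_positions: tuple[int, ...]  # read coordinates of substitutions

    @property
    def n_matches(self) -> int:
        return sum(l for op, l in self.operations if op == "M") - len(
            self.mismatch_positions
        )

    def identity(self) -> float:
        aligned = sum(l for op, l in self.operations if op == "M")
        return self.n_matches / aligned if aligned else 0.0


def _fill_py(a, b, match, mismatch, gap_open, gap_extend):
    """Affine-gap local-alignment matrix fill (H, E, F).

    E holds gap-in-query states (consuming reference, op D); F holds
    gap-in-reference states (consuming query, op I).
    """
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            if ai == b[j - 1] and ai < 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


try:  # pragma: no cover - exercised implicitly wherever numba is installed
    from numba import njit

    _fill = njit(cache=True)(_fill_py)
except Exception:  # pragma: no cover
    _fill = _fill_py


def _traceback(a, b, H, E, F, end, scoring):
    """Walk one optimal path back from ``end``; returns (qs, rs, ops, mismatches)."""
    i, j = end
    state = "H"
    steps: list[str] = []
    mismatches: list[int] = []
    go, ge = scoring.gap_open, scoring.gap_extend
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            ai, bj = a[i - 1], b[j - 1]
            s = scoring.match if (ai == bj and ai < 4) else scoring.mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                steps.append("M")
                if not (ai == bj and ai < 4):
                    mismatches.append(i - 1)
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            steps.append("I")
            if F[i, j] == H[i - 1, j] + go:
                state = "H"
            i -= 1
        else:  # E
            steps.append("D")
            if E[i, j] == H[i, j - 1] + go:
                state = "H"
            j -= 1
    steps.reverse()
    mismatches.reverse()
    ops: list[tuple[str, int]] = []
    for op in steps:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return i, j, tuple(ops), tuple(mismatches)


def smith_waterman(
    query: str,
    ref: str,
    scoring: ScoringScheme | None = None,
    segment_id: str = "",
) -> SegmentAlignment:
    """Optimal affine-gap local alignment of ``query`` against ``ref``."""
    if not query or not ref:
        raise ValueError("query and ref must be non-empty")
    scoring = scoring or ScoringScheme()
    a, b = _encode(query), _encode(ref)
    H, E, F = _fill(
        a, b, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    best = int(H.max())
    if best == 0:
        return SegmentAlignment(segment_id, 0, (0, 0), (0, 0), (), ())
    ends = np.argwhere(H == best)
    # co-optimal ends are rare; bound the tie search to keep worst cases sane
    candidates = [tuple(map(int, e)) for e in ends[:64]]
    chosen = None
    for end in candidates:
        qs, rs, ops, mm = _traceback(a, b, H, E, F, end, scoring)
        key = (qs, rs, len(ops), end[0], end[1])
        if chosen is None or key < chosen[0]:
            chosen = (key, end, ops, mm)
    (qs, rs, _, qe, re_), end, ops, mm = chosen
    return SegmentAlignment(
        segment_id=segment_id,
        score=best,
        query_interval=(qs, qe),
        ref_interval=(rs, re_),
        operations=ops,
        mismatch_positions=mm,
    )


def migrate_boundary(aln: SegmentAlignment, ref_pos: int) -> int | None:
    """Map a reference coordinate onto the read through an alignment.

    Returns the read coordinate aligned to ``ref_pos``, or the read
    coordinate immediately 3' of a deletion that swallows it; ``None`` when
    ``ref_pos`` lies outside the aligned reference interval.
    """
    rs, re_ = aln.ref_interval
    if not (rs <= ref_pos < re_):
        return None
    qpos, rpos = aln.query_interval[0], rs
    for op, length in aln.operations:
        if op == "M":
            if rpos <= ref_pos < rpos + length:
                return qpos + (ref_pos - rpos)
            qpos += length
            rpos += length
        elif op == "I":
            qpos += length
        else:  # D: read is missing these reference bases
            if rpos <= ref_pos < rpos + length:
                return qpos
            rpos += length
    return None


@dataclass(frozen=True)
class SegmentCalls:
    """Best V/D/J/C hits for one read, plus the isotype call."""

    v: SegmentAlignment | None = None
    d: SegmentAlignment | None = None
    j: SegmentAlignment | None = None
    c: SegmentAlignment | None = None
    isotype: str = "unknown"
    c_ambiguous: bool = False


#: Minimum alignment score per gene type (configurable; V/J floors gate
#: assignability, the low D floor reflects how short true D matches are).
DEFAULT_THRESHOLDS = {"V": 40, "J": 16, "C": 16, "D": 10}


def _best_hit(
    query: str,
    segments: Sequence[GermlineSegment],
    scoring: ScoringScheme,
    threshold: int,
) -> tuple[SegmentAlignment | None, bool]:
    """Best-scoring hit above threshold; ties break to the lexicographically
    first segment id. Second return: whether the top score was tied."""
    best: SegmentAlignment | None = None
    tied = False
    for seg in segments:  # already sorted by id
        aln = smith_waterman(query, seg.sequence, scoring, seg.segment_id)
        if aln.score < threshold:
            continue
        if best is None or aln.score > best.score:
            best, tied = aln, False
        elif aln.score == best.score:
            tied = True
    return best, tied


def assign_segments(
    sequence: str,
    db: GermlineDatabase,
    locus: str,
    scoring: ScoringScheme | None = None,
    thresholds: dict[str, int] | None = None,
) -> SegmentCalls | None:
    """Call germline V, D, J and C segments for one merged read.

    Returns ``None`` when no V or no J clears its score floor (or their
    order on the read is inverted) — the read is unassignable.
    """
    scoring = scoring or ScoringScheme()
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)

    v, _ = _best_hit(sequence, db.segments_of(locus, "V"), scoring, thr["V"])
    j, _ = _best_hit(sequence, db.segments_of(locus, "J"), scoring, thr["J"])
    if v is None or j is None:
        return None
    if j.query_interval[0] < v.query_interval[0]:
        return None

    c, c_tied = _best_hit(sequence, db.segments_of(locus, "C"), scoring, thr["C"])
    if c is not None and c.query_interval[0] < j.query_interval[0]:
        c, c_tied = None, False

    d = None
    d_segs = db.segments_of(locus, "D")
    if d_segs:
        v_seg = db.get(v.segment_id)
        win_start = migrate_boundary(v, v_seg.cdr3_anchor)
        if win_start is None:
            win_start = v.query_interval[1]
        win_end = j.query_interval[0]
        if win_end - win_start >= 1:
            window = sequence[win_start:win_end]
            d, _ = _best_hit(window, d_segs, scoring, thr["D"])
            if d is not None:
                d = replace(
                    d,
                    query_interval=(
                        d.query_interval[0] + win_start,
                        d.query_interval[1] + win_start,
                    ),
                    mismatch_positions=tuple(
                        p + win_start for p in d.mismatch_positions
                    ),
                )
    if d is not None and not (
        v.query_interval[0] <= d.query_interval[0] <= j.query_interval[0]
    ):
        d = None

    if c is None:
        isotype = "unknown"
    else:
        label = db.get(c.segment_id).isotype_label
        isotype = label if label is not None else "TRBC"
    return SegmentCalls(v=v, d=d, j=j, c=c, isotype=isotype, c_ambiguous=c_tied)


def call_isotype(calls: SegmentCalls) -> str:
    """Isotype label of the called constant segment ('unknown' when absent)."""
    return calls.isotype
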
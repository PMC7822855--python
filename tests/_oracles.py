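"""Independent reference computations used to check the implementation.

These deliberately use different machinery (top-down recursion, exact
rational arithmetic, linear prefix scans) from the code paths they verify.
"""

from fractions import Fraction
from functools import lru_cache

NEG = float("-inf")


def sw_oracle_score(a, b, match=2, mismatch=-2, gap_open=-3, gap_extend=-1):
    """Best local-alignment score by memoized top-down recursion over the
    three-state affine automaton (match / gap-in-query / gap-in-ref)."""

    @lru_cache(maxsize=None)
    def H(i, j):
        best = 0.0
        if i > 0 and j > 0:
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT") else mismatch
            best = max(best, H(i - 1, j - 1) + s)
        if j > 0:
            best = max(best, D(i, j))
        if i > 0:
            best = max(best, I(i, j))
        return best

    @lru_cache(maxsize=None)
    def D(i, j):  # gap consuming the reference
        if j == 0:
            return NEG
        return max(H(i, j - 1) + gap_open, D(i, j - 1) + gap_extend)

    @lru_cache(maxsize=None)
    def I(i, j):  # gap consuming the query
        if i == 0:
            return NEG
        return max(H(i - 1, j) + gap_open, I(i - 1, j) + gap_extend)

    return int(max(H(i, j) for i in range(len(a) + 1) for j in range(len(b) + 1)))


def realign_score(aln, query, ref, match=2, mismatch=-2, gap_open=-3, gap_extend=-1):
    """Recompute an alignment's score from its operation list."""
    qi, ri = aln.query_interval[0], aln.ref_interval[0]
    score = 0
    for op, length in aln.operations:
        if op == "M":
            for k in range(length):
                qc, rc = query[qi + k], ref[ri + k]
                score += match if (qc == rc and qc in "ACGT") else mismatch
            qi += length
            ri += length
        else:
            score += gap_open + (length - 1) * gap_extend
            if op == "I":
                qi += length
            else:
                ri += length
    return score


def d50_oracle_C(abundances):
    """C of the D50 definition by a literal prefix scan with exact rationals."""
    r = sorted(abundances, reverse=True)
    J = Fraction(sum(r))
    half = J / 2
    for c in range(1, len(r) + 1):
        if sum(r[:c]) >= half and sum(r[: c - 1]) < half:
            return c
    raise AssertionError("no C satisfies the definition")
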
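"""Rank-abundance construction, the D50 diversity index, and V-gene usage.

D50 asks: what percentage of the distinct CDR3 sequences is needed to
account for at least half of all sequencing reads? With abundances ranked
r_1 >= r_2 >= ... >= r_S and J = sum(r_i), C is the unique rank satisfying

    sum_{i<=C} r_i >= J/2   and   sum_{i<=C-1} r_i < J/2,

and D50 = 100 * C / S. A monoclonal repertoire scores 100 (its single
clone is also all clones); a perfectly even repertoire scores ~50; strong
clonal expansions push D50 toward 100/S. J/2 is compared exactly (integer
arithmetic), never rounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import Clonotype

__all__ = [
    "RankAbundance",
    "D50Result",
    "rank_abundance",
    "subsample",
    "d50",
    "v_usage",
]


@dataclass(frozen=True)
class RankAbundance:
    """Ranked clone abundances: r_1 >= ... >= r_S, J = sum r_i."""

    r: tuple[int, ...]
    labels: tuple[str, ...]  # CDR3 (or V|J|CDR3) label per rank

    def __post_init__(self) -> None:
        if not self.r:
            raise ValueError("empty repertoire")
        if any(x < 1 for x in self.r):
            raise ValueError("abundances must be >= 1")
        if any(a < b for a, b in zip(self.r, self.r[1:])):
            raise ValueError("abundances must be sorted non-increasing")

    @property
    def S(self) -> int:
        return len(self.r)

    @property
    def J(self) -> int:
        return sum(self.r)


@dataclass(frozen=True)
class D50Result:
    C: int
    D50: float
    S: int
    J: int


def rank_abundance(clonotypes: list[Clonotype], key: str = "vj_cdr3") -> RankAbundance:
    """Ranked copy counts per distinct CDR3 (or per V-J-CDR3 combination).

    Ties in abundance order lexicographically by label — deterministic for
    any input order.
    """
    if not clonotypes:
        raise ValueError("empty repertoire")
    counts: dict[str, int] = {}
    for ct in clonotypes:
        if key == "vj_cdr3":
            label = f"{ct.v_gene}|{ct.j_gene}|{ct.cdr3_nt}"
        elif key == "cdr3":
            label = ct.cdr3_nt
        else:
            raise ValueError(f"unknown key {key!r}")
        counts[label] = counts.get(label, 0) + ct.total_copies
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankAbundance(
        r=tuple(n for _, n in items), labels=tuple(l for l, _ in items)
    )


def subsample(ra: RankAbundance, depth: int, seed: int = 0) -> RankAbundance:
    """Rarefy a repertoire to ``depth`` reads drawn without replacement.

    Depth-normalisation hook for cross-sample D50 comparisons; off by
    default in the pipeline. Returns ``ra`` unchanged when it already holds
    ``depth`` or fewer reads. Clones drawn zero times drop out.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if depth >= ra.J:
        return ra
    rng = np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(list(ra.r), depth)
    items = sorted(
        ((int(n), lab) for n, lab in zip(drawn, ra.labels) if n > 0),
        key=lambda t: (-t[0], t[1]),
    )
    return RankAbundance(
        r=tuple(n for n, _ in items), labels=tuple(lab for _, lab in items)
    )


def d50(ra: RankAbundance) -> D50Result:
    """The D50 index: C = minimum ranks reaching >= J/2 of reads; D50 = 100*C/S."""
    J = ra.J
    prefix = 0
    for c, r_i in enumerate(ra.r, start=1):
        prefix += r_i
        if 2 * prefix >= J:  # exact comparison with J/2
            return D50Result(C=c, D50=100.0 * c / ra.S, S=ra.S, J=J)
    raise AssertionError("unreachable: prefix sums reach J")


def v_usage(clonotypes: list[Clonotype], weighting: str = "copy") -> dict[str, float]:
    """V-gene usage fractions (copy-weighted by default, or per unique clonotype)."""
    if weighting not in ("copy", "unique"):
        raise ValueError(f"unknown weighting {weighting!r}")
    counts: dict[str, float] = {}
    for ct in clonotypes:
        w = ct.total_copies if weighting == "copy" else 1
        counts[ct.v_gene] = counts.get(ct.v_gene, 0) + w
    total = sum(counts.values())
    if not total:
        return {}
    return {v: n / total for v, n in sorted(counts.items())}
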
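"""Read preprocessing: demultiplexing, quality trimming, pair merging, deduplication.

The stages mirror a standard amplicon-repertoire workflow:

1. **Demultiplex** mate pairs by a fixed-length barcode at the 5' end of the
   constant-region-side mate (R2 by convention).
2. **Quality-trim** each mate with a 2-base sliding window: at the first
   window containing any Phred score below ``qmin``, the window's first
   position and everything 3' of it is removed.
3. **Merge** mates by gap-free end-free overlap alignment; any mismatch in
   the overlap discards the pair outright (the assay relies on perfectly
   matched overlaps rather than consensus-calling).
4. **Collapse** identical merged sequences into unique sequences with copy
   counts — the unit on which the copy filter for mutation statistics acts.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SequencingRead",
    "MergedSequence",
    "UniqueSequence",
    "MergeFailure",
    "DemuxResult",
    "reverse_complement",
    "read_fastq",
    "write_fastq",
    "read_fastq_pairs",
    "demultiplex",
    "quality_trim",
    "merge_pair",
    "collapse_duplicates",
]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class SequencingRead:
    """A single read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]
    mate: str = "R1"

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"{self.read_id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MergedSequence:
    """A merged mate pair; the overlap is identical between mates by construction."""

    merged_id: str
    sequence: str
    overlap_length: int
    source_pair: str


@dataclass(frozen=True)
class MergeFailure:
    """Contract outcome of :func:`merge_pair` when the pair is discarded."""

    reason: str  # "short_overlap" | "mismatch"


@dataclass(frozen=True)
class UniqueSequence:
    """An exact-duplicate group of merged sequences within one sample."""

    sequence: str
    copy_count: int
    representative_id: str


# ---------------------------------------------------------------------------
# FASTQ IO (Sanger Phred+33, gzip-transparent)
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path, mate: str = "R1") -> Iterator[SequencingRead]:
    with _open_text(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield SequencingRead(
                read_id=title.split()[0],
                sequence=seq.upper(),
                qualities=tuple(ord(c) - 33 for c in qual),
                mate=mate,
            )


def write_fastq(reads: Iterable[SequencingRead], path: str | Path) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(
                f"@{r.read_id}\n{r.sequence}\n+\n"
                + "".join(chr(q + 33) for q in r.qualities)
                + "\n"
            )
            n += 1
    return n


def read_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[SequencingRead, SequencingRead]]:
    for r1, r2 in zip(
        read_fastq(r1_path, "R1"), read_fastq(r2_path, "R2"), strict=True
    ):
        yield r1, r2


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------


@dataclass
class DemuxResult:
    """Pairs routed per sample, plus the unassigned bin and a count ledger."""

    by_sample: dict[str, list[tuple[SequencingRead, SequencingRead]]]
    unassigned: list[tuple[SequencingRead, SequencingRead]]
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return self.counts["input"]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _strip_prefix(read: SequencingRead, n: int) -> SequencingRead:
    return SequencingRead(
        read.read_id, read.sequence[n:], read.qualities[n:], read.mate
    )


def demultiplex(
    pairs: Iterable[tuple[SequencingRead, SequencingRead]],
    barcode_table: dict[str, str],
    max_mismatch: int = 0,
    barcode_mate: str = "R2",
) -> DemuxResult:
    """Assign mate pairs to samples by the barcode prefix of one mate.

    A pair is assigned when exactly one barcode lies within ``max_mismatch``
    of the mate's prefix; the barcode prefix is then removed. Pairs matching
    no barcode go to the unassigned bin; pairs matching two or more
    ("ambiguous") are also unassigned but counted separately.
    """
    if not barcode_table:
        raise ValueError("empty barcode table")
    lengths = {len(b) for b in barcode_table}
    if len(lengths) != 1:
        raise ValueError("barcodes must share one length")
    blen = lengths.pop()
    barcodes = sorted(barcode_table)

    by_sample: dict[str, list[tuple[SequencingRead, SequencingRead]]] = {
        s: [] for s in sorted(set(barcode_table.values()))
    }
    unassigned: list[tuple[SequencingRead, SequencingRead]] = []
    counts = {"input": 0, "assigned": 0, "unassigned": 0, "ambiguous": 0}

    for r1, r2 in pairs:
        counts["input"] += 1
        tagged = r2 if barcode_mate == "R2" else r1
        prefix = tagged.sequence[:blen]
        hits = [b for b in barcodes if _hamming(prefix, b) <= max_mismatch]
        if len(hits) == 1 and len(prefix) == blen:
            stripped = _strip_prefix(tagged, blen)
            pair = (r1, stripped) if barcode_mate == "R2" else (stripped, r2)
            by_sample[barcode_table[hits[0]]].append(pair)
            counts["assigned"] += 1
        else:
            if len(hits) > 1:
                counts["ambiguous"] += 1
            counts["unassigned"] += 1
            unassigned.append((r1, r2))
    return DemuxResult(by_sample=by_sample, unassigned=unassigned, counts=counts)


# ---------------------------------------------------------------------------
# Quality trimming
# ---------------------------------------------------------------------------


def quality_trim(
    read: SequencingRead, window: int = 2, qmin: int = 20
) -> SequencingRead:
    """Truncate at the first sliding window containing a quality below ``qmin``.

    Windows of width ``window`` advance in steps of 1 from the 5' end; at
    the first window holding any quality < ``qmin`` the read is cut so that
    the window's first position and everything 3' of it is dropped. Reads
    shorter than the window, or with no failing window, are unchanged.
    The operation is idempotent.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(read)
    if n < window:
        return read
    qual = np.asarray(read.qualities)
    bad = np.flatnonzero(qual < qmin)
    if bad.size == 0:
        return read
    first_bad = int(bad[0])
    # earliest window (of the n - window + 1 valid starts) covering first_bad
    cut = min(max(0, first_bad - window + 1), n - window)
    return SequencingRead(read.read_id, read.sequence[:cut], read.qualities[:cut], read.mate)


# ---------------------------------------------------------------------------
# Pair merging
# ---------------------------------------------------------------------------


def merge_pair(
    r1: SequencingRead, r2: SequencingRead, min_overlap: int = 10
) -> MergedSequence | MergeFailure:
    """Join a mate pair by gap-free overlap; discard on any overlap mismatch.

    ``r2`` is reverse-complemented, then the longest exact overlap between
    r1's 3' end and r2's 5' end is sought. If an exact overlap of at least
    ``min_overlap`` exists the concatenated amplicon is returned. Otherwise
    the best-scoring (matches minus mismatches) overlap over all offsets
    decides the discard reason: ``short_overlap`` when even the best overlap
    is shorter than ``min_overlap``, else ``mismatch``. N never matches.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    s1 = r1.sequence
    s2 = reverse_complement(r2.sequence)
    n1, n2 = len(s1), len(s2)
    max_l = min(n1, n2)
    if max_l == 0:
        return MergeFailure("short_overlap")

    # fast path: longest exact overlap (string comparison is C-speed)
    for ln in range(max_l, min_overlap - 1, -1):
        cand = s1[n1 - ln :]
        if "N" not in cand and cand == s2[:ln]:
            return MergedSequence(
                merged_id=r1.read_id,
                sequence=s1 + s2[ln:],
                overlap_length=ln,
                source_pair=r1.read_id,
            )

    # no exact overlap long enough: classify the failure
    a = np.frombuffer(s1.encode(), dtype=np.uint8)
    b = np.frombuffer(s2.encode(), dtype=np.uint8)
    n_code = ord("N")
    best_score, best_len = -(10**9), 0
    for ln in range(1, max_l + 1):
        x = a[n1 - ln :]
        y = b[:ln]
        matches = int(np.count_nonzero((x == y) & (x != n_code)))
        score = 2 * matches - ln
        if score > best_score:
            best_score, best_len = score, ln
    if best_len < min_overlap:
        return MergeFailure("short_overlap")
    return MergeFailure("mismatch")


# ---------------------------------------------------------------------------
# Duplicate collapsing
# ---------------------------------------------------------------------------


def collapse_duplicates(merged: Iterable[MergedSequence]) -> list[UniqueSequence]:
    """Group identical merged sequences; conserves total copies, order-independent.

    Output is sorted by descending copy count then sequence; the
    representative is the lexicographically smallest contributing read id.
    """
    groups: dict[str, list[str]] = {}
    for m in merged:
        groups.setdefault(m.sequence, []).append(m.merged_id)
    uniques = [
        UniqueSequence(sequence=seq, copy_count=len(ids), representative_id=min(ids))
        for seq, ids in groups.items()
    ]
    uniques.sort(key=lambda u: (-u.copy_count, u.sequence))
    return uniques
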
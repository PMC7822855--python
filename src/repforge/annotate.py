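"""CDR boundary migration, CDR3 extraction/translation, clonotype aggregation.

CDR3 convention: the nucleotide interval from the first base of the V
segment's conserved-Cys codon to the end of the J segment's conserved
Phe/Trp codon, obtained by migrating the two reference anchors onto the
read through the V and J alignments. A sequence is *productive* when its
CDR3 length is a multiple of three and the translated CDR3 contains no
stop codon (the amplicon does not reliably cover the full V frame, so
productivity is judged on CDR3 alone).

Clonotypes group sequences by (V gene, J gene, CDR3 nucleotide sequence)
by default; a ``cdr3``-only key is available for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .align import (
    ScoringScheme,
    SegmentCalls,
    assign_segments,
    migrate_boundary,
)
from .germline import GermlineDatabase
from .preprocess import UniqueSequence

__all__ = [
    "AnnotatedSequence",
    "Clonotype",
    "IsotypeComposition",
    "migrate_boundary",
    "annotate_sequence",
    "annotate_all",
    "extract_cdr3",
    "build_clonotypes",
    "isotype_composition",
    "write_airr",
]


@dataclass
class AnnotatedSequence:
    """One unique merged transcript with segment calls and CDR3 annotation."""

    unique: UniqueSequence
    calls: SegmentCalls
    cdr2_start_read: int | None = None
    cdr3_interval_read: tuple[int, int] | None = None
    cdr3_nt: str = ""
    cdr3_aa: str = ""
    productive: bool = False
    flags: tuple[str, ...] = ()

    @property
    def copies(self) -> int:
        return self.unique.copy_count

    @property
    def v_gene(self) -> str:
        return self.calls.v.segment_id if self.calls.v else ""

    @property
    def j_gene(self) -> str:
        return self.calls.j.segment_id if self.calls.j else ""


def extract_cdr3(
    sequence: str, calls: SegmentCalls, db: GermlineDatabase
) -> tuple[tuple[int, int] | None, str, str, bool, tuple[str, ...]]:
    """Extract CDR3 by anchor migration; returns (interval, nt, aa, productive, flags)."""
    flags: list[str] = []
    v_seg = db.get(calls.v.segment_id)
    j_seg = db.get(calls.j.segment_id)
    start = migrate_boundary(calls.v, v_seg.cdr3_anchor)
    end = migrate_boundary(calls.j, j_seg.cdr3_anchor)
    if start is None:
        flags.append("v_anchor_uncovered")
    if end is None:
        flags.append("j_anchor_uncovered")
    if start is None or end is None:
        return None, "", "", False, tuple(flags)
    if end <= start:
        return None, "", "", False, ("inverted_cdr3",)
    cdr3_nt = sequence[start:end]
    if len(cdr3_nt) % 3 == 0:
        cdr3_aa = str(Seq(cdr3_nt).translate())
        productive = "*" not in cdr3_aa
    else:
        cdr3_aa = ""
        productive = False
        flags.append("out_of_frame")
    return (start, end), cdr3_nt, cdr3_aa, productive, tuple(flags)


def annotate_sequence(
    unique: UniqueSequence,
    db: GermlineDatabase,
    locus: str,
    scoring: ScoringScheme | None = None,
    thresholds: dict[str, int] | None = None,
) -> AnnotatedSequence | None:
    """Assign segments and annotate CDR2/CDR3 boundaries for one unique sequence.

    Returns ``None`` for unassignable sequences (no V or J above threshold).
    """
    calls = assign_segments(unique.sequence, db, locus, scoring, thresholds)
    if calls is None:
        return None
    v_seg = db.get(calls.v.segment_id)
    cdr2 = (
        migrate_boundary(calls.v, v_seg.cdr2_start)
        if v_seg.cdr2_start is not None
        else None
    )
    interval, nt, aa, productive, flags = extract_cdr3(unique.sequence, calls, db)
    return AnnotatedSequence(
        unique=unique,
        calls=calls,
        cdr2_start_read=cdr2,
        cdr3_interval_read=interval,
        cdr3_nt=nt,
        cdr3_aa=aa,
        productive=productive,
        flags=flags,
    )


def annotate_all(
    uniques: list[UniqueSequence],
    db: GermlineDatabase,
    locus: str,
    scoring: ScoringScheme | None = None,
    thresholds: dict[str, int] | None = None,
) -> tuple[list[AnnotatedSequence], int]:
    """Annotate a collection; returns (annotated, n_unassignable)."""
    out: list[AnnotatedSequence] = []
    unassignable = 0
    for u in uniques:
        ann = annotate_sequence(u, db, locus, scoring, thresholds)
        if ann is None:
            unassignable += 1
        else:
            out.append(ann)
    return out, unassignable


@dataclass
class Clonotype:
    """A (V gene, J gene, CDR3-nt) group with aggregated abundance."""

    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str = ""
    total_copies: int = 0
    n_unique: int = 0
    isotype_copies: dict[str, int] = field(default_factory=dict)


def build_clonotypes(
    annotated: list[AnnotatedSequence], key: str = "vj_cdr3"
) -> list[Clonotype]:
    """Aggregate annotated sequences into clonotypes.

    ``key`` is ``vj_cdr3`` (default) or ``cdr3``; sequences without a CDR3
    are excluded. Output order: descending total copies, then lexicographic
    key — deterministic.
    """
    if key not in ("vj_cdr3", "cdr3"):
        raise ValueError(f"unknown clonotype key {key!r}")
    groups: dict[tuple[str, str, str], Clonotype] = {}
    for ann in annotated:
        if not ann.cdr3_nt:
            continue
        if key == "vj_cdr3":
            k = (ann.v_gene, ann.j_gene, ann.cdr3_nt)
        else:
            k = ("", "", ann.cdr3_nt)
        ct = groups.get(k)
        if ct is None:
            ct = Clonotype(
                v_gene=ann.v_gene if key == "vj_cdr3" else "",
                j_gene=ann.j_gene if key == "vj_cdr3" else "",
                cdr3_nt=ann.cdr3_nt,
                cdr3_aa=ann.cdr3_aa,
            )
            groups[k] = ct
        ct.total_copies += ann.copies
        ct.n_unique += 1
        iso = ann.calls.isotype
        ct.isotype_copies[iso] = ct.isotype_copies.get(iso, 0) + ann.copies
    out = list(groups.values())
    out.sort(key=lambda c: (-c.total_copies, c.v_gene, c.j_gene, c.cdr3_nt))
    return out


@dataclass
class IsotypeComposition:
    """Copy-weighted isotype percentages over sequences with a known isotype."""

    percent: dict[str, float]  # isotype -> percent of known-isotype copies
    unknown_copies: int
    known_copies: int

    @property
    def unknown_percent(self) -> float:
        total = self.known_copies + self.unknown_copies
        return 100.0 * self.unknown_copies / total if total else 0.0


def isotype_composition(annotated: list[AnnotatedSequence]) -> IsotypeComposition:
    """Percent of transcript copies per isotype; 'unknown' reported separately."""
    copies: dict[str, int] = {}
    unknown = 0
    for ann in annotated:
        iso = ann.calls.isotype
        if iso == "unknown":
            unknown += ann.copies
        else:
            copies[iso] = copies.get(iso, 0) + ann.copies
    known = sum(copies.values())
    percent = {
        iso: 100.0 * n / known for iso, n in sorted(copies.items())
    }
    return IsotypeComposition(
        percent=percent, unknown_copies=unknown, known_copies=known
    )


_AIRR_COLUMNS = [
    "sequence_id",
    "v_call",
    "d_call",
    "j_call",
    "c_call",
    "junction",
    "junction_aa",
    "productive",
    "duplicate_count",
    "v_identity",
]


def write_airr(annotated: list[AnnotatedSequence], path: str | Path) -> pd.DataFrame:
    """Write an AIRR Rearrangement-style TSV; returns the DataFrame written."""
    rows = []
    for ann in annotated:
        c = ann.calls
        rows.append(
            {
                "sequence_id": ann.unique.representative_id,
                "v_call": c.v.segment_id if c.v else "",
                "d_call": c.d.segment_id if c.d else "",
                "j_call": c.j.segment_id if c.j else "",
                "c_call": c.c.segment_id if c.c else "",
                "junction": ann.cdr3_nt,
                "junction_aa": ann.cdr3_aa,
                "productive": "T" if ann.productive else "F",
                "duplicate_count": ann.copies,
                "v_identity": round(c.v.identity(), 6) if c.v else "",
            }
        )
    df = pd.DataFrame(rows, columns=_AIRR_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df
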
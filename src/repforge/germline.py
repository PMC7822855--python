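"""Germline V/D/J/C segment references with CDR anchor annotations.

A germline database pairs a plain FASTA of segment sequences with a
tab-separated anchor table declaring, for each segment, its locus, gene
type and — where applicable — the CDR2 start and the CDR3 boundary anchor.
All coordinates are 0-based; intervals are half-open.

Anchor conventions
------------------
* V segments: ``cdr3_anchor`` is the first nucleotide of the conserved
  cysteine codon that opens CDR3; ``cdr2_start`` is the first nucleotide
  of CDR2 (the 5' end of the somatic-hypermutation counting window).
* J segments: ``cdr3_anchor`` is the first nucleotide *after* the
  conserved Phe/Trp codon, i.e. the half-open 3' boundary of CDR3.
* D and C segments carry no anchors; C segments carry an isotype label
  (IGH only).

A deterministic built-in toy reference is bundled so the pipeline and its
tests never need an external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IGH_ISOTYPES",
    "GermlineSegment",
    "GermlineDatabase",
    "GermlineError",
    "load_germline",
    "write_germline",
    "builtin_toy_reference",
]

#: IGH constant-region isotype labels, in heavy-chain locus order.
IGH_ISOTYPES = ("IgM", "IgD", "IgG3", "IgG1", "IgG2b", "IgG2c", "IgE", "IgA")

_LOCI = ("IGH", "TRB")
_GENE_TYPES = ("V", "D", "J", "C")
_NT = frozenset("ACGT")


class GermlineError(ValueError):
    """Raised for malformed or inconsistent germline references."""


@dataclass(frozen=True)
class GermlineSegment:
    """One germline reference sequence with its anchor annotations."""

    segment_id: str
    locus: str
    gene_type: str
    sequence: str
    cdr2_start: int | None = None
    cdr3_anchor: int | None = None
    isotype_label: str | None = None

    def __post_init__(self) -> None:
        if self.locus not in _LOCI:
            raise GermlineError(f"{self.segment_id}: unknown locus {self.locus!r}")
        if self.gene_type not in _GENE_TYPES:
            raise GermlineError(
                f"{self.segment_id}: unknown gene type {self.gene_type!r}"
            )
        if not self.sequence or not _NT.issuperset(self.sequence):
            raise GermlineError(
                f"{self.segment_id}: sequence must be non-empty over A/C/G/T"
            )
        n = len(self.sequence)
        if self.gene_type == "V":
            if self.cdr2_start is None or self.cdr3_anchor is None:
                raise GermlineError(f"{self.segment_id}: V segment needs both anchors")
            if not (0 <= self.cdr2_start < self.cdr3_anchor < n):
                raise GermlineError(
                    f"{self.segment_id}: need 0 <= cdr2_start < cdr3_anchor < "
                    f"{n}, got ({self.cdr2_start}, {self.cdr3_anchor})"
                )
        elif self.gene_type == "J":
            if self.cdr3_anchor is None:
                raise GermlineError(f"{self.segment_id}: J segment needs cdr3_anchor")
            if not (0 < self.cdr3_anchor < n):
                raise GermlineError(
                    f"{self.segment_id}: J cdr3_anchor {self.cdr3_anchor} out of "
                    f"(0, {n})"
                )
            if self.cdr2_start is not None:
                raise GermlineError(f"{self.segment_id}: cdr2_start is V-only")
        else:  # D, C
            if self.cdr2_start is not None or self.cdr3_anchor is not None:
                raise GermlineError(
                    f"{self.segment_id}: {self.gene_type} segments carry no anchors"
                )
        if self.gene_type == "C":
            if self.locus == "IGH":
                if self.isotype_label not in IGH_ISOTYPES:
                    raise GermlineError(
                        f"{self.segment_id}: IGH C segment needs an isotype label "
                        f"from {IGH_ISOTYPES}"
                    )
            elif self.isotype_label is not None:
                raise GermlineError(
                    f"{self.segment_id}: isotype labels apply to IGH constants only"
                )
        elif self.isotype_label is not None:
            raise GermlineError(f"{self.segment_id}: isotype_label is C-only")


@dataclass
class GermlineDatabase:
    """Validated collection of germline segments, indexed by (locus, gene type)."""

    segments: dict[str, GermlineSegment] = field(default_factory=dict)

    @classmethod
    def from_segments(cls, segments: Iterable[GermlineSegment]) -> "GermlineDatabase":
        db = cls()
        for seg in segments:
            if seg.segment_id in db.segments:
                raise GermlineError(f"duplicate segment_id {seg.segment_id!r}")
            db.segments[seg.segment_id] = seg
        db.validate()
        return db

    def validate(self) -> None:
        for locus in self.loci():
            for gt in ("V", "J", "C"):
                if not self.segments_of(locus, gt):
                    raise GermlineError(f"locus {locus}: no {gt} segment present")

    def loci(self) -> list[str]:
        return sorted({s.locus for s in self.segments.values()})

    def segments_of(self, locus: str, gene_type: str) -> list[GermlineSegment]:
        """Segments of one locus and gene type, sorted by id (deterministic)."""
        return sorted(
            (
                s
                for s in self.segments.values()
                if s.locus == locus and s.gene_type == gene_type
            ),
            key=lambda s: s.segment_id,
        )

    def get(self, segment_id: str) -> GermlineSegment:
        return self.segments[segment_id]

    def __len__(self) -> int:
        return len(self.segments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GermlineDatabase):
            return NotImplemented
        return self.segments == other.segments


_ANCHOR_COLUMNS = (
    "segment_id",
    "locus",
    "gene_type",
    "cdr2_start",
    "cdr3_anchor",
    "isotype_label",
)


def load_germline(fasta_path: str | Path, anchors_path: str | Path) -> GermlineDatabase:
    """Load a germline database from a FASTA plus TSV anchor table.

    The anchor table has columns ``segment_id  locus  gene_type  cdr2_start
    cdr3_anchor  isotype_label`` (header required, empty field = absent).
    Every FASTA record must have an anchor row and vice versa.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in sequences:
            raise GermlineError(f"duplicate segment_id {rec.id!r} in FASTA")
        sequences[rec.id] = str(rec.seq).upper()

    segments: list[GermlineSegment] = []
    seen: set[str] = set()
    with open(anchors_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _ANCHOR_COLUMNS:
            raise GermlineError(
                f"anchor table header must be {list(_ANCHOR_COLUMNS)}, got {header}"
            )
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_ANCHOR_COLUMNS):
                raise GermlineError(f"anchor table line {line_no}: wrong field count")
            sid, locus, gene_type, c2, c3, iso = parts
            if sid not in sequences:
                raise GermlineError(
                    f"anchor table names segment {sid!r} absent from the FASTA"
                )
            if sid in seen:
                raise GermlineError(f"duplicate anchor row for {sid!r}")
            seen.add(sid)
            segments.append(
                GermlineSegment(
                    segment_id=sid,
                    locus=locus,
                    gene_type=gene_type,
                    sequence=sequences[sid],
                    cdr2_start=int(c2) if c2 else None,
                    cdr3_anchor=int(c3) if c3 else None,
                    isotype_label=iso or None,
                )
            )
    missing = set(sequences) - seen
    if missing:
        raise GermlineError(
            f"FASTA records without anchor rows: {sorted(missing)} "
            "(every segment needs a row; V/J anchors are mandatory)"
        )
    return GermlineDatabase.from_segments(segments)


def write_germline(
    db: GermlineDatabase, fasta_path: str | Path, anchors_path: str | Path
) -> None:
    """Write a database back to FASTA + anchor TSV (inverse of :func:`load_germline`)."""
    ordered = sorted(db.segments.values(), key=lambda s: s.segment_id)
    records = [
        SeqRecord(Seq(s.sequence), id=s.segment_id, description="") for s in ordered
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(anchors_path, "w") as fh:
        fh.write("\t".join(_ANCHOR_COLUMNS) + "\n")
        for s in ordered:
            fh.write(
                "\t".join(
                    [
                        s.segment_id,
                        s.locus,
                        s.gene_type,
                        "" if s.cdr2_start is None else str(s.cdr2_start),
                        "" if s.cdr3_anchor is None else str(s.cdr3_anchor),
                        s.isotype_label or "",
                    ]
                )
                + "\n"
            )


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


# Toy reference geometry: the V CDR2->CDR3 window is ~246 nt so that, at a
# somatic-hypermutation rate of 25 substitutions per kb, a transcript carries
# ~6 mutations on average; with a ~30 nt 5' flank, ~50 nt CDR3+FR4 and a
# 60 nt constant-region prefix the amplicon lands near 400 bp.
_V_LEN = 310
_V_CDR2 = 58
_V_CDR3 = 304  # first nt of the conserved Cys codon (TGT), 6 nt from the 3' end
_J_LEN = 48
_J_CDR3 = 15  # first nt after the conserved Trp codon (TGG at 12..15)


def _toy_v(rng: np.random.Generator, sid: str, locus: str) -> GermlineSegment:
    seq = list(_random_nt(rng, _V_LEN))
    seq[_V_CDR3 : _V_CDR3 + 3] = "TGT"
    return GermlineSegment(
        segment_id=sid,
        locus=locus,
        gene_type="V",
        sequence="".join(seq),
        cdr2_start=_V_CDR2,
        cdr3_anchor=_V_CDR3,
    )


def _toy_j(rng: np.random.Generator, sid: str, locus: str) -> GermlineSegment:
    seq = list(_random_nt(rng, _J_LEN))
    seq[_J_CDR3 - 3 : _J_CDR3] = "TGG"
    return GermlineSegment(
        segment_id=sid,
        locus=locus,
        gene_type="J",
        sequence="".join(seq),
        cdr3_anchor=_J_CDR3,
    )


def builtin_toy_reference(locus: str = "IGH") -> GermlineDatabase:
    """Deterministic hand-seeded toy germline reference (no download needed).

    IGH: 3 V, 2 D, 2 J and one C per isotype (8 constants); the IgG2b and
    IgG2c constants deliberately share their first 20 nt, mimicking the
    near-identical 5' ends of the gamma-2 subclass genes. TRB: 4 V, 2 J,
    1 unlabelled C. Byte-identical across calls.
    """
    if locus not in _LOCI:
        raise GermlineError(f"unknown locus {locus!r}")
    rng = np.random.default_rng(20201122 if locus == "IGH" else 20201123)
    segs: list[GermlineSegment] = []
    if locus == "IGH":
        for i in (1, 2, 3):
            segs.append(_toy_v(rng, f"IGHV{i}-tst", locus))
        for i, dlen in ((1, 16), (2, 14)):
            segs.append(
                GermlineSegment(
                    segment_id=f"IGHD{i}-tst",
                    locus=locus,
                    gene_type="D",
                    sequence=_random_nt(rng, dlen),
                )
            )
        for i in (1, 2):
            segs.append(_toy_j(rng, f"IGHJ{i}-tst", locus))
        shared_g2 = _random_nt(rng, 20)
        for iso in IGH_ISOTYPES:
            if iso in ("IgG2b", "IgG2c"):
                seq = shared_g2 + _random_nt(rng, 40)
            else:
                seq = _random_nt(rng, 60)
            segs.append(
                GermlineSegment(
                    segment_id=f"IGHC-{iso}",
                    locus=locus,
                    gene_type="C",
                    sequence=seq,
                    isotype_label=iso,
                )
            )
    else:
        for i in (1, 2, 3, 4):
            segs.append(_toy_v(rng, f"TRBV{i}-tst", locus))
        for i in (1, 2):
            segs.append(_toy_j(rng, f"TRBJ{i}-tst", locus))
        segs.append(
            GermlineSegment(
                segment_id="TRBC1-tst",
                locus=locus,
                gene_type="C",
                sequence=_random_nt(rng, 60),
            )
        )
    return GermlineDatabase.from_segments(segs)
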
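"""Somatic-hypermutation statistics over the CDR2 -> CDR3 window.

The amplicon's forward primer sits in framework region 2, so mutation
counting is restricted to the V-region window from the start of CDR2 to
the start of CDR3: there the read is genuinely template-derived rather
than primer-derived. Mutations are substitutions between the read and its
best-aligned germline V segment; indels are not counted as mutation events
(records containing one inside the window are flagged but retained).

Sequencing error is controlled not by subtraction but by the copy filter:
only unique sequences observed in more than four identical copies enter
the summary statistics (a sequencing error would have to recur identically
to survive).

Two summary statistics are produced per sample:

* ``frac_gt5`` — the fraction of transcripts carrying more than five
  substituted nucleotides in the window;
* ``rate_per_kb`` — substitutions per 1000 examined bases.

Both are copy-weighted by default (each read copy is a transcript);
unique-sequence weighting is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotate import AnnotatedSequence

__all__ = ["MutationRecord", "ShmSummary", "count_mutations", "shm_summary"]


@dataclass(frozen=True)
class MutationRecord:
    """Per-unique-sequence mutation tally over the examined window."""

    representative_id: str
    examined_interval_read: tuple[int, int]  # [CDR2 start, CDR3 start)
    n_mismatch: int
    examined_length: int  # window positions actually covered by the V alignment
    copies: int
    has_indel: bool = False


def count_mutations(ann: AnnotatedSequence) -> MutationRecord | None:
    """Count germline mismatches in [CDR2 start, CDR3 start) of one sequence.

    ``examined_length`` counts only window positions aligned to the V
    reference (M columns); read bases the alignment does not cover, and
    inserted bases, are excluded. Returns ``None`` (caller flags it) when
    the CDR2 or CDR3 anchor did not migrate onto the read.
    """
    if ann.cdr2_start_read is None or ann.cdr3_interval_read is None:
        return None
    lo, hi = ann.cdr2_start_read, ann.cdr3_interval_read[0]
    if hi <= lo:
        return None
    v = ann.calls.v
    covered = 0
    has_indel = False
    qpos = v.query_interval[0]
    for op, length in v.operations:
        if op == "M":
            seg_lo, seg_hi = qpos, qpos + length
            covered += max(0, min(hi, seg_hi) - max(lo, seg_lo))
            qpos += length
        elif op == "I":
            if lo <= qpos < hi or lo < qpos + length <= hi:
                has_indel = True
            qpos += length
        else:  # D — the read lacks reference bases at read coordinate qpos
            if lo <= qpos < hi:
                has_indel = True
    if covered == 0:
        return None
    n_mm = sum(1 for p in v.mismatch_positions if lo <= p < hi)
    return MutationRecord(
        representative_id=ann.unique.representative_id,
        examined_interval_read=(lo, hi),
        n_mismatch=n_mm,
        examined_length=covered,
        copies=ann.copies,
        has_indel=has_indel,
    )


@dataclass
class ShmSummary:
    """Sample-level SHM summary; statistics are ``None`` when no record survives."""

    n_sequences_used: int
    n_copies_used: int
    frac_gt5: float | None
    rate_per_kb: float | None
    weighting: str
    min_copies: int
    gt_threshold: int


def shm_summary(
    records: list[MutationRecord],
    min_copies: int = 5,
    gt_threshold: int = 5,
    weighting: str = "copy",
) -> ShmSummary:
    """Summarise mutation records under the copy filter.

    Only records with ``copies >= min_copies`` (default 5, i.e. more than
    four copies) are included. With copy weighting each copy counts as a
    transcript; with unique weighting every surviving record counts once.
    """
    if weighting not in ("copy", "unique"):
        raise ValueError(f"unknown weighting {weighting!r}")
    kept = [r for r in records if r.copies >= min_copies]
    if not kept:
        return ShmSummary(0, 0, None, None, weighting, min_copies, gt_threshold)
    weights = [r.copies if weighting == "copy" else 1 for r in kept]
    w_total = sum(weights)
    w_gt = sum(w for r, w in zip(kept, weights) if r.n_mismatch > gt_threshold)
    mm = sum(w * r.n_mismatch for r, w in zip(kept, weights))
    bases = sum(w * r.examined_length for r, w in zip(kept, weights))
    return ShmSummary(
        n_sequences_used=len(kept),
        n_copies_used=sum(r.copies for r in kept),
        frac_gt5=w_gt / w_total,
        rate_per_kb=1000.0 * mm / bases,
        weighting=weighting,
        min_copies=min_copies,
        gt_threshold=gt_threshold,
    )
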
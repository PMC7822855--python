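"""Ground-truthed repertoire and paired-end read simulation.

The generator emulates the amplicon assay the pipeline is built for: a
clonally structured repertoire (configurable clone-size law), V(D)J
junctional diversity (trimmed segment ends plus random inserts, with a D
fragment on IGH), class-switched isotype mixtures, somatic hypermutation
confined to the V region 5' of CDR3, and ~400 bp amplicons read as
overlapping 250 nt mate pairs with a 5' constant-region barcode on R2 and
configurable per-base sequencing error.

Somatic hypermutation is applied once per clone — every transcript copy of
a clone carries the same substitutions, as the copies of a real cell's
transcript do — while sequencing error is drawn independently per copy.
This separation is what makes the >4-copy filter informative: clone-level
mutations survive it, per-copy errors do not.

Every emitted read is backed by a :class:`TruthRecord`, so each pipeline
stage can be tested against exact ground truth with no external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import Clonotype
from .germline import GermlineDatabase
from .preprocess import SequencingRead, reverse_complement, write_fastq

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_repertoire",
    "emit_reads",
    "truth_clonotypes",
    "write_truth",
]

_ALPHABET = "ACGT"


@dataclass
class SimulationConfig:
    """Study conditions for one simulated sample.

    Defaults describe an unmutated, IgM-dominated repertoire (the resting
    B-1a-like condition) sequenced without error; tests and experiments
    override the knobs they probe.
    """

    seed: int = 0
    locus: str = "IGH"
    n_clones: int = 100
    clone_size_law: str = "geometric"  # geometric | power_law | uniform
    clone_size_param: float = 0.3  # geometric p / zipf a / uniform constant size
    clone_size_offset: int = 0  # added to every clone size (e.g. to force >=5)
    v_usage_weights: dict[str, float] | None = None  # None = uniform over V genes
    isotype_mixture: dict[str, float] | None = None  # None = locus default
    shm_rate_per_base: float = 0.0  # substitutions/base, V region 5' of CDR3
    shm_indel_rate: float = 0.0  # 1-nt insertions/deletions per base, same region
    junction_insert_range: tuple[int, int] = (0, 6)  # inclusive, per insert
    v_trim3_max: int = 3
    j_trim5_max: int = 6
    flank_5prime: int = 30  # amplicon start, nt 5' of the V CDR2 start
    c_prefix_len: int = 60  # constant-region prefix included in the amplicon
    read_length: int = 250
    barcode: str = "ACGTACGT"
    seq_error_rate: float = 0.0
    quality_value: int = 35
    low_quality_tail: int = 0  # trailing bases emitted at Phred 10

    def __post_init__(self) -> None:
        if self.isotype_mixture is not None:
            total = sum(self.isotype_mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"isotype mixture sums to {total}, not 1")
        if self.clone_size_law not in ("geometric", "power_law", "uniform"):
            raise ValueError(f"unknown clone_size_law {self.clone_size_law!r}")
        if not (0.0 <= self.shm_rate_per_base < 1.0):
            raise ValueError("shm_rate_per_base must be in [0, 1)")
        if not (0.0 <= self.shm_indel_rate < 1.0):
            raise ValueError("shm_indel_rate must be in [0, 1)")
        if not (0.0 <= self.seq_error_rate < 1.0):
            raise ValueError("seq_error_rate must be in [0, 1)")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one clone: segments, coordinates, mutations, copies."""

    clone_id: str
    v_id: str
    d_id: str  # "" when no D fragment survives (or TRB)
    j_id: str
    c_id: str
    isotype: str
    amplicon: str  # clean (pre-sequencing-error), SHM applied
    cdr2_pos: int  # amplicon coordinate of the CDR2 start
    cdr3_start: int  # amplicon coordinate of the conserved-Cys codon
    cdr3_end: int  # half-open end (after the J Phe/Trp codon)
    cdr3_nt: str
    copies: int
    shm_positions: tuple[int, ...]  # amplicon coordinates, all < cdr3_start
    shm_in_window: int  # how many fall in [cdr2_pos, cdr3_start)


def _weighted_choice(rng, items: list, weights: list[float]):
    w = np.asarray(weights, dtype=float)
    return items[int(rng.choice(len(items), p=w / w.sum()))]


def _clone_size(rng, cfg: SimulationConfig) -> int:
    if cfg.clone_size_law == "geometric":
        size = int(rng.geometric(cfg.clone_size_param))
    elif cfg.clone_size_law == "power_law":
        size = min(int(rng.zipf(cfg.clone_size_param)), 100000)
    else:
        size = int(cfg.clone_size_param)
    return max(1, size) + cfg.clone_size_offset


def _default_mixture(locus: str) -> dict[str, float]:
    # IgM-dominated resting repertoire; TRB has a single unlabelled constant.
    return {"IgM": 0.98, "IgD": 0.02} if locus == "IGH" else {"TRBC": 1.0}


def simulate_repertoire(
    cfg: SimulationConfig, db: GermlineDatabase
) -> list[TruthRecord]:
    """Sample a clonal repertoire with full ground truth; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    vs = db.segments_of(cfg.locus, "V")
    ds = db.segments_of(cfg.locus, "D")
    js = db.segments_of(cfg.locus, "J")
    cs = db.segments_of(cfg.locus, "C")
    if not vs or not js or not cs:
        raise ValueError(f"database lacks {cfg.locus} segments")
    if cfg.v_usage_weights is None:
        v_weights = [1.0] * len(vs)
    else:
        v_weights = [cfg.v_usage_weights.get(s.segment_id, 0.0) for s in vs]
    mixture = cfg.isotype_mixture or _default_mixture(cfg.locus)
    iso_labels = sorted(mixture)
    iso_weights = [mixture[k] for k in iso_labels]
    by_isotype = {
        (s.isotype_label if s.isotype_label else "TRBC"): s for s in cs
    }
    for label in iso_labels:
        if label not in by_isotype:
            raise ValueError(f"no constant segment for isotype {label!r}")

    ins_lo, ins_hi = cfg.junction_insert_range
    records: list[TruthRecord] = []
    for idx in range(cfg.n_clones):
        for _attempt in range(20):
            v = _weighted_choice(rng, vs, v_weights)
            j = js[int(rng.integers(len(js)))]
            c = by_isotype[_weighted_choice(rng, iso_labels, iso_weights)]
            isotype = c.isotype_label if c.isotype_label else "TRBC"

            v_trim = int(rng.integers(0, cfg.v_trim3_max + 1))
            j_trim = int(rng.integers(0, cfg.j_trim5_max + 1))
            n1 = "".join(
                _ALPHABET[i]
                for i in rng.integers(0, 4, size=int(rng.integers(ins_lo, ins_hi + 1)))
            )
            d_frag, d_id = "", ""
            if ds:
                d = ds[int(rng.integers(len(ds)))]
                lo = int(rng.integers(0, len(d.sequence) // 2))
                hi = int(rng.integers(lo, len(d.sequence) + 1))
                if hi - lo >= 5:  # shorter fragments are unattributable
                    d_frag, d_id = d.sequence[lo:hi], d.segment_id
            n2 = "".join(
                _ALPHABET[i]
                for i in rng.integers(0, 4, size=int(rng.integers(ins_lo, ins_hi + 1)))
            )

            v_start = v.cdr2_start - cfg.flank_5prime
            if v_start < 0:
                raise ValueError("flank_5prime extends past the V segment start")
            v_part = v.sequence[v_start : len(v.sequence) - v_trim]
            if len(v.sequence) - v_trim <= v.cdr3_anchor:
                continue  # trim ate the Cys anchor; resample
            if j_trim >= j.cdr3_anchor:
                continue  # trim ate the J anchor region; resample
            j_part = j.sequence[j_trim:]
            amplicon = v_part + n1 + d_frag + n2 + j_part + c.sequence[: cfg.c_prefix_len]

            cdr2_pos = cfg.flank_5prime
            cdr3_start = v.cdr3_anchor - v_start
            j_off = len(v_part) + len(n1) + len(d_frag) + len(n2)
            cdr3_end = j_off + (j.cdr3_anchor - j_trim)
            if cdr3_end <= cdr3_start:
                continue

            # clone-level SHM indels (off by default): 1-nt events applied
            # 3'->5' so earlier coordinates stay valid; boundaries shift along
            if cfg.shm_indel_rate > 0:
                seq0 = list(amplicon)
                for p in np.flatnonzero(rng.random(cdr3_start) < cfg.shm_indel_rate)[::-1]:
                    p = int(p)
                    if rng.random() < 0.5:
                        del seq0[p]
                        shift = -1
                    else:
                        seq0.insert(p, _ALPHABET[int(rng.integers(4))])
                        shift = 1
                    if p < cdr2_pos:
                        cdr2_pos += shift
                    cdr3_start += shift
                    cdr3_end += shift
                amplicon = "".join(seq0)
                if cdr2_pos < 1 or cdr3_end - cdr3_start < 1:
                    continue  # degenerate after indels; resample

            # clone-level SHM: substitutions uniform over the V-derived part
            seq = list(amplicon)
            positions: list[int] = []
            if cfg.shm_rate_per_base > 0:
                hits = np.flatnonzero(
                    rng.random(cdr3_start) < cfg.shm_rate_per_base
                )
                for p in hits:
                    old = seq[p]
                    choices = [b for b in _ALPHABET if b != old]
                    seq[p] = choices[int(rng.integers(3))]
                    positions.append(int(p))
            amplicon = "".join(seq)

            records.append(
                TruthRecord(
                    clone_id=f"c{idx:05d}",
                    v_id=v.segment_id,
                    d_id=d_id,
                    j_id=j.segment_id,
                    c_id=c.segment_id,
                    isotype=isotype,
                    amplicon=amplicon,
                    cdr2_pos=cdr2_pos,
                    cdr3_start=cdr3_start,
                    cdr3_end=cdr3_end,
                    cdr3_nt=amplicon[cdr3_start:cdr3_end],
                    copies=_clone_size(rng, cfg),
                    shm_positions=tuple(positions),
                    shm_in_window=sum(1 for p in positions if p >= cdr2_pos),
                )
            )
            break
        else:
            raise RuntimeError("could not build a feasible junction in 20 attempts")
    return records


def emit_reads(
    truth: list[TruthRecord],
    cfg: SimulationConfig,
    r1_path: str | Path,
    r2_path: str | Path,
) -> dict[str, int]:
    """Write paired FASTQ for a truth table; returns emission counts.

    Per copy: R1 is the amplicon's first ``read_length`` nt; R2 is the
    reverse complement of its last ``read_length`` nt with the sample
    barcode prepended. Sequencing errors are drawn independently per copy.
    Deterministic per config seed; byte-identical across runs.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    rl = cfg.read_length
    max_amp = max((len(t.amplicon) for t in truth), default=0)
    if truth and 2 * rl < max_amp + 10:
        warnings.warn(
            f"read_length {rl} barely spans amplicons up to {max_amp} nt; "
            "pairs may fail to overlap",
            stacklevel=2,
        )

    def quals(n: int) -> tuple[int, ...]:
        q = [cfg.quality_value] * n
        for k in range(1, min(cfg.low_quality_tail, n) + 1):
            q[-k] = 10
        return tuple(q)

    r1_reads: list[SequencingRead] = []
    r2_reads: list[SequencingRead] = []
    n_err = 0
    for t in truth:
        for copy in range(t.copies):
            seq = t.amplicon
            if cfg.seq_error_rate > 0:
                arr = list(seq)
                hits = np.flatnonzero(rng.random(len(arr)) < cfg.seq_error_rate)
                for p in hits:
                    choices = [b for b in _ALPHABET if b != arr[p]]
                    arr[p] = choices[int(rng.integers(3))]
                    n_err += 1
                seq = "".join(arr)
            rid = f"{t.clone_id}:{copy:04d}"
            fwd = seq[:rl]
            rev = cfg.barcode + reverse_complement(seq)[:rl]
            r1_reads.append(SequencingRead(rid, fwd, quals(len(fwd)), "R1"))
            r2_reads.append(SequencingRead(rid, rev, quals(len(rev)), "R2"))
    write_fastq(r1_reads, r1_path)
    write_fastq(r2_reads, r2_path)
    return {
        "pairs": len(r1_reads),
        "error_bases": n_err,
        "clones": len(truth),
    }


def truth_clonotypes(truth: list[TruthRecord]) -> list[Clonotype]:
    """Collapse a truth table to its expected clonotype table (V, J, CDR3)."""
    groups: dict[tuple[str, str, str], Clonotype] = {}
    for t in truth:
        k = (t.v_id, t.j_id, t.cdr3_nt)
        ct = groups.get(k)
        if ct is None:
            ct = Clonotype(v_gene=t.v_id, j_gene=t.j_id, cdr3_nt=t.cdr3_nt)
            groups[k] = ct
        ct.total_copies += t.copies
        ct.n_unique += 1
        ct.isotype_copies[t.isotype] = ct.isotype_copies.get(t.isotype, 0) + t.copies
    out = list(groups.values())
    out.sort(key=lambda c: (-c.total_copies, c.v_gene, c.j_gene, c.cdr3_nt))
    return out


def write_truth(truth: list[TruthRecord], path: str | Path) -> None:
    """Dump the truth table as TSV."""
    pd.DataFrame(
        [
            {
                "clone_id": t.clone_id,
                "v_id": t.v_id,
                "d_id": t.d_id,
                "j_id": t.j_id,
                "c_id": t.c_id,
                "isotype": t.isotype,
                "copies": t.copies,
                "cdr3_nt": t.cdr3_nt,
                "cdr2_pos": t.cdr2_pos,
                "cdr3_start": t.cdr3_start,
                "cdr3_end": t.cdr3_end,
                "n_shm": len(t.shm_positions),
                "n_shm_window": t.shm_in_window,
                "amplicon": t.amplicon,
            }
            for t in truth
        ]
    ).to_csv(path, sep="\t", index=False)
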
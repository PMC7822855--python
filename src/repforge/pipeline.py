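"""End-to-end pipeline: demultiplex -> trim -> merge -> collapse -> assign ->
annotate -> clonotype -> SHM -> diversity -> tree-map, with per-stage count
ledgers and per-sample fault isolation.

Every stage's inputs and outputs are counted and the ledger must balance:
input pairs = assigned + unassigned; assigned = trim-discarded + merged +
merge-discarded; merged copies = unique copies; uniques = annotated +
unassignable. Reports and artifacts are byte-deterministic for a fixed
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .align import ScoringScheme
from .annotate import (
    annotate_all,
    build_clonotypes,
    isotype_composition,
    write_airr,
)
from .diversity import d50, rank_abundance, subsample, v_usage
from .germline import GermlineDatabase, builtin_toy_reference, load_germline
from .preprocess import (
    collapse_duplicates,
    demultiplex,
    merge_pair,
    MergedSequence,
    quality_trim,
    read_fastq_pairs,
)
from .shm import count_mutations, shm_summary
from .treemap import treemap_svg

__all__ = ["RunConfig", "SampleReport", "ConfigError", "validate_config", "run_pipeline"]

logger = logging.getLogger("repforge")


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass
class RunConfig:
    """Fully resolved pipeline parameters (documented defaults)."""

    r1: str = ""
    r2: str = ""
    output_dir: str = "repforge_out"
    # germline source: either both file paths, or a builtin locus
    germline_fasta: str | None = None
    germline_anchors: str | None = None
    builtin_locus: str | None = None
    locus: str = "IGH"
    # demultiplexing
    barcode_table: str | None = None  # TSV: barcode <tab> sample
    barcodes: dict[str, str] | None = None  # inline alternative
    barcode_mate: str = "R2"
    max_mismatch: int = 0
    # trimming / merging
    window: int = 2
    qmin: int = 20
    min_length: int = 50
    min_overlap: int = 10
    # alignment
    match: int = 2
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1
    threshold_v: int = 40
    threshold_j: int = 16
    threshold_c: int = 16
    threshold_d: int = 10
    # SHM
    min_copies: int = 5
    gt_threshold: int = 5
    weighting: str = "copy"
    copy_unit: str = "exact_duplicate"  # or "clonotype": filter on clonotype totals
    # clonotyping / diversity
    clonotype_key: str = "vj_cdr3"
    subsample_to: int | None = None  # rarefy to this read depth before D50
    subsample_seed: int = 0
    # treemap
    treemap_width: float = 1000.0
    treemap_height: float = 600.0
    treemap_seed: int = 0
    corner_radius: float = 4.0

    def scoring(self) -> ScoringScheme:
        return ScoringScheme(self.match, self.mismatch, self.gap_open, self.gap_extend)

    def thresholds(self) -> dict[str, int]:
        return {
            "V": self.threshold_v,
            "J": self.threshold_j,
            "C": self.threshold_c,
            "D": self.threshold_d,
        }


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration, reporting all errors at once."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    unknown = sorted(set(raw) - set(_FIELDS))
    if unknown:
        errors.append(f"unknown config keys: {unknown}")
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in _FIELDS})

    for key in ("r1", "r2"):
        val = getattr(cfg, key)
        if not val:
            errors.append(f"{key}: required")
        elif not Path(val).exists():
            errors.append(f"{key}: path {val!r} does not exist")
    if cfg.builtin_locus is None:
        for key in ("germline_fasta", "germline_anchors"):
            val = getattr(cfg, key)
            if not val:
                errors.append(f"{key}: required unless builtin_locus is set")
            elif not Path(val).exists():
                errors.append(f"{key}: path {val!r} does not exist")
    elif cfg.builtin_locus not in ("IGH", "TRB"):
        errors.append(f"builtin_locus: must be IGH or TRB, got {cfg.builtin_locus!r}")
    if cfg.barcode_table is None and cfg.barcodes is None:
        errors.append("one of barcode_table / barcodes is required")
    if cfg.barcode_table is not None and not Path(cfg.barcode_table).exists():
        errors.append(f"barcode_table: path {cfg.barcode_table!r} does not exist")
    for key, lo in (
        ("window", 1),
        ("min_overlap", 1),
        ("min_length", 0),
        ("qmin", 0),
        ("max_mismatch", 0),
        ("min_copies", 1),
        ("gt_threshold", 0),
    ):
        if not isinstance(getattr(cfg, key), int) or getattr(cfg, key) < lo:
            errors.append(f"{key}: must be an integer >= {lo}")
    if cfg.weighting not in ("copy", "unique"):
        errors.append("weighting: must be 'copy' or 'unique'")
    if cfg.copy_unit not in ("exact_duplicate", "clonotype"):
        errors.append("copy_unit: must be 'exact_duplicate' or 'clonotype'")
    if cfg.clonotype_key not in ("vj_cdr3", "cdr3"):
        errors.append("clonotype_key: must be 'vj_cdr3' or 'cdr3'")
    if cfg.subsample_to is not None and (
        not isinstance(cfg.subsample_to, int) or cfg.subsample_to < 1
    ):
        errors.append("subsample_to: must be a positive integer or absent")
    if cfg.treemap_width <= 0 or cfg.treemap_height <= 0:
        errors.append("treemap dimensions must be positive")
    try:
        cfg.scoring()
    except ValueError as exc:
        errors.append(f"scoring: {exc}")
    if errors:
        raise ConfigError(errors)
    return cfg


@dataclass
class SampleReport:
    """Per-sample stage ledger, summary statistics and artifact paths."""

    sample: str
    status: str = "ok"
    error: str = ""
    counts: dict[str, int] = field(default_factory=dict)
    isotype_percent: dict[str, float] = field(default_factory=dict)
    isotype_unknown_copies: int = 0
    shm: dict = field(default_factory=dict)
    d50: dict | None = None
    v_usage: dict[str, float] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)  # relative paths

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def ledger_balanced(self) -> bool:
        c = self.counts
        return (
            c.get("pairs_in", 0)
            == c.get("trim_discarded", 0)
            + c.get("merged", 0)
            + c.get("merge_short_overlap", 0)
            + c.get("merge_mismatch", 0)
            and c.get("merged", 0) == c.get("unique_copies", 0)
            and c.get("unique_sequences", 0)
            == c.get("annotated", 0) + c.get("unassignable", 0)
        )


def _load_barcodes(cfg: RunConfig) -> dict[str, str]:
    if cfg.barcodes is not None:
        return dict(cfg.barcodes)
    table: dict[str, str] = {}
    with open(cfg.barcode_table) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            barcode, sample = line.split("\t")[:2]
            table[barcode] = sample
    return table


def _load_db(cfg: RunConfig) -> tuple[GermlineDatabase, str]:
    if cfg.builtin_locus is not None:
        return builtin_toy_reference(cfg.builtin_locus), cfg.builtin_locus
    return load_germline(cfg.germline_fasta, cfg.germline_anchors), cfg.locus


def _process_sample(
    sample: str,
    pairs: list,
    cfg: RunConfig,
    db: GermlineDatabase,
    locus: str,
    outdir: Path,
) -> SampleReport:
    rep = SampleReport(sample=sample)
    c = rep.counts
    c["pairs_in"] = len(pairs)

    merged: list[MergedSequence] = []
    c["trim_discarded"] = c["merge_short_overlap"] = c["merge_mismatch"] = 0
    for r1, r2 in pairs:
        t1 = quality_trim(r1, cfg.window, cfg.qmin)
        t2 = quality_trim(r2, cfg.window, cfg.qmin)
        if len(t1) < cfg.min_length or len(t2) < cfg.min_length:
            c["trim_discarded"] += 1
            continue
        result = merge_pair(t1, t2, cfg.min_overlap)
        if isinstance(result, MergedSequence):
            merged.append(result)
        else:
            c[f"merge_{result.reason}"] += 1
    c["merged"] = len(merged)

    uniques = collapse_duplicates(merged)
    c["unique_sequences"] = len(uniques)
    c["unique_copies"] = sum(u.copy_count for u in uniques)

    annotated, c["unassignable"] = annotate_all(
        uniques, db, locus, cfg.scoring(), cfg.thresholds()
    )
    c["annotated"] = len(annotated)
    c["no_cdr3"] = sum(1 for a in annotated if not a.cdr3_nt)
    logger.info(
        "%s: %d pairs -> %d merged -> %d unique -> %d annotated",
        sample,
        c["pairs_in"],
        c["merged"],
        c["unique_sequences"],
        c["annotated"],
    )

    sdir = outdir / sample
    sdir.mkdir(parents=True, exist_ok=True)
    rel = lambda p: str(p.relative_to(outdir))  # noqa: E731

    airr_path = sdir / "airr.tsv"
    write_airr(annotated, airr_path)
    rep.artifacts["airr"] = rel(airr_path)

    comp = isotype_composition(annotated)
    rep.isotype_percent = comp.percent
    rep.isotype_unknown_copies = comp.unknown_copies

    clonotypes = build_clonotypes(annotated, cfg.clonotype_key)
    c["clonotypes"] = len(clonotypes)
    clonotype_totals = {
        (ct.v_gene, ct.j_gene, ct.cdr3_nt): ct.total_copies for ct in clonotypes
    }

    records = []
    for ann in annotated:
        mr = count_mutations(ann)
        if mr is None:
            continue
        if cfg.copy_unit == "clonotype" and ann.cdr3_nt:
            key = (
                (ann.v_gene, ann.j_gene, ann.cdr3_nt)
                if cfg.clonotype_key == "vj_cdr3"
                else ("", "", ann.cdr3_nt)
            )
            mr = dataclasses.replace(mr, copies=clonotype_totals[key])
        records.append(mr)
    summary = shm_summary(records, cfg.min_copies, cfg.gt_threshold, cfg.weighting)
    rep.shm = dataclasses.asdict(summary)
    mut_path = sdir / "mutations.tsv"
    pd.DataFrame(
        [
            {
                "sequence_id": r.representative_id,
                "window_start": r.examined_interval_read[0],
                "window_end": r.examined_interval_read[1],
                "n_mismatch": r.n_mismatch,
                "examined_length": r.examined_length,
                "copies": r.copies,
                "has_indel": r.has_indel,
            }
            for r in records
        ],
        columns=[
            "sequence_id",
            "window_start",
            "window_end",
            "n_mismatch",
            "examined_length",
            "copies",
            "has_indel",
        ],
    ).to_csv(mut_path, sep="\t", index=False)
    rep.artifacts["mutations"] = rel(mut_path)

    if clonotypes:
        ra = rank_abundance(clonotypes, cfg.clonotype_key)
        if cfg.subsample_to is not None:
            ra = subsample(ra, cfg.subsample_to, cfg.subsample_seed)
        res = d50(ra)
        rep.d50 = {"C": res.C, "D50": res.D50, "S": res.S, "J": res.J}
        rep.v_usage = v_usage(clonotypes)
        div_path = sdir / "diversity.tsv"
        pd.DataFrame(
            {
                "rank": range(1, ra.S + 1),
                "label": ra.labels,
                "copies": ra.r,
            }
        ).to_csv(div_path, sep="\t", index=False)
        rep.artifacts["diversity"] = rel(div_path)
        svg_path = sdir / "treemap.svg"
        treemap_svg(
            clonotypes,
            svg_path,
            cfg.treemap_width,
            cfg.treemap_height,
            cfg.treemap_seed,
            cfg.corner_radius,
        )
        rep.artifacts["treemap"] = rel(svg_path)
    else:
        logger.warning("%s: 0 sequences annotated with a CDR3; no diversity output", sample)

    summary_path = sdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(rep.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    rep.artifacts["summary"] = rel(summary_path)
    return rep


def run_pipeline(cfg: RunConfig) -> dict[str, SampleReport]:
    """Run every stage for every demultiplexed sample; failures are isolated
    per sample (a failed sample's report carries status='failed')."""
    db, locus = _load_db(cfg)
    barcode_table = _load_barcodes(cfg)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    pairs = read_fastq_pairs(cfg.r1, cfg.r2)
    demux = demultiplex(pairs, barcode_table, cfg.max_mismatch, cfg.barcode_mate)
    logger.info(
        "demultiplex: %(input)d pairs, %(assigned)d assigned, "
        "%(unassigned)d unassigned (%(ambiguous)d ambiguous)",
        demux.counts,
    )

    reports: dict[str, SampleReport] = {}
    for sample in sorted(demux.by_sample):
        try:
            rep = _process_sample(
                sample, demux.by_sample[sample], cfg, db, locus, outdir
            )
        except Exception as exc:  # per-sample isolation
            logger.error("sample %s failed: %s", sample, exc)
            rep = SampleReport(sample=sample, status="failed", error=str(exc))
        rep.counts["demux_input"] = demux.counts["input"]
        rep.counts["demux_unassigned"] = demux.counts["unassigned"]
        reports[sample] = rep

    run_report = {
        "demultiplex": demux.counts,
        "samples": {s: r.to_dict() for s, r in reports.items()},
    }
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(run_report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return reports
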
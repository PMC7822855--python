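# repforge

Analysis of amplicon-based immune-repertoire sequencing (AIRR-seq) data —
mouse IgH or TCRβ transcripts amplified from framework region 2 into the
constant region and read as overlapping Illumina mate pairs.

From raw paired FASTQ, the pipeline:

1. **demultiplexes** mate pairs by the barcode at the 5′ end of the
   constant-region-side read;
2. **quality-trims** each mate with a 2-base sliding window (truncate from
   the first window containing a Phred score < 20);
3. **merges** mates by end-free overlap alignment, discarding any pair whose
   overlap is not a perfect match;
4. **collapses** identical merged reads into unique transcripts with copy
   counts;
5. **assigns** germline V, D, J and C segments with an affine-gap
   Smith–Waterman aligner, calling the isotype from the best constant hit;
6. **extracts CDR3** by migrating the reference Cys/Phe-Trp anchors onto the
   read through the alignments, and groups sequences into
   (V, J, CDR3-nucleotide) clonotypes;
7. **quantifies somatic hypermutation (SHM)** as germline mismatches in the
   CDR2 → CDR3 window, restricted to transcripts seen in more than four
   identical copies (the copy filter that suppresses sequencing error);
8. **summarises diversity** with the D50 index and V-gene usage; and
9. **renders clonal tree-maps** (V → V–J → V–J–CDR3 nested rectangles, area
   ∝ read frequency) as SVG.

A ground-truthed simulator generates clonally structured repertoires and
paired reads with configurable SHM, isotype mixtures and sequencing error,
so the entire pipeline is testable without any external download; a
deterministic built-in toy germline reference is bundled.

## The statistics

**SHM.** For each unique transcript, mismatches against the best-aligned
germline V are counted over the window from the start of CDR2 to the start
of CDR3 (the amplicon's forward primer sits in FR2, so sequence 5′ of CDR2
is primer-derived). With copy weights $w_i$, mismatch counts $m_i$ and
examined lengths $\ell_i$ over transcripts with > 4 copies:

$$\text{rate} = 10^3 \cdot \frac{\sum_i w_i m_i}{\sum_i w_i \ell_i}
\quad\text{per kb},\qquad
\text{frac}_{>5} = \frac{\sum_i w_i\,[m_i > 5]}{\sum_i w_i}.$$

**D50.** Rank distinct CDR3 abundances $r_1 \ge r_2 \ge \dots \ge r_S$ with
$J = \sum_i r_i$. $C$ is the unique rank with
$\sum_{i \le C} r_i \ge J/2$ and $\sum_{i \le C-1} r_i < J/2$, and
$D50 = 100\,C/S$. Low D50 means an oligoclonal repertoire.

## Worked example

Simulate a mutated, class-switched 200-clone IgH repertoire and run the
pipeline on it:

```sh
cat > sim.yaml <<'YAML'
seed: 42
n_clones: 200
clone_size_law: geometric
clone_size_param: 0.25
shm_rate_per_base: 0.02
isotype_mixture: {IgM: 0.55, IgG1: 0.2, IgG2b: 0.1, IgG3: 0.1, IgA: 0.05}
YAML
repforge simulate -c sim.yaml -o reads
# -> 200 clones, 763 read pairs -> reads

cat > run.yaml <<'YAML'
r1: reads/R1.fastq
r2: reads/R2.fastq
builtin_locus: IGH
barcodes: {ACGTACGT: sample1}
output_dir: out
YAML
repforge run -c run.yaml
# -> sample1: 763 pairs, 200 clonotypes, D50=23.00

repforge d50 out/sample1/airr.tsv
# -> S=200  J=763  C=46  D50=23.0000
```

`out/sample1/` now holds an AIRR Rearrangement TSV (`airr.tsv`), the
per-sequence mutation table, the ranked diversity table, a tree-map SVG and
`summary.json`, which for this run reports an isotype composition of
IgM 62.6 / IgG1 17.2 / IgG2b 9.8 / IgG3 6.9 / IgA 3.4 percent of copies, an
SHM rate of 20.6 substitutions per kb with 35.9 % of transcripts carrying
more than five changes (63 transcripts pass the > 4-copy filter), and
D50 = 23.0: the 46 most abundant of 200 CDR3 sequences account for half of
the 763 reads. The tree-map in `treemap.svg` shows each CDR3 as one rounded
rectangle, nested inside its V–J and V blocks, with the expanded clones as
the large blocks toward the bottom-right.

All numbers above are deterministic for the given seeds.

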
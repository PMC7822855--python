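# Methods

## The assay model

The pipeline targets multiplex RT-PCR amplicon libraries of rearranged
antigen-receptor transcripts: a forward primer in the V framework region 2
(FR2) and a reverse primer in the constant region produce ~400 bp products
spanning CDR2, CDR3 and the start of the constant exon, sequenced as
paired-end reads long enough to overlap in the middle. The read pair that
starts in the constant region carries a sample barcode at its 5′ end. Two
consequences shape the analysis:

* sequence 5′ of CDR2 is partly primer-derived, so mutation counting is
  confined to the CDR2 → CDR3 window;
* both mates observe the overlap region independently, so a merged read with
  a perfectly matching overlap has effectively double-checked bases there.

## Preprocessing contracts

**Demultiplexing** assigns a pair when exactly one barcode lies within
`max_mismatch` (default 0) of the tagged mate's prefix; prefixes within
tolerance of two or more barcodes are *ambiguous* and go to the unassigned
bin, counted separately. Conservation (assigned + unassigned = input) holds
for any input.

**Quality trimming** slides a `window` (default 2) across the Phred scores;
at the first window containing any score below `qmin` (default 20) the read
is truncated at the window's first position. Trimming from the window start
rather than the offending base makes the operation idempotent. Pairs in
which either trimmed mate falls below `min_length` (default 50 nt;
unconstrained by the assay, chosen to leave enough sequence for a V
alignment) are dropped symmetrically.

**Merging** is deliberately strict: the best gap-free, end-free overlap of
R1's 3′ end against reverse-complemented R2's 5′ end is accepted only if it
is a perfect character match of at least `min_overlap` (default 10) bases.
Since any overlap containing a mismatch or gap is discarded anyway, the
merge reduces to finding the longest exact overlap; when none exists, the
best-scoring (matches − mismatches) offset over all overlap lengths decides
whether the failure is reported as `short_overlap` or `mismatch`. `N`
matches nothing, so an `N` surviving into an overlap forces a discard.
There is no consensus-calling or quality-aware correction — the assay's
error control is the downstream copy filter, and we keep that contract.

**Collapsing** groups byte-identical merged sequences; the copy count is
the group size and the representative is the lexicographically smallest
read id, so the operation is order-independent.

## Germline references and coordinates

A germline database is a FASTA plus a TSV anchor table (segment id, locus,
gene type, CDR2 start, CDR3 anchor, isotype label). All coordinates are
0-based half-open. The V anchor is the first nucleotide of the conserved
cysteine codon; the J anchor is the first nucleotide *after* the conserved
Phe/Trp codon, i.e. directly usable as the CDR3 3′ boundary. Keeping the
anchors in an explicit side table (rather than deriving them from gapped
reference alignments) makes the CDR3 convention testable and lets users
supply any reference release they trust. Only A/C/G/T are accepted in
references; ambiguity codes would poison the alignment scoring model.

The bundled toy reference (IGH: 3 V, 2 D, 2 J, 8 C — one per heavy-chain
isotype, with IgG2b/IgG2c sharing their first 20 nt as the real γ2
subclass genes nearly do; TRB: 4 V, 2 J, 1 C) is generated from fixed seeds
and is byte-identical across calls. Its geometry is chosen to mimic the
assay: a 246 nt CDR2 → CDR3 window, ~30 nt FR2 flank, ~50 nt of J, and a
60 nt constant prefix give ~400 bp amplicons that 250 nt mates overlap by
~85–100 nt.

## Alignment and segment calling

The aligner is an affine-gap Smith–Waterman (match +2, mismatch −2, gap
open −3, gap extend −1 by default; a gap of length *k* costs
`open + (k−1)·extend`). The scores are not meaningful in isolation — they
are chosen so that substitutions are strongly preferred over gaps (the
dominant error process here is SHM and sequencing substitutions, not
indels) and are fully exposed in configuration. Among co-optimal
alignments, the one with the smallest query start, then smallest reference
start, then fewest operations is returned; `N` scores as a mismatch against
everything. The dynamic-programming fill runs through a numba-compiled
kernel when numba is importable, with the identical pure-Python function as
fallback; the traceback is pure Python either way.

Per gene type the best-scoring segment above a score floor is kept
(defaults V 40, J 16, C 16, D 10; ties break to the lexicographically first
segment id, and a tied constant call additionally raises an ambiguity
flag — relevant when a read ends inside the shared 5′ region of two
subclass constants). D segments are short enough to match spuriously
anywhere, so they are searched only between the V segment's CDR3-anchor
projection on the read and the start of the J hit; an absent D is a legal
call. Calls must be ordered V ≤ D ≤ J ≤ C along the read; violations demote
D first, then C. A read with no V or no J above threshold (or with J
starting before V, which demotion cannot repair) is unassignable and is
counted, not annotated. Merged reads are oriented V → C by construction of
the assay, so only one strand is searched by default.

## CDR3, clonotypes, composition

CDR3 boundaries are obtained by *anchor migration*: walking the V (or J)
alignment's operation list to the read coordinate aligned to the reference
anchor. A position inside a deletion maps to the read coordinate
immediately 3′ of it; an anchor outside the aligned reference interval
leaves the CDR3 absent with a flag. The CDR3 nucleotide string runs from
the V Cys codon start to the end of the J Phe/Trp codon; it is translated
when its length is a multiple of three, and *productive* means in-frame
with no stop codon inside CDR3 (the amplicon does not reliably cover the
full V frame, so whole-sequence productivity is not assessed).

Clonotypes group annotated sequences by (V gene, J gene, CDR3 nucleotide
sequence) — the same hierarchy the tree-map draws; a CDR3-only key is
available via `clonotype_key` for sensitivity analysis. Isotype composition
and V-gene usage are copy-weighted (each read copy is a transcript), with
unknown-isotype copies reported separately rather than silently diluting
the percentages.

## SHM statistics

For each unique sequence the examined interval is [CDR2 start, CDR3 start)
on the read. `examined_length` counts only positions the V alignment
actually aligns to the reference (M columns); substitutions are the V
alignment's mismatch positions falling in the window; indels in the window
are flagged but not counted as mutation events, since the statistic is
defined on nucleotide substitutions. Only records with more than four
copies enter the summary — identical sequencing errors recurring five times
are vanishingly unlikely, so surviving mismatches are clone-level
mutations. Both copy-weighted (headline) and unique-sequence weightings are
computed. An empty surviving set yields explicitly undefined statistics
(`None`), never a fake zero.

At the simulator's default geometry (246 nt window) a mutation rate of 25
per kb corresponds to ~6 substitutions per transcript, so roughly half of
transcripts carry more than five changes — the regime of a germinal-center
response, and the regime the parameter-recovery tests exercise.

## D50 and tree-maps

D50 uses exact integer arithmetic for the J/2 comparison
(`2·prefix ≥ J`), so odd totals need no rounding convention; the two
defining inequalities pin C uniquely. The index is scale-invariant,
permutation-invariant, bounded by [100/S, 100], and never increases when
mass is concentrated into the top clone.

The tree-map subdivides the canvas V → V–J → V–J–CDR3 with every
rectangle's area exactly proportional to copy-weighted frequency. The
geometric algorithm (the literature fixes the semantics and ordering but
not the geometry) is a recursive weighted binary partition: siblings sorted
by descending frequency are split at the half-weight point, the parent
rectangle is cut across its longer axis in exact weight proportion, and the
heavier half is placed bottom/right — so the largest clone lands at the
bottom-right and the smallest at the top-left, with moderate aspect ratios
and zero overlap by construction. Leaf colours are seeded random HSL draws
with a redraw when consecutive leaves would be nearly identical; SVG output
is byte-deterministic for a fixed seed.

## The simulator

`simulate_repertoire` draws, per clone: a V (configurable usage weights), a
J, a constant/isotype from the mixture, junctional trims (V 3′ ≤ 3 nt,
J 5′ ≤ 6 nt), two random inserts (0–6 nt each) and, on IGH, a D fragment
(kept only when ≥ 5 nt — shorter fragments are unattributable even in
principle). Clone sizes follow a geometric (default p = 0.3), zipf or
constant law. SHM substitutions are applied *per clone*, uniformly over the
V-derived sequence 5′ of CDR3: the copies of a clone are transcript reads
of the same cell and share its mutations, which is exactly what makes the
copy filter informative. Per-copy, independent events are reserved for
sequencing error. Defaults are an unmutated, IgM-dominated mixture
(IgM 0.98 / IgD 0.02, the resting-repertoire condition); mutated or
class-switched conditions are explicit overrides in the experiments that
probe them.

What the simulator does **not** model: PCR amplification bias and chimeras,
realistic quality-score trajectories (qualities are constant with an
optional low-quality tail), indel-type SHM by default, and allelic
variation of the germline. Passing tests therefore demonstrate correctness
of the computations under the stated generative model, not robustness to
every artefact of real libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script use simulations of 150–1000
clones (up to ~10⁴ read copies), chosen as the smallest sizes at which the
statistical recovery checks have comfortable margins (3σ multinomial bands
on composition; ±15 % on SHM-rate recovery at 1000 clones). Alignment
score floors, the merge `min_overlap` of 10, and the trimming defaults are
recorded in `RunConfig` and exposed in the YAML config; unknown config
keys are rejected outright to catch typos. Determinism is part of the
contract: simulator, pipeline, layout and SVG output are byte-identical
for fixed seeds, and every test that draws randomness seeds it.

## Known limitations

* The co-optimal-alignment tie-break (smallest query start, then reference
  start, then fewest operations) can, in rare cases (~0.3 % of reads at
  2 % SHM), pick a gapped alignment over the equivalent ungapped one when a
  mutation sits near the V 3′ end next to a junction insert that
  chance-matches germline, shifting the reported CDR3 by the gap length.
  Mutation-free reads are unaffected: their ungapped alignment is strictly
  optimal.
* Isotype calling uses only the sequenced constant prefix; constants that
  are identical over that prefix are reported as the lexicographically
  first with an ambiguity flag.
* D50 is computed on the observed repertoire; no depth normalisation is
  applied by default (a subsampling hook exists in configuration but is
  off, since comparisons across samples of very different depth should be
  designed explicitly).
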
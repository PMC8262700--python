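# Methods

`smallrna` is a desk-scale small RNA-seq pipeline: raw FASTQ in, per-class
count matrices, differential-expression tables, sample-structure summaries
and novel miRNA precursor candidates out. This note describes the models and
procedures, the parameters that matter, the synthetic data the tests run on,
and the numerical choices made where the design was open.

## Preprocessing

Each read passes through, in order: 3' adapter trimming, 3' quality
trimming, removal of fixed bases (5' barcode, adapter barcode, UMI), the N
policy, and a minimum-length filter. Adapter trimming runs first so that
quality trimming operates on insert bases only; protocols that place
low-quality tails beyond the adapter are unaffected by the order.

**Adapter search.** The adapter is aligned semi-globally against every
suffix of the read. At a start position the alignment must explain the rest
of the read: either the adapter is truncated by the read's 3' end (partial
occurrence) or the read continues past a complete adapter (everything
downstream is trimmed anyway). Among positions whose edit distance is within
`max_adapter_edit_dist` (default 1) and whose overlap reaches `min_overlap`
(default 10 nt), the global minimum distance wins, ties broken to the
leftmost position (the shorter insert — small-RNA inserts are short and a
later occurrence is usually adapter-internal self-similarity).

**Quality trimming.** Windows of `qual_window` bases (default 4) slide
5'→3' in steps of one; the read is truncated at the first base of the first
window whose mean Phred score falls below `qual_threshold` (default 20).
Trailing partial windows are included so a short bad tail is still removed.

**UMI handling.** UMIs of `umi_len` bases are taken from the configured side
(inside the 5' barcode, or adjacent to the adapter barcode). Collapsing is
exact-match: without UMIs a collapsed record's count is the read
multiplicity; with UMIs it is the number of *distinct* UMIs seen for that
insert sequence. No UMI error-correction clustering is attempted — at toy
scale sequencing errors in the UMI inflate counts by a bounded, documented
amount, and the deduplication rule stays auditable.

**Defaults** (`min_read_len` 18, `n_policy` trim_ends) are conventional
small-RNA settings; every knob is exposed on `PreprocessConfig` and the CLI.

## Mapping and quantification

The internal mapper is deliberately simple: an exact seed of `seed_len`
(default 18 nt, no seed mismatches) looked up in a k-mer index of both
reference strands, extended ungapped over the rest of the read with a
per-class mismatch cap. Reads qualifying at more than `max_hits` (default 5)
loci are discarded as over-cap multimappers. Indels are out of scope for the
internal mapper; externally produced SAM (with NM tags) can be ingested
instead. The mapper targets provable correctness at fixture scale — it is
tested against an exhaustive ungapped search — not aligner performance.

**miRNA counting.** On precursor space, a read counts toward a mature
annotation when its 5' end is within `offset5` = 2 nt and its 3' end within
`offset3` = 5 nt of the annotated boundaries, with at most 1 mismatch. A
read compatible with several matures (or several equally-best precursors)
contributes its full collapsed count to each; there is no fractional
splitting, so multimapper totals can multi-count — the same convention the
lowest-mismatch rule implies for the other classes.

**isomiRs.** Mapping runs with one extra mismatch (cap 2). Terminal 3'
mismatches are reclassified, greedily from the last base inward, as
non-templated additions (NTA) wherever the read base disagrees with the
templated precursor continuation; reclassified bases do not count as
mismatches. A record is kept if at most 1 true mismatch remains and the
positional tolerances hold, measured on the templated portion (the NTA
suffix is excluded before the 3'-offset check). Variant labels follow the
miRGFF3 vocabulary (`iso_5p`, `iso_3p`, `iso_snv`, `iso_add3p`; `NA` for the
canonical form) and isomiR tables round-trip through the miRGFF3
writer/parser.

**Other ncRNA classes** (tRNA, piRNA, rRNA, scaRNA, lncRNA, snoRNA, snRNA,
miscRNA, circRNA) are quantified with zero mismatches by default; for each
read only the alignments achieving that read's minimum mismatch count
contribute, each receiving the full collapsed count. Classes may be
annotated as genomic intervals (GFF3/BED) or as sequence-space FASTA
references (the form in which piRNA and circRNA sets are usually
distributed). Classes are counted independently: no cross-class priority is
imposed, so a read may legitimately appear in two class matrices.

## Expression statistics

**Detection filter.** A feature is "detected" in a sample at ≥ 3 reads; it
is kept when detected in ≥ 50% of all samples, or — when a grouping variable
is supplied — in ≥ 50% of at least one level. Both comparisons are
inclusive, so a feature at exactly the boundary survives.

**Normalization** is log2(RPM + 1), RPM computed against the per-sample
total genome-mapped read count (configurable; values are then comparable
across classes).

**Differential expression.** For every unordered pair of levels (k levels →
k(k−1)/2 comparisons): Shapiro–Wilk normality per group, Welch's t-test, and
Wilcoxon Mann–Whitney (exact for groups ≤ 8 without ties, otherwise the
tie- and continuity-corrected normal approximation). With more than two
levels one-way ANOVA and Kruskal–Wallis are added. Both t and WMW p-values
are reported rather than auto-switched on normality; the headline adjusted
p-value is the BH-adjusted WMW, with BH families formed per comparison per
RNA class. Effect sizes: fold change on the RPM scale with a +1
pseudo-offset (so empty groups stay finite), its log2, the ROC AUC (ties
counted ½, so AUC = U/(n_A·n_B)), and Cohen's d with pooled SD on the log2
scale. Degenerate inputs follow p = 1 conventions for identical constant
groups; d is missing when the pooled SD is zero with unequal means.

**Candidate filter.** The conjunction of: mean expression ≥ 1 RPM in at
least one level, AND effect AUC ≥ 0.7 (or ≤ 0.3), AND adjusted p < 0.05.
"Effect size" is interpreted as the AUC; Cohen's d is reported and can be
selected as the filter effect instead (`effect="cohens_d"`).

## Sample structure

PCA embeddings use the top two components of the feature-centered matrix,
sign-fixed by making each component's largest-magnitude loading positive.
UMAP (n_neighbors 15, min_dist 0.1, fixed seed recorded in the output) is a
contract-only stochastic embedding; with too few samples it falls back to
PCA with a warning. Sample correlation is Spearman's rank correlation of RPM
vectors (ties mid-ranked); sample clustering applies complete-linkage
agglomeration to Euclidean distances between the rows of that correlation
matrix. Expression heatmap clustering can be restricted to the k
largest-variance features (ties broken by feature id).

### PVCA

Principal variance component analysis attributes expression variance to the
annotation variables:

1. features are centered and (by default) scaled to unit variance, so
   high-expression features do not dominate;
2. PCA on the samples retains the leading components whose cumulative
   explained variance reaches `pc_variance_threshold` (default 0.6, the
   conventional PVCA choice);
3. each retained component's scores are fitted with a variance-components
   mixed model — one random effect per annotation variable and per pairwise
   interaction, plus residual — by REML (statsmodels `MixedLM`); a fit that
   fails or diverges falls back to a method-of-moments estimate from
   between-level variances, flagged in the result;
4. per-term variance fractions are averaged across components weighted by
   the PCA eigenvalues and normalized to sum to one.

PVCA runs on the log2(RPM+1) matrix. It quantifies confounding; it does not
correct for it.

## Novel miRNA discovery

1. **Read stacks.** Genome alignments are grouped by shared 5' start (per
   contig and strand). A group is a stack when its summed collapsed count
   reaches `min_stack_height` and is strictly maximal among groups within ±
   `window_len` (default 70 nt) on the same strand; ties go to the 5'-most
   group. Raising `min_stack_height` is therefore monotone-restrictive.
2. **Excision.** Two windows of `window_len` are cut per stack: one placing
   the stack on the 5' arm (`[stack.start − flank, … + W)`), one on the 3'
   arm (`[stack.end + flank − W, …)`), with a 10-nt flank on the
   stack-proximal side. Windows extending beyond the contig are omitted;
   minus-strand windows are reverse-complemented.
3. **Folding.** The internal backend is a weighted Nussinov dynamic program:
   maximal nested pairing with weights GC = 3, AU = 2, GU = 1 and a minimum
   hairpin loop of 3 nt. The score is unit-free (more negative = more
   stable); it is *not* a nearest-neighbor free energy. Any callable with
   the same `(sequence) → (dot_bracket, score)` contract — e.g. a wrapper
   around RNAfold — can be substituted via the `fold` argument when physical
   kcal/mol values are needed.
4. **Arms and Dicer consistency.** The mature arm is the stack interval in
   window coordinates. Its duplex partner is read off the structure as the
   longest antiparallel helix run of the mature's pairing partners (this
   discards stray pairs, e.g. a terminal base caught by a loop helix), then
   extended by the canonical 2-nt 3' overhang. The Dicer-consistency
   fraction is the share of window reads whose 5' ends fall within
   `boundary_tolerance` (2 nt) of the mature or star 5' cut site; candidates
   below `min_dicer_fraction` (0.66) or with a mature length outside
   [18, 25] nt are rejected, as are candidates whose mature arm is mostly
   unpaired.
5. **Categories.** `novel`: no genomic overlap with known miRNA loci *and*
   the predicted mature is farther than edit distance 2 from every known
   mature of the species. `known_precursor_new_mature`: overlaps a known
   precursor whose expressed arm is unannotated. `overlaps_known`:
   everything else.
6. **Ranking.** Each candidate's features (precursor length, GC fraction,
   energy per nt, mature length, paired-base fraction) are z-scored against
   a reference feature table; the score is the mean absolute z, ascending =
   more miRNA-like. The shipped reference table is synthetic — a stand-in
   distribution with plausible means/SDs — and is meant to be replaced by a
   table derived from a curated miRNA set for real analyses.

## Synthetic data generator

`simulate` builds the study conditions the tests run under: a random genome
(default 50 kb) with planted hairpin precursors (perfectly complementary
22-nt arms around an 8-nt loop — ideal substrates, unlike real bulged
hairpins), interval annotations for the other classes, and per-sample reads
drawn from mature sequences under a Zipf abundance model (exponent 1.2;
1.5 for the low-complexity compression fixture). Group effects multiply
non-reference levels by 2^(planted log2 FC); batch effects are per-(feature,
batch) log-normal factors with SD `batch_shift_sd` — the minimal structure
PVCA can detect. Reads get substitution errors, the 3' adapter, optional 5'
UMIs, and high qualities with a mildly degraded 3' tail. Everything is
integer-RNG deterministic given the seed; emitted read counts equal the
requested depth exactly.

What the generator does **not** emulate — ligation bias, realistic indel
profiles, chemical modifications, imperfect hairpins, genomic repeats —
bounds what passing tests show: they demonstrate the pipeline's rules and
statistics are implemented correctly, not that the defaults are optimal on
real libraries.

## Problem sizes and numerics

The test suite runs at fixture scale by design: 4-sample studies of one to
two thousand reads each for end-to-end runs, a 10-kb reference with 1 000
reads for the mapping oracle, 2 000 features for the statistical
calibration, 40 samples × 200 features for PVCA recovery, and folding
oracles exhaustively enumerated up to 18 nt. The compression check uses one
million reads over 500 distinct sequences.

Tolerances and conventions worth knowing: BH q-values cap at 1 and leave
missing p-values out of the family; Spearman correlations with a constant
sample are reported missing; PCA is deterministic up to the documented sign
convention; dendrogram heights are non-decreasing under complete linkage;
the Nussinov traceback resolves ties deterministically (unpaired-left before
pairing before bifurcation), so identical inputs give identical structures.

## Known limitations

- The internal mapper is ungapped; reads spanning indels must come from an
  external aligner via SAM.
- Multimapper counts are not fractionally split; totals across features can
  exceed the read count when loci tie.
- The hierarchical class priority some pipelines impose (e.g. rRNA before
  miRNA) is intentionally absent; classes are counted independently.
- UMI deduplication is exact-match; sequencing errors in UMIs are not
  clustered away.
- The NovoMiRank-style reference table is synthetic; ranking orders
  candidates sensibly but the absolute scores are not calibrated against a
  curated miRNA population.
- PVCA reports variance attribution only; no batch correction is applied.
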
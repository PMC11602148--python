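# Methods

## The E-box alphabet

An E-box is a CANNTG hexanucleotide; a bHLH dimer reads it as two CAN
trinucleotide half-sites on opposing strands.  Writing a hexamer as
`half_a + revcomp(half_b)` and identifying each hexamer with its reverse
complement partitions the 16 CANNTG hexamers into 10 classes: 4 homotypic
(half_a = half_b; the hexamer is its own reverse complement) with one
representative each, 6 heterotypic with two.  The half-site order inside a
heterotypic label (CAT–CAG but CAA–CAT) follows the field's published
nomenclature and is stored as a fixed table because it is not derivable from
one lexical rule; labels use an ASCII hyphen (`CAT-CAT`) for file and CLI
friendliness.

Scanning is exact-match on the forward strand only.  This is complete: a
reverse-strand E-box is itself a forward-strand E-box, and canonicalization
absorbs strand (tested as a property on random sequences).  Overlapping
occurrences are all reported — the spacing analysis needs every occurrence —
and hexamers containing N never match, while flanks may contain N (reported
in an "other" bucket, since whether N-containing flanks were kept in the
original analyses is unknowable from the outputs).

Conventions: coordinates are 0-based half-open throughout; the hexamer
midpoint is taken as `start + 3`; `summit_distance = midpoint − summit`
(signed).  `flank_a` is `seq[start−2:start]`; `flank_b` is the reverse
complement of `seq[start+6:start+8]`, i.e. the dinucleotide 5′ of the
reverse-strand half-site read on its own strand; out-of-sequence positions
pad with N.

## Peaks and signal

The two-replicate consensus rule keeps an intersecting peak pair only when
both summits fall inside the intersection; the consensus interval is the
intersection and the consensus summit the floor of the summits' midpoint
(the source rule does not say which summit survives).  When one peak
qualifies against several partners, each qualifying pair yields a record and
overlapping records merge to their union keeping the leftmost summit.
Summit-centered resizing (default 1500 bp) clips at contig edges rather than
discarding, with a flag.

Signal tracks are in-memory bedGraphs (sorted non-overlapping intervals).
All window means are coverage-weighted over base pairs that *have* data;
uncovered base pairs are missing, never zero — essential for %CpG tracks,
which only exist at CpGs.

## Motif grammar statistics

Centrality is the fold change of motifs per base pair in a near window
(|d| ≤ 50 bp of the summit) versus a distal window (250–750 bp) within the
same summit-resized peaks; > 1 is centrally enriched.  The distal outer
bound defaults to the resized-peak half-width (750 for 1500 bp peaks); the
near-50/distal->150 variant is reachable through parameters.  A class with
zero distal occurrences reports a missing fold, not infinity.  Window
membership uses the midpoint distance; for the score-binned windows the full
hexamer must lie inside the window.

Pair spacing counts intervening nucleotides
(`downstream.start − upstream.end`) for every ordered-by-position pair in
the same peak within a maximum gap (default 30), so a mode at 6 matches a
"six-nucleotide spacing" reading; all pairs are counted, not only adjacent
ones (the original analysis does not state which; center-to-center is not
offered because it is redundant with an offset of 6 for hexamers).
Overlapping hexamers go to an overlap bucket excluded from proportions.

Score-binned enrichment sorts peaks by a score (pre-induction accessibility
averaged over a 2 kb window for ATAC / 4 kb for histone marks, or a
pre/post log₂ fold change with pseudocount 1) into equal-size bins and
counts motifs per peak inside either a fixed window or a window of 0.4 of
the peak length centered on the summit; optional per-class z-scaling across
bins maps zero-spread rows to zeros.

## Accessibility trajectories

Cells ordered by pseudotime are aggregated within cell type into groups of
175 (trailing cells form their own group only when at least half a group
remains, else they merge into the previous group — the source is silent on
remainders), giving the 8/5/7/8/2 NSC/IPC/PN1/PN2/PN3 block layout at the
study's cell numbers.  Counts are normalized as log₂ CPM with pseudocount 1
(recorded in the output); the ANOVA operates on the log₂ CPM scale (the
original scale is unstated; configurable).

A region is invariant when the one-way ANOVA across cell types gives
p ≥ 10⁻⁶ or the region vector is degenerate (zero variance — Pearson r is
undefined there).  Dynamic regions are assigned the group of the
best-correlating binary template.  Templates are **all** single-run binary
vectors whose run edges lie on cell-type block boundaries, excluding all-0
and all-1 (14 templates for 5 blocks) — the smallest complete family
containing both published example vectors; runs starting at the first
sample are *falling*, ending at the last are *neuronal*, internal runs are
*transient*.  Ties break by enumeration order, deterministically.

Recovery on synthetic data is measured as: the fraction of dynamic-called
truly-dynamic regions assigned their true group, plus the fraction of truly
flat regions called dynamic.  At the study noise level (sd = 0.25 ×
amplitude) short-run templates (e.g. the 2-sample PN3 run) have bounded
ANOVA F regardless of amplitude (F ≈ 7.5 at that SNR) and legitimately fall
below the very conservative 10⁻⁶ threshold, so sensitivity conditional on
detection is the meaningful recovery metric.

A CPM caveat: with *zero* noise, truly flat regions acquire
between-cell-type CPM shifts from library-size composition with zero
within-group variance, hence infinite F.  This is a property of CPM
normalization when few regions dominate the library, not of the classifier;
with realistic noise and region counts the invariant false-positive rate is
effectively zero (the 10⁻⁶ threshold is extremely conservative).

## Methylation

Per-class stage deltas average %mCpG over covered base pairs in a ±5 bp
window around the hexamer midpoint (11 bp; the hexamer-plus-5 bp reading is
a config option — the source wording "5 bp around" is ambiguous), separately
per stage, delta = PN − NSC.  Profiles delegate to the binned signal matrix
(10 bp bins) with SEM over anchors that have data.

## HT-SELEX

Per round, the fraction of reads carrying ≥ 1 representative hexamer of each
class (denominator: all reads in the round, matching a
"percentage of sequences that carried each hexanucleotide" definition; a
read may count toward several classes).  Matching both representatives on
the forward strand makes detection strand-insensitive, so whether reverse
strands were matched explicitly in the original is moot.  Trends are a
least-squares slope over round index plus a strict monotone-increase flag.

## Selection analysis

Polymorphisms: SNVs with MAF ≥ 0.05 (inclusive) inside the hexamer
(half-open interval).  Divergence: mismatches against the aligned outgroup
hexamer; any gap excludes the motif, as does a missing alignment (distinct
flag).  PSS = |d| ≤ 50 bp, NSS = 200–400 bp, boundaries inclusive as
printed; rates are counts per motif (hexamers are all 6 bp, so per-motif and
per-bp rates are proportional).  MK-style resampling draws seeded subsets
without replacement (default size: smallest per-class count) and labels a
subset purifying when both ratios are < 1.  Phylostratigraphic depth uses
cumulative gating — every shallower clade threshold must also be met — the
standard phylostratigraphy reading of a threshold list; excluded (gapped or
missing) species never count as conserved but clade totals stay absolute.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed) and write their
ground truth separately from the analysis inputs.

- **Genomes**: one contig per peak, i.i.d. background at a set GC (0.5
  default), E-boxes planted at Poisson per-bp rates near the summit
  (±50 bp) versus elsewhere.  Planting rejects positions where writing the
  hexamer creates an unintended E-box within ±8 bp, so planted densities
  stay interpretable as truth; background E-boxes elsewhere remain, as in a
  real genome (≈ 1/256 per bp at GC 0.5), which slightly dilutes recovered
  folds exactly as real background would.  No repeat structure,
  dinucleotide bias, or mappability artifacts.
- **Pseudobulks**: log-signal = baseline 3 + amplitude 4 × template +
  N(0, 0.25 × amplitude), rounded exponentials as counts.  Templates align
  exactly with cell-type blocks; real trajectories are smoother and real
  counts overdispersed beyond this model.
- **SELEX**: the selected pool is treated as effectively infinite — after t
  selection steps its distribution is the random library tilted by
  odds^(k·t) (k = contained high-affinity hexamers), and each round's reads
  are an independent importance-resampled draw from a fresh candidate
  library.  Naively bootstrap-resampling the previous round's reads instead
  amplifies individual carrier lineages, whose co-contained hexamers then
  drift coherently across rounds — an artifact of sequencing-depth-sized
  pools that real SELEX (sequencing a vanishing fraction of ~10¹² molecules)
  does not show.  No sequencing error or PCR bias.
- **Conservation**: per-position substitution/polymorphism probabilities
  scaled by a constraint factor at PSS motifs; MAFs Uniform(0, 0.5) so a
  known share falls below the 0.05 cutoff; optional planted indels exercise
  the exclusion paths.  No phylogenetic tree structure — species within a
  clade are i.i.d. — and no linkage between neighboring variants.
- **Methylation**: flat baseline 80 % with a 60-point rectangular dip within
  ±100 bp of dip-class motifs in the dip stage only; optional CpG
  subsampling.  Real methylation is CpG-sparse, noisy and graded.

Passing recovery checks on these inputs demonstrates the statistics are
implemented correctly and recover planted effects at realistic sizes; it
does not demonstrate robustness to the artifacts the generators omit.

## Problem sizes and checks

The recovery checks run at 200 peaks × 1500 bp (centrality), 150 peaks
(spacing), 2000 regions × 30 samples (trajectories), 4 × 50 000 reads
(SELEX, retention odds 3), 10 000 motifs (selection ratios; 3 seeds for the
neutral mean), 400 sites (methylation) — sizes at which the binomial/Poisson
sampling error of each estimate is several times smaller than the acceptance
band around its planted truth.  `scripts/acceptance.py --seed N --out F`
recomputes all of them from scratch.

## Known limitations

- The consensus rule is pairwise; multi-way replicate designs reduce to
  successive pairwise application.
- bigWig is not parsed; methylation/signal tracks are consumed as bedGraph
  text (a bigWig adapter can wrap an external reader upstream).
- Spacing over-representation is reported as a distribution against
  provided controls; no significance test is attached.
- The MK resampling reports ratio clouds and quadrant shares, not a formal
  neutrality index or alpha estimate.
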
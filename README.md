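# eboxgrammar

Analysis toolkit for the **E-box grammar** of proneural bHLH transcription
factors (NEUROG2, NEUROD2) during cortical neurogenesis.

bHLH dimers bind the hexanucleotide **CANNTG** (the E-box); each monomer
contacts one **CAN half-site** on opposing strands.  Naming an E-box by its
two 5′→3′ half-sites and collapsing the 16 CANNTG hexamers under reverse
complementation yields **10 strand-symmetric classes** — 4 homotypic
(palindromes such as CAT–CAT = CATATG) and 6 heterotypic (e.g. CAT–CAG =
CAGATG ≡ CATCTG).  The package implements, as a tested reusable pipeline,
the statistics used to characterize how these classes are deployed around
transcription-factor binding sites:

- **ebox core** — canonical classes, exact-match genome scanning
  (forward-strand scanning is complete because canonicalization absorbs
  strand), half-site flank extraction.
- **regions** — narrowPeak/BED/bedGraph plumbing, the two-replicate summit
  consensus rule, summit-centered resizing, anchor-centered signal matrices.
- **grammar** — summit *centrality*
  `(near occurrences / near bp) / (distal occurrences / distal bp)`
  (near = ±50 bp of the summit, distal = 250–750 bp by default),
  motifs-per-peak, flanking-dinucleotide bias, E-box pair spacing
  (intervening nucleotides), score-binned enrichment with the
  0.4-of-peak-length window rule.
- **trajectories** — pseudotime-ordered pseudobulks (groups of 175 cells;
  8/5/7/8/2 groups for NSC/IPC/PN1/PN2/PN3), log₂ CPM, one-way ANOVA
  invariance at p ≥ 10⁻⁶, binary-template Pearson classification into
  falling / transient / neuronal trajectories, expression–accessibility
  pseudobulk correlation (groups of 50 cells), the ≥ 3 %-of-cells
  accessibility rule, quantile occupancy, scaled Jaccard.
- **methylation** — %CpG methylation profiles (10 bp bins) and per-class
  PN − NSC deltas in a ±5 bp window around E-box midpoints.
- **selex** — HT-SELEX round-wise class fractions (share of reads carrying a
  representative hexamer) and enrichment trends.
- **conservation** — polymorphism counting (SNVs, MAF ≥ 0.05), substitution
  counting against an outgroup (indel-spanning motifs excluded), PSS/NSS
  rate ratios (putatively selected sites |d| ≤ 50 bp vs non-selected sites
  200–400 bp from the summit), McDonald–Kreitman-style subset resampling
  (purifying quadrant: pPSS/pNSS < 1 **and** dPSS/dNSS < 1), and
  phylostratigraphic depth (cumulative clade thresholds 20/39 placentals,
  1/3 marsupials, 1/1 monotreme, 8/16 non-mammals).
- **simulate** — seeded generators for every input with known ground truth:
  planted-motif genomes, trajectory-shaped pseudobulks, affinity-driven
  SELEX rounds, clade-structured substitutions and polymorphisms,
  methylation tracks with demethylation dips.

## Worked example

```python
from eboxgrammar import scan_eboxes
from eboxgrammar.simulate import gen_genome_with_peaks
from eboxgrammar.grammar import motif_centrality

for s in scan_eboxes("GCCAGATGCTTCACGTGAA"):
    print(s.start, s.hexamer, s.ebox_class, s.flank_a, s.flank_b)
# 2 CAGATG CAT-CAG GC AG
# 11 CACGTG CAC-CAC TT TT

seqs, peaks, truth = gen_genome_with_peaks(
    n_peaks=200, peak_width=1500, seed=1,
    class_density_near={"CAT-CAT": 0.03},    # motifs/bp within ±50 bp of summit
    class_density_distal={"CAT-CAT": 0.01},  # 3x dilution elsewhere in the peak
)
sites = [s for pk in peaks
         for s in scan_eboxes(seqs[pk.contig], contig=pk.contig,
                              summit=pk.summit)]
print(motif_centrality(sites, n_peaks=len(peaks)).round(2).to_string())
```

The CAT–CAG site at position 2 shows the nomenclature: CAGATG read on the
forward strand is CATCTG on the reverse, so one monomer sees a CAT half-site
(upstream flank `AG`) and the other a CAG half-site (upstream flank `GC`).
On the synthetic genome, the CAT–CAT row recovers the planted 3× summit
enrichment while every other class — appearing only as sequence background —
sits near 1:

```
ebox_class  near_count  distal_count  centrality
   CAT-CAT         631          2114        2.98
   CAT-CAG           6            80        0.75
   ...
```

(background classes fluctuate around 1 with only a handful of near-summit
counts each; CAT–CAT's 2.98 is the planted 3× density ratio diluted by the
same background.)

A CLI mirrors the library:
`eboxgrammar simulate|scan|classes|grammar|trajectories|methylation|selex|conservation`
— each subcommand writes delimited outputs, a resolved `config.json`, and a
log of record counts.

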
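# Methods

## Target enumeration and off-target counting

A target site is a 20-nt protospacer plus its PAM: `NGG` immediately 3' of
the protospacer for Cas9, `TTTN` immediately 5' for Cas12a. Both strands are
scanned; coordinates are 0-based half-open over protospacer+PAM (BED
convention, chosen for interoperability with narrowPeak input), and the
protospacer is reported 5'→3' on the PAM-carrying strand. IUPAC `N` in a PAM
pattern matches A/C/G/T only — a genomic `N` never matches, and any window
containing one is skipped, so ambiguous assembly regions cannot create
phantom targets. Overlapping and nested sites are all reported, since counts
are the statistic of interest. Sites are ordered by start coordinate with
`+` before `−` at ties.

Off-target counting asks, for one guide: how many sites in the genome carry
an exact PAM match and a protospacer at Hamming distance exactly *m*, for
*m* = 0..5? Mismatches are counted in the protospacer only; the PAM must
match its IUPAC pattern exactly (the convention of standard pattern-based
off-target searchers). The per-guide counts are normalised by genome length
when compared across genomes. Cross-enzyme comparison uses per-genome,
per-mismatch-level ratios: each Cas9 guide's normalised count divided by the
genome's median normalised Cas12a count (the two enzymes have different guide
sets, so no per-guide pairing exists; this convention is ours and is fixed).
Genome-level medians are compared across mismatch levels with Kruskal–Wallis
(mid-ranks for ties; an all-identical input is reported as H = 0, p = 1
rather than an error) and pairwise tests are Bonferroni-corrected by
multiplying p by the number of comparisons, capped at 1.

The scan is a vectorised linear pass, adequate for desk-scale genomes (tens
of Mb); no FM-index or suffix-array backend is provided, and bulges or
RNA-DNA heteroduplex scoring are out of scope.

## GUIDE-seq meta-analysis

Inputs are curated per-site read-count tables (guide, site, mismatch count,
reads, on-target flag) — no raw read processing. Relative cleavage of a site
is 100 × reads / on-target reads; guides with zero on-target reads are
excluded with a warning. A predicted site counts as cleaved iff it has ≥ 1
read (no detection threshold is stated by the sources such tables come from,
so the minimal one is used). The cleaved fraction at each mismatch level is
the percentage of sequence-predicted sites with ≥ 1 read; levels with no
predicted sites are reported missing, and more cleaved than predicted sites
is a consistency error.

## Editing-outcome landscape

Allele tables carry one row per (target, variant) with a read count, where a
variant is an insertion, deletion, SNV or WT with a length and a position.
Positions are 0-based offsets in the analysis window on the PAM-carrying
strand; the deletion position is the 5'-most deleted base and the insertion
position the base left of the insert (a convention we fix and document since
aligners differ). All statistics are read-count weighted, so splitting a row
into two rows with the same coordinates and summed reads changes nothing.

The window length is a parameter, default 39 nt (10-nt 5' flank + 20-nt
protospacer + 9-nt 3' flank), giving a uniform positional expectation of
100/39 ≈ 2.56% per position. (Sources disagree internally on whether the
window holds 29 or 39 positions while quoting the 2.56% figure, which only
100/39 reproduces; hence the parameterisation and the 39 default.) Hotspot
positions are stored 0-based in window coordinates; protospacer position 17
(1-based) is window offset 26 under the default layout.

The deletion:insertion ratio is total deletion reads over total insertion
reads (flagged infinite when no insertions exist). Welch's *t* (unequal
variances) and Cohen's *d* with the pooled SD compare per-target deletion vs
insertion read frequencies. The SNV noise filter retains a target's SNV
outcome iff SNV reads / total reads is strictly greater than 1%.

## Sequence featurisation

The tokeniser maps a DNA string to a fixed-order numeric vector: global
mononucleotide counts (A,C,G,T), global dinucleotide counts (AA..TT,
lexicographic), positional one-hot mono- and di-nucleotides
(position-major), and GC fraction last. Counts are raw integers; GC is a
fraction. For length L with all families on the vector has
4 + 16 + 4L + 16(L−1) + 1 entries. Components (e.g. guide vs flank) can be
tokenised separately and concatenated with name prefixes so one component's
composition never dilutes another's, and sliding windows provide region
features. The canonical Cas12a context is 34 nt:
`[4-nt 5' flank][TTTN][20-nt protospacer][6-nt 3' flank]` (685 features).
A schema version string is embedded in serialised models and checked at
predict time, so train/predict drift fails loudly. All feature families are
on by default with flags to ablate.

## Screen efficiency inference

In a pooled knockout screen, guides that cut well in essential genes deplete
over time. Counts are normalised to counts-per-million within each library;
LFC(t) = log2((cpm_t + 1)/(cpm_ref + 1)) with a pseudocount of 1 (no
normalisation scheme is canonical here; cpm+1 keeps LFC scale-invariant to
sequencing depth up to < 1% distortion at cpm ≥ 100). The efficiency score is
the negative mean LFC over post-reference timepoints (a slope-vs-time variant
is available behind `method="slope"`); higher = more depleted = more
efficient. Because the score is a log-ratio, the training table min–max
scales retained guides' scores to the 0–100 efficiency units the models train
and predict on (raw scores are kept alongside).

Essentiality confounds depletion, so guides are restricted to genes with a
Bayes Factor ≥ 6 — a conventional high-confidence-essential cutoff, since no
specific threshold is canonical; it is configurable. Gene joins are
case-insensitive; unmatched symbols are counted and logged, never silently
dropped. Accessibility labels are 1 iff the guide interval overlaps any
DNase narrowPeak by ≥ 1 bp under half-open semantics (abutting intervals do
not overlap). Accessibility is a validation stratifier by default, not a
model feature.

## Random-forest models

Both models keep scikit-learn defaults except `n_estimators=450`; this is
deliberate — the forest is robust at defaults and only tree count is pinned
(in config, so library upgrades cannot drift the other defaults silently).
Regression CV uses plain k-fold (k=5, shuffled, seeded); classification uses
StratifiedKFold to preserve class proportions. OOB error is the OOB MSE for
regression and the OOB misclassification rate for classification. Regression
predictions are clipped to [0, 100] at output. Percentile ranks use the
mean-of-strict-and-weak convention (all-tied input → 50). Feature importances
are the forest's impurity importances, non-negative and summing to 1, sorted
descending with ties broken by schema order. An 80/20 seeded shuffled
holdout (`holdout_report`) provides the visualisation split; stratified for
classification. With a fixed seed the whole train→predict path is
bit-reproducible.

The SNV-outcome classifier labels each target with its outcome base at the
hotspot; the reference base is excluded, so chance accuracy is 1/3, which the
validation report documents via one-vs-all ROC/AUC and per-class accuracy.

## Synthetic data

The generators exist so every stage is testable without downloads; they are
pure functions of (config, seed).

* **Genomes**: i.i.d. bases with P(G)=P(C)=gc/2. Real genomes have
  autocorrelated composition, repeats and N runs; an i.i.d. model reproduces
  only the marginal GC dependence of PAM density, which is the property under
  test.
* **Screens**: defaults mirror a mini-human-style library — 2,061 guides over
  687 genes, reference + 4 weekly timepoints, mean reference depth 500 reads
  per guide, 15% essential genes (so the BF ≥ 6 filter leaves ≈ 306 guides).
  Planted efficiency is a logistic function of protospacer base composition
  scaled to [0,100]; essential-gene guides deplete as
  ref · 2^(−t · eff/100 · k) with rate constant k = 1/week (no functional
  form is canonical; exponential decay per week is the simplest
  self-consistent choice and k is exposed). Counts are Poisson around a
  lognormal-overdispersed expectation (sd 0.1). Essential genes draw
  BF = 6 + Gamma(2, 5); non-essential genes draw Normal(−3, 3), whose upper
  tail rarely crosses the cutoff — deliberate realism, as BAGEL scores are
  noisy. The planted law is a smooth composition effect; real guide activity
  also has positional, structural and chromatin determinants, so recovery
  here shows the pipeline's statistical machinery works, not that real
  efficiency is this predictable.
* **Outcomes**: per-read variant types are drawn with shares set by the
  edited fraction (default 0.41), the SNV share of variants (default 0.634)
  and the deletion:insertion ratio (default 1.91). Indel lengths are
  geometric (monotone decay matches observed spectra; parameters exposed,
  deletion p = 0.38 so 1-nt deletions are ≈ 25% of indels), with an optional
  deletion-length cap (default off) to emulate the truncation artifact seen
  in lentivirally-integrated target libraries. SNV positions are multinomial
  with an enrichment-fold weight at the hotspot (default 3× at window offset
  26 = protospacer position 17); outcome bases are uniform over the three
  non-reference bases unless a deterministic planted rule (complement of the
  base at a chosen offset) is enabled for classifier tests.
* **GUIDE-seq**: expected reads at mismatch level m are
  on-target reads · decay^m (default decay 0.5) for sites cleaved with
  probability p_m (default (1.0, 0.8, 0.55, 0.3, 0.15, 0.05)); predicted-site
  counts grow with m. Reads are Poisson unless `poisson_reads=False`.

## Numerical and degenerate-input choices

* Kruskal–Wallis on identical values returns H = 0, p = 1 (scipy raises).
* Welch t with two zero-variance equal-mean groups returns t = 0, p = 1.
* Cohen's d with zero pooled variance returns 0.
* Ratios with zero denominators: Cas9:Cas12a target ratio is NaN when Cas12a
  has no targets; deletion:insertion ratio is flagged infinite with zero
  insertion reads; cleaved fraction is NaN at levels with no predicted sites.
* The >1% SNV filter is a strict inequality; exactly 1% is excluded.
* Zero-variance vectors make correlations undefined; they are reported
  missing rather than 0.
* Tokeniser rejects non-ACGT characters, reporting the offending position.

## Problem sizes and verification

The test suite and acceptance script run everything at desk scale on one
CPU: oracle equivalence on 100 random genomes up to 5 kb (exhaustive
brute-force scans as the oracle); the screen pipeline at its default 2,061
guides with the forest trained on the ≈ 306 retained; outcome recovery at
100k reads and hotspot recovery over 50 seeds; 50 label permutations for the
regression null guard (run with 100 trees — the null property does not
depend on forest size — while all signal-bearing fits use the 450-tree
default). The permutation p-value for the held-out pipeline correlation
permutes truth labels against the fixed out-of-fold predictions (999
permutations) rather than refitting per permutation.

## Known limitations

* Linear-scan off-target search; not intended for mammalian-genome scale.
* No bulge/RNA-bulge off-target models, cleavage kinetics, thermodynamic or
  secondary-structure features, and no editing-outcome prediction beyond the
  hotspot SNV classifier.
* Screen inference assumes depletion-only dynamics; copy-number effects and
  off-target toxicity are not modelled.
* Synthetic generators validate machinery, not biology: passing recovery
  tests demonstrates correctness of the estimators under the stated
  generative assumptions, and nothing about performance on real screens.
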
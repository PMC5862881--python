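# Methods

This note documents the models, statistics and numerical choices behind
`progenomix`, and what the synthetic cohort does and does not emulate.

## Proteome processing and differential expression

Raw linear-scale protein intensities are log2-transformed and
quantile-normalized (Bolstad style: every column receives the mean of the
sorted columns; ties within a column get the interpolated reference value
at their average rank). Technical replicate MS runs are assessed by the
one-way random-effects single-measure intraclass correlation ICC(1,1),
with each protein as a subject measured twice — the simplest ICC form
consistent with duplicate runs — and by a permutation test on the
Spearman correlation of the two runs (1,000 permutations, add-one
estimator p = (1 + #{ρ_perm ≥ ρ_obs}) / (1 + n), so p is never 0).
Replicate pairs are then collapsed to their mean (log2 scale).

Differential expression between two disease groups uses the two-sided
Wilcoxon rank-sum test per feature: the exact null when the combined
sample size is ≤ 30 and tie-free, otherwise the normal approximation with
tie and continuity corrections. Benjamini–Hochberg adjustment is applied
per comparison over the tested feature universe. The fold change is the
ratio of group medians computed on the linear scale as
2^(median_A − median_B); "median ratio > 1.5" is read two-sidedly as
max(r, 1/r) > 1.5, since both directions of regulation are of interest.
All-constant features are assigned p = 1 rather than an error. Swapping
the groups inverts the ratio (r → 1/r) and preserves p-values, a property
the test suite asserts.

## Correlation densities

For two layers sharing genes and samples (copy-number dosage vs mRNA,
DMR fragment counts vs protein, ...), the per-sample Spearman ρ across
genes is computed with average-rank tie handling; samples with a constant
layer yield an undefined ρ that is excluded (not imputed) from densities.
Densities are Gaussian-kernel estimates with Scott's rule for d = 1,
h = σ̂ · n^(−1/5) with σ̂ the sample standard deviation (the rule has
minor variants; this one is recorded in output metadata), evaluated on a
512-point grid spanning [min − 3h, max + 3h]. The background null pools
the ρ of every mismatched sample pair (layer A of sample i vs layer B of
sample j ≠ i), up to n(n−1) values. The KDE is asserted equal to a naive
direct-sum oracle to 1e−10 and to integrate to 1 ± 2% by trapezoid.

DMR–gene links use the minimal distance from the 0-based half-open DMR
interval to the TSS (0 if the TSS lies inside); "within 10 kb" is
inclusive (≤ 10,000 bp), the 250 kb zone exclusive, matching the
phrasings they implement. The TSS is the annotated position; strand
affects which gene coordinate is the TSS but not the distance sign.

## Mutation metrics

Mutation impact is a z-score of the mutated sample's expression against
the unmutated samples of the same gene (≥ 3 required), per layer, with an
|z| > 2 outlier rule, a Fisher 2×2 contrast of somatic vs germline
outlier rates, and a null built from pseudo-mutated (randomly selected
unmutated) samples. The concrete statistic is a documented design choice
of this package (the z-threshold is configurable).

CIN tiles the genome into consecutive 500 bp blocks (last block may be
short); each block takes the integer copy number of the segment covering
its midpoint — blocks are much shorter than CNV segments, so
midpoint assignment and overlap-weighted averaging differ negligibly —
and blocks over coverage gaps are excluded from the mean.

## miRNA screens

Consensus targets need ≥ 2 of the 3 database flags. miRNAs with read
counts below 8 in every sample are unexpressed and removed (a single
sample at 8 keeps the miRNA). Counts are normalized as log2(CPM + 1)
before correlation and differential expression. The negative-correlation
threshold ρ ≤ −0.50 is inclusive, with a 1e−12 epsilon so that exact
−0.5 rank configurations are not lost to floating-point rounding. The
enrichment population is, per miRNA, the genes measured at the relevant
layer inside the prediction universe; when the universe-wide correlated
sets are not computed the screen's own hits stand in (the most
conservative choice). The p-value is the upper tail P(X ≥ k) of the
hypergeometric distribution.

## Structural-variant caller

Evidence combines (i) discordant read pairs — both mates mapped with
mapq ≥ 20, on different chromosomes or more than `max_span` apart, with
the junction-side (inner) mate coordinates reported — and (ii) split
reads: mates that failed full-length alignment are split into terminal
25 bp anchors (terminal placement maximizes junction-spanning power),
each realigned independently; uniquely placed anchor pairs passing the
same discordance rule are refined by scanning every split position
between the anchors and minimizing total mismatches against the two
flanks (leftmost split on ties; candidates above a 5-mismatch cap are
dropped). A candidate is discarded when the read segment assigned to one
anchor continues across the breakpoint with more than 70% ungapped
identity to the other flank (identity exactly 0.70 is kept). Reoriented
pairs (lower chromosome/coordinate first) are clustered by single
linkage within a window (default 1,000 bp — the value is not dictated by
the method; it matches the blacklist scale and is configurable); a
cluster becomes a call only with ≥ 1 read pair and ≥ 1 split read, takes
its coordinates from the split read with fewest mismatches, and is
blacklisted when either breakend lies within ±1 kb (inclusive) of any
breakend called in benign control samples.

On the 2 × 50 kb test genome the discordance span and window are scaled
down (`max_span` = 5 kb); production defaults keep 100 kb / 1 kb.

## Synthetic cohort generator

The generator reproduces the *statistical structure* of a three-stage
prostate-cancer cohort: 10 BPH / 17 PC / 11 CRPC samples, 3,000 genes
measured at both mRNA and protein level, duplicate protein MS runs.

* Per gene, log2 mRNA and protein are bivariate Gaussian with
  group-specific correlation; target Spearman ρ_s (defaults 0.45 BPH /
  0.5 PC / 0.3 CRPC, emulating the weakened coupling of progressed
  disease) is converted to the Pearson r = 2·sin(πρ_s/6) that realizes it
  under Gaussianity. Within-group noise is log2-scale Gaussian (σ = 1),
  keeping rank-correlation targets analytically controllable.
* 10% of genes carry ±1.5 log2 group mean shifts (in PC, in CRPC, or
  both), concordant at both levels — the differentially expressed genes.
* 25% of genes lie in copy-number-altered regions; per tumour sample they
  deviate from CN 2 with probability 0.05/0.3/0.5 (BPH/PC/CRPC), drawn
  from {0,1,3,4}. Expression responds to the true integer dosage with
  slopes 0.5 (mRNA) and 0.1 (protein) log2 per copy — the five-fold
  attenuation plants the "dosage does not propagate to the proteome"
  contrast; the reported dosage table adds measurement noise (σ = 0.05).
  The large altered fraction reflects the substantial
  fraction-of-genome-altered of progressed prostate cancers and is what
  gives per-sample dosage–expression correlations a visible mode shift.
* DMRs (default 60) get latent methylation deviations with tumour-specific
  directional shifts; linked genes respond with slopes −0.5 (mRNA) and
  −0.1 (protein); fragment counts are non-negative linear transforms of
  the latent plus noise. Each DMR sits a few hundred bp upstream of its
  gene's TSS on a toy annotation chromosome with 20 kb gene spacing, so
  only the planted link is within 10 kb.
* miRNA counts are negative-binomial (size 10) around group-dependent
  log2 means; 10% of miRNAs are kept below the count-8 floor to exercise
  the expression filter, and half of the expressed ones carry ±2 log2
  CRPC shifts. Each miRNA represses its targets proportionally to its
  standardized latent abundance — degradation mode hits mRNA and protein,
  translation-only mode hits protein alone. The default effect (1 log2
  unit per latent SD) gives moderate anti-correlations; recovery
  guarantees (sensitivity ≥ 0.8 for mode classification) hold at strong
  effects (2 log2 units), which is how the recovery tests run.
* Somatic mutations (tumour samples only) shift the mutated sample's
  mRNA by ±3 log2 units with probability 0.5; germline variants have no
  planted effect — reproducing the somatic-impact-at-mRNA-only contrast.
* Technical replicates add σ = 0.1 log2 noise to each protein column.

Rearranged genomes are built segment-wise from a random two-chromosome
reference (50 kb each, so inter-chromosomal discordance is testable at
desk scale): deletions, inversions and reciprocal translocations are
specified in reference coordinates and validated against regions not
already rearranged. Single reference bases flanking each junction are
adjusted so that junctions carry no microhomology: with microhomology the
"exact breakpoint" is inherently ambiguous (the leftmost-split tie rule
resolves it differently for forward- and reverse-sequenced reads), so
homology-free junctions are what makes exact-breakend ground truth well
defined. Reads are 90 bp pairs, insert ~ Normal(300, 30), coverage 30×,
uniform per-base error, aligned back to the reference by the built-in
exact-seed (k = 20, multiple offsets) + ungapped-extension aligner
(mapq 60 unique / 0 ambiguous); externally aligned SAM is accepted
everywhere.

What the generator does **not** emulate: peptide-level quantification
noise structure (missing peptides, shared peptides), compositional
library-size artifacts of real small-RNA sequencing beyond simple CPM,
linkage between copy-number segments (gene-level aberrations are drawn
independently), quality-score-dependent sequencing error, and any
pathway-level correlation structure. Passing recovery tests therefore
demonstrates the pipeline's statistical machinery, not performance on
real instrument data.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds (`numpy.random.default_rng`);
identical config + seed gives byte-identical cohorts, and the pipeline
derives per-stage substreams from one root seed. The test suite runs the
cohort at 400–600 genes and the SV caller at 30× coverage on the 100 kb
genome; the acceptance script uses the full 3,000-gene / 38-sample design
and three seeds of the error-bearing read panel — sizes chosen so a
complete run stays within a couple of minutes on a single CPU while
keeping Monte-Carlo tolerances (±0.05 on coupling means, ≥ 9/10 seeds on
the density-mode contrast) comfortably resolvable.

## Known limitations

* The mutation-impact statistic is a stand-in with configurable
  threshold; it is not calibrated against any external cohort.
* The enrichment population choice matters when target predictions cover
  only part of the measured genome; both the restricted and the
  hits-as-draws variants are exposed.
* The toy aligner is exact-seed based: reads whose first and last 20-mers
  both carry errors go unmapped; at the simulated error rates this loses
  < 1% of reads and is ignored.
* Densities pool all samples by default; group-restricted densities are
  available by subsetting the input matrices.
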
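# Methods

## Problem and model

`sexscan` targets cohorts of diploid, phenotypically sexed individuals
genotyped by whole-genome re-sequencing at moderate depth (~10×).  Under
genetic sex determination with a recombination-suppressed region, the
heterogametic sex (females under ZW, males under XY) is heterozygous at
fully sex-linked SNPs while the homogametic sex is homozygous; partially
linked SNPs show the same pattern with probability < 1 per individual.
Everything downstream follows from that diploid genotype signature — the
package never models the W/Y sequence itself, only its observable footprint
in genotypes and in read coverage of assembled contigs.

Key realistic degradations assumed throughout: at ~10× depth a true
heterozygote is sometimes sampled on one allele only and miscalled
homozygous, and genotypes are missing at random at a low rate.  The
heterozygote screen and its defaults exist specifically to be robust to
this.

## Pipeline stages and parameters

| stage | statistic | parameters (default) |
|---|---|---|
| QC | vcftools-style cascade | MAF ≥ 0.05; mean DP ∈ [6, 300]; GQ ≥ 20 (else genotype set missing); call rate ≥ 0.9; biallelic only |
| GWAS | 1-df allelic Pearson χ², no continuity correction | significant P < 1e−8; suggestive P < 1e−4 |
| FST | Weir–Cockerham (1984) per-site, two populations = sexes | signature when F̂ > 0.25 |
| screen | het count ≥ c in focal sex, ≤ e in other | c = 25, e = 0; missing = neither het nor hom |
| PCA | SVD/Gram eigendecomposition of (d−2p)/√(2p(1−p)) | separation = max abs point-biserial corr over PC1–2; "separates" at ≥ 0.9 |
| region | composite rank + shortest window run | 1-Mb tiling windows; ≥ 0.9 of significant SNPs contained |
| seq screen | breadth-of-coverage presence/absence | present ≥ 0.9, absent ≤ 0.05; marker filters: length > 1000 bp, N ≤ 0.1, dinucleotide entropy ≥ 1.5 bits |

Notes on fixed interpretive choices:

- **QC order** is GQ-mask → mean-depth → call-rate → MAF, each variant
  counted at the first filter that removes it; mean depth is averaged over
  non-missing genotypes; "max-missing 0.9" is read as minimum call rate
  0.9 (the vcftools convention).  The cascade is idempotent.
- **Allelic test**: each non-missing diploid genotype contributes two
  alleles.  Monomorphic sites (or a sex with no data) are flagged `na`,
  never silently dropped, and excluded from tier counts.  No
  multiple-testing correction: fixed genome-wide thresholds are the
  convention this analysis style uses, and both thresholds are config.
- **FST**: the 1984 estimator with heterozygosity-based within-individual
  component c; negative estimates are retained (not clamped), NA exactly
  when a+b+c = 0.  Useful anchors: fixed difference → 1.0; the fully
  sex-linked ZW pattern (all females het, all males hom) → 0.5.
- **Screen**: missing genotypes can neither satisfy c nor violate e — the
  screen's whole point is tolerance of het under-calling, and a missing
  call is evidence of neither state.  By default the screen sees only
  variants below the suggestive threshold (GWAS-first order); a
  genome-wide mode exists and is recorded in the output.
- **PCA**: allele frequencies are estimated per variant on non-missing
  calls, missing entries mean-filled (0 after standardization),
  zero-variance columns dropped.  Components come from the
  eigendecomposition of the sample-sample Gram matrix — identical to the
  SVD of the standardized matrix and to a GRM eigendecomposition up to
  scale — with a deterministic sign convention (largest-magnitude loading
  positive).  Because standardization is per-variant it is
  subset-independent, so per-chromosome and leave-one-chromosome-out scans
  reuse one standardized matrix.
- **Separation** is quantified (point-biserial correlation) rather than
  judged visually; 0.9 is this package's operationalization of "clearly
  distinguishes the sexes" and is configurable.
- **Ranking** uses min–max normalization because the five tracks have
  incommensurate units; a constant track contributes equally to every
  chromosome.  Ties break by PCA score, then natural chromosome order
  (`chr2` < `chr10`).  Chromosomes within 0.7 of the top composite are
  reported as secondary candidates — a second chromosome with similar
  enrichment but poor PCA separation is a real pattern and should never be
  silently dropped.
- **Localization** formalizes "the significant SNPs are mainly in this
  interval": among contiguous runs of 1-Mb tiling windows containing at
  least 90 % of the chromosome's significant SNPs, take the shortest, then
  the best-contained, then the leftmost.  The returned fraction is exact.
  Shrinking `min_contained` never widens the interval.
- **No-call**: zero genome-wide-significant SNPs, or no chromosome at the
  PCA cutoff, yields an explicit no-call with reasons — the correct output
  for a species without (detectable) genetic sex determination.
- **System inference**: ZW iff ≥ 80 % of screened loci are female-het (XY
  mirrored); with no informative loci the sex of specific sequences
  decides; otherwise inconclusive.  Any sensible majority cutoff gives the
  same answer on real signals, which are typically ~99 % one-sided.
- **Imputation**: statistical phasing is out of scope; an optional,
  off-by-default modal imputation (ties to the lower dosage code) is
  provided for completeness.  The heterozygote screen always runs on
  unimputed genotypes — imputation can fabricate heterozygotes.

Coordinates are 1-based only inside VCF records; all internal intervals and
windows are 0-based half-open.

## The synthetic cohort generator

`SimConfig` defaults are the emulated study conditions: 40 females + 40
males; 22 chromosomes; background SNPs in Hardy–Weinberg proportions with
allele frequency ~ U(0.05, 0.5), positions uniform; one sex-determination
interval containing 100 fully and 100 partially sex-linked SNPs (per-SNP
female-het probability ~ U(0.6, 0.95)); het→hom miscall 0.02 and
missingness 0.02 per genotype; DP ~ Poisson(10), GQ 99.  Miscalled
heterozygotes always become hom-ref so the homogametic pattern is never
spuriously broken.  The genome is a desk-scale stand-in — 22 × 5 Mb with a
1-Mb SD interval at chr10:2–3 Mb — chosen so that one cohort simulates and
analyzes in ~2 s while keeping ≥ 1,000 SNPs per chromosome; all window
parameters scale via config.  The noise rates are plausible placeholders
for ~10× short-read data, not estimates from any particular dataset.

For the sequence screen the generator emits contigs (500–3,000 bp) with
per-sample breadths: shared contigs high everywhere; sex-specific contigs
high in the heterogametic sex and 0 (optionally ≤ 0.02 contamination) in
the other; decoys high in all but one heterogametic-sex sample; optional
false positives that pass the 5-vs-5 round but are covered in the pooled
opposite-sex track; optional marker-filter violators (N-rich,
low-complexity, sub-kilobase).  "High" breadth is Beta(20,1)-shaped mapped
into [0.9, 1] so that a planted "covered" sample can never fall below the
presence threshold — coverage of planted contigs is a designed fact, not a
random event.

What the generator does **not** emulate — and therefore what green tests do
not establish about real data: linkage disequilibrium among background
SNPs, allele-frequency spectra from real demography, depth-dependent (as
opposed to uniform) miscall rates, batch/reference-bias artifacts,
repetitive-sequence mismapping, and real assembly fragmentation.  Recovery
rates on synthetic cohorts are upper bounds on real-data performance.

Determinism: one integer seed drives every draw; identical configs produce
byte-identical VCF/FASTA/TSV outputs.  The coverage generator derives an
independent stream from the same seed so genotype and coverage outputs can
be generated in any order.

## Numerical details

- Chi-square tails via `scipy.stats.chi2.sf`; a zero statistic reports
  p = 1 exactly.  The test suite cross-checks against an independent
  Σ(O−E)²/E evaluation with an erfc-based tail.
- FST is computed vectorized in float64; the suite cross-checks against an
  exact-rational (Fraction) evaluation of the variance components to
  1e−12.
- Gram-matrix eigenvalues are clipped at 0 before taking square roots;
  explained-variance fractions use the full spectrum of the subset.
- The screen and GWAS operate on int8 dosage matrices with −1 as the
  missing sentinel; missingness is never conflated with hom-ref anywhere.

## Known limitations

- Two-sex, two-population contrasts only; no covariates, kinship
  correction or mixed models — cryptic relatedness in a real cohort can
  inflate the association signal.
- The allelic χ² assumes Hardy–Weinberg within sexes (as the standard
  basic association test does); a fully sex-linked locus violates it in
  the heterogametic sex, which is precisely the signal being detected.
- The localization rule is a reproducible formalization of a descriptive
  practice; window width (1 Mb) and containment (0.9) are conventions, and
  candidate intervals should be inspected against the per-window density
  table the pipeline also emits.
- The sequence screen consumes breadth tables or depth tracks, not BAMs;
  producing per-contig depth from alignments is upstream of this package.
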
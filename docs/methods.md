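# Methods

This note records the statistical definitions, numerical conventions and
design choices behind `coevoscan`, and what the synthetic-data experiments
do and do not establish about real data.

## Data model and conventions

Genotypes are alternate-allele dosages in {0, 1, 2} with a dedicated
missing sentinel (−1); all two-locus statistics are complete-case per pair
of variants, never listwise across a whole matrix. External files are
1-based (VCF convention); internal interval arithmetic is half-open
0-based, converted at the boundary. Only biallelic SNPs are retained when
reading VCFs; multiallelic records are dropped, not split. The MAF filter
(default ≥ 5%) and missingness filter (default ≤ 10%) are computed on
non-missing calls, after any sample subsetting — so per-population filters
reflect the analysis panel, not the full file. Genetic maps are
two-column (bp, cM) tables per chromosome, interpolated linearly with
clamping beyond the terminal knots.

## Selection statistics

**F_ST.** The per-site Weir & Cockerham (1984) estimator for two
populations, using the genotype-aware variance components a, b, c (the
observed heterozygote frequency enters b and c). Sites monomorphic for the
same allele in both populations are undefined, not zero; negative
estimates are reported and only clamped downstream. Multi-locus summaries
use the ratio-of-averages Σa / Σ(a+b+c), which is much less biased than
averaging per-site ratios.

**PBS.** Branches T = −log(1 − F_ST) with negatives clamped to 0 and F_ST
capped at 1 − 1e-12 (T ≤ −log 1e-12) to avoid infinities at fixed
differences. PBS_A = (T_AB + T_AC − T_BC)/2 and cyclic analogues; negative
raw branches are reported. The normalized form floors branches at 0 and
divides by 1 + (sum of the three branches), shrinking positions with large
branches in every population. Both raw and normalized branches are emitted
and labelled, since published per-SNP values are not always explicit about
which is printed. Empirical significance uses the genome-wide 95th
percentile under the linear-interpolation quantile convention (recorded so
thresholds are reproducible); a site's empirical p is the fraction of
genome-wide values at least as large.

**EHH / iHH / iHS.** EHH(x) is the probability that two random haplotypes
carrying the core allele are identical at every variant between the core
and x inclusive, computed from haplotype-class counts. iHH integrates EHH
over cM by the trapezoid rule separately in each direction, truncating at
the first crossing below the EHH cutoff (default 0.05, the common tool
default) with the crossing point linearly interpolated; arms that reach
the data end or a physical gap > 200 kb before crossing are truncated
there and boundary-flagged (the gap rule prevents inflated iHH across
assembly gaps). The production scan exploits the fact that EHH only
changes at columns that split a haplotype class: it scans ahead in
vectorized blocks for the next splitting column, adds constant-EHH
rectangles in between, and prunes haplotypes that have fallen into
singleton classes. This is exactly equal to the reference curve-then-
integrate implementation (asserted in tests) and is what makes multi-
thousand-variant scans affordable. Unstandardized iHS = ln(iHH_A/iHH_D) is
standardized within derived-allele-frequency bins (default 50 equal-width
bins over [maf, 1−maf]; bins with < 2 variants are left unstandardized and
flagged). A candidate region can be standardized against a separate
reference scan's bins — the analogue of scoring a locus against a
genome-wide empirical distribution — which is how the sweep experiments
score swept sites against a neutral panel.

## Long-range LD

Genotype r² is the squared Pearson correlation of dosage vectors on
complete cases (symmetric, allele-flip invariant; undefined for constant
vectors rather than 0). The genotypic χ²₄ statistic compares the 3×3
genotype-combination table with the product of its marginals; when a
genotype class is absent at either SNP the table collapses to the observed
classes and the degrees of freedom adjust to (r−1)(c−1), with permutation
inference preferred in that case. Three nulls are implemented:

1. *Gene-pair*: the r² distribution over all cross-region SNP pairs, with
   the 99th percentile as threshold and p = (#pairs ≥ observed)/total.
2. *Permutation*: one SNP's genotypes permuted across individuals within
   the complete-case set; p = (k+1)/(B+1), never zero, super-uniform under
   the null (B defaults to 1000-scale resolution).
3. *Matched-pair genome-wide*: all same-chromosome SNP pairs whose MAFs,
   bp separation and cM separation fall in windows around the focal pair
   are enumerated first, then subsampled without replacement at a fixed
   seed (enumeration-first reproduces a near-exhaustive published pair
   count when feasible); empirical p is the plain fraction k/N, reported
   as < 1/N when k = 0. Window compliance is re-verified in tests.

Sex-stratified scans evaluate the identical pair set per stratum. The
sex-difference permutation test shuffles sex labels preserving stratum
sizes; the default statistic is D = r²_male − r²_female, two-sided on
|D|; a log-ratio variant is available since the published procedure for
this step admits more than one reading.

## Local ancestry

RFMix v2 `.msp.tsv` input is parsed with strict validation (declared code
set, paired `.0/.1` haplotype columns, non-overlapping ordered intervals).
Genome-wide ancestry proportions weight each interval by its cM length,
each haplotype contributing half a sample's weight, and average
chromosomes by cM size. Per-interval cohort attribution is haplotype-level
(fraction of haplotypes assigned to the label); a region is enriched iff
its cM-weighted attribution exceeds the genome-wide 95th percentile of
interval attributions, sharing the same percentile convention as the
selection thresholds. Group comparisons use the two-sided Mann–Whitney U
test — exact for untied groups of ≤ 25, normal approximation with tie
correction otherwise.

## Interaction models

SNPs enter either additively (count of non-reference alleles) or
genotypically (het / hom-alt indicators, hom-ref baseline). The full model
is a complete factorial of the two SNP encodings (plus sex for the
three-way model) with covariates (PCs, age, PEER-style factors) consumed
as plain columns; the reduced model drops the highest-order interaction
block, and the LRT statistic 2·Δll is referred to χ² with d.f. equal to
the number of dropped parameters (2 for genotypic×additive, 4 for
genotypic×genotypic). Gaussian fits use least squares, binomial fits
logistic maximum likelihood; under (quasi-)separation the fit is flagged
and the LRT is the primary inference. Missing data are removed listwise
with the retained n reported. Continuous outcomes can optionally be
z-scored first (biomarker-model convention). Outlier handling fits the
covariate-only linear model, computes externally studentized residuals and
removes |t| > 4 — a deliberately conservative default (no published
threshold exists for this step) that removes essentially nothing from
clean Gaussian data; filtering is per-trait. Average marginal effects of
the focal SNP (which must be additively coded) are the stratum means of
p(1−p)·∂η/∂g (binomial) or ∂η/∂g (gaussian), computed with the exact
design derivative since every design column is linear in the focal dosage;
standard errors are delta-method with the analytic gradient, validated
against finite differences and bootstrap in tests.

## Synthetic cohorts

The generator emulates the study design, not any particular population's
haplotype structure. An ancestral pool of allele frequencies
(Uniform(0.05, 0.95)) drifts into two source populations and an outgroup
by Balding–Nichols sampling; the drift parameter F of each population is
calibrated such that the realized genome-wide ratio-of-averages WC F_ST
between two populations drifted with the same F matches F (verified to
±0.02 in tests). Admixed haplotypes are tract mosaics: crossover
breakpoints Poisson in genetic distance over the configured generations
since admixture (default 15), tract ancestries i.i.d. from the admixture
proportions (default 0.75/0.25), alleles drawn from the tract ancestry's
source frequencies. Tracts are recorded exactly and exported as an
`.msp.tsv` track on the union breakpoint grid (breakpoints that round to
the same bp are merged).

Default geometry mirrors the two-gene use case: a ~154 kb region and a
~22 kb region on one chromosome separated by ~53 Mb, a uniform map at
1.15 cM/Mb (putting the gap at ~61 cM), one focal SNP per region at alt
frequency 0.25 shared across sources (so the focal pair is not
ancestry-confounded unless drift at focal sites is switched on), and
optional background chromosomes for genome-wide nulls. Two named scales
ship: a discovery scale (n = 85; 44 F / 41 M) and a replication scale
(n = 3,243; 1,302 F / 1,941 M). Viability selection retains individuals
with probability proportional to the sex-specific relative viability of
their focal genotype combination; presets boost the (hom-ref, hom-ref)
combination ×1.5 (weak) or ×3 (strong) in males only, or in both sexes
(`*_both`). Expression and binary traits add configured main, interaction
and per-sex interaction effects (binary traits centre the genetic columns
so realized prevalence tracks the configured baseline). Within-source
sites are in linkage equilibrium — adequate for genotype-level statistics
but not for haplotype statistics, which instead use the msprime coalescent
backend (neutral panels, and partial hard sweeps with the selected
mutation planted on the tree node closest to the target frequency).
Everything is deterministic given the seed, including emitted files.

**What passing tests show, and what they do not.** Calibration and power
results on these cohorts establish that the statistics are implemented
correctly and behave as designed under the generative model: type-I error
at nominal level under neutrality, monotone response to selection
strength, parameter recovery within sampling error. They do not establish
robustness to features the generator omits: within-region LD between
background SNPs, non-uniform recombination, genotyping error, population
structure beyond two-way admixture, or ascertainment of variants.

## Problem sizes and experiment design

Desk-scale experiments use: 1000-replicate calibrations for the
permutation and regression tests; a ~5,000-variant coalescent panel for
iHS bin moments; 200 replicates at n = 287 for interaction-effect
recovery; and 8–12 replicates at n = 500–600 for the power/sign
properties, where the strong preset separates the sexes essentially
deterministically. The matched-pair calibration scores all exchangeable
qualifying pairs from one neutral genome against their own enumerated
null — rank uniformity among exchangeable pairs is the same property as
uniformity of the focal pair's p over replicate genomes, at a fraction of
the cost. Stochastic tests fix their seeds; the coverage property for
±2·SE intervals (nominal ~95.4%) would otherwise flake by construction.

## Known limitations

- The admixture model is a pool-of-ancestors approximation (no explicit
  pedigree), so ancestry-LD between the two regions decays as
  exp(−g·d_Morgans) in expectation and is negligible at the default 15
  generations; lower g values create the confound deliberately.
- The EHH scan's gap rule and boundary flags follow common tool defaults;
  scans on very short panels leave many arms boundary-flagged and their
  iHS values conservative (tail fractions run slightly below the Gaussian
  0.046 at desk scale).
- Binomial separation handling falls back to a weakly regularized fit for
  coefficient reporting; inference in that regime should rely on the LRT
  or permutation machinery.
- The local-ancestry module consumes inference output; it does not model
  inference error in the track itself.
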
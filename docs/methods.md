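# Methods

## The system being modelled

The package models an experimental harvest-selection study: a captive
population bred in a North Carolina II design (4 blocks, 3 sires x 3 dams
reciprocally crossed, 36 full-sib families from 24 founders), with each
family split at hatching between a baseline-density and a reduced-density
rearing environment (360 fish per density).  After phenotyping, the fish
face six weekly trawl trials; each trial splits the population into
~16-fish events swimming against a model trawl and removes the 20% most
vulnerable by capture time.  The 20% most vulnerable overall (shortest
first-trial capture times, "captured") and the 20% never captured across
all trials ("escaped") define the vulnerability groups, 24 of each per
density are whole-genome sequenced at ~2x, and the analysis asks which
SNPs differ in frequency between captured and escaped fish — separately
per density, and whether the answers agree between densities.

## Cohort generator

**Founders and breeding.**  Ancestral minor-allele frequencies are
uniform on [0.05, 0.5] across L biallelic SNPs (default L = 20,000 spread
over 25 chromosomes of 1 Mb — zebrafish has 25 chromosomes; the count is
sized so a full run takes minutes, not the genome-scale 5.67 M).
Founder genotypes are Hardy-Weinberg draws; offspring receive one allele
from each parent independently per site (no linkage).  Each family
contributes 10 offspring per density.

**Vulnerability liability.**  Capture vulnerability is a liability
`l_i = sum_l beta_d(l) g_il + N(0, sigma_E)` with density-specific
selected loci/effects (the G-by-E structure).  Phenotypes load on the
liability *standardised within density*; loadings and noise are therefore
in liability-SD units and independent of the effect-size scale (a
zero-variance liability standardises to 0).  Default loadings give the
trait contrasts of the modelled experiment: escaped (low-liability) fish
grow faster, have a higher aerobic scope, bite a mirror less and stay
further from conspecifics; SMR is unloaded, and MMR is defined as
SMR + aerobic scope so AS = MMR - SMR holds identically.  Bases/noises
are zebrafish-scaled (mass ~0.25-0.35 g, SMR ~0.08 mg O2/h, AS ~0.25 mg
O2/h, ~20 bites/10 min, ~10 cm distance).

**Planted architecture and detectability.**  For truncation selection
shifting mean liability by Delta z between the tail groups, the expected
per-locus frequency shift is

    Delta p  ~  Delta z * beta * p q / sigma_L  =  Delta z * sqrt(p q h2 / (2 n))

for n equal-effect loci — independent of beta.  With Delta z ~ 2.7 (20%
tails after six trials) and the ~4.6 global zdAF cutoff over the ~0.1
sampling SD of dAF at 2x/24 fish, detectability requires Delta p >~ 0.55,
i.e. n <= 2-3 loci per density at common variants.  The default effect
model therefore plants **2 selected loci per density** (disjoint between
densities in the G-by-E configuration), at sites with ancestral MAF >=
0.40, effects +/-2.5 with h2 = 0.85.  This is deliberately an oligogenic
scaled-down analogue: a genuinely polygenic architecture is available
(`EffectModel.gxe(n_loci=...)`) but its per-locus shifts saturate near
0.3 and produce no desk-scale outliers, exactly as the scaling law
predicts.

**Trawl mechanics.**  Within an event each fish gets a vulnerability
score v = liability_z + N(0, 0.5); fish with v above an absolute
swim-performance threshold (0.25, mimicking the fixed event water
velocity) fall back into the net and get a capture time
t = 600 s * expit(-v), a strictly increasing function of -v; the rest
escape the event.  Each trial removes the quota (default: 20% of the
*current* population; fraction-of-original and fixed-count policies are
selectable) with the shortest times.  Trial-1 removals are "captured";
after six trials the never-captured fish with the lowest liability, up to
20% of the original population, are "escaped"; other survivors are
"intermediate" and later removals stay unlabeled.  The published event
schedule is arithmetically over-constrained (six 20% trials from 360 fish
cannot give exactly 75 events); event counts are reported, never
asserted — the default schedule gives 22+18+14+11+9+7 = 81 events with 22
in trial 1.

**Sequencing.**  Per-individual mean depth ~ Normal(2.0, 0.5) truncated
at 0; per-site depth Poisson; each read reports the true allele with
probability 1 - err (default err = 0.01, i.e. Q20, matching the quality
floor of the modelled filters).  The 24 fish per group are drawn balanced
across the families present in all four groups (round-robin; shortfalls
are filled arbitrarily with a warning).

## Genotype likelihoods and frequencies

L(g) for dosage g in {0,1,2} is binomial with per-read alternate
probability (g/2)(1-err) + (1-g/2)err; triples are stored log-normalised
(max 0), zero-read entries flagged missing.  Base/mapping quality act
upstream of the count matrix (exact for simulated reads).  Allele
frequencies are EM maximum-likelihood estimates under HWE (initial
p = 0.1, |delta p| < 1e-6 or 100 iterations, vectorised across sites with
an active-set loop); polarisation to the minor allele is fixed *once*
from all 96 fish pooled so group frequencies share an allele and dAF
cannot flip sign site-by-site.  The SNP test is the likelihood-ratio
statistic against p = 0 on a chi-square(1); ignoring the boundary mixture
is conservative by half at the boundary.  Site filters: summed depth in
[48, 600], >= 48 covered individuals, SNP p < 1e-6, MAF >= 0.05.
Expected heterozygosity is mean 2p(1-p) over passing sites by default; an
SFS mode computes the maximum-likelihood sample spectrum by EM over
sample-allele-frequency likelihoods (exact polynomial convolution of the
per-individual triples, O(N^2 L)) and averages 2p(1-p) under it.

## The scan

zdAF standardises dAF with sample moments (ddof = 1) over all passing
sites of a comparison.  The null: 25 groups of 24 drawn without
replacement within themselves (groups may overlap; the pool is all 96
sequenced fish across densities, since one global cutoff pair serves both
densities), all 625 ordered pairings including self-pairings — the only
scheme consistent with 25 groups yielding 625 values; self-pairings have
dAF identically 0 and their 0/0 standardisation is defined as 0.
Per-site thresholds are type-7 quantiles at the per-tail level
tail_p / L (tail_p = 0.0005).  With 625 null values this level is far
below the sample resolution, so the quantiles clamp to the per-site
extremes; the degeneracy is inherent to the published design and is
flagged in every threshold report.  Global cutoffs are the 0.5% /
99.5% type-7 quantiles of the compiled per-site lower/upper thresholds;
outlier calls use strict inequality (equality is not "exceeding").
Alternative pairing schemes (no self-pairings, unordered) are selectable.

## Overlap, PCA, phenotype models

Overlap between the two densities' outlier sets is tested
hypergeometrically in both one-sided orientations plus the
minimum-likelihood two-sided p; the SNP universe is all filtered SNPs and
the gene universe all genes containing a filtered SNP (both configurable
— the appropriate universe is a genuine judgement call and every
orientation is reported).  SNP-to-gene assignment converts GFF3 (1-based
inclusive) and BED (0-based half-open) to one internal convention and
assigns a site to every containing interval.

PCA uses posterior expected dosages (HWE prior at the site MAF times the
likelihood triple; missing data imputed at the prior mean 2p), entries
centred by 2p and scaled by sqrt(2p(1-p)), covariance averaged over
sites, eigendecomposition with signs fixed so each component's
largest-magnitude loading is positive.  Components are 1-based; the
analysis PC defaults to index 2 (the convention when the first component
absorbs within-group variability), with a max-group-separation selector
as the alternative.  An optional iterative refinement re-estimates
individual allele frequencies from the top components; the default is a
single pass, which suffices when the analysed sites separate groups
strongly.  When fewer than 20 SNPs clear the global cutoff (possible at
desk scale) the pipeline's PCA stage falls back to the strongest-|zdAF|
sites per density and flags this in the manifest.

Phenotype stages: SGR defaults to the conventional
100 (ln m_f - ln m_i)/T in % body mass per day; the printed-form variant
ln(m_f - m_i)/T is retained verbatim but is dimensionally odd (it
requires m_f > m_i and goes negative for sub-unit gains), so it is not
the default.  SMR is the type-7 0.2 quantile of the overnight oxygen
series, MMR the post-exercise maximum within a 30-min window, AS their
difference.  Non-normal responses are rank-transformed (average ranks for
ties).  Factorial models are OLS with sum-to-zero coding and Type-III
marginal F tests (the convention of the commercial package the analysis
emulates); rank-deficient designs are rejected naming an aliased term.
The multivariate stage reports Pillai's trace with its F approximation
(a single response reduces exactly to the univariate F).  PC-trait
correlations are Pearson r per density and combined, with the
interaction p from the score x density term of an OLS model.

Type-7 (linear-interpolation) quantiles are used everywhere — scan
thresholds, SMR, global cutoffs — one convention globally.

## Reproducibility

Every operation takes a seed or Generator; the pipeline derives per-stage
child seeds (< 2^31) from one master seed via `numpy.random.SeedSequence`
and records them in the run manifest together with the full config (YAML,
lossless round trip).  Stages communicate through files, so re-running a
stage with the same config and seed reproduces its artifacts
byte-for-byte; results are independent of thread count because nothing is
threaded.

## What the generator does and does not emulate

It reproduces the *structure* of the experiment — family design, density
split, density-specific genetic effects, iterated truncation selection,
balanced group sequencing, depth/error characteristics of low-coverage
data — and is the ground for all tests.  It does not emulate: linkage and
recombination maps (sites segregate independently, so linked hitchhiking
and windowed signals are absent), mapping/duplicate artefacts and
reference bias (counts are error-symmetric), indels or multi-allelic
sites, sex-specific architecture, tank effects, or real zebrafish gene
content (the annotation is synthetic intervals).  Passing tests therefore
demonstrate that the inference machinery is correct and calibrated on
data with known truth, not that real sequencing data meet these
idealisations.

## Known limitations

* The 625-pairing null cannot resolve tail probabilities below ~1/625;
  the per-SNP "Bonferroni" quantiles are really the null extremes, and
  the global cutoffs inherit that granularity (as in the published
  design).
* Self-pairings shrink the extreme quantiles slightly toward zero; the
  no-self scheme is available for comparison.
* Group frequency estimates ignore family structure (fish are treated as
  unrelated within groups), which inflates the dAF sampling variance
  relative to an unrelated sample of the same size; the permutation null
  absorbs this empirically.
* At desk scale the default run yields a handful of outliers per density,
  so gene-level overlap statistics operate on very small sets; the
  genome-scale counts (hundreds of outliers) are not reproducible without
  the full 5.67M-SNP dataset.
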
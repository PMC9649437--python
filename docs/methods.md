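# Methods

This note documents the statistical model, the conventions chosen where
several were defensible, what the synthetic-data generator does and does
not emulate, and the numerical choices that affect results.

## Transmission model

For family *i* with stratified child score `c_i` and midparent score
`m_i = (mother_i + father_i) / 2`, the deviation is
`d_i = (c_i − m_i) / s.d.(m)`, where `s.d.(m)` is the sample standard
deviation (ddof = 1) of midparent scores over the analyzed families. The
cohort estimate is `mean(d)`, tested with a one-sample two-sided Student's
t-test; 95% CIs come from the t distribution. The normalizer is recomputed
per partition in the stratified scan, after any family filtering
(e.g. CNV-carrier exclusion) has been applied.

Two invariances follow from the construction and are enforced by tests:
adding a constant to every sample's score leaves deviations unchanged, and
multiplying all SNP weights by a positive constant cancels between
numerator and normalizer. This is why scoring uses the simple *sum*
dialect `score = Σ dosage × weight` rather than a per-allele average: the
distinction cannot affect any transmission statistic.

Missing dosages are imputed at scoring time to twice the effect-allele
frequency estimated from the non-missing samples (the column mean); a SNP
missing in every sample is dropped with a warning. Upstream genotype QC is
the caller's responsibility.

## Partitions and the residual model

SNP-count partitions lay consecutive blocks of exactly `block_size` SNPs
from the chromosome start or end; the leftover run at the non-anchor end
belongs to no partition. A partition's span runs from its first to its
last member SNP (the simplest reproducible choice; it only affects the
length covariate). Fixed-length windows (default 33 Mb) tile each
chromosome from its start, discarding the trailing remainder.

Coordinates: intervals are 0-based half-open; SNP positions are 1-based
(VCF convention). A SNP at 1-based position `p` lies in `[start, end)` iff
`start ≤ p−1 < end`. Genes and histone peaks are assigned to the unique
partition containing their body midpoint — midpoint assignment avoids
double-counting boundary-spanning features under the half-open convention.

Because expected transmission grows with partition SNP count and extent,
per-partition estimates are regressed (OLS with intercept) on SNP count
and *effective length*, and residuals are standardized by their sample
s.d. (ddof = 1) to give residual z-scores. Effective length sums
consecutive inter-SNP gaps with each gap capped at 1 Mb, which
acknowledges that linkage disequilibrium does not extend across large SNP
deserts; the cap applies to internal gaps only, not flanks, so a
single-SNP partition has effective length 0. For equal-length windows the
model uses SNP count alone (the length column would be constant; the
implementation also detects and drops collinear covariates with a
warning). Raw length is retained for reporting. When the design fits the
estimates exactly, residual z-scores are defined as 0.

The quadrant-enrichment test asks whether annotated partitions (e.g. those
holding GWAS loci) concentrate in the (z₁ > 0, z₂ > 0) quadrant of two
cohorts' residual z-scores. The baseline is the overall fraction of
partitions in that quadrant and the p-value is a one-sided (greater) exact
binomial tail at that fraction — chosen because the flagged set is small
and the exact tail needs no large-sample approximation.

Block-removal decay ranks blocks by their point estimate of
over-transmission (matching what is plotted, rather than the t-statistic),
removes the largest remaining one per step with ties broken by genomic
order, and re-tests the union each time.

## Expression association

The combined per-gene model is
`expression ~ regional PGS + diagnosis + African ancestry + single-cell`,
fit by OLS after per-gene expression and per-partition PGS are
standardized to mean 0 / s.d. 1 *within each cohort* (ddof = 1); cohorts
are then concatenated. No additional cohort fixed effects are added beyond
the two binary indicators — with three cohorts the indicators identify the
cohorts, and a third dummy would be collinear. Rank-deficient designs
raise an error naming the collinear columns.

The mean-effect test uses permutation: the observed statistic is the mean
per-gene PGS t over the regional gene set; the null shuffles the
PGS-to-donor assignment independently within each cohort, keeping
expression and covariates fixed, so the null preserves both the expression
correlation structure and the within-cohort PGS distribution. The
one-sided empirical p uses the add-one convention
`p = (1 + #{null ≤ observed}) / (1 + n_perm)`, the standard choice that
never returns 0 and is exact under exchangeability. The per-gene fits
inside the permutation loop use a vectorized multi-response least-squares
path (one factorization per permutation, all genes at once); tests verify
it against statsmodels per-gene fits to 1e-8.

The CNV contrast takes an upstream per-gene differential-expression table
(log2 fold-change and t per gene), drops genes whose body overlaps the
deletion window widened by ±100 kb on both sides (their cis-regulatory
context may be perturbed by the deletion itself; overlap is any-overlap of
the gene body with the widened half-open window), and reports the region
genes' mean t and mean log2 fold-change with one-sample two-sided t-tests
plus a two-sided two-sample t-test of region versus all remaining genes.

## Hi-C contact

Within-partition contact is the mean of the square sub-matrix over the
partition's bins — off-diagonal elements only for raw count matrices
(where the diagonal dominates), all elements for matrices whose diagonal
was zeroed upstream. Partition bounds snap to the nearest bin boundary,
never to an empty range. Contact is corrected for genomic composition by
regressing on gene count and segmental-duplication coverage fraction
(merged intervals, so coverage is invariant to interval splitting and
order) and standardizing the residuals, shared machinery with the
transmission residual model; at least four partitions are required.

The distal-rectangle test compares the bin pairs of an A×B rectangle
(e.g. the 0.7-Mb 16p11.2 locus against the 0–5.2-Mb telomeric segment of
chromosome 16) with all other same-chromosome bin pairs whose separation
lies within the band spanned by the rectangle — from the nearest-edge to
the farthest-edge distance of the two intervals (24.3–30.2 Mb for the
canonical windows). Separation is measured between bin start coordinates
and the band is inclusive at both ends (the endpoint convention is stated
here because either open or closed ends is defensible). Zero entries are
excluded from both sets by default, since zeros in processed matrices
typically mark masked, segmental-duplication-rich bins rather than absent
contact; `zero_policy="include"` is the robustness variant. The statistic
is the fold `mean(target)/mean(control)` — invariant to global rescaling
of the matrix — with a two-sided two-sample t-test. Only intra-chromosomal
matrices are supported.

## Synthetic data

The generator produces every input class with the structure the analyses
assume, and nothing more:

- **SNP maps**: positions uniform per chromosome (so >1-Mb gaps arise
  naturally and exercise gap capping), normal weights, inflated by a
  multiplier inside a designated effect region. Defaults: three 99-Mb
  chromosomes × 600 SNPs, effect region chr16:0–33 Mb with multiplier 3 —
  a desk-scale genome in which the effect region carries roughly half the
  score variance.
- **Trios**: parents Binomial(2, f) per SNP with f ~ U(0.05, 0.5); one
  fair Mendelian allele draw per parent. Probands are ascertained by a
  liability `L = z(PGS)·√h² + ε·√(1−h²)` exceeding a quantile threshold
  (default top 2%), with the PGS standardized by its analytic population
  moments. Over-transmission is therefore *emergent*: nothing injects a
  deviation, so its magnitude can be checked against Monte-Carlo
  expectations, and unascertained siblings from the same families give a
  free null. The default liability share h² = 0.3 makes effects detectable
  at 500 families; real psychiatric PGS shares are far smaller, which is
  precisely why the real studies need thousands of trios.
- **Expression**: three cohorts sized like the contributing brain cohorts
  (122 single-cell European, 229 bulk European, 193 bulk African-ancestry
  donors) with distinct baseline means and scales (exercising within-cohort
  scaling), a diagnosis effect, and a regional effect `β·z(PGS)` (default
  −0.3) on region genes only.
- **Annotations**: gene density varies between 33-Mb windows (lognormal,
  log-s.d. 0.5) with the effect region fixed at 1.8× baseline density —
  matching the ratio between the most gene-dense windows and the average
  in real 33-Mb tilings; a narrow-spread background would make the region
  an extreme-leverage point and let the gene-count covariate absorb
  genuine contact or transmission excess, which real gene-count spreads do
  not do. Segmental duplications and centromeres are random interval sets;
  the differential-expression table is standard normal t-statistics with
  an optional planted regional shift.
- **Contact matrices**: `scale·(|i−j|·resolution)^(−decay)` with symmetric
  multiplicative lognormal noise (σ = 0.1), an optional boosted block and
  boosted off-diagonal rectangle, and optional zero-masking.

All generators are pure functions of (config, seed) and reproduce
byte-identically. What the generator does **not** emulate: linkage
disequilibrium between sites (no transmission statistic here requires it;
LD-block partitions are exercised through arbitrary block files),
population structure, imputation error, genotyping batch effects, count
noise and normalization artifacts in expression, or realistic Hi-C
features such as TADs, loops and compartments. Passing tests therefore
demonstrate the statistics' correctness and calibration under the stated
model, not robustness to those real-data complications.

## Problem sizes and numerical choices

The validation suite uses desk-scale sizes chosen to keep Monte-Carlo
error well inside the asserted margins: 1,000 replicates of 200
unascertained trios (3 × 100 SNPs) for type-I error; 500 ascertained
probands per liability-share grid point with paired random streams;
200 replicates × 200 permutations for permutation-null calibration;
100 replicates for planted-effect ranking checks; and a single full
scenario with 500 trios, 544 expression donors and 9 partitions for the
end-to-end ranking. Tolerances: least-squares routes must agree with
normal-equations solutions to 1e-8; residual z columns are standardized to
1e-8; score conservation holds to 1e-12 relative (summation order
differs between routes); planted folds are recovered within 10%.

Degenerate inputs are defined rather than left to chance: constant
midparent scores, constant deviations, constant covariates, empty gene
sets, empty control contact sets, overlapping rectangle regions and
sub-bin partitions all raise informative errors; all-zero-weight
partitions are flagged and excluded from the residual model rather than
aborting a scan. Ties in the top-decile specificity flagging are broken by
gene id, and ties in decay-block ranking by genomic order, so both are
deterministic.

## Known limitations

- No genome-build liftover: all inputs must share one build.
- No X-chromosome or phasing support; analyses are autosomal.
- The quadrant enrichment p-value is this package's exact-binomial
  definition; other reasonable tests of the same counts will differ.
- PGS weight estimation, genotype QC/imputation, expression normalization
  and differential-expression fitting are upstream of this toolkit and are
  consumed as inputs.
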
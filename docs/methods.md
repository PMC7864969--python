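# Methods

This note documents the statistical models implemented in `hzadapt`, the
choices made where the design was genuinely open, what the synthetic
generator does and does not emulate, and the numerical details a user
reproducing or extending an analysis needs.

## Data model

Genotypes are unphased biallelic SNPs in 012 coding (counts of a
per-locus "counted" allele; −1 = missing). The counted allele is
locus-local — conventionally the minor allele of the source VCF — and no
downstream statistic depends on its polarity: r² and the squared Ohta
components are direction-invariant, the association scan pairs a
polarity-invariant Bayes factor with |ρ|, and the cline machinery
re-orients every locus to the allele more frequent in the donor species.
Missing calls are carried as masks and never imputed (the one exception,
noted below, is the mean imputation the Hellinger/RDA response requires);
the proportion of missing data is itself a matching covariate for null
construction, so imputing it away would bias the nulls.

Populations belong to one of three groups: the two pure parental species
P1 and P2 and the hybrid zone HYB. Throughout, P2 is the donor species
whose direction of introgression is tested.

## Association scan (GEA)

Per locus, population frequencies are standardized as
x = (f − f̄)/√(f̄(1−f̄)) with f̄ the across-population mean. A
population-covariance matrix Ω is the average outer product of x over a
random subset of loci (default 1,000), ridge-stabilised when its smallest
eigenvalue falls below 1e−8. The slope of x on the centred/scaled
gradient e is estimated by GLS with error covariance Ω, and evidence is
the Savage–Dickey Bayes factor for that slope under a Normal(0, τ²)
prior (τ = 1 on the standardized scale) against the point null.

Because x is centred on the across-population mean, Ω lives in the
contrast space: patterns common to every population carry no information
and the matrix's rows sum to ~0. This is sufficient for the GLS
correction (only contrasts matter there) but it means Ω is not an
estimate of an absolute covariance around an ancestral frequency; an
exchangeable correlation c across populations, for instance, maps to
−1/(P−1) after centring. Tests therefore check the structure Ω preserves
(within- vs between-block ranking), not absolute levels.

The scan is replicated three times, each run differing only in the locus
subset behind Ω, mirroring the replicate-and-intersect logic of
MCMC-based scans while staying deterministic. Per run and gradient,
candidates are SNPs strictly above the type-7 99th-percentile of both BF
and |ρ| (Spearman, computed on raw frequencies); the final outlier set is
the intersection across runs, scored by the per-locus median BF. The
candidate budget is therefore at most 1% of loci per gradient, before
intersection.

## Differentiation statistics and matched nulls

F-statistics come from a moment (ANOVA) decomposition of allele-indicator
variance over the nested design gene copies ⊂ individuals ⊂ populations
⊂ groups, with Searle-type expected-mean-square coefficients for
unbalanced sizes and per-locus missingness. F_CT is the among-group
fraction, F_ST the among-population (group + population) fraction;
multilocus values are ratios of summed components, which reduces to the
single-locus value for one locus. Negative component estimates (a normal
feature of moment estimators near zero differentiation) are retained.
Observed and expected heterozygosities are per-locus means over loci with
data, equal-weighted.

Outlier sets are tested against bootstrap nulls matched in two dimensions:
minor-allele-frequency bins of width 0.05 on [0, 0.5] and missingness
bins of width 0.05 on [0, 1] (the source study fixes neither width). The
neutral pool excludes the outliers of *all* gradients (the conservative
reading). Each bootstrap draws, per outlier SNP, one matched neutral SNP
with replacement — duplicate draws are legitimate and the statistics
accept them — widening the bin one step at a time when empty (logged).
Empirical p-values use the +1 correction and the identical estimator code
path as the observed value.

## LD networks (outlier clusters)

r² is the squared Pearson correlation of 012 dosages over individuals
complete at both loci. Single-linkage clustering on 1 − r² (equivalently,
connected components of the r²-threshold graph) yields a merge tree; for
every cluster C with parent P, λ(C) = (median r² within C − median r²
within P)·|C| measures how sharply LD collapses when C dissolves.
Clusters with λ above median(λ) + φ·MAD(λ) and at least E_min members
(defaults φ = 2, E_min = 5), taken innermost among nested candidates (the
highest r² threshold at which they exist), are outlier clusters (OCs).

Two robustness details matter in practice. First, the λ distribution is
typically a point mass near zero plus a few extreme true clusters, which
drives the MAD towards zero; the scale is floored at 5% of the λ dynamic
range so the limit sits between the noise spike and genuine outliers.
Second, single linkage chains background loci onto strong clusters
through single edges; members whose median r² to the rest of a flagged
cluster is below half the cluster median are trimmed iteratively. With
these, planted blocks are recovered exactly on constructed matrices.

The replicate design pairs all association outliers with an equal number
of MAF-bin-matched neutral SNPs (drawn without replacement within a
replicate), re-clusters per replicate (default 100), and reports per-OC
composition (outlier fraction, dominant gradient by plurality with ties
broken by summed median BF, same-contig flags) and the co-occurrence
fraction of outlier subsets of size 3–6. Subset enumeration is capped at
30 outlier members per OC (logged) to bound the combinatorics.

## Ohta's LD partition and MMRR

For a locus pair and S = 2 populations with counted-allele frequencies
p_i, q_i and counted–counted gamete frequency x_i:

    D²_IS = (1/S) Σ_i (x_i − p_i q_i)²
    D²_ST = (1/S) Σ_i (p_i q_i − p̄ q̄)²

Gamete frequencies are estimated from unphased genotypes by EM under
Hardy–Weinberg (only double heterozygotes are phase-ambiguous; tolerance
1e−8, 100 iterations); data consisting solely of double heterozygotes are
non-identifiable and fall back to the Burrows composite estimate,
flagged. Per gradient, the response matrices are the medians over all
outlier-locus pairs for every population pair; pairs with fewer than two
complete individuals in either population are skipped.

Predictors are pairwise absolute environmental differences and
Vincenty-inverse WGS84 distances (hand-implemented; nearly antipodal
non-convergence falls back to a spherical distance, logged — irrelevant
within one hybrid zone). Three OLS matrix regressions on the vectorised
strict lower triangle (full, environment-only, geography-only) give the
decomposition pureEnv = R²_full − R²_geo, pureGeo = R²_full − R²_env,
confounded = remainder (exact by construction); significance is by joint
row/column permutation of the response with the +1 correction (default
999 permutations, matching p = 0.001 granularity).

Within-population LD responds to ancestry variance *inside* populations,
so the D_IS signature requires the generator's tree-level ancestry spread
(below); among-population LD responds to divergent frequency products.
On the preset, freeze-class (ancestry-correlated) outlier sets dominate
the D_IS regressions and the class ordering reverses for D_ST, checked as
an ordering over three replicate simulations.

## RDA and variance partitioning

The response is the population × locus frequency table, mean-imputed per
locus where undefined (count logged — RDA needs a complete matrix), then
row-wise Hellinger-transformed (√ of relative abundance; unit row sum of
squares). Predictor blocks: leading PCs of the scaled gradients up to 90%
cumulative variance (duplicate gradients dropped first); a centred/scaled
polynomial trend surface of (lat, lon, elev), degree 2 by default — the
classic broad-scale spatial basis, chosen over spatial eigenvector
methods to keep the basis explicit and small; mean per-population hybrid
index as ancestry; and the first eigenvector of Ω as population
structure. Collinearity is pruned by iteratively dropping the
highest-VIF column above 10.

R² is the constrained fraction of total variance; R²_adj =
1 − (1 − R²)(n − 1)/(n − m − q − 1) with m constrained predictors
(rank) and q conditioning columns. Permutation tests shuffle response
rows freely when unconditioned, and reduced-model residual rows when
conditioned; all permutation statistics are computed through the
response Gram matrix, so each permutation costs O(n_pops²) regardless of
locus count (this is what makes 9,999 permutations cheap). A predictor
block entirely inside the conditioned space returns R² = 0.

Partitioning solves the inclusion–exclusion system linking the adjusted
R² of all 15 non-empty predictor-subset unions to the 15 exclusive Venn
regions; components may be negative (standard varpart behaviour,
flagged) and sum to the full-model adjusted R² exactly. The interaction
comparison adds columnwise env × ancestry products to the joint model
and tests the added terms with a Freedman–Lane permutation F-test under
the reduced model, both models conditioned on geography and structure.
The `vegan` implementations of RDA R² and two-set varpart serve as
independent cross-checks in the test suite.

## Hybrid index and genomic clines

The hybrid index h maximises the binomial mixture likelihood
P(counted allele) = h·f_P2 + (1 − h)·f_P1 over loci with parental
frequency difference ≥ 0.1 (parental frequencies pooled per group and
shrunk into [10⁻³, 1 − 10⁻³] so no genotype has zero likelihood), solved
by bounded scalar optimisation to 1e−6; individuals with fewer than 50
informative loci are flagged low-confidence.

Per locus, genotypes re-oriented to the P2-like allele are modelled as a
three-class multinomial logistic function of h with linear and quadratic
terms, *anchored to the neutral expectation*: the class log-odds carry
the neutral h-mixture probabilities as offsets, so the neutral model is
exactly the origin of the six-dimensional coefficient space and the LRT
is χ² with df = 6 (df = 3 for the binomial collapse used when a genotype
class is entirely absent, flagged). This exact nesting is what makes the
null p-values uniform, which the calibration suite verifies. Fitting is
a batched Newton iteration across loci with step capping, halving, a
1e−8 ridge, and an active-set update; the genotype-class model is
deliberately preferred over an allele-dosage collapse because it also
captures Hardy–Weinberg-structure deviations (measurably higher power on
planted loci).

The neutral envelope simulates loci from the h-mixture at parental
frequency pairs resampled from the observed informative pairs, fits the
same model, and records per tree the upper (1 + level)/2 quantile of the
fitted donor-homozygote probability *in excess of the simulated locus's
own neutral curve*. The excess scale is the package's documented choice:
a raw-probability envelope is dominated by near-fixed parental pairs and
no locus with moderate frequencies could ever exceed it; the excess
scale makes exceedance comparable across loci (the raw scale remains
available as `scale="phi"`). A SNP is called significantly introgressed
from P2 when its LRT p-value passes the Bonferroni family threshold
(α = 0.05 over all tested SNPs) and its excess exceeds the envelope in at
least 20% of trees — the one-sided envelope condition is what restricts
calls to the donor direction. Calls are monotone in both thresholds.

## Fold enrichment

FE = (Bpf/B)/(Spf/S) is evaluated in exact rational arithmetic before
the final division. The permutation null redraws exactly B loci per
permutation, uniformly without replacement from the tested universe
(10,000 draws by default), so the null overlap count is
hypergeometric(S, Spf, B) — the test suite checks the empirical null
against that closed form, keeping the two routes independent. Gradients
are tested separately (one null per outlier set size); empirical
percentiles (95th/99th) and +1-corrected p-values are reported with
per-class summaries.

## Synthetic generator

The generator emulates the sampling structure of a conifer hybrid zone:
hybrid populations on a latitudinal transect with logistic ancestry
cline q(lat), flanking pure parental populations, Balding–Nichols
parental divergence (F = 0.2), binomial genotypes via explicit gametes
(optionally returned for Ohta oracles), i.i.d. missingness (10%), and
environmental gradients built to have an exact in-sample correlation
with latitude (freeze class: ρ = 0.75–0.85; water class: ρ = 0)
plus a linear continuation over the parental transect. Trees within a
hybrid population vary in ancestry around the population value
(logit-scale SD 0.5), the within-population spread visible in admixture
plots of real hybrid zones and the mechanism that generates
within-population mixture LD (hence a meaningful D_IS).

Planted truth, desk preset: 20 hybrid populations × 8 trees, 4 + 4
parental populations × 8 trees, 5,000 loci, 20 `adaptive_introgressed`
and 20 `adaptive_background` loci over 3 + 3 gradients.

* `adaptive_introgressed` loci shift each tree's locus-level ancestry
  weight on the logit scale by s_intro·z, z the standardized target
  freeze gradient of its population (s_intro = 10), and are drawn from
  near-diagnostic markers (parental Δ ≥ 0.95). These strengths were set
  by a power computation for the preset's 160 trees against the
  Bonferroni χ²₆ threshold (per-locus call power ≈ 0.93): the desk scale
  trades the field study's ~1,100 trees for larger effects, the standard
  scaled-down design. Detectable recent introgression is, by its nature,
  carried by strongly ancestry-informative loci.
* `adaptive_background` loci shift population frequency directly by
  s_bg·z (s_bg = 0.1) along a water gradient, independent of ancestry,
  and are drawn from low-divergence loci (Δ ≤ 0.3) — background variants
  are by definition not identifiable as recent introgression.

What the generator does *not* emulate: linkage and recombination (loci
are independent given ancestry, so all LD is admixture- or
selection-induced and there are no physically linked clusters),
selection dynamics over generations, spatially explicit dispersal,
sequencing error, and locus-specific missingness structure. Passing the
planted-truth tests therefore demonstrates that the estimators recover
strong, cleanly planted signals at desk scale — not field-data error
rates, nor behaviour under physical linkage.

## Determinism and scale

Every stochastic routine takes a seed or Generator; the pipeline derives
per-stage seeds from the master seed and identical configurations
reproduce outputs byte for byte. Default iteration counts mirror
standard practice (1,000 bootstraps, 100 LD replicates, 999 MMRR and
9,999 RDA permutations, 10,000 FE permutations, 1,000 envelope
simulations); the validation suite and the reproduction script run
reduced counts (e.g. 500 envelope simulations, 2,000 FE permutations,
99-permutation size checks) chosen so the whole analysis of the preset
completes in seconds per run while keeping Monte-Carlo error well below
the decision margins involved.

## Known limitations

* Ω is a contrast-space covariance (see above); Bayes-factor magnitudes
  are not comparable to MCMC-based scans, only their ranking is used.
* The F-statistics are moment estimates; no confidence intervals are
  attached (the matched bootstrap serves that role for outlier sets).
* OC membership after trimming is a heuristic refinement of single
  linkage; clusters of genuinely intermediate cohesion may be split.
* The genomic-cline neutral model conditions on the estimated hybrid
  index and parental frequencies; their sampling error mildly inflates
  the LRT for very small parental samples.
* MMRR p-values use free matrix permutations; spatially autocorrelated
  responses can be anticonservative, as with any Mantel-type test.
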
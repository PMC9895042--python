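# Methods

## Demographic models and the coalescent engine

Each habitat pair is modelled as two demes — beach (B) and inland (I) — of
constant diploid effective sizes N_B and N_I that descend from a single
ancestral deme of size N_A at T_div generations before present.  Migration
is specified forwards in time as per-generation, per-lineage movement
probabilities m_BI (beach→inland) and m_IB (inland→beach).  Three nested
models are supported:

* `NOGFLOW` — all migration rates zero (4 free parameters);
* `ONEGFLOW` — constant bidirectional migration since the split (6 free
  parameters);
* `TWOGFLOW` — migration rates switch at T_rec, 0 < T_rec < T_div, giving
  separate recent and ancient epochs (9 free parameters).

The simulator runs the structured coalescent backwards in time as a
continuous-time exponential race: in a deme of diploid size N each lineage
pair coalesces at rate 1/(2N) per generation, and a lineage currently in
deme X jumps to deme Y at the *forwards* rate Y→X (a present-day beach
lineage descends from an inland migrant with probability m_IB).  Epoch
boundaries at T_rec and T_div interrupt the race; beyond T_div all lineages
enter the ancestral deme and migration stops.  This exponential
approximation is accurate for m, 1/N ≪ 1, which holds at every parameter
scale used here.  The event loop is numba-compiled; a lineage's
descendant-sample class (k_B, k_I) is constant over its lifetime, so
per-class branch lengths — the sufficient statistic for the expected SFS —
accumulate in O(1) per event.

Genotype datasets mimic the GBS design: one independent genealogy per
300-bp tag (no within-tag recombination, no between-tag linkage), Poisson
mutations with mean μ·L·(total branch length) placed on branches
proportionally to length at distinct sites within the tag (collisions
redrawn), diploids formed by pairing consecutive haploid samples within a
deme (no inbreeding model), and i.i.d. missingness.  Real GBS missingness
is structured by depth and restriction-site polymorphism; that structure is
deliberately not modelled, so tests exercising the missingness filters show
robustness to random missingness only.

Default study-scale parameters (`study_scale_params`) place the divergence
at 2.5×10⁵ generations with a recent epoch of ~1.2×10³ generations,
recent-epoch migration ~10⁻³ in both directions, ancient-epoch migration
10⁻⁶ (B→I) and 3.6×10⁻⁵ (I→B), and μ = 10⁻⁸ per site per generation.
Times and rates follow the reported locality-level estimates; effective
sizes are not reported anywhere and are set to 5×10⁴ diploids, which
reproduces a realistic GBS yield of ~4 SNPs per 300-bp tag.  The reporting
helper uses 2.1 years per generation, a published wall-lizard estimate.

## Joint folded SFS and the composite likelihood

The observed joint folded SFS uses complete-case SNPs only.  Ancestral
states are unknown, so each SNP is folded on the global minor allele: a
cell (c₁, c₂) with c₁ + c₂ past half the total copies is mapped to its
mirror; the exact-half class keeps the orientation whose population-1 count
does not exceed half of that sample, retaining the original orientation on
the residual tie.  The monomorphic-site count is extrapolated from
filtering attrition — used sites = total sites × (filtered SNPs / master
SNPs), monomorphic = used − SNPs — and enters the likelihood as one extra
class, anchoring the absolute mutation-rate scale.

The expected SFS under θ is a Monte-Carlo average over simulated
genealogies: P(site in class c) = μ·E[T_c], the remainder monomorphic.
Achievable cells with zero estimated mass are floored at 10⁻¹⁰ (bounded
penalty for observing a count in an unvisited cell) and the vector is
renormalized.  The composite log₁₀ likelihood treats SNPs (and monomorphic
sites) as independent multinomial draws; in the all-SNP dataset role linked
SNPs on one tag violate this independence, which is why model *comparison*
uses the thinned, outlier-free (one SNP per tag) role and parameter
*estimation* uses all SNPs.  Reported fit quality is the deviation
D = log₁₀CL(saturated) − log₁₀CL(fit).

## Optimization

Fitting is a seeded stochastic coordinate search, not an ECM algorithm;
its contract is that each replicate's accepted likelihood is monotone
non-decreasing.  Per replicate: a starting point (log-uniform in bounds, a
warm start, or a moment-based heuristic — Watterson θ for the sizes,
T_div = 2N, generic 10⁻³/10⁻⁵ migration), then cyclic per-parameter
multiplicative proposals with log-width log 3 shrinking as 1/(1 + 0.1·cycle),
widened to log 10 every third cycle to cross likelihood ridges (the
divergence-time/migration trade-off is the usual offender).  All
evaluations within a replicate share one simulation seed (common random
numbers), making acceptance a true hill climb on a fixed Monte-Carlo
surface.  The winning replicate is re-evaluated with a larger simulation
count on a seed derived from the fit seed alone, so different models fitted
with the same seed are compared on common final randomness.

Nested models are fitted simplest-first with warm-start chaining: each
richer model receives the simpler fits embedded in its parameter space
(new migration rates at the lower bound, epoch ratio at 0.5), preventing a
special case from spuriously out-fitting its superset.  The search space is
restricted to ≤ 50 expected backwards deme jumps per lineage over the
divergence span: beyond a handful of jumps the SFS is at the
migration-drift equilibrium (no information), and unbounded m·T products
make event counts — and run time — explode.

AIC = 2k − 2 ln(10)·log₁₀CL with parameter counts k = 4/7/10; only the
differences Δk = 3 between successive models carry information, and k is
configurable.  Relative model probabilities default to exp(−ΔAIC), the
convention matching the published worked value (1.1×10⁻¹⁵⁷ at
ΔAIC = 361.4); the textbook exp(−ΔAIC/2) is available behind a flag.
Parametric-bootstrap intervals simulate datasets at the fitted parameters
with the observed amount of genomic data, rebuild each folded SFS, refit
starting from the fitted values, and take 2.5/97.5 percentiles.

## Selection scan and environmental association

The outlier scan centers and scales genotypes by √(p̂(1−p̂)) with mean
imputation, regresses each SNP on the leading K = 4 orthonormal principal
components of individuals (K standing in for the four observed population
groups; configurable), and forms Mahalanobis D² of the per-SNP z-vector
against the *uncentered* second-moment matrix of z — uncentered because
E[z] = 0 under the null and because it makes D² invariant to
reference/alternate allele flips.  The reference method uses a robust
covariance estimator instead; a median-based genomic-inflation rescaling
compensates at the scales used here.  Because a SNP's K z-scores share one
residual-variance estimate with ν = n − K − 1 degrees of freedom, the exact
null distribution is Hotelling-type, D²/K ~ F(K, ν), and p-values use that
F reference (λ = median(D²)/(K·F_median)); the customary large-n χ²_K limit
is anti-conservative in the far tail at n ≈ 100 and produced excess false
flags at the Bonferroni threshold.  Outliers: MAF > 5% and
Bonferroni-adjusted p < 0.1.

Environmental association models the per-SNP standardized site-frequency
vector as MVN(β·e*, Ω) with e* the centered beach/inland indicator and Ω a
moment estimator of the between-site drift covariance on a thinned SNP set
(the reference tool estimates Ω by MCMC; its algorithm is not described in
the source text, and the moment estimator is the transparent substitute).
The Bayes factor integrates a uniform prior on β (halfwidth 10) by
trapezoid quadrature against the point null.  A BF threshold of 10
("strong" on Jeffreys' scale) defines significance — the reference
analysis does not state its cut-off.  Replicate-to-replicate stochasticity
of the MCMC tool is recreated by bootstrap-resampling the thinned SNP set
used for Ω in each of the 10 runs.

## Structure summaries

Pairwise F_ST is the Weir–Cockerham (1984) estimator, ratio of summed
variance components across loci, with per-locus removal of missing
genotypes; identical samples give the expected slightly negative value
(≈ −1/(n−1)), and the diagonal is 0 by convention.  DAPC selects its PC
count by stratified 90/10 cross-validation (100 training sets by default;
the holdout fraction and stratification are the package's own defaults, as
the source text states neither), maximizing the mean successful assignment
rate with ties to fewer PCs, then runs canonical discriminant analysis on
the PC scores.  sPCA eigen-decomposes (1/n)·Xᵀ((L+Lᵀ)/2)X over a
within-locality neighbour network (all same-locality pairs connected,
regardless of sample size); the permutation tests use the maximum positive
and |most negative| eigenvalues as global/local statistics with
p = (1 + #{perm ≥ obs})/(n_rand + 1).  The external implementation the
observed values 34.39/29.02 come from does not print its exact statistic,
so absolute sPCA statistics are not comparable across implementations —
only their permutation p-values are.

## Morphometrics and phenotype statistics

Centroid size is √Σ‖xᵢ − x̄‖².  GPA uses partial Procrustes
superimposition — center, scale to unit centroid size, iterate SVD-optimal
rotations (no reflection) to the evolving mean, with the mean realigned to
its predecessor each round so convergence is measured net of rotational
drift (tolerance 10⁻⁸, 100 iterations, non-convergence flagged).  Object
symmetry follows the doubled-dataset protocol: reflect x → −x, swap
left/right landmark labels, superimpose originals and reflected copies in
one joint GPA, then symmetric = pairwise average and asymmetric = half the
difference; this defines the reflection axis implicitly through the joint
consensus rather than by a separate midline regression, matching standard
morphometric software.  Shape PCA retains the smallest PC count reaching
95% cumulative variance.  Luminance calibration is the two-point linear map
through the grey-standard anchors (10.17% and 59.41% reflectance), with
downstream analyses on log₁₀ values.

MANOVA uses a cross-classified linear model with interaction, sum-to-zero
contrasts and Type III (partial) hypothesis tests — matching mainstream
statistical software for unbalanced designs — reporting Pillai's trace V,
its F approximation, and partial η² = V/s with s = min(hypothesis df,
responses).  Responses are standardized internally (Pillai is invariant to
per-response scaling) and a single response reduces exactly to the
univariate ANOVA, where partial η² = F·df_h/(F·df_h + df_e).  Canonical DFA
solves W⁻¹B (ridge on a singular W, with a warning) and draws 95% normal-
theory ellipses from the χ²₂ quantile.  Distributional diagnostics are the
user's concern; Pillai is retained regardless, by design.

## Synthetic-data scope

The generator reproduces the study's design parameters — 4 localities ×
{beach, inland}, ~9–14 genotyped diploids per site, ~4,000 300-bp tags,
two-epoch gene-flow genealogies at study-scale parameters, optional
habitat-differentiated spiked loci (one per tag, frequencies p ± Δp/2
redrawn binomially), and landmark/colour samples with a beach mean shift.
Two things it does not attempt: recombination/selection within the
coalescent itself (selection is emulated post hoc by spiking), and an
island-wide eight-site coalescent (the two-deme engine is per-locality; the
eight-site matrices for scan/structure stages come from a hierarchical
Balding–Nichols frequency model with locality- and habitat-level drift).
Consequently, passing tests demonstrate correct behaviour under these
idealizations, not robustness to depth-structured missingness, linked
selection, or unmodelled spatial continuity.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own single-CPU defaults for routine verification:

* coalescent closed forms: 10⁴–10⁵ genealogies (tolerance 5%);
* model selection: 10 datasets at study-scale parameters, 2000 tags,
  17+17 diploids; fits with 14 cycles × 2500 simulations × 3 replicates,
  final re-evaluation with 8×10⁴ simulations (the reference workflow's
  full settings — 100 cycles × 2×10⁵ simulations × 100 replicates — are
  available through the same API);
* parameter recovery: 10 datasets at N = 500, T_div = 4000, T_rec = 400,
  m_rec = 10⁻³, m_anc = 10⁻⁵; fits with 12 cycles × 4000 simulations × 3
  replicates;
* bootstrap coverage: 1 dataset × 20 bootstrap replicates; the primary fit
  uses 20 cycles × 6000 simulations × 4 replicates and each refit 20
  cycles × 2500 simulations × 2 replicates from the fitted values — refit
  search effort matters here, because improvement-only refits with too few
  cycles stay near their common starting point and understate the bootstrap
  scatter;
* outlier scan: 10 × 5000 neutral SNPs (size), 20 spiked loci at Δp = 0.6
  (power); sPCA: 200 meta-replicates × 199 randomizations (size), 9999
  randomizations (power).

## Known limitations

* The composite likelihood ignores linkage within tags in the all-SNP
  role; deviations there are optimistic.
* T_div and N_A are weakly identified from a folded SFS when recent
  migration is strong; the bootstrap intervals are wide accordingly.
* The moment estimator of Ω and the quadrature Bayes factor are
  transparent stand-ins for an MCMC machine; absolute BF values should not
  be compared against MCMC output, only their rankings and thresholds.
* sPCA statistics are implementation-specific (see above).
* The optimizer is stochastic; with few replicates a rich model can score
  slightly worse than a nested special case on a given final evaluation
  seed.  Warm-start chaining makes this rare but not impossible.
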
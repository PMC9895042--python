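# beachflow

Tools for asking a population-genomics question that keeps coming up in
microgeographic divergence studies: **can phenotypic divergence between
adjacent habitats arise and persist despite ongoing gene flow?**  The
motivating system is an island lizard sampled in matched pairs of shingle
beach and inland sites less than a kilometre apart, genotyped at thousands of
short GBS tags and phenotyped for dorsal luminance and head-shape landmarks.

`beachflow` implements the full genotype-to-inference chain for that design,
plus a synthetic-data engine so every stage is testable without the archived
field data:

* **simdata** — a structured-coalescent simulator for two demes with
  epoch-switching migration (models `NOGFLOW`, `ONEGFLOW`, `TWOGFLOW`),
  GBS-style genotype matrices (300-bp tags, missingness), spiked
  habitat-differentiated loci, and landmark/colour phenotype generators.
* **genomatrix** — matrix-level SNP filters (call rate ≥ 0.90, exact
  one-sided heterozygote-excess test at α = 0.01, MAF floor), one-SNP-per-tag
  thinning, per-site individual trimming, the joint folded site frequency
  spectrum, and monomorphic-site extrapolation.
* **demog** — composite-likelihood fitting of the three gene-flow models on
  the joint folded SFS (Monte-Carlo expected SFS, seeded stochastic
  coordinate search), AIC model comparison with relative model
  probabilities, and parametric-bootstrap confidence intervals.
* **scan** — PCA-regression Mahalanobis outlier scan with genomic-inflation
  correction and Bonferroni flags, plus environmental-association Bayes
  factors against a between-site drift covariance, with replicate-
  consistency counts.
* **popstruct** — Weir–Cockerham pairwise F_ST, DAPC with cross-validated PC
  selection (MSAR/RMSE), and spatial PCA with local/global eigenvalue
  permutation tests over a neighbour network.
* **morpho / mvstats** — centroid size, Generalized Procrustes Analysis,
  object-symmetry decomposition, shape PCA with the 95% rule, grey-standard
  luminance calibration, two-way Pillai MANOVA / ANOVA with partial η², and
  canonical DFA with confidence ellipses.
* **pipeline / cli** — a config-driven end-to-end run
  (`beachflow run --seed 1`) writing TSV reports and a JSON manifest.

## The model at the core

For each habitat pair, a beach and an inland deme of diploid sizes
N_B, N_I split from an ancestral deme of size N_A at time T_div generations
before present.  Migration is parameterized forwards in time: m_XY is the
per-generation probability that a lineage in X moves to Y, with separate
recent (t < T_rec) and ancient (T_rec ≤ t < T_div) epochs in `TWOGFLOW`.
The expected joint folded SFS under a parameter vector θ is estimated from
simulated genealogies (probability of a site segregating at minor-allele
copies (c₁, c₂) is μ·E[branch length ancestral to that class]), and θ is
scored by the multinomial composite log₁₀ likelihood over all SFS cells
including the monomorphic class.  Models are compared by
AIC = 2k − 2 ln(10)·log₁₀CL, equivalently ΔAIC = 2 ln(10)·ΔD − 2Δk from the
deviations D to the saturated likelihood, with Δk = 3 between successive
models.

## Worked example

`python examples/02_model_selection.py` simulates one habitat pair under the
two-epoch model at study-scale parameters and fits the model ladder:

```
observed SFS: 8720 SNPs, 591280 monomorphic sites
   model  k  deviation           AIC  delta_AIC
TWOGFLOW 10 132.508877 163960.135590   0.000000
ONEGFLOW  7 151.287868 164040.616042  80.480452
 NOGFLOW  4 211.453191 164311.687594 351.552004

relative probability of ONEGFLOW vs best: 1.12e-35
best-fit divergence 3.82e+04 gen; recent-epoch migration B->I 6.6e-04,
I->B 1.0e-03 (ancient 2.7e-06, 1.3e-05)
```

The two-epoch model wins decisively (ΔAIC ≈ 80 against constant gene flow),
and the fit recovers the generating regime: recent migration orders of
magnitude above ancient migration.  The other examples walk through SFS
construction, the outlier scan (recall of spiked loci, replicate-consistent
Bayes factors), structure summaries (F_ST / DAPC / sPCA) and the phenotype
statistics (GPA, symmetric shape PCA, Pillai MANOVA, DFA).

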
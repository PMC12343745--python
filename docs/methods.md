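# Methods

This package re-creates, at desk scale, a simulation study of whether
imputing the geographic origins of genebank accessions from their genotypes
— and then imputing environments at those predicted origins — improves
genome–environment association (GEA) scans. It has four parts: a forward
spatial simulator of a selfing crop adapting to a synthetic environment, a
coordinate-predicting neural-network ensemble with a masking design, an
environment layer, and a suite of GEA statistics with power/true-discovery
evaluation across three analysis schemes.

## The forward simulator

The demographic model is a spatial stepping-stone on irregular collection
sites. Candidate sites are drawn uniformly in a Fertile-Crescent-sized
lon/lat extent and greedily thinned to a 40 km minimum spacing (haversine
distances, Earth radius 6371.0088 km throughout). Adjacency is the Gabriel
graph over great-circle distances — a planar neighbor graph that
approximates a stepping stone on irregular points. Migration along edge
(i, j) is m0/d_ij per generation (m0 = 1 km), with each site's outgoing
rates rescaled so the total emigration probability per site is at most
`m_total`.

Each generation: every individual produces Poisson(2) offspring, selfed
with probability 1 − outcrossing rate (0.01, matching a highly selfing
crop such as barley) and otherwise mated to a uniformly drawn same-site
individual; gametes receive one crossover per linkage group (10 groups,
loci evenly spaced) at a uniform position, with free recombination between
groups; symmetric per-locus mutation at rate mu flips alleles; offspring
then migrate, survive viability selection, and each site is truncated
uniformly at random to its carrying capacity. Generations do not overlap.

Phenotype is the additive sum of QTL allele effects plus N(0, 0.5) noise
drawn once at birth. Each of the 100 QTLs carries an allelic effect drawn
once from N(0, 0.45). Fitness is the Gaussian density N(y_opt, sigma)
evaluated at the phenotype, where y_opt is the raster value at the site and
sigma = 2.85 (the plasticity parameter: larger sigma, weaker stabilizing
selection); survival probability is the density rescaled by its mode, so a
perfectly adapted individual survives with probability 1. A burn-in phase
confines the population to the refugium site(s) — one (1R) or two (2R)
domestication centers — at an enlarged carrying capacity with no migration;
the post-burn-in phase opens migration and caps every site, producing range
expansion, serial founder effects and isolation by distance.

Neutral loci are simulated forward directly rather than overlaid backward
on recorded genealogies: at desk-scale locus counts the hybrid
forward/backward strategy buys nothing, and neutral allele-frequency fields
are statistically equivalent.

### Profiles

Three named profiles fix the problem sizes:

* `full` — 312 sites, 999,900 neutral + 100 QTL loci, 10,000 + 10,000
  generations, K = 5,000 (refugium) / 250 (site), 50 sampled per site,
  mu = 6.5e-7. This is the full-scale study design; it is provided for
  cluster use and is not exercised by the test suite.
* `desk` — 50 sites, 10,000 neutral loci, 500 + 500 generations, K = 100,
  25 sampled per site, mu = 1e-4.
* `mini` — the profile the test suite and `scripts/acceptance.py` run:
  50 sites, 2,500 neutral + 100 QTL loci, 1,000 burn-in + 400 expansion
  generations, K = 600 (refugium) / 60 (site), 15 sampled per site,
  mu = 2.5e-4, stepping-stone emigration cap `m_total` = 0.01.

The reduced profiles raise the mutation rate above the full profile's
(itself a 100x-scaled rate) so that per-locus diversity — and hence the
number of segregating markers per simulated locus — stays in a realistic
range when the locus count and population size shrink by orders of
magnitude. The mini profile's low emigration cap compensates for its small
marker panel: with ~2,500 loci instead of a million, stronger between-site
drift is what keeps sites genetically recognizable, which is the regime the
full design's site-recognition accuracy lives in. The cost, measured and
accepted during generator design, is that unseen-site (Type 1)
interpolation — which the full design supports with 156 densely spaced
training sites — is noticeably noisier at 25 training sites; Type 1
accuracy numbers at this scale sit below the full design's, and the
documentation reports them as such rather than as estimates of the
full-scale values.

## Masking and origin prediction

The masking design emulates a genebank in which most accessions lack
passport coordinates: half of the sites are selected, five individuals per
selected site keep their coordinates (the training set), and every other
individual is masked. Masked individuals from unselected sites form the
Type 1 prediction set (their site is wholly absent from training); masked
individuals from selected sites form Type 2 (site overlap with training —
deliberate data leakage, the realistic genebank case). At the full design
(312 sites x 50 sampled, 50% of sites, 5 per site) this yields 780 training
and 14,820 prediction individuals — 95% masked.

The predictor is an ensemble of fully connected networks mapping
standardized SNP dosages (QTLs excluded) to standardized (lon, lat), trained
with Adam on the mean Euclidean distance between predicted and true
standardized coordinates, ELU activations, inverted dropout, and early
stopping on one held-out fold per member: k folds x r replicates members,
final prediction the arithmetic mean of all members' back-transformed
coordinates. The full design uses 10 x 8 = 80 members; the reduced profile
uses 5 x 2 = 10 with a (128, 64) net, dropout 0.1, learning rate 5e-3,
minibatch 32 — sized for a hundred-odd training genotypes rather than
thousands.

Accuracy is reported per axis as squared Pearson correlation (the
coefficient of determination 1 − SSE/SST is reported alongside, since
either reading is defensible) and as great-circle error in km, stratified
by prediction type. R² is flagged missing, not zero, when the truth has no
variance.

## Environment layer

The raster is a stand-in for a gridded bioclimatic layer: a fixed
latitudinal/longitudinal linear gradient (0.25 and 0.15 units per degree)
plus six seed-controlled Gaussian bumps (amplitude SD 0.5, scale 3
degrees), in standardized environment units centered near zero — so raster
values can serve directly as locally optimal phenotypes with sigma = 2.85
without a separate standardization step (the package's resolution of an
ambiguity in the source design). Masked cells model missing coverage (sea);
extraction is bilinear by default (nearest-cell is available), with a
nearest-unmasked-corner fallback within one cell and missing values
otherwise; individuals with missing imputed environments are excluded from
GEA input, with counts logged. A PCA utility for multivariate environmental
panels operates on the correlation matrix (bioclimatic variables have
heterogeneous units) with a largest-loading-positive sign convention.

## GEA statistics

Population-based scans first group individuals by complete-linkage
hierarchical clustering on great-circle distances, cut so that within-group
distances stay below 10 km; any group whose environmental standard
deviation exceeds 1% of the overall SD is recursively bisected by
complete-linkage clustering on the environmental value itself (splitting on
the violated criterion directly; geographic splitting is available as an
option). Group allele frequencies f_m and group-mean environments feed four
nested linear models:

    LM_naive : Env ~ f_m
    LM_P     : Env ~ f_m + Env_PC
    LM_RR    : Env ~ f_m + Env_Kinship
    LM_PRR   : Env ~ f_m + Env_PC + Env_Kinship

where Env_PC is the least-squares fit of Env on the first three principal
components of the frequency matrix and Env_Kinship the genome-wide ridge
prediction of Env from an LD-pruned (r² < 0.2, sliding-window greedy) SNP
set. Covariates enter as fitted-value regressors, matching the model
notation, rather than by residualization — equivalent for the test on f_m.
The ridge penalty is chosen over the grid 10^{−2..4} x n by efficient
leave-one-out generalized cross-validation (k-fold is available); no
leave-one-chromosome-out scheme is applied, so the kinship prediction can
absorb part of a strong causal signal (proximal contamination — the
documented caveat, and the reason the individual-level analogue is a
simplification of two-stage whole-genome-regression methods rather than a
re-implementation).

The likelihood-ratio statistic for adding f_m is computed through the
Gaussian identity lambda_LR = n ln(RSS_null/RSS_alt) = −n ln(1 − r²_partial),
vectorized over loci via QR residualization; it equals −2 ln L(null)/L(alt)
from an independent likelihood evaluation to 1e−8 (asserted in tests).
Monomorphic or covariate-collinear loci are flagged: statistic 0, p = 1, and
excluded from the inflation median below. A perfect fit is capped at
2 ln(1e300).

RDA scans standardize frequency columns to unit variance, project them onto
the (covariate-residualized, for the partial variant) environmental axis,
and robust-standardize the loadings (median, 1.4826 x MAD); the squared
standardized loading is treated as chi-squared with df = 1. With a single
constrained axis this reduces the Mahalanobis construction to one
dimension; column standardization makes the simple-RDA score exactly
monotone in |cor(f_m, Env)|.

The individual-based scan applies the LM_PRR construction to individual
dosages with the first three genotype PCs plus Env_Kinship as covariates.

Every scan's statistics are divided by the genomic inflation factor
lambda = median(statistic)/median(chi²₁) (median chi²₁ ≈ 0.4549364), and
p-values come from the upper chi²₁ tail of the adjusted statistic;
Benjamini–Hochberg q-values are attached. Simulation-study significance
uses the adjusted-p cutoff 0.005; BH at 0.05 is the intended cutoff for
empirical panels.

## Evaluation

Three schemes are compared on the same simulated panel and mask (paired
design): `regular` (training set only, true environments), `geaplus`
(training set plus the prediction set with environments imputed at
predicted coordinates; individuals with missing imputed environments are
dropped), and `perfect_geaplus` (every sampled individual with its true
environment — the upper bound of errorless imputation, for which no
predictor is trained). Panels are MAF-filtered at 0.005 after simulation
and 0.01 before scanning; segregating QTLs are those passing the pre-scan
filter on the scheme's own panel, which is the denominator the power
formula implies. Power = N_true/N_segQTL and TDR = N_true/N_sigSNPs at the
adjusted-p cutoff; TDR is missing, not zero, when nothing is significant.

## Numerical and design notes

* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; identical configuration and seed give
  byte-identical outputs.
* Distance matrices for clustering are dense; panels beyond ~20k
  individuals need chunking that this package does not implement.
* The p-value floor is the smallest positive double; q-values are clipped
  to 1.
* Site truncation at carrying capacity is uniform random, making density
  regulation selection-neutral.
* The simulator's founding population is monomorphic; burn-in length
  trades equilibration against runtime, and reduced-profile burn-in
  (1,000 generations at refugium size 600) reaches the inbreeding
  equilibrium (F = s/(2−s) ≈ 0.98) but not full mutation–drift equilibrium
  — acceptable here because the analyses consume post-expansion
  differentiation, not absolute diversity.

## What the generator does and does not emulate

The synthetic data reproduce the study conditions that matter for the
questions asked: high selfing, stepping-stone isolation by distance,
refugial expansion histories (1R vs 2R), local stabilizing selection on an
additive trait toward a spatially autocorrelated optimum, and the 95%
masking design. They do not emulate: genotyping error or missingness, seed
exchange and mislabeling (the geo-genetic outliers that real genebank data
require cleaning for), long-distance human-mediated dispersal, microclimate
(so environment at a predicted coordinate is better-behaved than WorldClim
at a misplaced coordinate), linkage maps with realistic recombination
heterogeneity, or ecological constraints on where predictions may fall.
Passing tests therefore demonstrate internal correctness of the pipeline
and the direction and rough magnitude of the full study's effects at
reduced scale — not empirical performance on real genebank panels.

## Known limitations

* The individual-based scan is an OLS analogue of two-stage whole-genome
  regression, without the leave-one-chromosome-out correction; its
  absolute power is conservative where causal loci dominate the kinship
  prediction.
* Genomic-control recalibration matches the null median, not the full null
  distribution; heavy structure can leave residual tail miscalibration.
* Reduced-profile accuracy numbers are noisier than the full design's
  (hundreds of prediction individuals instead of ~15,000); replicate
  averages are reported for that reason.
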
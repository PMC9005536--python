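# Methods

This note documents the models and numerical procedures implemented in
`microbreed`, the assumptions behind them, and the choices made where the
design was genuinely open.

## The scientific problem

Ruminal methanogenesis is carried out by a microbial community whose
composition is partly under the control of the host's genome. If the
abundances of specific microbial taxa or gene families are heritable and
genetically correlated with methane output (CH4, measured in g per kg of
dry-matter intake), then selecting hosts on those abundances changes CH4
emissions in the next generation — *microbiome-driven breeding*. The package
implements the full analysis chain needed to quantify and exploit that
route: compositional treatment of metagenomic abundance tables, genomic
relationship matrices from SNP data, Bayesian estimation of genomic
(co)variances, significance gates, selection-response prediction under
three information scenarios, and a co-abundance network of deregressed
genomic effects.

## Compositional treatment of abundance tables

Metagenomic counts and coverages carry only relative information. The
package closes tables to relative abundances, filters a *core* of features
(present in every sample — or, for coverage-based uncultured genomes, in a
minimum number of samples at ≥ 1× coverage — and above a mean-RA floor,
0.001 % by default), and maps to unconstrained coordinates by the additive
log-ratio (ALR) transform ln(x_j/x_ref) or, where no suitable reference
exists, the centred log-ratio (CLR) transform ln(x_j) − mean_j ln(x_j).

ALR reference choice is supported by `reference_diagnostics`, which scores
each candidate on occupancy, mean RA, log-ratio variance (the mean over the
other parts j of var_s ln(x_j/x_cand); the aggregation across parts is our
convention — a single per-candidate number is standard but the exact
summary varies between software), the quartile rank of that variance, and
the Procrustes correlation between the sample configuration in the full
pairwise-log-ratio geometry (principal coordinates of the pairwise
log-ratio distance matrix, which equals √J times the CLR distance) and the
candidate's ALR configuration. The Procrustes statistic permits centring,
orthogonal rotation and isotropic scaling, and is computed trace-norm
style: the sum of singular values of X'Y over the product of Frobenius
norms, padding the narrower configuration with zero columns.

**Zero replacement.** Count zeros are replaced by a Bayesian-multiplicative
rule: sample counts are multinomial with a Dirichlet prior α_j = s_i·t_j,
where t is the across-sample geometric-mean composition (computed from the
non-zero entries of each feature) and the per-sample prior strength
defaults to s_i = √n_i for sample total n_i. A zero entry becomes
n_i·t_j·s_i/(n_i + s_i) on the count scale (capped at 0.65 of the sample's
smallest observed count so a replacement can never rival a real
observation), and non-zero entries are rescaled multiplicatively so the
sample total — and every ratio among originally non-zero parts — is
preserved. This is our parameterisation of the geometric
Bayesian-multiplicative family; both t and s are overridable.

## Genotypes and the genomic relationship matrix

SNP QC removes unmapped and non-autosomal markers, then markers with call
rate < 95 %, Hardy–Weinberg χ² p < 1e-4 (one degree of freedom, no
continuity correction; monomorphic markers pass HWE trivially and fall to
the MAF filter) or MAF < 0.05, then samples with call rate < 90 %. Missing
genotypes surviving QC are mean-imputed (2p per marker) before centring.

The genomic relationship matrix is the VanRaden form
G = WW′ / 2Σp_n(1−p_n) with W the frequency-centred dosage matrix and p_n
recomputed from the genotyped population at hand. For MCMC the matrix is
stabilized as G* = 0.99·G + 0.01·I (blend configurable); all results are
conditional on G*.

## Bayesian GBLUP

Univariate animal model: y = Xb + Zg + e with g | G\*, σg² ~ N(0, G\*σg²)
and e ~ N(0, Iσe²); the fixed effects are the combined
experiment × breed × diet factor (treatment-coded with an intercept;
levels with fewer than two records are merged into the reference level).
Bivariate and multi-trait models use g ~ N(0, G\* ⊗ G0), e ~ N(0, I ⊗ R0).

**Priors.** Fixed effects are flat. Variance components get flat
(constant) improper priors, giving conditionals σ² ~ S/χ²_(n−2) and
G0 ~ IW(S, n−t−1). We deliberately do not use the ν = 0 limit of the
scaled-inverse-χ²/inverse-Wishart family: that prior carries an improper
spike at singular covariance matrices, and in multi-trait models the Gibbs
chain is then absorbed at genetic correlations of ±1 (we observed exactly
this collapse before switching). The prior degrees of freedom remain
configurable via `ModelSpec.prior_df` for users who want proper priors.

**Sampler.** The Gibbs sampler works in the eigenbasis of G* = UDU′. With
one record per animal the transformed genomic effects a = U′g have a
diagonal (univariate) or per-animal block-diagonal (multi-trait)
conditional precision, so a sweep costs O(n) or O(n·t³) instead of a dense
n×n solve. Genomic effects are drawn as a single block; fixed effects as a
second block. Missing records in multi-trait models are imputed each sweep
from their residual conditional given the animal's observed traits (data
augmentation). Two refinements apply when the (co)variance components are
frozen (the selection scenarios):

- the fixed effects are drawn from their genomic-effect-marginalized
  conditional (per eigen-row, y_i ~ N(B′x_i, d_i·G0 + R0)) followed by
  a | B — a blocked draw with no fixed-effect/genomic-effect
  autocorrelation;
- when every animal shares one missing pattern (e.g. CH4 set missing for
  all records), the observed-data residual precision is the same padded
  matrix for all animals, the eigenbasis stays separable, and no
  augmentation is performed at all.

The reported `gebv_mean` is the Rao-Blackwellized posterior mean: the
average of the genomic effects' full-conditional means, which has much
smaller Monte-Carlo error than the average of the draws; with frozen
components it is exact (the conditional mean is linear in the fixed
effects, whose marginal posterior mean is available in closed form).
Posterior spread (`gebv_sd`, used for accuracies) always comes from the
thinned draws.

**Schedules.** The default desk-scale schedule is 100,000 iterations,
20,000 burn-in, thinning 100; `ModelSpec.production_settings()` switches to
1,000,000 / 200,000 / 100 for production runs. The test-suite and
acceptance-script runs use shorter chains (stated in each test) chosen so
that Monte-Carlo error is small relative to the tolerances they assert.

**Diagnostics.** Geweke's Z compares the means of the first 10 % and last
50 % of a chain with spectral variance estimates (Bartlett-windowed
autocovariances, lag cut-off ≈ n^(1/3)); the Monte-Carlo standard error
uses batch means with √n batches and is reported with the sd/MCSE ratio
(the working rule is ratio ≥ 10). On iid chains of a few thousand samples
|Z| < 2 holds in ≈ 94–96 % of replicates; shorter segments make the
statistic slightly heavy-tailed, which is a property of the estimator, not
of the chains.

**Posterior summaries.** Parameters are summarized by the posterior
median, the shortest interval containing 95 % of the samples (HPD95%), and
P0 = max(fraction of draws > 0, fraction < 0), the probability that the
parameter shares the sign of its median. Note that P0 lives on [0.5, 1]
and its null expectation under perfect calibration is 0.75, not 0.5;
significance is declared at P0 ≥ 0.95, which corresponds to a ~10 % null
rejection rate at most (measured lower in our calibration runs because of
posterior shrinkage).

**Model comparison.** The genomic effect's significance combines two
gates, both computed from a full fit (with g) and a reduced fit (without):
DIC = D̄ + pD with pD = D̄ − D(θ̄), computed on the conditional
(observed-data) deviance, significant when ΔDIC ≤ −20; and a Bayes factor
from Laplace–Metropolis marginal-likelihood estimates on the g-integrated
likelihood (parameters b and log-variances; in that parameterisation the
package's improper scale priors are flat, so the posterior kernel is the
integrated likelihood itself), corrected for multiplicity by prior odds
1/n_tests and significant when the corrected BF > 3. Because the
marginal-likelihood approximation is only defined up to the improper-prior
constant, BF values are comparable within this package but not across
software.

**Derived quantities.** Heritability is computed per draw as
σg²/(σg² + σe²) and classified low (< 0.20), moderate (0.20–0.40) or high
(> 0.40). At moderate information (a few hundred animals, ~10³ markers)
the posterior median of h² shows a mild downward shrinkage of a few
hundredths relative to the simulated truth — visible in our calibration
runs with and without nuisance fixed-effect levels, and attributable to
the joint flat prior on the two variance components rather than to the
design matrix; HPD-interval coverage is unaffected. Genomic correlations come from the bivariate G0 draws. Per-animal
accuracy is √(1 − sd_i²/(g_ii·σg²)); values whose sd exceeds the prior
variance are clipped to 0 with a warning. Deregressed GEBVs are
dGEBV_i = GEBV_i / r_i² with r_i² the reliability (squared accuracy),
floored at 0.01 — animals below the floor are excluded from network input
rather than inflated. The deregression formula is our documented choice;
the procedure it emulates is usually performed by dedicated software whose
exact rule is not public. Per-group genomic variances (the Sorensen-style
partition) are the within-group empirical variances of the sampled genomic
effects, one value per retained draw.

## Selection

Selection intensity uses the infinite-population formula i = φ(z_p)/p. The
correlated CH4 response to selection on microbial trait j is computed per
posterior draw as R = i·h_j·r_gCH4j·σ_gCH4 where h_j is the square root of
the trait's heritability draw.

The multi-trait (CH4 + panel) genomic and residual covariance matrices are
assembled from all pairwise bivariate fits: off-diagonals are pairwise
posterior medians; each diagonal is the mean of that trait's per-fit
posterior-median variances (for CH4 this is exactly the mean across all its
bivariate models). Assembled matrices are bent to positive definiteness by
eigenvalue flooring at 0.001; bending is idempotent and the log records the
maximum element change.

Three prediction scenarios are fitted with the bent matrices as fixed
components: (1) CH4 records only; (2) microbial records only, with every
CH4 record treated as missing so CH4 genomic values are predicted purely
through the genetic covariances; (3) all records. Truncation responses per
selected fraction p take, per posterior draw, the ⌊p·n⌋ animals with the
*lowest* CH4 genomic value (ties broken by stable animal order — the
breeding goal is CH4 reduction) and report mean(all) − mean(selected), a
positive number for a reduction; signed g/kg DMI changes are also written.

The breeding panel filter keeps microbial traits present in all animals,
with mean RA ≥ 0.01 %, significant heritability (both the DIC and
corrected-BF gates) and r_gCH4 sign confidence P0 ≥ 0.95; when more traits
qualify than the panel cap (30 by default) the strongest |r_gCH4| are kept,
ties broken by higher h² — the capping rule is our choice and is logged.

## Co-abundance network

Nodes are microbial traits, edges connect pairs whose deregressed GEBVs
have Pearson r > 0.70 (signed by default; an absolute-value mode exists).
Nodes with degree < 2 are removed in one pass and nodes left isolated by
that pass are dropped (a full 2-core iteration is available as a flag).
Edges are then ranked by a k-nearest-neighbour rule — each node marks its
k = 10 strongest incident edges as preferred; edges sort by (number of
endpoints preferring them, |weight|) — and the top 80 % are kept, so every
retained edge ranks at or above every dropped one. Markov clustering
alternates expansion (matrix power 2) and inflation (elementwise power 2.0,
column renormalisation) on the column-stochastic adjacency with self-loops
at each node's maximum incident weight, to a 1e-6 convergence tolerance and
at most 200 iterations; clusters are read off attractor rows, and clusters
below the 2-node granularity dissolve to unclustered.

## The synthetic-data generator

The generator provides ground truth for every stage and emulates the study
conditions: SNP genotypes drawn binomial(2, p) with p ~ U(0.05, 0.5)
(Hardy–Weinberg, independent markers — no linkage disequilibrium, which is
sufficient for GRM-based inference but means the generator cannot test
LD-dependent phenomena); a cross-classified experiment (5) × breed (4) ×
diet (2) design with additive level shifts on the combined factor, scaled
by `fixed_effect_scale` times the phenotypic SD (1.0 by default — diet
effects of the same order as the phenotypic spread, as observed before
adjustment in such designs); multi-trait breeding values g ~ N(0, GRM ⊗ G0)
drawn with the realized GRM so the fitted model is correctly specified; and
CH4 defaults of h² = 0.33, genomic variance 3.9 (g/kg DMI)², mean 19.7
g/kg DMI, with microbial traits at unit phenotypic variance on the
log-ratio scale and a default host-genomic correlation of −0.8 with CH4.

Microbiome tables are logistic-normal-multinomial: per sample the latent
ALR row is inverse-ALR-mapped to proportions (reference appended last), a
sequencing depth is drawn log-uniform from `depth_range` (1e5–1e6 by
default), and counts are multinomial at that depth. The distribution of
real microbial abundances is unknown; logistic-normal-multinomial is our
modelling choice and is stated as such. Coverage-mode (uncultured-genome)
tables are continuous coverages with entries below 1× zeroed and
independent Bernoulli dropout at the configured zero-inflation rate —
real coverage zeros are depth- and abundance-dependent, which the
independent-dropout model does not capture. Passing tests therefore show
that the estimators recover parameters under a correctly specified
compositional model with realistic depth variation, not that they are
robust to every artefact of real metagenomic data.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at n = 500 animals × 1,000 SNPs for univariate
recovery (20 replicates, 20k/4k/10 chains), n = 1,000 for bivariate
recovery (20 replicates, 12k/3k/9), n = 200–285 with 10 indicator traits
for the scenario-ordering and response computations, and n = 30–50 toys
for the exact linear-algebra equivalence checks. These sizes were chosen so
each check's Monte-Carlo error is small against the tolerance it asserts
while the whole suite stays desk-scale; all seeds are fixed and every
stochastic path is reproducible.

## Known limitations

- Independent SNPs only; no LD, no pedigree relationships, no single-step
  H-matrix.
- The Bayes factor depends on an improper-prior constant; only its use as
  a relative gate within one analysis is meaningful.
- The Geweke statistic is reported as defined (asymptotically N(0,1));
  narrow empirical bands sometimes quoted for long production chains are
  not enforced.
- Augmentation-based missing-data handling mixes more slowly than the
  uniform-pattern exact path; posterior means for heterogeneous missing
  patterns carry ordinary Monte-Carlo error.
- `group_genomic_variance` reports within-group variances of sampled
  effects; it does not decompose scale differences induced by group
  differences in GRM diagonals.
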
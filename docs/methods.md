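# Methods

## Model

`merlin-mr` estimates the causal effect of an exposure X on an outcome Y when
that effect may be modified by a variable E (sex, age group, a standardized
continuous covariate).  The generative structural model, for individual *i*
with centered genotypes G and standardized modifier E, is

    X_i = Σ_j G_ij γ_j(G) + E_i γ(E) + Σ_j G_ij E_i γ_j(GI) + e_X,i
    Y_i = X_i β_A + Σ_j G_ij β_j(G) + E_i β(E) + X_i E_i β_I + e_Y,i

so the causal effect of X on Y for an individual at modifier level E is
β_A + E·β_I.  The two parameters of interest are the **average causal effect
β_A** and the **causal interaction β_I**; β_j(G) are horizontal-pleiotropy
effects, and the residuals e_X, e_Y absorb confounding and noise (they may be
correlated — that is what the instruments protect against).

Only summary statistics are observed: per-SNP effect estimates and standard
errors from four analyses — exposure GWAS (γ̂(G)), exposure GWIS (γ̂(GI), the
SNP-by-E interaction coefficient), outcome GWAS (Γ̂(G)) and outcome GWIS
(Γ̂(GI)).  The true outcome-scale effects are linked to the exposure-scale
ones by

    Γ(G)  = β_A γ(G)  + β(G)
    Γ(GI) = β_A γ(GI) + β_I γ(G).

## Summary-statistics likelihood

With S_k the diagonal matrix of block-*k* standard errors and R the
instrument LD matrix, each observed vector is modelled as multivariate
normal, e.g. γ̂(G) ~ N(S₁RS₁⁻¹ γ(G), S₁RS₁).  The outcome blocks carry
modifier-moment cross-terms.  For a binary modifier (standardized Bernoulli
with stratum-1 proportion p, levels √((1−p)/p) and −√(p/(1−p)), third moment
μ₃ = (1−2p)/√(p(1−p))):

    E[Γ̂(G)]  = S₃RS₃⁻¹ (Γ(G) + β_I γ(GI))
    E[Γ̂(GI)] = S₄RS₄⁻¹ Γ(GI) + μ₃ β_I S₄² S₃⁻¹ R S₃⁻¹ γ(GI)

and for a continuous modifier with zero skewness the β_I γ(GI) cross-term
moves to the GWAS block with an SE-ratio weighting while the μ₃ term
vanishes.  The β_I γ(GI) leakage into the *marginal* outcome GWAS is the
signature that biases classical MR when instrument main effects and
interaction effects are correlated ("polygenic gene–environment
interaction", ρ_{A−I}), and is exactly what the joint model exploits.  These
mean structures were validated against a large-cohort simulation oracle
(per-SNP regression coefficients at n = 150,000 agree with the model means
within Monte-Carlo error for balanced binary, unbalanced binary p = 0.25 and
continuous modifiers; dropping the μ₃ term fails that check decisively).

## Priors and Gibbs sampler

Per-SNP true effects get hierarchical priors.  The pair
(γ_j(G), γ_j(GI)) is bivariate normal with an unknown 2×2 covariance —
variances σ₁², σ₃² and correlation ρ_prior, the model-level counterpart of
ρ_{A−I} — updated by a conjugate inverse-Wishart step (ν₀ = 3, Ψ₀ = 10⁻⁸ I,
i.e. effectively flat at M = 200 instruments).  Pleiotropic effects are
β(G) ~ N(0, σ₂² I) with σ₂² ~ InvGamma(a, b), a = b = 0.01.  β_A and β_I
carry improper flat priors and are updated jointly (their conditional is a
2-dimensional Gaussian); this joint update is what separates an
interaction-induced tilt of the outcome GWAS from a genuine average effect.
When the estimated effect correlation is zero the prior reduces to the
independent N(0, σ₁²I), N(0, σ₃²I) form.  Modelling the correlation matters
at moderate sample sizes: with independent priors and ρ_{A−I} = 0.8 truth,
β_A acquired a finite-sample bias of ≈ +0.02 at n = 20,000 in our replicate
studies; the joint prior removes it.

**Cross-block error correlations.**  The sampling errors of the four
statistics for one SNP are not independent in common designs: a trait's GWAS
and GWIS are usually run on the same cohort (errors correlate through the
polygenic background — ≈ 2ρ√(h²_G h²_GI) ≈ 0.48 in the default simulation
design), and exposure and outcome cohorts may share individuals.  The
likelihood therefore supports a 4×4 cross-block error-correlation matrix
(`error_corr`): per SNP the error covariance is diag(s) P diag(s).  All
Gibbs conditionals remain Gaussian.  P can be supplied (the simulation
engine estimates it per replicate by heteroscedasticity-robust score
products, on a 4,000-individual subsample; in real data the within-trait
entries are estimable genome-wide, LD-score-intercept style), set to
identity, or — for the two within-trait entries only — sampled by
griddy-Gibbs on a uniform grid.  Sampling them is weakly identified from
instruments alone (the latent per-SNP effects can absorb error correlation),
so the default is identity and supplying known values is preferred.

Sampler defaults: 5,000 iterations, 2,000 burn-in, 2 chains; replicate
studies inside the simulation harness use 2,000/500 with one chain, which is
sufficient because only the posterior mean enters those summaries (split-R̂
for β_A, β_I is ≈ 1.00 well before that).  All draws are pre-generated from
a seeded PCG64 generator, so identical seed + configuration gives
bit-identical chains.  Initialization is moment-based (IVW-style slope for
β_A, observed vectors for the γ's, residuals for β(G)) with overdispersed
variance components to avoid the low-σ² sticking region.  Posterior
summaries report means, sds, 2.5/97.5% quantile intervals and Wald-style
two-sided normal P values on mean/sd — the simplest construction consistent
with reporting frequentist-style P values from a Bayesian fit.

With a dense LD matrix R the same conditionals are evaluated with dense
M×M precision matrices (Cholesky solves; no explicit inversion of S R S).
The dense path keeps independent priors and independent blocks; R is made
safely invertible by shrinkage (λ = 0.05 toward identity) at estimation
time.  A `fit_beta_I`-pinned reduction (interaction fixed at zero,
uninformative GWIS blocks) agrees with IVW, which we use as a validation
bridge to classical MR.

The reduced-data mode (`fit_merlin_no_outcome_gwis`) drops the outcome-GWIS
block; β_I is then identified only through its leakage into the outcome
GWAS, needs γ(GI) ≠ 0, and is flagged `experimental` with a warning when its
posterior sd exceeds 0.5.

## Instrument selection

Candidates pass if exposure-GWAS P < T_GWAS **or** exposure-GWIS P < T_GWIS
(defaults 5×10⁻⁸ and 5×10⁻⁶) — interaction-driven instruments enter on
their own merits.  Greedy clumping keeps the candidate with the smallest
priority P (min of the two), removing candidates with r² > r²_max (default
0.3) within a 1 Mb window; ties break lexicographically by SNP id, making
selection independent of row order.  Harmonization aligns all four tables
to the exposure-GWAS effect allele, resolves strand flips by complement,
and drops strand-ambiguous A/T, C/G SNPs by default (their orientation is
undecidable from alleles alone).

## Simulation engine

The engine draws independent binomial SNPs (MAF ~ U(0.05, 0.5), dosages
kept in single precision), a binary or continuous modifier, and phenotypes
from the structural model.  Genetic variance shares are rescaled to hit
their targets exactly (defaults: h²_γ(G) = 0.3; h²_γ(GI), ρ_{A−I}, h²_β(G)
per scenario); modifier main effects γ(E) = β(E) = 0.1 are folded into
composite residuals whose correlation is 0.6 and whose scales solve
var(X) = var(Y) = 1, accounting for the covariance the average effect
channels between the two residuals.  GWAS and GWIS are per-SNP least
squares (trait ~ SNP, and trait ~ SNP + E + SNP·E reporting the interaction
coefficient), solved in batch from column-wise reductions and verified
coefficient-for-coefficient against a generic OLS routine.  The exposure
cohort serves both exposure analyses (complete GWAS/GWIS overlap, as in
real pipelines); the outcome cohort may share `n_overlap` individuals with
the exposure cohort (shared genotypes, modifier and residual draws).

Replicate studies default to two cohorts of n = 20,000 with M = 200
instruments and use all simulated causal SNPs as instruments without
threshold selection: at generative scale essentially all of them reach
significance, and thresholding a deliberately reduced cohort would add
winner's-curse artifacts that say nothing about the method.

What the engine does **not** emulate: LD-structured genotypes (instruments
are exactly independent), genotyping error or imputation noise, population
stratification, case-control outcomes, and genetically influenced modifiers
(E is drawn independently of G, matching the framework's assumption).
Passing tests therefore certify the estimator under its stated sampling
model, not robustness to those real-data complications.

## Numerical choices

* Genotype dosages and score matrices in float32 (coefficients are accurate
  to ~10⁻⁵ relative, far below Monte-Carlo noise); all likelihood and MCMC
  arithmetic in float64.
* 2×2 conditional draws via closed-form Cholesky with a 10⁻¹² jitter;
  near-singular (β_A, β_I) precisions (e.g. the unidentified reduced-data
  mode) produce wide draws rather than failures.
* Inverse-Wishart draws by Bartlett decomposition with pre-generated χ²
  variates; inverse-gamma draws as scale over pre-generated gammas.
* The error-correlation grid for griddy-Gibbs spans ±0.95 in steps of 0.01;
  supplied correlations are clipped to ±0.95 and the 4×4 matrix is shrunk
  minimally toward identity if not positive definite.
* Zero-variance reference-panel SNPs are excluded from LD estimation;
  zero exposure-effect SNPs are excluded from IVW/Egger with a warning.

## Known limitations

* At n = 20,000 per cohort the interaction estimate carries a small
  multiplicative attenuation (≈ −1.3% of β_I at ρ_{A−I} = 0.8) that is not a
  property of the sampler (an exactly model-distributed rig recovers β_I to
  within Monte-Carlo error) but of per-SNP least squares on a finite cohort
  with polygenic background; it shrinks like 1/n (≈ −0.5% at n = 60,000)
  and is invisible at biobank scale.  Replicate averages at the default
  desk scale resolve this offset, so very tight recovery bands can flag it.
* The overlap-aware error-correlation matrix is estimated from
  individual-level scores inside the engine; for real data the
  exposure–outcome entries require an external estimate (e.g. from the
  known overlap design), and only the within-trait entries are readily
  estimable from summary data.
* Binary outcome traits are out of scope: effects are treated on the
  continuous (linear-model) scale throughout.
* MR-LDP and RAPS are not reimplemented; the comparison harness accepts
  externally computed estimates via TSV for side-by-side tables.
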
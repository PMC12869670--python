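# merlin-mr

Mendelian randomization with gene–environment interaction, from summary
statistics.

## The problem

Two-sample Mendelian randomization (MR) uses genetic variants as instruments
to estimate the causal effect of an exposure X (say, BMI) on an outcome Y
(say, testosterone) from GWAS summary statistics alone.  Classical
estimators (IVW, MR-Egger) assume that effect is one number.  When the
effect is modified by a variable E — sex being the canonical example — two
things go wrong: the interaction itself is invisible, and, worse, if a
SNP's main effect on the exposure correlates with its SNP-by-E interaction
effect (*polygenic gene–environment interaction*, ρ_{A−I}), the interaction
signal leaks into the marginal outcome GWAS and classical MR reports a
**spurious average effect**.  In the package's illustrative scenario the
stratum-specific effects are β_M = 0.3 and β_F = −0.3 (true average effect
zero): sex-combined IVW confidently reports a large positive effect, every
time.

`merlin-mr` implements MERLIN, a Bayesian model that jointly estimates the
**average causal effect β_A** and the **causal interaction β_I** from four
summary-statistics tables: exposure GWAS (γ̂(G)), exposure GWIS (γ̂(GI),
genome-wide interaction study), outcome GWAS (Γ̂(G)) and outcome GWIS
(Γ̂(GI)).  The structural link is

    Γ(G)  = β_A γ(G)  + β(G)          (β(G): horizontal pleiotropy)
    Γ(GI) = β_A γ(GI) + β_I γ(G)

with modifier-moment cross-terms (including the skewness term
μ₃ = (1−2p)/√(p(1−p)) for an unbalanced binary modifier) in the outcome
likelihood blocks; inference is by a blocked Gibbs sampler with
hierarchical priors on per-SNP effects.  See `docs/methods.md` for the full
model, priors and numerical choices.

The package also provides: dual-threshold instrument selection with min-P LD
clumping (GWAS *or* GWIS significance admits an instrument), four-way allele
harmonization and QC filters, stratified-GWAS transforms
(GWIS = ½(b̂_M − b̂_F), IVW meta-combination, sex-specific reconstruction
β̂_M = β̂_A + β̂_I, β̂_F = β̂_A − β̂_I), classical IVW/MR-Egger comparators
(plain and sex-stratified), and a full synthetic GWAS/GWIS cohort engine for
power and calibration studies.

## Worked example

Simulate the sex-inverted illustrative scenario (two independent cohorts of
20,000, 200 instruments, β_M = 0.3, β_F = −0.3, correlated GWAS/GWIS
instrument effects ρ_{A−I} = 0.8) and fit:

```python
import merlin_mr as mm

sc = mm.SimulationScenario.illustrative(seed=11)
panel, truth = mm.simulate_scenario(sc)
fit = mm.fit_merlin(panel, mod=sc.modifier,
                    cfg=mm.McmcConfig(5000, 2000, 2, seed=11),
                    error_corr=truth["err_corr_matrix"])
ivw = mm.ivw(panel.gamma_G, panel.s1, panel.Gamma_G, panel.s3)
```

Output (printed by the snippet in this repository):

```
beta_A: mean 0.0051 sd 0.0186 ci (-0.0323, 0.0409) p 0.79
beta_I: mean 0.2967 sd 0.0185 ci (0.2607, 0.3326) p 4.6e-58
IVW  : est 0.2145 se 0.0127 p 4.6e-64
male 0.3018 +/- 0.0128 ; female -0.2917 +/- 0.0348
```

The joint model recovers the null average effect (β̂_A ≈ 0.005, P = 0.79)
and the interaction (β̂_I ≈ 0.297 for a truth of 0.3), while IVW on the
same sex-combined panel reports a strongly "significant" average effect of
0.21 that does not exist.  The last line reconstructs the sex-specific
effects (truth +0.3 / −0.3) from the joint posterior via
β̂_M = β̂_A + β̂_I and β̂_F = β̂_A − β̂_I.

### Command line

```sh
merlin-mr simulate  --config scenario.yaml --seed 1 --outdir sim/    # 4 sumstats TSVs + truth
merlin-mr fit       --exp-gwas sim/exposure_gwas.tsv --exp-gwis sim/exposure_gwis.tsv \
                    --out-gwas sim/outcome_gwas.tsv --out-gwis sim/outcome_gwis.tsv \
                    --no-select --outdir fit/
merlin-mr compare   ... # joint fit + IVW + MR-Egger, one table
merlin-mr derive-gwis --male male.tsv --female female.tsv            # stratified -> GWIS + meta
merlin-mr select-ivs  ... # dual-threshold selection + clumping
merlin-mr benchmark   --config scenario.yaml --n-reps 100            # type-I / power table
```

Every run writes a JSON manifest (configuration, version, seed) making it
reproducible from the output directory alone.

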
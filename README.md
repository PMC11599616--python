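# volconsist

Automated segmentation tools (e.g., FSL FIRST and FreeSurfer ASEG) each
produce subcortical volume estimates that agree well with expert annotation —
yet they can disagree substantially *with each other*. When the between-method
consistency of a structure's volume is poor, two labs studying the same
question with different tools can reach conflicting conclusions: one finds a
significant correlation with an outcome and the other does not, or both find
significant correlations with opposite signs. `volconsist` is an analysis
pipeline for quantifying that problem and simulating its downstream
consequences, built for methodologists and neuroimaging researchers who use
regional volumes as biomarkers.

## What it computes

**Consistency and agreement ICCs.** For an n×k table of participants measured
by k methods, the two-way crossed ANOVA mean squares (MSR between
participants, MSC between methods, MSE residual) give the single-measurement
intraclass correlations

    ICC(C,1) = (MSR − MSE) / (MSR + (k−1)·MSE)
    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

with F-based 95% confidence intervals (McGraw & Wong conventions; the
agreement interval uses a Satterthwaite-approximated df). Values are banded
qualitatively: < 0.4 poor, [0.4, 0.6) fair, [0.6, 0.75) good, ≥ 0.75
excellent. Consistency ignores additive method offsets; agreement does not.

**Structural comparisons.** Orthogonal (total least squares / Deming)
regression of one method on the other; proportional differences
(v₁ − v₂)/((v₁ + v₂)/2) and their SD by structure size; standardized
hemisphere × method contrasts with paired t-tests; OLS confound
residualization with ICC recomputation.

**Discordance simulations.** The generative triplet model
T ~ N(0,1), X_m = T + e_m with e_m ~ N(0, (1−ICC)/ICC), Y = ρT + √(1−ρ²)ε
fixes the population consistency of the two measurements at ICC and attenuates
the observable signal to corr(X_m, Y) = ρ·√ICC. Batches of simulated
experiments estimate two conditional conflict rates — P(exactly one method
significant | at least one significant) and P(opposite signs | both
significant) — with medians and 95% equal-tailed intervals across batches,
over a grid of (ICC, ρ, n).

**Cohort resampling.** On a cohort table (here synthetic, shaped like a
biobank extract), phenotypes are screened by |Spearman correlation| with the
cross-method average volume; repeated subsamples of n participants tally the
same conflict categories per phenotype.

Because the real data behind this design are access-restricted, the package
includes a first-class synthetic-cohort generator with user-specified target
consistencies, method offsets and asymmetries, confound loadings, and
phenotype correlations; latent "true" volumes are retained as oracle columns
so every stage is testable.

## Worked example

```sh
volconsist run-all --config configs/demo.yaml --out-dir results --seed 7
```

or, stage by stage, `python analysis/01_generate_cohort.py` through
`analysis/05_cohort_resampling.py`. With the shipped demo configuration
(20,000 participants; amygdala target consistency 0.2, hippocampus 0.65) the
summary reports:

```
amygdala left cross-method ICC(C,1): 0.20 [0.19, 0.22] (poor)
hippocampus left cross-method ICC(C,1): 0.66 [0.64, 0.67] (good)
```

i.e. the generator's poor-consistency structure is correctly banded "poor"
while the well-measured control is "good". The contrasts table shows the
planted hemisphere effects: method 1 reports left > right (≈ +0.04 SD),
method 2 right > left (≈ −0.19 SD), interaction ≈ 0.23 SD, all p < .001 —
two tools, same participants, opposite lateralization claims. The
discordance grid shows that at ICC 0.2, ρ = 0.1, n = 50, roughly 95% of
experiments with at least one significant correlation have exactly one
(falling steeply as ICC rises), and the size-variability table shows the
smaller structure with several times the proportional-difference SD of the
larger one.

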
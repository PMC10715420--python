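# mrmediate

Two-sample Mendelian randomization (MR) with two-step mediation analysis
on GWAS summary statistics.

`mrmediate` is written for epidemiologists studying causal chains of the
form *exposure → mediator → disease* from published GWAS association
tables — the motivating use case is linking gut-microbiota taxa to an
autoimmune vasculitis (Granulomatosis with Polyangiitis, GPA) through
immune-cell traits, where the exposure GWAS comes from a microbiome
consortium, the mediator GWAS from an immune-trait panel, and the
outcome GWAS from a disease biobank. The package covers the complete
workflow: harmonizing effect alleles across studies, selecting
independent genetic instruments, the univariable MR estimator suite with
sensitivity diagnostics, multivariable MR (MVMR), and the mediation
decomposition — plus a summary-statistics simulator with known causal
truth so every stage can be validated end to end.

## The model

For SNP *j*, let γ̂ⱼ (SE σ_γⱼ) be its effect on the exposure and Γ̂ⱼ
(SE σ_Γⱼ) its effect on the outcome (log-odds for a binary disease).
Under the instrumental-variable assumptions each ratio Γ̂ⱼ/γ̂ⱼ estimates
the causal effect β, and the estimators combine them:

- **IVW**: β̂ = Σwⱼγ̂ⱼΓ̂ⱼ / Σwⱼγ̂ⱼ², wⱼ = 1/σ_Γⱼ² — weighted regression
  through the origin; a multiplicative random-effects variant inflates
  the SE by √(Q/(J−1)) under heterogeneity.
- **MR-Egger**: the same regression with a free intercept; the intercept
  estimates average directional pleiotropy (InSIDE assumption).
- **Weighted median**: consistent while <50% of the weight comes from
  invalid instruments; bootstrap SE.
- **MR-PRESSO**: simulation-based residual-sum-of-squares test for
  horizontal pleiotropy with per-SNP outlier flagging and an
  outlier-corrected estimate.
- **Cochran's Q** for heterogeneity; instrument strength via per-SNP
  R² = t²/(t² + N − 2) and the F-statistic.

For mediation, the total effect (univariable MR of exposure on outcome)
is split by the difference method against the MVMR direct effect
(exposure coefficient adjusting for the mediator):

    indirect = total − direct,    proportion mediated = indirect / total,

with the two-step product (exposure→mediator × mediator→outcome) emitted
as a cross-check.

## Worked example

Simulate a causal chain with direct effect θ_d = 0.35, exposure→mediator
effect α = 0.3 and mediator→outcome effect θ_m = 0.5 (so the true total
effect is 0.5 and the true proportion mediated is 30%), then run the
full pipeline:

```sh
mrmediate simulate --n-snp 100 --seed 6 \
    --n-exposure 300000 --n-mediator 300000 --n-outcome 300000 \
    --out-dir sim/
cat > config.yaml <<EOF
paths:
  exposures:
    - {path: sim/exposure.tsv, name: taxon, level: genus}
  mediators:
    - {path: sim/mediator.tsv, name: immune}
  outcome: {path: sim/outcome.tsv, name: disease}
thresholds: {p_ladder: [5.0e-8, 5.0e-5], min_snps: 10}
analysis: {seed: 8, n_boot: 300, n_sim: 500}
output_dir: out/
EOF
mrmediate pipeline config.yaml
```

which prints

```
forward 1 rows, reverse 1 rows, mediation 1 rows
```

`out/forward_screening.tsv` then holds the screened exposure row
(sample sizes of 300k per trait give strong instruments, so the total
effect is recovered close to the generative 0.5):

```
exposure  n_snp  method_primary  beta    OR      F
taxon     72     ivw_fe          0.5048  1.657   361.7
```

and `out/mediation_results.tsv` the decomposition for the screened
triple — total effect, MVMR direct effect, their difference, and the
proportion mediated in percent (generative truth: 0.5, 0.35, 0.15,
30%):

```
exposure  mediator  total_beta  direct_beta  indirect  proportion_pct
taxon     immune    0.5048      0.3446       0.1602    31.74
```

(At the default sample sizes, which mirror the real consortium panels —
18,340 for the microbiota exposure, 3,757 for the immune mediator — the
mediator GWAS yields no significant instruments and the mediation table
is empty; detecting mediation at that scale is underpowered, which the
simulator reproduces faithfully.)

Estimates are reported on the log-odds scale together with the odds
ratio and 95% CI; the primary method per row is routed by the
diagnostics (Egger under a significant Egger intercept, random-effects
IVW under heterogeneity, fixed-effect IVW otherwise), and p-values are
Bonferroni-corrected within each taxonomic level.

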
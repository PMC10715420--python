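# Methods

## Scope and data model

`mrmediate` performs two-sample Mendelian randomization (MR) entirely on
GWAS summary statistics: per-SNP effect sizes, standard errors, allele
frequencies and p-values, never individual-level genotypes. The target
study design is a bidirectional univariable MR screen of many exposures
against one binary outcome, a mediator screen, and a two-step mediation
decomposition through multivariable MR (MVMR). All causal effects on the
outcome are on the log-odds scale.

The canonical input is a tab-separated table with ten fields
(variant id, chromosome, 1-based position, effect allele, other allele,
effect-allele frequency, beta, SE, p, N); a column map translates
arbitrary headers. At read time, rows with non-ACGT or identical alleles
(indels, multi-allelics), non-positive SEs, or p-values outside (0, 1]
are dropped with a logged count.

## Harmonization

Exposure and outcome effects must refer to the same effect allele.
Matching is by variant id only; a chromosome/position disagreement logs
a warning but does not drop the SNP, since summary sources often differ
in genome build. For each shared SNP the first exposure's allele pair is
the reference:

- identical pair → keep; swapped pair → negate the other study's beta
  and complement its EAF (row flagged `flipped`);
- strand-complement pair → complement, then re-compare;
- palindromic pairs (A/T, C/G) are oriented by allele frequency: if
  either study's EAF lies inside the ambiguity window (default
  [0.42, 0.58]) or is missing, the SNP is dropped as irrecoverably
  ambiguous; otherwise the orientation placing both EAFs on the same
  side of 0.5 wins. A `drop` mode discards all palindromic SNPs.

The window default is the conventional one; the source datasets only
require frequencies "close to 0.5" to be treated as ambiguous, so the
window is exposed as configuration. The audit invariant
`retained + palindromic drops + mismatch drops = shared variants` is
enforced by tests.

## Instrument selection

Candidates are SNPs with p below a significance ladder entry (default
5×10⁻⁸, then 5×10⁻⁵), choosing the most stringent rung yielding at
least `min_snps` (default 20) candidates and falling back to the last
rung with a warning. Clumping is greedy by ascending p (ties broken
lexicographically on variant id for determinism): a SNP is kept iff its
LD r² with every kept SNP on the same chromosome within the window
(default 10,000 kb) is ≤ `r2_max` (default 0.01). The LD matrix is an
input; without one, all candidates are kept and the instrument set is
flagged `independence_assumed`.

Instrument strength: per-SNP R² = t²/(t² + N − 2) with t = γ̂/σ̂_γ — a
quantity computable from summary statistics alone — summed over the
clumped set. Two F-statistic variants are provided:
`paper` F = R²·[(N−1−k)/k]·(1−R²) and the textbook
`standard` F = [R²/(1−R²)]·[(N−1−k)/k]. The first reproduces the
formula as printed in applied reports of this design, the second is the
usual one and dominates it for all R² > 0; both remain user-visible
because neither can be inferred from the other's output alone. Default
is `paper` for reproduction; `standard` is recommended for new analyses.

## Estimators

Rows with γ̂ = 0 have undefined Wald ratios and are excluded with a
logged count. All estimators canonically sort rows by variant id first,
so every result is invariant to input row order (bitwise, given a seed).

- **IVW** is the weighted regression of Γ̂ on γ̂ through the origin with
  weights 1/σ_Γ². The random-effects flavour is multiplicative: SE
  scaled by √(Q/(J−1)), floored at 1 (additive random effects is out of
  scope); p-values are two-sided normal.
- **MR-Egger** first orients each SNP so γ̂ ≥ 0, then fits weighted
  least squares with intercept. SEs carry a multiplicative
  overdispersion factor φ̂ = max(1, RSS_w/(J−2)); slope and intercept
  use t(J−2) reference distributions. Requires J ≥ 3 and non-constant
  |γ̂|. A diagnostic `intercept=False` mode reduces exactly to IVW
  (regression-nesting check).
- **Weighted median**: per-SNP ratios ordered ascending with normalized
  weights γ̂²/σ_Γ²; the estimate linearly interpolates the ratio at
  cumulative weight midpoint 0.5. The SE is the SD of the estimate over
  `n_boot` (default 1000) parametric resamples of (γ̂, Γ̂); the seed is
  mandatory in the pipeline.
- **Cochran's Q** uses ratio weights (γ̂/σ_Γ)², χ²(J−1) reference.
- **MR-PRESSO**: the observed statistic is the weighted RSS of each Γ̂ⱼ
  about its leave-one-out IVW prediction. The null distribution draws
  γ*ⱼ ~ N(γ̂ⱼ, σ_γⱼ²) and Γ*ⱼ ~ N(γ̂ⱼβ̂₍₋ⱼ₎, σ_Γⱼ²) and recomputes the
  statistic with leave-one-out slopes re-estimated per draw (default
  1000 draws). Per-SNP outliers: empirical tail probability of the j-th
  residual contribution, Bonferroni-compared to α across SNPs. With
  outliers present, the corrected estimate is IVW on the outlier-free
  set, and the distortion p compares the observed shift in β̂ against
  shifts from removing equally many randomly chosen non-outlier SNPs.

Odds ratios and CIs are exp-transformed Wald intervals; rounding to two
decimals happens only at presentation. The helper `se_from_or_p`
inverts a printed (OR, p) pair to the implied Wald SE, which is how the
worked-example CIs are reconstructed.

## MVMR, mediation, routing, multiplicity

MVMR regresses Γ̂ on the matrix of exposure effects (no intercept,
weights 1/σ_Γ², overdispersion floored at 1, normal p-values). A
rank-deficient design — including an exactly zero mediator column — is
a collinearity error naming the exposures rather than a silent
pseudo-inverse fit. The MVMR instrument set is the union of the
exposure's and mediator's own instruments, re-clumped jointly by the
smaller of the two association p-values (union is standard MVMR
practice).

Mediation uses the difference method: indirect = total − direct,
proportion = indirect/total, exactly additive by construction. The
two-step product (exposure→mediator × mediator→outcome) is emitted
under a separate column as a cross-check; in valid-instrument
simulations the two agree in expectation. Proportions outside [0, 1]
(inconsistent mediation) are reported verbatim with
`sign_consistent = False`, never truncated. A proportion is undefined
when the total effect is zero — that row errors and is flagged by the
pipeline, not fatal.

Primary-estimate routing follows the sensitivity diagnostics:
significant Egger intercept (directional pleiotropy) → Egger slope;
else significant Q (heterogeneity) → random-effects IVW; else
fixed-effect IVW. Mediator screening keeps (exposure, mediator) triples
with all three paths nominally significant at α = 0.05 (screening is at
unadjusted p, matching common practice in this design). Bonferroni
correction is applied within each taxonomic level,
p_adj = min(1, p·m_level), with the per-level m supplied in config (or
defaulted to the number of taxa tested at that level in the run).

## The simulator

`simulate_chain` generates one shared variant panel for the three
traits (complete overlap — the harmonization path the pipeline
exercises), with per SNP: EAF ~ Uniform(0.05, 0.5); true exposure
effects γⱼ ~ N(0, gamma_sd²) (default 0.05); mediator effects
mⱼ = α·γⱼ plus the mediator's own instruments (default 20 SNPs with
zero exposure effect — these make the MVMR design identifiable);
outcome effects Γⱼ = θ_d·γⱼ + θ_m·mⱼ + πⱼ. Observed effects add
independent N(0, sⱼ²) noise with sⱼ = 1/√(2·N·EAF(1−EAF)); binary
outcome effects are generated directly on the log-odds scale rather
than via individual-level logistic simulation, since summary-level MR
consumes exactly these quantities. Default sample sizes mirror the
motivating data sources: 18,340 (microbiome consortium), 3,757
(immune-trait panel), 365,946 (biobank case+control total). Note the
SE formula treats N as an effective sample size; for a heavily
imbalanced case-control study the appropriate effective N
(4/(1/cases + 1/controls)) is far smaller than the total, so
power analyses at the biobank defaults are optimistic in precision.

Pleiotropy offsets πⱼ are carried by a configurable invalid fraction of
the exposure instruments: `balanced` ~ N(0, sd²); `directional` ~
sign(γⱼ)·N(mean, sd²), i.e. applied in the orientation of each SNP's
exposure-increasing allele. This is the frame in which directional
pleiotropy does not cancel across SNPs of opposite sign, InSIDE holds
(offsets independent of |γ|), and the Egger intercept is interpretable;
with symmetric unoriented offsets, IVW would be asymptotically unbiased
and the Egger contrast vacuous. Allele pairs are drawn from
non-palindromic pairs only, so simulation studies are not silently
thinned by the ambiguity rule. `make_ld_blocks` produces block-diagonal
r² with within-block r²(i,j) = ρ^(2|i−j|) for exercising the clumping
rule. `simulate_study` extends the chain to a multi-exposure,
multi-mediator study over disjoint instrument blocks (one chromosome
per block), with even-indexed exposures carrying a real effect routed
through one mediator and odd-indexed exposures as pure nulls.

What the simulator does **not** emulate: sample overlap between
studies, winner's curse from in-sample instrument discovery, real-genome
LD structure, allele-coding errors, population stratification, or
non-linear exposure effects. Passing recovery tests therefore
demonstrates correctness of the estimators under their own assumptions,
not robustness to those real-data pathologies.

## Validation scenarios and problem sizes

The acceptance checks (test suite and `scripts/acceptance.py`) use
these scenario scales, chosen to separate the statistical property
under test from finite-sample noise while keeping desk-scale runtimes:

- **Q calibration**: J = 20, null chain, N_exposure = 10⁶,
  N_outcome = 10⁴, 2000 replicates. The large exposure-to-outcome
  precision ratio makes the exposure-side measurement error (which the
  Q weights ignore) negligible — Q's nominal calibration is only
  expected in that regime; at equal precisions Q over-rejects by
  construction.
- **Chain recovery**: truth (θ_d, α, θ_m) = (0.35, 0.3, 0.5), J = 100,
  N = 5×10⁵ per trait, 500 replicates — mean total ≈ 0.5, mean MVMR
  direct ≈ 0.35, mean proportion ≈ 30%.
- **MR-PRESSO**: 20 SNPs, two implanted outliers at +10σ_Γ, 1000 null
  draws, 100 replicates per scenario.
- **Egger vs IVW**: J = 200, 30% invalid with directional offsets
  N(0.02, 0.02²), 500 replicates.
- **Weighted median**: J = 100, 40% invalid with directional offsets
  N(0.1, 0.05²), gamma_sd = 0.3, N_outcome = 2×10⁵, 500 replicates.
  The weighted-median bias shrinks with the spread of the *valid*
  ratios (σ_Γ/γ), not with J, so this scenario uses strong instruments.
- **Determinism**: a 10-exposure, 5-mediator study run twice and
  compared byte for byte (weighted-median bootstrap 300, PRESSO draws
  500 in the pipeline configs used for this check).

## Numerical choices and degenerate inputs

- WLS fits solve the weighted normal equations directly (J is at most
  a few hundred; no need for QR), with explicit rank checks.
- Clumping ties on p break lexicographically by variant id;
  estimators sort rows canonically before any seeded resampling, so
  results are order-invariant and reruns bitwise-identical.
- Sub-seeds for weighted-median/PRESSO inside the pipeline are derived
  from the run seed and a per-trait tag via CRC-32, keeping every seed
  below 2³¹ and independent of execution order.
- Zero-γ̂ rows are excluded from ratio-based estimators (logged);
  all-equal ratios give Q = 0 and identical FE/RE estimates; an exact
  affine fit gives Egger RSS 0 with the dispersion floor keeping SEs
  finite.
- Output TSVs are written with a fixed `%.10g` float format so that
  identical runs produce identical bytes.

## Known limitations

- No Steiger directionality filtering, mode-based estimators, MR-RAPS,
  or correlated-instrument generalized IVW.
- No proxy-SNP lookup, liftover, or VCF parsing; LD must be supplied as
  a matrix, never computed from genotypes.
- Mediators are decomposed one at a time; no joint multiple-mediator
  model.
- The mediation proportion is reported as a point estimate; its
  sampling uncertainty (e.g. by bootstrap over total/direct) is not
  part of the output contract.
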
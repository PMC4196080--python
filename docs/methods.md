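# Methods

## The analysis model

Every association in the package is a binary logistic regression fitted by
iteratively reweighted least squares (IRLS/Newton-Raphson) with Wald
inference. For a single SNP the model is the additive dosage model

    logit P(case) = b0 + b1 · d,        d ∈ [0, 2],

where d is the expected effect-allele count (fractional under imputation);
for the score it is the same model with the weighted-mean score as
predictor. Standard errors come from the observed information at the
optimum, p-values from the two-sided normal reference for b/SE — the
convention of SNP-level GWAS reporting and of forest plots, in preference
to likelihood-ratio tests.

Convergence contract: iteration stops when the log-likelihood improves by
less than 1e-10, capped at 50 iterations, with monotonicity enforced by
step-halving. Separation is detected by any of (i) perfect prediction
(max |y − μ| < 1e-8), (ii) a standardized coefficient |b·sd(x)| exceeding
30, (iii) a singular or overflowing information matrix; each raises a
`SeparationError` rather than returning a garbage fit. Rank-deficient
designs and single-class outcomes are rejected up front.

Multi-region studies are analysed per stratum and pooled by fixed-effects
inverse-variance meta-analysis: pooled b = Σ(b_i/se_i²)/Σ(1/se_i²),
pooled se = 1/√Σ(1/se_i²), heterogeneity by Cochran's Q on k−1 df and
I² = max(0, (Q−df)/Q)·100. Fixed effects only: the use case is a single
combined estimate over regions assumed to share one true effect; a
random-effects model is deliberately out of scope. All 95% CIs use the
fixed quantile 1.959964 for bit-stable output.

## The telomere score

The score is a weighted mean of dosages, Σw·d/Σw, taken after orienting
every SNP to its telomere-*lengthening* allele (d → 2−d and w → −w where
w < 0). The phrase "weighted mean" is ambiguous when weights carry signs;
the oriented form is well defined, bounded in [0, 2], and monotone in
genetically predicted telomere length. The choice of mean over sum is an
affine rescaling, and a test asserts that z and p are identical under
either choice, so nothing inferential hangs on it.

Missing dosages are mean-imputed per SNP (per stratum when a cohort is
supplied) by default, so every sample receives a score; a `strict` policy
that refuses missing data is available. Mean imputation is exact on
complete data (a test asserts the no-op). Per-SNP association tests,
by contrast, drop incomplete samples for that SNP — unbiased under the
missing-completely-at-random mechanism the simulator produces.

Quartile analysis cuts the score at its pooled empirical quartiles
(cases + controls; whether the original analysis used controls-only
boundaries is unknowable from the available description, and pooled
boundaries are deterministic from the data at hand). Ties at a boundary go
to the lower quartile. Per-quartile ORs come from a logistic fit on
quartile indicators with the lowest quartile as reference; the trend test
regresses status on quartile index 1..4.

## The synthetic cohort generator

The generator emulates a nine-region retrospective case-control study of
melanoma with the seven telomere-length instrument SNPs:

- **Genotypes** are independent draws from Hardy-Weinberg proportions at
  the published MAFs. The seven loci are treated as unlinked (they sit on
  seven chromosomes), so no LD is modelled.
- **Latent telomere trait** T = Σ β_i(d_i − 2p_i) + c_T·U + ε with
  ε ~ N(0, σ_ε), σ_ε chosen in closed form so the SNPs explain exactly
  1.2% of Var(T) in the confounder-free model — the published variance
  fraction for these loci — making power at simulated scale commensurate
  with the real study. With the default weights σ_ε ≈ 1.00, so T is
  effectively in SD units.
- **Disease** follows logit P(case) = α_s + γ·T + c_D·U. The default
  γ = 1.0 per trait-SD places the induced per-SNP melanoma log-ORs in the
  regime of the published per-SNP effects (e.g. the induced marginal
  *TERC* log-OR is −0.083 against a published −0.079). Baseline log-odds
  default to α = −1.5 in every stratum (≈18% population risk): the real
  per-region baselines are not published, and this level keeps rejection
  sampling cheap while leaving odds ratios near risk ratios.
- **Ascertainment** is rejection sampling to fixed per-stratum quotas
  (cases and controls split as evenly as possible across strata, the
  published per-region sizes being unavailable), matching retrospective
  sampling so the logistic model's odds ratios remain the estimand. An
  unattainable quota raises a descriptive error after a bounded number of
  draws.
- **Confounding**: U ~ N(0,1) is shared between trait (c_T) and disease
  (c_D) — the simplest structure exhibiting the bias a genetic instrument
  is supposed to evade. Genotypes are drawn before U acts, and a test
  asserts their sample correlation with U is null.
- **Reverse causation** adds δ to the *measured* trait in cases only;
  genotypes and the latent trait are untouched, encoding the fact that
  germline variation predates disease.
- **Imputation noise**: `dosage_noise` ρ ∈ (0,1] is an INFO-score
  analogue. A noisy read-out s = g + N(0, σ) is drawn and the HWE-prior
  posterior mean E[g|s] returned as the dosage; σ is solved by bisection
  so Var(d)/Var(g) = ρ, which for posterior means equals corr²(d, g).
  Dosages are therefore in [0, 2] by construction with mean 2·MAF. The
  latent trait is built from the hard genotypes; noise degrades only what
  is observed.

What the generator does *not* emulate: linkage disequilibrium, covariate
structure (the published weights are already age- and sex-adjusted
upstream, so no age/sex simulation), population stratification,
non-random missingness, genotyping batch effects, and per-region
heterogeneity of the true effect. Passing tests therefore certify the
statistical machinery under the stated generative model, not robustness
to those real-data complications.

## Exact estimands and non-collapsibility

A marginal logistic regression of disease on the score targets a smaller
coefficient than the conditional γ·Σw: the residual trait noise γ·ε acts
as an omitted covariate, and odds ratios do not collapse over it (the
attenuation is ≈ 0.86 at defaults). Recovery and CI-coverage experiments
must therefore compare against the *marginal* estimand, not γ·Σw — at
full study scale the difference is worth ≈1.2 standard errors and would
by itself push 95% CI coverage to ≈0.78.

`induced_effects` computes these estimands exactly rather than by a
reference mega-simulation: the 3⁷ genotype combinations are enumerated
with their HWE probabilities, the normal noise channel (variance
γ²σ_ε² + (γc_T + c_D)²) is integrated by 64-point Gauss-Hermite
quadrature, and the probability limit of each case-control logistic fit
is obtained by solving the weighted maximum-likelihood equations on the
enumerated table, with weights given by the case-control sampling law
(case rows weighted by the case fraction times P(combo|case), control
rows analogously). The computation is deterministic, assumes perfectly
observed dosages and a common baseline α across strata, and is itself
validated against a 120,000-sample Monte Carlo fit in the test suite.
`TruthRecord` carries both the conditional products γ·β_i (the
pure-mediation bookkeeping) and these marginal estimands.

## Allele harmonization

Weight-file SNPs are matched to the dosage source by rsID first, then by
chrom:pos. Allele pairs are compared allowing a strand complement:
`match`, `allele_flip` (d → 2−d), `strand_flip`, and
`strand_flip_and_allele_flip` are resolved deterministically; palindromic
(A/T, C/G) SNPs are oriented by frequency concordance only when both the
weight MAF and the observed minor-allele frequency are below 0.4
(conservative standard practice), else dropped; unmatched SNPs are
dropped and every weight-file SNP is accounted for exactly once in the
report. Plain dosage TSVs carry no allele metadata and are trusted as
already coded to the effect allele. After harmonization the
coded-frequency vs weight-MAF delta is reported, and deltas above 0.2
warn — never silently. Coordinates are 1-based throughout (native to
VCF). Harmonizing an already-harmonized matrix is the identity, and
recoding (d, w) → (2−d, −w) leaves |z| and p unchanged end to end; both
are asserted to 1e-12.

## Numerical and design notes

- The bundled weight table takes the published minor allele as the effect
  allele for both the telomere and melanoma effect columns (no separate
  effect-allele column is published); the non-effect alleles are the
  variants' standard reference alleles. None of the seven pairs is
  palindromic, so default-set harmonization never depends on the
  frequency rule.
- Effect-vector comparison: Pearson r with the exact t-transform
  p (t = r√(n−2)/√(1−r²), n−2 df). Zero betas count as sign-discordant —
  a deterministic rule for a qualitative measure. The published
  correlation p for these vectors is slightly smaller than the
  t-transform on the rounded printed betas yields (unrounded inputs or a
  different test upstream); the correlation itself, not that p, is the
  reproduced quantity.
- McFadden pseudo-r² = 1 − ll/ll₀, computed only on converged fits.
- Determinism: a `SimulationConfig` (including seed) maps to bit-identical
  outputs; the pipeline manifest records SHA-256 checksums of every
  artifact and double-runs are checksum-identical.
- Problem sizes in the test suite: study-scale experiments use the full
  25,041-sample design (250 replicates for bias/coverage/power);
  calibration experiments use 5,000-sample single-stratum cohorts
  (1000 replicates for type-I error at the per-SNP and score level, 500
  for each immunity scenario); the variance-fraction and HWE self-checks
  use 100,000–200,000 draws. These sizes give binomial/normal error bars
  comfortably inside the asserted tolerances.

## Known limitations

- Fixed-effects pooling only; heterogeneous true effects across regions
  would need a random-effects extension.
- The covariate interface on per-SNP tests accepts a numeric matrix but no
  formula machinery; the default analysis is covariate-free.
- `induced_effects` enumerates 3^k genotype combinations and is intended
  for instrument-sized panels (k ≲ 10), not genome-wide scores.
- The harmonizer handles biallelic SNPs only and performs no liftover
  between genome builds.
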
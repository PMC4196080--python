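# telogrs

Telomere-length genetic scores and case-control association analysis for
melanoma risk.

## The problem

Measured telomere length correlates with the risk of several cancers, but a
measured trait is a treacherous exposure: shared environment (e.g. UV
exposure) can drive both telomere attrition and melanoma, and disease or its
treatment can itself alter telomere length (reverse causation). Germline
variants that shift telomere length are assigned at conception, before either
mechanism can act, so a *genetic score* built from telomere-length SNPs is an
instrument whose disease association cannot be explained by either bias.

`telogrs` implements that analysis end to end for epidemiologists and
statistical geneticists:

- per-SNP additive-dosage logistic regression (case/control ~ dosage),
  stratified by geographic region and pooled by inverse-variance
  fixed-effects meta-analysis with Cochran's Q and I²;
- a weighted telomere genetic score over seven published instrument SNPs
  (*TERC*, *TERT*, *NAF1*, *OBFC1*, *ZNF208*, *RTEL1*, *ACYP2*):
  after orienting every SNP to its telomere-lengthening allele so that all
  weights w_i > 0,

      score_j = Σ_i w_i d_ij / Σ_i w_i ,   d_ij ∈ [0, 2],

  with the w_i the published per-allele telomere-length effects;
- quartile-of-score odds-ratio profiles with a linear trend test, McFadden's
  pseudo-r², and effect-vector summaries (Pearson correlation between
  telomere and disease effect vectors, sign concordance);
- allele harmonization between weight files and dosage sources (VCF with DS
  or GT, or plain TSV), including strand flips and frequency-based handling
  of palindromic SNPs;
- a synthetic-cohort generator with a latent telomere trait, case-control
  ascertainment, and explicit shared-confounder and reverse-causation
  scenarios, calibrated so the seven instrument SNPs explain 1.2% of trait
  variance — plus *exact* large-sample estimands of every regression the
  package runs, computed by genotype enumeration (see
  `telogrs.synthetic_cohort.induced_effects`).

## Worked example

```python
import telogrs as tg

config = tg.SimulationConfig(seed=2026)          # 11,108 cases / 13,933 controls, 9 regions
dosages, cohort, truth = tg.simulate_cohort(config)
score = tg.compute_score(dosages, list(config.snps))
per_region, meta = tg.score_association(score, cohort)
print(f"combined: beta = {meta.beta:.4f} (SE {meta.se:.4f}), z = {meta.z:.2f}, p = {meta.p:.3g}")
print(f"heterogeneity: Q = {meta.q:.2f} on {meta.df} df, I^2 = {meta.i2:.1f}%")
```

prints

```
combined: beta = 0.4939 (SE 0.0563), z = 8.77, p = 1.84e-18
heterogeneity: Q = 8.21 on 8 df, I^2 = 2.5%
```

The pooled log-OR is the precision-weighted average of the nine per-region
score coefficients: at this sample size a score effect of the calibrated
magnitude is detected far below genome-wide thresholds, and the low I² says
the nine regions tell one consistent story. The matching quartile analysis
(`examples/03_quartile_risk_profile.py`) gives a top-vs-bottom quartile OR
of 1.27 [1.19, 1.36] with trend p = 3.7e-10 — samples in the highest score
quartile carry roughly 1.3 times the odds of melanoma of those in the
lowest, even though the score explains only ~0.2% of risk variation by
McFadden's pseudo-r².

The `examples/` directory holds one short narrative script per capability:

| script | what it shows |
| --- | --- |
| `01_published_effect_table.py` | recomputes the published table-level summaries (Pearson r = 0.92 between effect vectors, 6/7 sign concordance, 4/7 SNPs at p < 0.05) |
| `02_simulate_score_and_meta.py` | study-scale simulation, per-region fits, forest table, pooled estimate |
| `03_quartile_risk_profile.py` | quartile ORs and the linear trend test |
| `04_confounding_and_reverse_causation.py` | why the score is immune to the two biases that plague measured-telomere studies |

A thin CLI mirrors the stages (`telogrs simulate / harmonize / assoc /
score / meta / report / run-all`); `telogrs run-all --seed 1 --out out/`
writes every intermediate plus a checksummed manifest.

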
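"""Simulate a multi-region case-control study and test the telomere score.

Generates a nine-region cohort at the full study scale (11,108 cases /
13,933 controls) under the default causal model, computes the weighted
telomere score, fits the score-disease logistic regression per region,
and pools the regions by fixed-effects meta-analysis — the analysis
sequence behind a forest plot of score effects with a combined diamond.
"""

import telogrs as tg
from telogrs.assoc_core import fit_logistic, mcfadden_r2
from telogrs.meta_analysis import forest_table

import numpy as np

config = tg.SimulationConfig(seed=2026)  # study-scale defaults
dosages, cohort, truth = tg.simulate_cohort(config)
score = tg.compute_score(dosages, list(config.snps))
per_region, meta = tg.score_association(score, cohort)

print(forest_table(meta).to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"\ncombined: beta = {meta.beta:.4f} (SE {meta.se:.4f}), z = {meta.z:.2f}, "
      f"p = {meta.p:.3g}")
print(f"heterogeneity: Q = {meta.q:.2f} on {meta.df} df, I^2 = {meta.i2:.1f}%")
print(f"exact large-sample estimand of this regression: {truth.score_logor_marginal:.4f}")

X = np.column_stack([np.ones(score.values.size), score.values])
r2 = mcfadden_r2(fit_logistic(cohort.status, X))
print(f"McFadden pseudo-r^2 of the score: {100 * r2:.3f}%")
print("\nThe pooled log-OR is positive (longer genetically predicted telomeres "
      "-> higher melanoma risk), consistent across regions (low I^2), highly "
      "significant at this scale, yet explains well under 1% of risk variation.")
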
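"""Quartile-of-score risk profile with a linear trend test.

Simulates a study-scale cohort, splits samples into quartiles of the
telomere score (pooled boundaries, ties to the lower quartile), and
estimates each quartile's odds ratio against the lowest quartile plus a
per-quartile linear trend.
"""

import telogrs as tg

config = tg.SimulationConfig(seed=11)
dosages, cohort, _ = tg.simulate_cohort(config)
score = tg.compute_score(dosages, list(config.snps))
q = tg.quartile_analysis(score, cohort)

print(q.to_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\nboundaries: {', '.join(f'{b:.3f}' for b in q.boundaries)}")
print(f"trend: log-OR per quartile = {q.trend_beta:.4f} "
      f"(SE {q.trend_se:.4f}), p = {q.trend_p:.3g}")
print(f"top-vs-bottom quartile OR = {q.odds_ratios[-1]:.3f} "
      f"[{q.ci_low[-1]:.3f}, {q.ci_high[-1]:.3f}]")
print("\nA monotone rise in odds ratios across quartiles — with the top "
      "quartile around 1.2-1.4x the risk of the bottom — is the pattern a "
      "linear score effect of this magnitude produces.")
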
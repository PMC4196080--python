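"""Why the genetic score is immune to confounding and reverse causation.

Two null-effect scenarios (gamma = 0, so genes truly do nothing to
disease) in which a naive measured-telomere analysis goes wrong while
the genetic-score test stays null:

* a shared environmental confounder (think UV exposure) pushes both the
  measured trait and disease risk;
* reverse causation shifts the measured trait in cases only (disease or
  its treatment altering telomere length).

Germline genotypes are fixed before either mechanism acts, so the score
inherits neither bias — the core of the instrument argument.
"""

import numpy as np

import telogrs as tg
from telogrs.assoc_core import fit_logistic


def trait_and_score_z(config):
    dosages, cohort, _ = tg.simulate_cohort(config)
    mt = cohort.measured_telomere
    fit = fit_logistic(cohort.status, np.column_stack([np.ones(mt.size), mt]))
    score = tg.compute_score(dosages, list(config.snps))
    _, meta = tg.score_association(score, cohort)
    return fit.coef[1] / fit.se[1], meta.z


base = dict(n_cases=5000, n_controls=5000, n_strata=1, gamma=0.0)

z_trait, z_score = trait_and_score_z(tg.SimulationConfig(**base, seed=1))
print(f"no bias mechanism:   measured-trait z = {z_trait:+.2f}   score z = {z_score:+.2f}")

z_trait, z_score = trait_and_score_z(
    tg.SimulationConfig(**base, confounder_strength=(0.5, 0.5), seed=2)
)
print(f"shared confounder:   measured-trait z = {z_trait:+.2f}   score z = {z_score:+.2f}")

z_trait, z_score = trait_and_score_z(
    tg.SimulationConfig(**base, reverse_causation_delta=0.5, seed=3)
)
print(f"reverse causation:   measured-trait z = {z_trait:+.2f}   score z = {z_score:+.2f}")

print("\nIn both biased scenarios the measured-trait association is wildly "
      "significant despite a zero causal effect, while the genetic-score z "
      "stays near the null — a score association therefore cannot be "
      "explained by either mechanism.")
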
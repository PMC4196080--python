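"""Fixed-effects inverse-variance meta-analysis across geographic strata.

Per-stratum log-OR estimates are pooled with weights 1/SE^2 — the
precision-weighted average that is the maximum-likelihood combination
under a common true effect.  Between-stratum heterogeneity is summarized
by Cochran's Q (chi-squared with k-1 df under homogeneity) and
I^2 = max(0, (Q - df)/Q) * 100, the percentage of variation across
strata attributable to heterogeneity rather than chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_core import AssocResult
from .errors import TelogrsError

__all__ = ["MetaResult", "ivw_fixed", "forest_table", "forest_plot", "Z_95"]

#: normal 97.5% quantile used for all 95% CIs (fixed for bit-stable output).
Z_95 = 1.959964


@dataclass
class MetaResult:
    label: str
    beta: float
    se: float
    z: float
    p: float
    q: float | None       # Cochran's Q; None when a single stratum
    df: int
    q_p: float | None
    i2: float | None      # percent
    strata: list[AssocResult]

    @property
    def n_cases(self) -> int:
        return sum(r.n_cases for r in self.strata)

    @property
    def n_controls(self) -> int:
        return sum(r.n_controls for r in self.strata)

    def ci95(self) -> tuple[float, float]:
        return self.beta - Z_95 * self.se, self.beta + Z_95 * self.se

    def to_assoc(self) -> AssocResult:
        """View the pooled estimate as an AssocResult labelled 'combined'."""
        return AssocResult(
            label=self.label,
            stratum="combined",
            beta=self.beta,
            se=self.se,
            z=self.z,
            p=self.p,
            n_cases=self.n_cases,
            n_controls=self.n_controls,
        )


def ivw_fixed(results: Sequence[AssocResult]) -> MetaResult:
    """Inverse-variance fixed-effects pooling of same-label stratum results.

    pooled beta = sum(b_i/se_i^2) / sum(1/se_i^2); pooled se =
    1/sqrt(sum(1/se_i^2)).  With a single stratum the pooled estimate
    equals the input and Q/I^2 are reported as not applicable (None).
    """
    if not results:
        raise TelogrsError("meta-analysis needs at least one stratum result")
    labels = {r.label for r in results}
    if len(labels) > 1:
        raise TelogrsError(f"mixed labels in meta-analysis: {sorted(labels)}")
    b = np.array([r.beta for r in results], dtype=float)
    se = np.array([r.se for r in results], dtype=float)
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise TelogrsError("every stratum SE must be finite and positive")
    wt = 1.0 / se**2
    beta = float(np.sum(wt * b) / np.sum(wt))
    pooled_se = float(1.0 / np.sqrt(np.sum(wt)))
    z = beta / pooled_se
    k = len(results)
    if k == 1:
        q = q_p = i2 = None
    else:
        q = float(np.sum(wt * (b - beta) ** 2))
        q_p = float(stats.chi2.sf(q, k - 1))
        i2 = float(max(0.0, (q - (k - 1)) / q) * 100.0) if q > 0 else 0.0
    return MetaResult(
        label=results[0].label,
        beta=beta,
        se=pooled_se,
        z=float(z),
        p=float(2.0 * stats.norm.sf(abs(z))),
        q=q,
        df=k - 1,
        q_p=q_p,
        i2=i2,
        strata=list(results),
    )


def forest_table(meta: MetaResult) -> pd.DataFrame:
    """Tabular forest-plot data: one row per stratum plus the combined row.

    ``weight`` is each stratum's share of the total meta-analytic weight
    (sums to 1 over the stratum rows); ``box_size`` is proportional to it
    and drives the square sizes in :func:`forest_plot`.
    """
    wt = np.array([1.0 / r.se**2 for r in meta.strata])
    share = wt / wt.sum()
    rows = [
        {
            "stratum": r.stratum,
            "beta": r.beta,
            "se": r.se,
            "ci_low": r.beta - Z_95 * r.se,
            "ci_high": r.beta + Z_95 * r.se,
            "weight": share[i],
            "box_size": share[i],
            "n_cases": r.n_cases,
            "n_controls": r.n_controls,
        }
        for i, r in enumerate(meta.strata)
    ]
    lo, hi = meta.ci95()
    rows.append(
        {
            "stratum": "combined",
            "beta": meta.beta,
            "se": meta.se,
            "ci_low": lo,
            "ci_high": hi,
            "weight": 1.0,
            "box_size": 1.0,
            "n_cases": meta.n_cases,
            "n_controls": meta.n_controls,
        }
    )
    return pd.DataFrame(rows)


def forest_plot(meta: MetaResult, path: str | Path) -> None:
    """Render the forest table: squares sized by weight, diamond for the
    combined estimate, horizontal bars for 95% CIs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = forest_table(meta)
    strata = tab.iloc[:-1]
    comb = tab.iloc[-1]
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(tab) + 1.5))
    ypos = np.arange(len(strata))[::-1] + 1.5
    for y, (_, r) in zip(ypos, strata.iterrows()):
        ax.plot([r.ci_low, r.ci_high], [y, y], color="black", lw=1)
        ax.scatter([r.beta], [y], marker="s", s=60 + 600 * r.box_size, color="#2c5f8a")
    ax.scatter([comb.beta], [0.5], marker="D", s=160, color="#a03030")
    ax.plot([comb.ci_low, comb.ci_high], [0.5, 0.5], color="#a03030", lw=1.5)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(list(ypos) + [0.5])
    ax.set_yticklabels(list(strata.stratum) + ["combined"])
    ax.set_xlabel(f"log odds ratio ({meta.label})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
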
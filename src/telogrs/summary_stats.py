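"""Cross-trait effect-vector comparison and the per-SNP report table.

If the telomere-length loci act on melanoma risk through telomere
biology, their melanoma log-ORs should be proportional to their
telomere-length effects.  Two table-level summaries capture this:
the Pearson correlation between the two effect vectors (with the exact
t-transform p-value on n-2 df) and a sign-concordance count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_core import AssocResult
from .errors import TelogrsError
from .genotype_io import SnpWeight

__all__ = ["EffectComparison", "effect_correlation", "build_table1"]


@dataclass
class EffectComparison:
    n_snps: int
    pearson_r: float
    t_statistic: float
    df: int
    p: float
    n_sign_concordant: int
    discordant_rsids: list[str]

    def to_dict(self) -> dict:
        return {
            "n_snps": self.n_snps,
            "pearson_r": self.pearson_r,
            "t_statistic": self.t_statistic,
            "df": self.df,
            "p": self.p,
            "n_sign_concordant": self.n_sign_concordant,
            "discordant_rsids": list(self.discordant_rsids),
        }


def effect_correlation(
    telomere_betas: np.ndarray,
    melanoma_betas: np.ndarray,
    rsids: Sequence[str] | None = None,
) -> EffectComparison:
    """Pearson correlation and sign concordance of two effect vectors.

    The p-value uses the exact small-sample t-transform
    t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 df, two-sided.  A SNP is
    sign-concordant when sign(telomere beta) == sign(melanoma beta);
    a zero beta counts as discordant (a deterministic rule for a
    qualitative measure).
    """
    x = np.asarray(telomere_betas, dtype=float).reshape(-1)
    y = np.asarray(melanoma_betas, dtype=float).reshape(-1)
    if x.size != y.size:
        raise TelogrsError("effect vectors have different lengths")
    if x.size < 3:
        raise TelogrsError("need at least 3 SNPs for a correlation test")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise TelogrsError("effect vectors must be finite")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise TelogrsError("zero variance in an effect vector")
    n = x.size
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df) / np.sqrt(1 - r**2)
        p = float(2.0 * stats.t.sf(abs(t), df))
    conc = (np.sign(x) == np.sign(y)) & (np.sign(x) != 0)
    ids = list(rsids) if rsids is not None else [f"snp{i + 1}" for i in range(n)]
    discordant = [ids[i] for i in range(n) if not conc[i]]
    return EffectComparison(
        n_snps=n,
        pearson_r=r,
        t_statistic=float(t),
        df=df,
        p=p,
        n_sign_concordant=int(conc.sum()),
        discordant_rsids=discordant,
    )


def build_table1(
    per_snp_assoc: Sequence[AssocResult],
    weights: Sequence[SnpWeight],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP report table: weight-file columns, combined melanoma
    beta/p, and a ``significant`` flag at ``alpha``.

    Every weight-file SNP must have exactly one combined result; the
    number of flagged SNPs is available as ``df.attrs['n_significant']``.
    """
    by_label = {}
    for r in per_snp_assoc:
        if r.label in by_label:
            raise TelogrsError(f"duplicate combined result for {r.label}")
        by_label[r.label] = r
    missing = [w.rsid for w in weights if w.rsid not in by_label]
    if missing:
        raise TelogrsError(f"no combined result for weight-file SNPs: {missing}")
    rows = []
    for w in weights:
        r = by_label[w.rsid]
        rows.append(
            {
                "rsid": w.rsid,
                "chrom": w.chrom,
                "pos": w.pos,
                "effect_allele": w.effect_allele,
                "maf": w.maf,
                "telomere_beta": w.weight,
                "melanoma_beta": r.beta,
                "melanoma_se": r.se,
                "melanoma_p": r.p,
                "significant": r.p < alpha,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_significant"] = int(df["significant"].sum())
    df.attrs["alpha"] = alpha
    return df
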
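"""The weighted telomere genetic score: construction, testing, quartiles.

The score for sample j is a weighted mean of effect-allele dosages over
the instrument SNPs,

    score_j = sum_i w_i * d_ij / sum_i w_i,

computed after orienting every SNP to its telomere-LENGTHENING allele
(where the weight is negative, the dosage is flipped d -> 2-d and the
weight negated), so all weights are positive and the score is bounded in
[0, 2] and increases with genetically predicted telomere length.  The
choice of weighted mean over weighted sum is an affine rescaling and
leaves all association inference unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_core import AssocResult, fit_logistic
from .errors import TelogrsError
from .genotype_io import CohortTable, DosageMatrix, SnpWeight
from .meta_analysis import MetaResult, Z_95, ivw_fixed

__all__ = ["ScoreVector", "QuartileResult", "compute_score", "score_association", "quartile_analysis"]


@dataclass
class ScoreVector:
    """Per-sample weighted telomere score.

    Every sample gets a score: missing dosages are imputed per policy
    before the weighted mean, never silently dropped.  ``n_snps_used``
    counts the SNPs with an observed (non-imputed) dosage per sample.
    """

    sample_ids: np.ndarray
    values: np.ndarray
    n_snps_used: np.ndarray
    orientation_note: str = "weights oriented to telomere-lengthening alleles"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "score": self.values, "n_snps_used": self.n_snps_used}
        )


@dataclass
class QuartileResult:
    """Quartile-of-score risk profile relative to the lowest quartile."""

    boundaries: np.ndarray        # three cut points
    n_cases: np.ndarray           # per quartile, length 4
    n_controls: np.ndarray
    odds_ratios: np.ndarray       # vs Q1; OR[0] == 1 by construction
    ci_low: np.ndarray
    ci_high: np.ndarray
    trend_beta: float             # log-OR per quartile step
    trend_se: float
    trend_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quartile": [1, 2, 3, 4],
                "n_cases": self.n_cases,
                "n_controls": self.n_controls,
                "odds_ratio": self.odds_ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _oriented(dosages: DosageMatrix, weights: Sequence[SnpWeight]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (values, mask, positive weights) with every SNP oriented to
    its lengthening allele; dosage columns follow the weight order."""
    wmap = {w.rsid: w for w in weights}
    missing = [r for r in (w.rsid for w in weights) if r not in set(map(str, dosages.rsids))]
    if missing:
        raise TelogrsError(f"dosage matrix lacks weight-file SNPs: {missing}")
    cols, masks, ws = [], [], []
    for w in weights:
        d, m = dosages.column(w.rsid)
        if w.weight < 0:
            cols.append(2.0 - d)
        else:
            cols.append(d.copy())
        masks.append(m)
        ws.append(abs(w.weight))
    return np.column_stack(cols), np.column_stack(masks), np.array(ws)


def compute_score(
    dosages: DosageMatrix,
    weights: Sequence[SnpWeight],
    missing_policy: str = "mean",
    cohort: CohortTable | None = None,
) -> ScoreVector:
    """Weighted-mean telomere score per sample.

    ``missing_policy``:

    * ``"mean"`` (default) — a missing dosage is replaced by the SNP's
      mean observed dosage, per stratum when a cohort is supplied (the
      replacement is exact on complete data: it changes nothing).
    * ``"strict"`` — any missing dosage is an error.

    Dosages must already be harmonized to the weight file's effect
    alleles.
    """
    if not weights:
        raise TelogrsError("empty weight set: no SNPs to score")
    vals, mask, w = _oriented(dosages, weights)
    n_used = (~mask).sum(axis=1)
    if missing_policy == "strict":
        if mask.any():
            bad = int(mask.any(axis=1).sum())
            raise TelogrsError(f"strict policy: {bad} samples have missing dosages")
    elif missing_policy == "mean":
        vals = _mean_impute(vals, mask, cohort)
    else:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    score = vals @ w / w.sum()
    return ScoreVector(sample_ids=dosages.sample_ids, values=score, n_snps_used=n_used)


def _mean_impute(vals: np.ndarray, mask: np.ndarray, cohort: CohortTable | None) -> np.ndarray:
    if not mask.any():
        return vals
    out = vals.copy()
    groups = (
        [np.ones(vals.shape[0], dtype=bool)]
        if cohort is None
        else [np.asarray(cohort.stratum) == s for s in cohort.strata()]
    )
    for g in groups:
        sub = np.ma.masked_array(vals[g], mask[g])
        means = sub.mean(axis=0)
        means = np.where(np.ma.getmaskarray(means), np.nan, means.filled(np.nan))
        gi = np.flatnonzero(g)
        for j in range(vals.shape[1]):
            mj = mask[gi, j]
            if mj.any():
                if not np.isfinite(means[j]):
                    raise TelogrsError(
                        f"SNP column {j} entirely missing within a stratum; cannot mean-impute"
                    )
                out[gi[mj], j] = means[j]
    return out


def score_association(
    score: ScoreVector,
    cohort: CohortTable,
    per_stratum: bool = True,
) -> tuple[list[AssocResult], MetaResult]:
    """Logistic regression of case status on the score.

    With ``per_stratum`` (the default, mirroring a multi-region
    case-control study) each stratum is fitted separately and pooled by
    fixed-effects meta-analysis; the pooled MetaResult carries the
    headline beta/SE/p.  With ``per_stratum=False`` a single whole-cohort
    fit is returned, wrapped in a one-stratum MetaResult.
    """
    results: list[AssocResult] = []
    strata = cohort.strata() if per_stratum else [None]
    for s in strata:
        keep = np.ones(len(score.values), dtype=bool) if s is None else np.asarray(cohort.stratum) == s
        y = cohort.status[keep]
        x = score.values[keep]
        if np.ptp(x) == 0.0:
            raise TelogrsError(f"score is constant in stratum {s!r}")
        fit = fit_logistic(y, np.column_stack([np.ones(x.size), x]))
        beta, se = float(fit.coef[1]), float(fit.se[1])
        results.append(
            AssocResult(
                label="score",
                stratum="all" if s is None else str(s),
                beta=beta,
                se=se,
                z=beta / se,
                p=float(2.0 * stats.norm.sf(abs(beta / se))),
                n_cases=int(y.sum()),
                n_controls=int((1 - y).sum()),
            )
        )
    return results, ivw_fixed(results)


def quartile_analysis(score: ScoreVector, cohort: CohortTable) -> QuartileResult:
    """Quartile-of-score analysis with a linear trend test.

    Boundaries are the empirical quartiles of the score over ALL samples
    (cases and controls pooled); a score tied with a boundary goes to the
    lower quartile.  Per-quartile odds ratios vs the lowest quartile come
    from a logistic fit on quartile indicators; the trend test regresses
    case status on the quartile index 1..4.
    """
    s = np.asarray(score.values, dtype=float)
    y = cohort.status
    if s.size < 8:
        raise TelogrsError("quartile analysis needs at least 8 samples")
    if np.ptp(s) == 0.0:
        raise TelogrsError("score is constant; quartiles undefined")
    if y.min() == y.max():
        raise TelogrsError("both outcome classes are required")
    bounds = np.quantile(s, [0.25, 0.5, 0.75])
    q = np.searchsorted(bounds, s, side="left")  # ties -> lower quartile
    counts_case = np.array([(y[q == k] == 1).sum() for k in range(4)])
    counts_ctrl = np.array([(y[q == k] == 0).sum() for k in range(4)])

    dummies = np.column_stack([np.ones(s.size)] + [(q == k).astype(float) for k in (1, 2, 3)])
    fit = fit_logistic(y, dummies)
    beta = np.concatenate([[0.0], fit.coef[1:]])
    se = np.concatenate([[0.0], fit.se[1:]])
    trend = fit_logistic(y, np.column_stack([np.ones(s.size), (q + 1).astype(float)]))
    tb, tse = float(trend.coef[1]), float(trend.se[1])
    return QuartileResult(
        boundaries=bounds,
        n_cases=counts_case,
        n_controls=counts_ctrl,
        odds_ratios=np.exp(beta),
        ci_low=np.exp(beta - Z_95 * se),
        ci_high=np.exp(beta + Z_95 * se),
        trend_beta=tb,
        trend_se=tse,
        trend_p=float(2.0 * stats.norm.sf(abs(tb / tse))),
    )
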
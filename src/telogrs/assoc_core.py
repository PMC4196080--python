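"""Maximum-likelihood logistic regression with Wald inference.

This is the engine behind both the per-SNP additive dosage test and the
genetic-score regression: a binary outcome (melanoma case vs control) is
regressed on a dosage or score, by iteratively reweighted least squares
(IRLS, i.e. Newton-Raphson on the log-likelihood).  Inference is Wald:
standard errors come from the observed information at the optimum, and
two-sided p-values from the normal reference for beta/SE, matching how
GWAS per-SNP results and forest plots are conventionally reported.

Fits are deliberately self-contained (a dense solve per Newton step) so
their convergence contract is explicit: iteration stops when the
log-likelihood improves by less than 1e-10, with a hard cap of 50
iterations, and a separation guard rejects fits whose standardized
coefficients diverge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, special, stats

from .errors import ConvergenceError, MonomorphicError, SeparationError, TelogrsError
from .genotype_io import CohortTable

__all__ = ["GlmFit", "AssocResult", "fit_logistic", "snp_association", "mcfadden_r2"]

#: |delta log-likelihood| convergence tolerance.
LOGLIK_TOL = 1e-10
MAX_ITER = 50
#: standardized-coefficient magnitude beyond which separation is declared.
SEPARATION_BOUND = 30.0


@dataclass
class GlmFit:
    """A converged (or not) logistic fit with likelihoods and Wald SEs."""

    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    converged: bool
    iterations: int

    def wald_z(self) -> np.ndarray:
        return self.coef / self.se

    def wald_p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.wald_z()))


@dataclass
class AssocResult:
    """One predictor's association with case status in one stratum."""

    label: str
    stratum: str
    beta: float
    se: float
    z: float
    p: float
    n_cases: int
    n_controls: int

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    def ci95(self) -> tuple[float, float]:
        from .meta_analysis import Z_95

        return self.beta - Z_95 * self.se, self.beta + Z_95 * self.se


def _loglik(y: np.ndarray, eta: np.ndarray, w: np.ndarray | None) -> float:
    # log sigma(eta)*y + log sigma(-eta)*(1-y), numerically safe
    ll = y * eta - np.logaddexp(0.0, eta)
    return float(np.sum(ll if w is None else w * ll))


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    sample_weight: np.ndarray | None = None,
) -> GlmFit:
    """Fit logit P(y=1) = X @ beta by IRLS.

    ``X`` must include an intercept column and have full column rank;
    ``y`` must contain both classes.  Optional non-negative
    ``sample_weight`` scales each observation's log-likelihood
    contribution (used for frequency-weighted fits on enumerated
    genotype tables).

    Raises :class:`SeparationError` when any standardized coefficient
    exceeds 30 or the information matrix degenerates, and
    :class:`TelogrsError` on rank-deficient design.
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise TelogrsError("design matrix and outcome are misaligned")
    if not np.isin(y, (0.0, 1.0)).all():
        raise TelogrsError("outcome must be binary 0/1")
    w = None if sample_weight is None else np.asarray(sample_weight, dtype=float).reshape(-1)
    wsum = float(y.size if w is None else w.sum())
    ybar = float(np.mean(y) if w is None else np.sum(w * y) / wsum)
    if not 0.0 < ybar < 1.0:
        raise TelogrsError("outcome has a single class; logistic fit undefined")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise TelogrsError("design matrix is rank deficient")

    # scale used only by the separation guard: |beta_j| * sd(x_j) <= bound
    sd = X.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)

    p = X.shape[1]
    beta = np.zeros(p)
    # warm start the intercept at the observed log-odds
    intercept_col = np.flatnonzero(np.all(X == X[0], axis=0) & (X[0] != 0))
    if intercept_col.size:
        beta[intercept_col[0]] = np.log(ybar / (1 - ybar)) / X[0, intercept_col[0]]

    eta = X @ beta
    ll = _loglik(y, eta, w)
    null_ll = _null_loglik(y, w, wsum, ybar)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        mu = special.expit(eta)
        if np.max(np.abs(y - mu)) < 1e-8:
            raise SeparationError("model predicts the outcome perfectly; data are separated")
        wvar = mu * (1 - mu)
        if w is not None:
            wvar = w * wvar
        XtW = X.T * wvar
        info = XtW @ X
        grad = X.T @ ((y - mu) if w is None else w * (y - mu))
        try:
            step = linalg.solve(info, grad, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise SeparationError("information matrix is singular (separation?)") from exc
        new_beta = beta + step
        new_eta = X @ new_beta
        new_ll = _loglik(y, new_eta, w)
        # step-halving keeps Newton monotone on badly scaled designs
        halves = 0
        while new_ll < ll - 1e-12 and halves < 20:
            step *= 0.5
            new_beta = beta + step
            new_eta = X @ new_beta
            new_ll = _loglik(y, new_eta, w)
            halves += 1
        beta, eta = new_beta, new_eta
        if np.any(np.abs(beta * scale) > SEPARATION_BOUND):
            raise SeparationError(
                "standardized coefficient exceeded 30; data are (quasi-)separated"
            )
        if abs(new_ll - ll) < LOGLIK_TOL:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    mu = special.expit(eta)
    wvar = mu * (1 - mu)
    if w is not None:
        wvar = w * wvar
    info = (X.T * wvar) @ X
    try:
        cov = linalg.inv(info)
    except linalg.LinAlgError as exc:
        raise SeparationError("information matrix not invertible at optimum") from exc
    se = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(se)):
        raise SeparationError("standard errors overflowed; data are separated")
    return GlmFit(
        coef=beta,
        se=se,
        loglik=ll,
        loglik_null=null_ll,
        n=int(y.size),
        converged=converged,
        iterations=it,
    )


def _null_loglik(y, w, wsum, ybar) -> float:
    return float(wsum * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar)))


def snp_association(
    dosage: np.ndarray,
    cohort: CohortTable,
    label: str,
    stratum: object | None = None,
    missing: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
) -> AssocResult:
    """Additive-model dosage test: logit P(case) = b0 + b1*dosage (+ covariates).

    ``stratum=None`` uses the whole cohort; otherwise only samples from
    the named stratum enter the fit.  Samples with a missing dosage are
    dropped from this SNP's test (missingness is completely at random in
    the simulated data, so the estimate stays unbiased).
    """
    dosage = np.asarray(dosage, dtype=float).reshape(-1)
    keep = np.ones(dosage.size, dtype=bool)
    if stratum is not None:
        keep &= np.asarray(cohort.stratum) == stratum
    if missing is not None:
        keep &= ~np.asarray(missing, dtype=bool)
    d = dosage[keep]
    y = cohort.status[keep]
    if d.size == 0 or np.ptp(d) == 0.0:
        raise MonomorphicError(f"{label}: dosage carries no variation in stratum {stratum!r}")
    cols = [np.ones(d.size), d]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        cols.append(cov[keep].reshape(d.size, -1))
    X = np.column_stack(cols)
    fit = fit_logistic(y, X)
    beta = float(fit.coef[1])
    se = float(fit.se[1])
    return AssocResult(
        label=label,
        stratum="all" if stratum is None else str(stratum),
        beta=beta,
        se=se,
        z=beta / se,
        p=float(2.0 * stats.norm.sf(abs(beta / se))),
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
    )


def mcfadden_r2(fit: GlmFit) -> float:
    """McFadden's pseudo-r-squared, 1 - loglik(model)/loglik(null).

    Lies in [0, 1); 0 for an intercept-only model.  Raises on
    non-converged fits, whose likelihood is not the maximum.
    """
    if not fit.converged:
        raise ConvergenceError("pseudo-r2 requires a converged fit")
    if fit.loglik_null == 0.0:
        return 0.0
    r2 = 1.0 - fit.loglik / fit.loglik_null
    return float(max(r2, 0.0))
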
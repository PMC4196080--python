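"""Synthetic multi-region case-control cohorts with a latent telomere trait.

Generative model
----------------
Genotypes for the seven instrument SNPs are drawn independently under
Hardy-Weinberg proportions at their published minor-allele frequencies.
A latent telomere-length trait is

    T = sum_i beta_i * (d_i - 2*maf_i) + c_T * U + eps,

with U ~ N(0,1) a shared-environment confounder, eps ~ N(0, sigma_eps)
and sigma_eps chosen so that, at the default weights, the seven SNPs
explain 1.2% of Var(T) — the variance fraction these loci explain in
leukocyte telomere length.  Disease follows a logistic model

    logit P(case) = alpha_stratum + gamma * T + c_D * U,

and case-control ascertainment is by rejection sampling: population
individuals are drawn and kept until the per-stratum case and control
quotas fill, mirroring retrospective GWAS sampling so odds ratios retain
their interpretation.  Reverse causation acts on the MEASURED trait only
(T + delta for cases); germline genotypes predate disease and are never
touched.

Because the marginal (score-on-disease) odds ratio in a logistic model
with residual trait noise is attenuated relative to the conditional
coefficient (non-collapsibility), :func:`induced_effects` computes the
exact large-sample estimands of the per-SNP and score regressions by
enumerating all genotype combinations and integrating the noise by
Gauss-Hermite quadrature; these are the right targets for
parameter-recovery and CI-coverage experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import special, stats

from .assoc_core import fit_logistic
from .errors import SimulationError, TelogrsError
from .genotype_io import CohortTable, DosageMatrix, SnpWeight, default_weights

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_genotypes",
    "simulate_population",
    "simulate_cohort",
    "induced_effects",
    "residual_sd",
    "genetic_variance",
    "variance_explained",
    "save_study",
]

#: fraction of latent-trait variance the instrument SNPs explain at default
#: weights (the published figure for these seven loci).
TARGET_GENETIC_VARIANCE_FRACTION = 0.012

#: give up after drawing this many times the requested cohort size.
MAX_DRAW_FACTOR = 2000


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and causal parameters for one simulated cohort.

    ``gamma`` is the causal log-OR of melanoma per unit of the latent
    telomere trait; the default 1.0 makes the induced per-SNP melanoma
    log-ORs approximately equal to the telomere-length weights, the
    regime the published per-SNP effects sit in.  ``alpha_by_stratum``
    are baseline log-odds (default -1.5 everywhere, a ~20% population
    risk that keeps ascertainment sampling cheap while leaving odds
    ratios effectively rare-disease-like).  ``confounder_strength`` is
    (effect of U on T, log-OR of U on disease); ``dosage_noise`` is an
    imputation-quality (INFO-score) analogue in (0, 1], 1 = perfectly
    observed genotypes.
    """

    n_cases: int = 11108
    n_controls: int = 13933
    n_strata: int = 9
    snps: tuple[SnpWeight, ...] = field(default_factory=lambda: tuple(default_weights()))
    gamma: float = 1.0
    alpha_by_stratum: tuple[float, ...] | None = None
    confounder_strength: tuple[float, float] = (0.0, 0.0)
    reverse_causation_delta: float = 0.0
    dosage_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise TelogrsError("n_cases and n_controls must be >= 1")
        if self.n_strata < 1:
            raise TelogrsError("n_strata must be >= 1")
        if not 0.0 < self.dosage_noise <= 1.0:
            raise TelogrsError("dosage_noise must lie in (0, 1]")
        if not np.isfinite(self.gamma):
            raise TelogrsError("gamma must be finite")
        for w in self.snps:
            if not 0.0 < w.maf <= 0.5:
                raise TelogrsError(f"{w.rsid}: MAF outside (0, 0.5]")
        if self.alpha_by_stratum is not None and len(self.alpha_by_stratum) != self.n_strata:
            raise TelogrsError("alpha_by_stratum length must equal n_strata")

    @property
    def alphas(self) -> np.ndarray:
        if self.alpha_by_stratum is None:
            return np.full(self.n_strata, -1.5)
        return np.asarray(self.alpha_by_stratum, dtype=float)


@dataclass
class TruthRecord:
    """Ground truth for parameter-recovery tests.

    ``per_snp_logor`` are the conditional induced log-ORs gamma*beta_i
    under pure mediation; ``per_snp_logor_marginal`` and
    ``score_logor_marginal`` are the exact large-sample estimands of the
    corresponding marginal logistic regressions (attenuated by
    non-collapsibility), computed by :func:`induced_effects`.
    """

    gamma_true: float
    per_snp_logor: dict[str, float]
    per_snp_logor_marginal: dict[str, float]
    score_logor_conditional: float
    score_logor_marginal: float
    confounder_strength: tuple[float, float]
    reverse_causation_delta: float
    genetic_variance_fraction: float
    residual_sd: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        d = dict(self.__dict__)
        d["confounder_strength"] = list(d["confounder_strength"])
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def genetic_variance(snps: Sequence[SnpWeight]) -> float:
    """Variance of the genetic part of T under HWE: sum beta_i^2 * 2pq."""
    return float(sum(w.weight**2 * 2 * w.maf * (1 - w.maf) for w in snps))


def residual_sd(snps: Sequence[SnpWeight], fraction: float = TARGET_GENETIC_VARIANCE_FRACTION) -> float:
    """Residual SD of T such that the SNPs explain ``fraction`` of Var(T)
    in the confounder-free model."""
    vg = genetic_variance(snps)
    return float(np.sqrt(vg * (1.0 / fraction - 1.0)))


def _hard_genotypes(maf: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if not 0.0 < maf <= 0.5:
        raise TelogrsError(f"MAF {maf} outside (0, 0.5]")
    if n < 1:
        raise TelogrsError("n must be >= 1")
    return rng.binomial(2, maf, size=n).astype(float)


def _hwe_probs(maf: float) -> np.ndarray:
    return np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])


@lru_cache(maxsize=256)
def _noise_sigma(maf: float, info: float) -> float:
    """Observation-noise SD such that posterior-mean dosages carry the
    requested INFO score.

    The generative read-out is s = g + N(0, sigma); the posterior mean
    E[g|s] under the HWE prior satisfies Cov(d, g) = Var(d), so
    INFO = Var(d)/Var(g) = corr^2(d, g).  Var(d) is computed by
    quadrature over the 3-component normal mixture marginal of s, and
    sigma solved by bisection (INFO is monotone decreasing in sigma).
    """
    from scipy.optimize import brentq

    probs = _hwe_probs(maf)
    vg = 2 * maf * (1 - maf)

    def achieved(sigma: float) -> float:
        s = np.linspace(-5 * sigma, 2 + 5 * sigma, 4001)
        dens = probs[:, None] * stats.norm.pdf(s[None, :], np.arange(3)[:, None], sigma)
        tot = dens.sum(axis=0)
        ok = tot > 0
        post = np.zeros_like(tot)
        post[ok] = (dens * np.arange(3)[:, None]).sum(axis=0)[ok] / tot[ok]
        m1 = np.trapezoid(tot * post, s)
        m2 = np.trapezoid(tot * post**2, s)
        return (m2 - m1**2) / vg

    # genotype classes are fully resolved at sigma=0.05, so INFO(0.05) ~ 1
    return float(brentq(lambda sg: achieved(sg) - info, 0.05, 100.0, xtol=1e-8))


def _noisy_dosage(g: np.ndarray, maf: float, noise: float, rng: np.random.Generator) -> np.ndarray:
    """Posterior-mean dosage whose squared correlation with the hard
    genotype equals ``noise`` (the INFO-score analogue).

    A noisy read-out s = g + N(0, sigma) is drawn and the HWE-prior
    posterior mean E[g|s] returned; sigma is calibrated by
    :func:`_noise_sigma` so Var(d)/Var(g) = noise.  Posterior means lie
    in [0, 2] by construction and average 2*maf.
    """
    if noise >= 1.0:
        return g
    sigma = _noise_sigma(round(maf, 9), round(noise, 9))
    s = g + rng.normal(0.0, sigma, size=g.shape)
    probs = _hwe_probs(maf)
    dens = probs[None, :] * stats.norm.pdf(s[:, None], np.arange(3)[None, :], sigma)
    return (dens @ np.arange(3)) / dens.sum(axis=1)


def simulate_genotypes(
    maf: float, n: int, dosage_noise: float = 1.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Dosage vector for one SNP: HWE hard genotypes, optionally degraded
    to imputation-like dosages (see :func:`_noisy_dosage`)."""
    if not 0.0 < dosage_noise <= 1.0:
        raise TelogrsError("dosage_noise must lie in (0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    g = _hard_genotypes(maf, n, rng)
    return _noisy_dosage(g, maf, dosage_noise, rng)


def simulate_population(
    config: SimulationConfig, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw ``n`` population individuals (no ascertainment).

    Returns arrays: hard genotypes ``G`` (n x k), observed dosages ``D``,
    latent trait ``T``, confounder ``U``, and case probability ``p`` for
    stratum baseline alpha[0].  The latent trait is built from the hard
    genotypes; dosage noise degrades only what is *observed*.
    """
    snps = config.snps
    mafs = np.array([w.maf for w in snps])
    betas = np.array([w.weight for w in snps])
    G = np.column_stack([_hard_genotypes(m, n, rng) for m in mafs])
    D = np.column_stack(
        [_noisy_dosage(G[:, i], mafs[i], config.dosage_noise, rng) for i in range(len(snps))]
    )
    U = rng.normal(size=n)
    eps = rng.normal(0.0, residual_sd(snps), size=n)
    c_t, c_d = config.confounder_strength
    T = (G - 2 * mafs) @ betas + c_t * U + eps
    eta = config.alphas[0] + config.gamma * T + c_d * U
    return {"G": G, "D": D, "T": T, "U": U, "p": special.expit(eta)}


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[DosageMatrix, CohortTable, TruthRecord]:
    """Simulate one ascertained case-control study.

    Cases and controls are split as evenly as possible across
    ``n_strata`` strata; within each stratum individuals are drawn from
    the population model and kept until both quotas fill.  Identical
    configs (including seed) give bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    snps = config.snps
    k = len(snps)
    mafs = np.array([w.maf for w in snps])
    betas = np.array([w.weight for w in snps])
    sd_eps = residual_sd(snps)
    c_t, c_d = config.confounder_strength
    alphas = config.alphas

    case_quota = _split(config.n_cases, config.n_strata)
    ctrl_quota = _split(config.n_controls, config.n_strata)

    dos_blocks, status_blocks, t_blocks, strat_blocks = [], [], [], []
    for s in range(config.n_strata):
        need_case, need_ctrl = case_quota[s], ctrl_quota[s]
        got_case = got_ctrl = 0
        drawn = 0
        limit = MAX_DRAW_FACTOR * (need_case + need_ctrl) + 100_000
        parts_d, parts_y, parts_t = [], [], []
        while got_case < need_case or got_ctrl < need_ctrl:
            if drawn > limit:
                raise SimulationError(
                    f"stratum {s}: case/control quota unattainable after {drawn} draws "
                    f"(alpha={alphas[s]:.3g}, gamma={config.gamma:.3g})"
                )
            b = int(min(max(4096, 2 * (need_case + need_ctrl)), 200_000))
            drawn += b
            G = rng.binomial(2, mafs, size=(b, k)).astype(float)
            U = rng.normal(size=b)
            eps = rng.normal(0.0, sd_eps, size=b)
            T = (G - 2 * mafs) @ betas + c_t * U + eps
            y = (rng.random(b) < special.expit(alphas[s] + config.gamma * T + c_d * U)).astype(int)
            if config.dosage_noise < 1.0:
                D = np.column_stack(
                    [_noisy_dosage(G[:, i], mafs[i], config.dosage_noise, rng) for i in range(k)]
                )
            else:
                D = G
            take_case = np.flatnonzero(y == 1)[: need_case - got_case]
            take_ctrl = np.flatnonzero(y == 0)[: need_ctrl - got_ctrl]
            take = np.sort(np.concatenate([take_case, take_ctrl]))
            got_case += take_case.size
            got_ctrl += take_ctrl.size
            parts_d.append(D[take])
            parts_y.append(y[take])
            parts_t.append(T[take])
        dos_blocks.append(np.vstack(parts_d))
        status_blocks.append(np.concatenate(parts_y))
        t_blocks.append(np.concatenate(parts_t))
        strat_blocks.append(np.full(need_case + need_ctrl, f"region{s + 1}", dtype=object))

    values = np.vstack(dos_blocks)
    status = np.concatenate(status_blocks)
    latent = np.concatenate(t_blocks)
    measured = latent + config.reverse_causation_delta * status
    n_total = values.shape[0]
    sample_ids = np.array([f"S{i + 1:06d}" for i in range(n_total)], dtype=object)

    dosages = DosageMatrix(
        sample_ids=sample_ids,
        rsids=np.array([w.rsid for w in snps], dtype=object),
        values=values,
        mask=np.zeros_like(values, dtype=bool),
        coded_allele=np.array([w.effect_allele for w in snps], dtype=object),
        other_allele=np.array([w.other_allele for w in snps], dtype=object),
        chrom=np.array([w.chrom for w in snps], dtype=object),
        pos=np.array([w.pos for w in snps], dtype=int),
    )
    cohort = CohortTable(
        sample_ids=sample_ids,
        status=status,
        stratum=np.concatenate(strat_blocks),
        measured_telomere=measured,
    )
    truth = make_truth(config)
    return dosages, cohort, truth


def _split(total: int, k: int) -> np.ndarray:
    base = total // k
    out = np.full(k, base)
    out[: total - base * k] += 1
    return out


# ---------------------------------------------------------------------------
# exact induced effects (large-sample estimands)
# ---------------------------------------------------------------------------


def induced_effects(config: SimulationConfig, gh_points: int = 64) -> dict[str, float]:
    """Exact marginal estimands of the per-SNP and score regressions.

    All genotype combinations over the instrument SNPs are enumerated
    with their HWE probabilities; the normal noise (residual trait noise
    plus any confounder channel) is integrated by Gauss-Hermite
    quadrature; and the large-sample limit of each case-control logistic
    regression is obtained by solving its weighted score equations on
    the enumerated table.  Assumes perfectly observed dosages
    (``dosage_noise=1``) and a common baseline alpha across strata.

    Returns ``{"score": ..., "rs...": ..., "case_fraction_population": ...}``.
    """
    snps = config.snps
    k = len(snps)
    if 3**k > 100_000:
        raise TelogrsError("too many SNPs to enumerate exactly")
    mafs = np.array([w.maf for w in snps])
    betas = np.array([w.weight for w in snps])
    grids = np.array(np.meshgrid(*([np.arange(3)] * k), indexing="ij")).reshape(k, -1).T
    hwe = np.column_stack(
        [np.array([(1 - m) ** 2, 2 * m * (1 - m), m**2]) for m in mafs]
    )  # 3 x k
    probs = np.prod(hwe[grids.astype(int), np.arange(k)], axis=1)

    t_gen = (grids - 2 * mafs) @ betas
    c_t, c_d = config.confounder_strength
    noise_sd = float(
        np.sqrt((config.gamma * residual_sd(snps)) ** 2 + (config.gamma * c_t + c_d) ** 2)
    )
    nodes, wts = np.polynomial.hermite.hermgauss(gh_points)
    x = np.sqrt(2.0) * nodes  # standard-normal nodes
    gw = wts / np.sqrt(np.pi)
    alpha = float(config.alphas[0])
    eta = alpha + config.gamma * t_gen[:, None] + noise_sd * x[None, :]
    p_case = special.expit(eta) @ gw  # per genotype combo

    p_bar = float(probs @ p_case)
    frac_case = config.n_cases / (config.n_cases + config.n_controls)
    w_case = frac_case * probs * p_case / p_bar
    w_ctrl = (1 - frac_case) * probs * (1 - p_case) / (1 - p_bar)
    y = np.concatenate([np.ones(len(probs)), np.zeros(len(probs))])
    wts2 = np.concatenate([w_case, w_ctrl])

    # oriented weighted-mean score for each combo
    w_abs = np.abs(betas)
    oriented = np.where(betas < 0, 2 - grids, grids)
    s = oriented @ w_abs / w_abs.sum()

    out: dict[str, float] = {"case_fraction_population": p_bar}
    xs = np.concatenate([s, s])
    fit = fit_logistic(y, np.column_stack([np.ones(xs.size), xs]), sample_weight=wts2)
    out["score"] = float(fit.coef[1])
    for i, w in enumerate(snps):
        d = np.concatenate([grids[:, i], grids[:, i]]).astype(float)
        fit = fit_logistic(y, np.column_stack([np.ones(d.size), d]), sample_weight=wts2)
        out[w.rsid] = float(fit.coef[1])
    return out


def make_truth(config: SimulationConfig) -> TruthRecord:
    """Assemble the TruthRecord, including exact marginal estimands."""
    snps = config.snps
    marg = induced_effects(config)
    w_sum = float(np.sum(np.abs([w.weight for w in snps])))
    vg = genetic_variance(snps)
    sd_e = residual_sd(snps)
    c_t, _ = config.confounder_strength
    frac = vg / (vg + sd_e**2 + c_t**2)
    return TruthRecord(
        gamma_true=config.gamma,
        per_snp_logor={w.rsid: config.gamma * w.weight for w in snps},
        per_snp_logor_marginal={w.rsid: marg[w.rsid] for w in snps},
        score_logor_conditional=config.gamma * w_sum,
        score_logor_marginal=marg["score"],
        confounder_strength=config.confounder_strength,
        reverse_causation_delta=config.reverse_causation_delta,
        genetic_variance_fraction=frac,
        residual_sd=sd_e,
        seed=config.seed,
    )


def variance_explained(trait: np.ndarray, dosages: np.ndarray) -> float:
    """R-squared of an OLS regression of a quantitative trait on dosage
    columns (with intercept)."""
    X = np.column_stack([np.ones(len(trait)), dosages])
    coef, *_ = np.linalg.lstsq(X, trait, rcond=None)
    resid = trait - X @ coef
    tss = float(np.sum((trait - trait.mean()) ** 2))
    return float(1.0 - np.sum(resid**2) / tss)


def save_study(
    dosages: DosageMatrix,
    cohort: CohortTable,
    truth: TruthRecord,
    outdir: str | Path,
    dosage_format: str = "tsv",
) -> dict[str, Path]:
    """Write a simulated study to disk (dosage TSV or VCF, phenotype TSV,
    truth JSON); returns the paths written."""
    from .genotype_io import write_dosage_tsv, write_dosage_vcf, write_phenotypes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if dosage_format == "tsv":
        paths["dosages"] = outdir / "dosages.tsv"
        write_dosage_tsv(dosages, paths["dosages"])
    elif dosage_format == "vcf":
        paths["dosages"] = outdir / "dosages.vcf"
        write_dosage_vcf(dosages, paths["dosages"])
    else:
        raise ValueError(f"unknown dosage format {dosage_format!r}")
    paths["phenotypes"] = outdir / "phenotypes.tsv"
    write_phenotypes(cohort, paths["phenotypes"])
    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return paths
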
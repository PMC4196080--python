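"""End-to-end orchestration: ingest or simulate, harmonize, test, report.

A run executes the full analysis sequence — per-SNP additive dosage
tests per stratum, fixed-effects meta-analysis, the weighted telomere
score and its association, quartile analysis, and the effect-vector
summaries — writing every intermediate as TSV/JSON plus a manifest with
SHA-256 checksums so identical config+seed yields identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .assoc_core import AssocResult, fit_logistic, mcfadden_r2, snp_association
from .errors import TelogrsError
from .genotype_io import (
    CohortTable,
    DosageMatrix,
    default_weights,
    harmonize,
    read_dosages,
    read_phenotypes,
    read_weights,
)
from .meta_analysis import forest_plot, forest_table, ivw_fixed
from .summary_stats import build_table1, effect_correlation
from .synthetic_cohort import SimulationConfig, simulate_cohort
from .telomere_score import compute_score, quartile_analysis, score_association

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("telogrs")


@dataclass
class RunConfig:
    """One pipeline run: either file inputs or a simulation, never both."""

    weights_path: str | None = None
    dosages_path: str | None = None
    dosage_format: str = "tsv"
    phenotypes_path: str | None = None
    simulation: SimulationConfig | None = None
    outdir: str = "telogrs_out"
    alpha: float = 0.05
    palindromic_maf_limit: float = 0.4
    missing_policy: str = "mean"
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        has_files = self.dosages_path is not None and self.phenotypes_path is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise TelogrsError(
                "exactly one of {dosages+phenotypes paths, simulation config} must be given"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        if sim is not None:
            sim_kwargs = dict(sim)
            if "snps" in sim_kwargs:  # path to a weight file
                sim_kwargs["snps"] = tuple(read_weights(sim_kwargs["snps"]))
            if "confounder_strength" in sim_kwargs:
                sim_kwargs["confounder_strength"] = tuple(sim_kwargs["confounder_strength"])
            if "alpha_by_stratum" in sim_kwargs and sim_kwargs["alpha_by_stratum"] is not None:
                sim_kwargs["alpha_by_stratum"] = tuple(sim_kwargs["alpha_by_stratum"])
            sim = SimulationConfig(**sim_kwargs)
        return cls(simulation=sim, **d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "missing_policy": config.missing_policy,
        "stages": [],
        "outputs": {},
    }
    outputs: dict[str, Path] = {}

    def stage(name: str):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        # -- inputs -------------------------------------------------------
        stage("inputs")
        weights = (
            read_weights(config.weights_path) if config.weights_path else default_weights()
        )
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            manifest["inputs"] = {"simulation": _sim_summary(sim)}
            dosages, cohort, truth = simulate_cohort(sim)
            truth_path = outdir / "truth.json"
            truth.to_json(truth_path)
            outputs["truth"] = truth_path
        else:
            manifest["inputs"] = {
                "weights": config.weights_path or "bundled",
                "dosages": config.dosages_path,
                "phenotypes": config.phenotypes_path,
            }
            dosages = read_dosages(config.dosages_path, format=config.dosage_format)
            cohort = read_phenotypes(config.phenotypes_path)
            dosages, cohort = _align(dosages, cohort)

        # -- harmonization ------------------------------------------------
        stage("harmonize")
        harm, report = harmonize(weights, dosages, config.palindromic_maf_limit)
        outputs["harmonization"] = outdir / "harmonization.tsv"
        report.to_tsv(outputs["harmonization"])
        kept = set(report.kept_rsids)
        weights_kept = [w for w in weights if w.rsid in kept]
        if not weights_kept:
            raise TelogrsError("score stage: no SNPs survived harmonization")

        # -- per-SNP association ------------------------------------------
        stage("assoc")
        per_stratum: list[AssocResult] = []
        combined: list[AssocResult] = []
        for w in weights_kept:
            d, m = harm.column(w.rsid)
            fits = [
                snp_association(d, cohort, label=w.rsid, stratum=s, missing=m)
                for s in cohort.strata()
            ]
            per_stratum.extend(fits)
            combined.append(ivw_fixed(fits).to_assoc())
        _write_assoc(per_stratum, outdir / "assoc_per_stratum.tsv")
        _write_assoc(combined, outdir / "assoc_combined.tsv")
        outputs["assoc_per_stratum"] = outdir / "assoc_per_stratum.tsv"
        outputs["assoc_combined"] = outdir / "assoc_combined.tsv"

        # -- score --------------------------------------------------------
        stage("score")
        score = compute_score(harm, weights_kept, config.missing_policy, cohort)
        outputs["score"] = outdir / "score.tsv"
        score.to_frame().to_csv(outputs["score"], sep="\t", index=False, float_format="%.6g")
        stratum_fits, meta = score_association(score, cohort)

        stage("meta")
        outputs["forest"] = outdir / "forest.tsv"
        forest_table(meta).to_csv(outputs["forest"], sep="\t", index=False, float_format="%.6g")
        if config.make_plots:
            outputs["forest_plot"] = outdir / "forest.svg"
            forest_plot(meta, outputs["forest_plot"])
        pooled_fit = fit_logistic(
            cohort.status, np.column_stack([np.ones(len(score.values)), score.values])
        )
        outputs["score_meta"] = outdir / "score_meta.json"
        outputs["score_meta"].write_text(
            json.dumps(
                {
                    "beta": meta.beta,
                    "se": meta.se,
                    "z": meta.z,
                    "p": meta.p,
                    "cochran_q": meta.q,
                    "df": meta.df,
                    "q_p": meta.q_p,
                    "i2_percent": meta.i2,
                    "mcfadden_r2": mcfadden_r2(pooled_fit),
                },
                indent=2,
            )
            + "\n"
        )

        # -- quartiles ----------------------------------------------------
        stage("quartiles")
        quart = quartile_analysis(score, cohort)
        outputs["quartiles"] = outdir / "quartiles.tsv"
        quart.to_frame().to_csv(outputs["quartiles"], sep="\t", index=False, float_format="%.6g")
        outputs["quartiles_json"] = outdir / "quartiles.json"
        outputs["quartiles_json"].write_text(
            json.dumps(
                {
                    "boundaries": list(quart.boundaries),
                    "odds_ratios": list(quart.odds_ratios),
                    "trend_beta": quart.trend_beta,
                    "trend_se": quart.trend_se,
                    "trend_p": quart.trend_p,
                },
                indent=2,
            )
            + "\n"
        )

        # -- summary report -----------------------------------------------
        stage("report")
        tel = np.array([w.weight for w in weights_kept])
        mel = np.array([r.beta for r in combined])
        comp = effect_correlation(tel, mel, [w.rsid for w in weights_kept])
        outputs["effect_comparison"] = outdir / "effect_comparison.json"
        outputs["effect_comparison"].write_text(json.dumps(comp.to_dict(), indent=2) + "\n")
        table = build_table1(combined, weights_kept, alpha=config.alpha)
        outputs["report_table"] = outdir / "report_table.tsv"
        table.to_csv(outputs["report_table"], sep="\t", index=False, float_format="%.6g")
        manifest["n_significant_snps"] = table.attrs["n_significant"]
    except TelogrsError as exc:
        manifest["error"] = str(exc)
        manifest["outputs"] = {k: str(p) for k, p in outputs.items()}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise TelogrsError(f"stage '{manifest['stages'][-1]}' failed: {exc}") from exc

    manifest["outputs"] = {
        k: {"path": str(p), "sha256": _sha256(p)} for k, p in sorted(outputs.items())
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _sim_summary(sim: SimulationConfig) -> dict:
    return {
        "n_cases": sim.n_cases,
        "n_controls": sim.n_controls,
        "n_strata": sim.n_strata,
        "gamma": sim.gamma,
        "confounder_strength": list(sim.confounder_strength),
        "reverse_causation_delta": sim.reverse_causation_delta,
        "dosage_noise": sim.dosage_noise,
        "seed": sim.seed,
        "snps": [w.rsid for w in sim.snps],
    }


def _align(dosages: DosageMatrix, cohort: CohortTable) -> tuple[DosageMatrix, CohortTable]:
    """Restrict both tables to shared samples, in dosage order."""
    pheno_idx = {s: i for i, s in enumerate(cohort.sample_ids)}
    keep = [i for i, s in enumerate(dosages.sample_ids) if s in pheno_idx]
    if not keep:
        raise TelogrsError("no samples shared between dosage and phenotype tables")
    order = [pheno_idx[dosages.sample_ids[i]] for i in keep]
    dm = DosageMatrix(
        sample_ids=dosages.sample_ids[keep],
        rsids=dosages.rsids,
        values=dosages.values[keep],
        mask=dosages.mask[keep],
        coded_allele=dosages.coded_allele,
        other_allele=dosages.other_allele,
        chrom=dosages.chrom,
        pos=dosages.pos,
    )
    ct = CohortTable(
        sample_ids=cohort.sample_ids[order],
        status=cohort.status[order],
        stratum=cohort.stratum[order],
        measured_telomere=(
            cohort.measured_telomere[order] if cohort.measured_telomere is not None else None
        ),
        covariates=(
            cohort.covariates.iloc[order].reset_index(drop=True)
            if cohort.covariates is not None
            else None
        ),
    )
    return dm, ct


def _write_assoc(results: list[AssocResult], path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "label": r.label,
                "stratum": r.stratum,
                "beta": r.beta,
                "se": r.se,
                "z": r.z,
                "p": r.p,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
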
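"""Weight tables, dosage matrices, phenotype tables, and allele harmonization.

The analyses in this package consume three kinds of input:

* a *weight table* of instrument SNPs — rsID, position, effect allele,
  minor-allele frequency, and the per-allele effect on telomere length
  (the score weight, in trait-SD units);
* a *dosage matrix* of expected effect-allele counts in [0, 2] per sample
  per SNP, possibly fractional when genotypes were imputed;
* a *phenotype table* with case/control status, a geographic stratum label,
  and optional covariates.

Because the dosage source and the weight table may code each SNP to
different alleles (or different strands), :func:`harmonize` re-orients the
dosage matrix to the weight table's effect alleles before any scoring or
association testing.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, HarmonizationError

__all__ = [
    "SnpWeight",
    "DosageMatrix",
    "CohortTable",
    "HarmonizationReport",
    "default_weights",
    "load_melanoma_effects",
    "read_weights",
    "write_weights",
    "read_dosages",
    "write_dosage_tsv",
    "write_dosage_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "harmonize",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Maximum tolerated |observed frequency - weight-file MAF| before a warning.
FREQUENCY_WARN_DELTA = 0.2


@dataclass(frozen=True)
class SnpWeight:
    """One instrument SNP: alleles, frequency, and its telomere-length effect.

    ``weight`` is the additive effect of one copy of ``effect_allele`` on
    mean leukocyte telomere length, in trait-SD units.  Negative weights
    mean the effect allele shortens telomeres.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str | None
    maf: float
    weight: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.other_allele is not None and self.effect_allele == self.other_allele:
            raise FormatError(f"{self.rsid}: effect and other allele are identical")
        if not 0.0 < self.maf <= 0.5:
            raise FormatError(f"{self.rsid}: MAF {self.maf} outside (0, 0.5]")
        if not np.isfinite(self.weight) or self.weight == 0.0:
            raise FormatError(f"{self.rsid}: weight must be finite and nonzero")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or C/G pairs, whose strand cannot be told from alleles."""
        if self.other_allele is None:
            return False
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class DosageMatrix:
    """Samples x SNPs expected effect-allele counts with a missingness mask.

    ``values[i, j]`` is the dosage of sample ``i`` at SNP ``j`` for the
    recorded ``coded_allele[j]``; entries where ``mask`` is True are
    missing.  All non-missing values lie in [0, 2].
    """

    sample_ids: np.ndarray
    rsids: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    coded_allele: np.ndarray  # per-SNP allele the dosage counts (may contain None)
    other_allele: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape != (len(self.sample_ids), len(self.rsids)):
            raise ValueError("values shape does not match sample/SNP labels")
        ok = self.values[~self.mask]
        if ok.size and (ok.min() < -1e-6 or ok.max() > 2 + 1e-6):
            raise ValueError("non-missing dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.rsids)

    def coded_freq(self) -> np.ndarray:
        """Observed coded-allele frequency per SNP (missing entries excluded)."""
        vals = np.ma.masked_array(self.values, self.mask)
        return np.asarray(vals.mean(axis=0) / 2.0)

    def column(self, rsid: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (dosage, missing mask) for one SNP."""
        j = np.flatnonzero(self.rsids == rsid)
        if j.size != 1:
            raise KeyError(rsid)
        return self.values[:, j[0]], self.mask[:, j[0]]


@dataclass
class CohortTable:
    """Per-sample phenotype: case/control status, stratum, optional extras."""

    sample_ids: np.ndarray
    status: np.ndarray  # 1 = case, 0 = control
    stratum: np.ndarray
    measured_telomere: np.ndarray | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=int)
        if not np.isin(self.status, (0, 1)).all():
            raise FormatError("status must be coded 0 (control) / 1 (case)")
        n = len(self.sample_ids)
        if len(self.status) != n or len(self.stratum) != n:
            raise FormatError("phenotype columns have unequal lengths")

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.status).sum())

    def strata(self) -> list:
        seen: dict = {}
        for s in self.stratum:
            seen.setdefault(s, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sample_id": self.sample_ids, "status": self.status, "stratum": self.stratum}
        )
        if self.measured_telomere is not None:
            df["measured_telomere"] = self.measured_telomere
        if self.covariates is not None:
            df = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        return df


@dataclass
class HarmonizationReport:
    """Per-SNP record of what :func:`harmonize` did and why."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    ACTIONS = (
        "match",
        "allele_flip",
        "strand_flip",
        "strand_flip_and_allele_flip",
        "dropped_palindromic",
        "dropped_unmatched",
    )

    @property
    def kept_rsids(self) -> list[str]:
        keep = ~self.records["action"].str.startswith("dropped")
        return list(self.records.loc[keep, "rsid"])

    def action(self, rsid: str) -> str:
        row = self.records[self.records["rsid"] == rsid]
        if row.empty:
            raise KeyError(rsid)
        return str(row["action"].iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# weight tables
# ---------------------------------------------------------------------------

_WEIGHT_COLUMNS = ("rsid", "chrom", "pos", "effect_allele", "maf", "weight")


def read_weights(path: str | Path) -> list[SnpWeight]:
    """Read a TSV weight table into an ordered list of :class:`SnpWeight`.

    Required columns: ``rsid chrom pos effect_allele maf weight``;
    ``other_allele`` is optional (minimal weight files may omit it).
    Duplicate rsIDs are rejected.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse weight file {path}: {exc}") from exc
    missing = [c for c in _WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"weight file {path} lacks columns: {', '.join(missing)}")
    has_other = "other_allele" in df.columns
    out: list[SnpWeight] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rsid = str(row["rsid"])
        if rsid in seen:
            raise FormatError(f"duplicate rsID {rsid!r} at row {i + 2} of {path}")
        seen.add(rsid)
        try:
            other = str(row["other_allele"]) if has_other and pd.notna(row["other_allele"]) else None
            out.append(
                SnpWeight(
                    rsid=rsid,
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    effect_allele=str(row["effect_allele"]),
                    other_allele=other,
                    maf=float(row["maf"]),
                    weight=float(row["weight"]),
                    source=str(path),
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"unparseable weight row {i + 2} ({rsid}) in {path}: {exc}") from exc
    return out


def write_weights(weights: Sequence[SnpWeight], path: str | Path) -> None:
    pd.DataFrame(
        {
            "rsid": [w.rsid for w in weights],
            "chrom": [w.chrom for w in weights],
            "pos": [w.pos for w in weights],
            "effect_allele": [w.effect_allele for w in weights],
            "other_allele": [w.other_allele for w in weights],
            "maf": [w.maf for w in weights],
            "weight": [w.weight for w in weights],
        }
    ).to_csv(path, sep="\t", index=False)


def _bundled_table() -> pd.DataFrame:
    text = resources.files("telogrs.data").joinpath("telomere_snps.tsv").read_text()
    return pd.read_csv(io.StringIO(text), sep="\t", dtype={"chrom": str})


def default_weights() -> list[SnpWeight]:
    """The bundled seven-SNP telomere-length instrument set.

    Effects and minor-allele frequencies are the published estimates from
    the leukocyte telomere-length GWAS meta-analysis; the minor allele is
    taken as the effect (coded) allele.
    """
    df = _bundled_table()
    return [
        SnpWeight(
            rsid=r.rsid,
            chrom=str(r.chrom),
            pos=int(r.pos),
            effect_allele=r.effect_allele,
            other_allele=r.other_allele,
            maf=float(r.maf),
            weight=float(r.weight),
            source=f"bundled:{r.gene}",
        )
        for r in df.itertuples()
    ]


def load_melanoma_effects() -> pd.DataFrame:
    """Published per-SNP melanoma log-ORs and p-values for the instrument set.

    Returns a DataFrame with columns ``rsid gene telomere_beta melanoma_beta
    melanoma_p``, used for effect-vector comparisons and report tables.
    """
    df = _bundled_table()
    return df[["rsid", "gene", "weight", "melanoma_beta", "melanoma_p"]].rename(
        columns={"weight": "telomere_beta"}
    )


# ---------------------------------------------------------------------------
# dosage matrices
# ---------------------------------------------------------------------------


def _clip_dosages(values: np.ndarray, where: str) -> np.ndarray:
    finite = values[np.isfinite(values)]
    if finite.size and (finite.min() < -1e-6 or finite.max() > 2 + 1e-6):
        warnings.warn(f"{where}: dosages outside [0,2] by more than 1e-6 were clipped")
    return np.clip(values, 0.0, 2.0)


def read_dosages(path: str | Path, format: str = "tsv") -> DosageMatrix:
    """Read a dosage matrix from ``tsv`` or ``vcf``.

    TSV layout: first column ``sample_id``, then one column per rsID; no
    allele metadata is carried, so the coded allele is recorded as unknown
    and :func:`harmonize` will assume the source is already coded to the
    weight file's effect allele.

    VCF: per-sample dosages come from the genotype-level ``DS`` field when
    present, otherwise hard genotypes are converted to 0/1/2 counts of the
    ALT allele.  Values are stored as read (no rounding); entries outside
    [0,2] by more than 1e-6 are clipped with a warning; missing entries are
    masked.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        if df.columns[0] != "sample_id":
            raise FormatError(f"{path}: first dosage column must be 'sample_id'")
        rsids = np.array(df.columns[1:], dtype=object)
        values = df.iloc[:, 1:].to_numpy(dtype=float)
        mask = ~np.isfinite(values)
        values = _clip_dosages(np.where(mask, 0.0, values), str(path))
        n = len(rsids)
        return DosageMatrix(
            sample_ids=df["sample_id"].to_numpy(dtype=object),
            rsids=rsids,
            values=values,
            mask=mask,
            coded_allele=np.array([None] * n, dtype=object),
            other_allele=np.array([None] * n, dtype=object),
        )
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dosage format {format!r}")


def _read_vcf(path: str | Path) -> DosageMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    rsids, coded, other, chroms, poss, cols, masks = [], [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise FormatError(f"{path}: multi-allelic record at {var.CHROM}:{var.POS}")
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            miss = ~np.isfinite(col) | (col < -0.5)
        else:
            gts = var.genotypes  # list of [a0, a1, phased]
            if not gts:
                raise FormatError(f"{path}: no DS field and no genotypes")
            alleles = np.asarray([g[:2] for g in gts])
            miss = (alleles < 0).any(axis=1)
            col = alleles.clip(min=0).sum(axis=1).astype(float)
        rsids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        coded.append(var.ALT[0])
        other.append(var.REF)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        cols.append(np.where(miss, 0.0, col))
        masks.append(miss)
    if not cols:
        raise FormatError(f"{path}: VCF contains no variant records")
    values = _clip_dosages(np.column_stack(cols), str(path))
    return DosageMatrix(
        sample_ids=samples,
        rsids=np.array(rsids, dtype=object),
        values=values,
        mask=np.column_stack(masks),
        coded_allele=np.array(coded, dtype=object),
        other_allele=np.array(other, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=int),
    )


def write_dosage_tsv(dm: DosageMatrix, path: str | Path) -> None:
    df = pd.DataFrame(np.where(dm.mask, np.nan, dm.values), columns=dm.rsids)
    df.insert(0, "sample_id", dm.sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_dosage_vcf(dm: DosageMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with per-sample DS (dosage) entries.

    The coded allele is emitted as ALT so a round-trip through
    :func:`read_dosages` preserves orientation.  SNPs without allele
    metadata cannot be written to VCF.
    """
    if any(a is None for a in dm.coded_allele) or any(a is None for a in dm.other_allele):
        raise FormatError("VCF output requires allele metadata for every SNP")
    chrom = dm.chrom if dm.chrom is not None else np.array(["1"] * dm.n_snps, dtype=object)
    pos = dm.pos if dm.pos is not None else np.arange(1, dm.n_snps + 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected alternate allele dosage">\n')
        for c in dict.fromkeys(chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in dm.sample_ids) + "\n")
        order = np.lexsort((pos, np.array([str(c) for c in chrom], dtype=object)))
        for j in order:
            fields = [
                str(chrom[j]), str(int(pos[j])), str(dm.rsids[j]),
                str(dm.other_allele[j]), str(dm.coded_allele[j]), ".", "PASS", ".", "DS",
            ]
            ds = [
                "." if dm.mask[i, j] else f"{dm.values[i, j]:.6g}"
                for i in range(dm.n_samples)
            ]
            fh.write("\t".join(fields + ds) + "\n")


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> CohortTable:
    """Read a phenotype TSV: ``sample_id status stratum`` plus optional
    ``measured_telomere`` and any further columns, which become covariates."""
    df = pd.read_csv(path, sep="\t")
    required = ("sample_id", "status", "stratum")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype file {path} lacks columns: {', '.join(missing)}")
    mt = df["measured_telomere"].to_numpy() if "measured_telomere" in df.columns else None
    extra = [c for c in df.columns if c not in required and c != "measured_telomere"]
    return CohortTable(
        sample_ids=df["sample_id"].to_numpy(dtype=object),
        status=df["status"].to_numpy(),
        stratum=df["stratum"].to_numpy(dtype=object),
        measured_telomere=mt,
        covariates=df[extra] if extra else None,
    )


def write_phenotypes(cohort: CohortTable, path: str | Path) -> None:
    cohort.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


def _complement_pair(a: str, b: str | None) -> tuple[str, str | None]:
    return _COMPLEMENT[a], (_COMPLEMENT[b] if b is not None else None)


def harmonize(
    weights: Sequence[SnpWeight],
    dosages: DosageMatrix,
    palindromic_maf_limit: float = 0.4,
) -> tuple[DosageMatrix, HarmonizationReport]:
    """Re-code a dosage matrix to the weight table's effect alleles.

    For each weight-file SNP (matched by rsID first, then chrom:pos) the
    source allele pair is compared to the weight pair, allowing a strand
    complement.  When the source's coded allele is the weight's *other*
    allele the dosage is flipped ``d -> 2 - d``.  Palindromic SNPs (A/T or
    C/G) are resolved by frequency concordance only when both the weight
    MAF and the observed minor-allele frequency are below
    ``palindromic_maf_limit``; otherwise they are dropped.  Source SNPs
    with no recorded alleles (plain dosage TSVs) are assumed to be coded
    to the effect allele already.

    Returns the harmonized matrix restricted to the surviving SNPs, in
    weight-file order, together with a :class:`HarmonizationReport` that
    accounts for every weight-file SNP exactly once.
    """
    by_rsid: dict[str, list[int]] = {}
    for j, r in enumerate(dosages.rsids):
        by_rsid.setdefault(str(r), []).append(j)
    by_pos: dict[tuple[str, int], list[int]] = {}
    if dosages.chrom is not None and dosages.pos is not None:
        for j in range(dosages.n_snps):
            by_pos.setdefault((str(dosages.chrom[j]), int(dosages.pos[j])), []).append(j)

    obs_freq = dosages.coded_freq()
    rows, keep_cols, flip_cols = [], [], []
    for w in weights:
        cand = by_rsid.get(w.rsid, []) or by_pos.get((w.chrom, w.pos), [])
        if len(cand) > 1:
            raise HarmonizationError(f"{w.rsid}: matched {len(cand)} source records")
        if not cand:
            rows.append((w.rsid, "dropped_unmatched", w.maf, np.nan, np.nan))
            continue
        j = cand[0]
        action, flip = _resolve_alleles(w, dosages, j, obs_freq[j], palindromic_maf_limit)
        f = obs_freq[j] if np.isfinite(obs_freq[j]) else np.nan
        f_after = (1 - f) if flip else f
        rows.append((w.rsid, action, w.maf, f_after, f_after - w.maf))
        if not action.startswith("dropped"):
            keep_cols.append(j)
            flip_cols.append(flip)
            if np.isfinite(f_after) and abs(f_after - w.maf) > FREQUENCY_WARN_DELTA:
                warnings.warn(
                    f"{w.rsid}: harmonized coded-allele frequency {f_after:.3f} "
                    f"differs from weight-file MAF {w.maf:.3f} by more than "
                    f"{FREQUENCY_WARN_DELTA}"
                )

    report = HarmonizationReport(
        pd.DataFrame(rows, columns=["rsid", "action", "weight_maf", "observed_freq", "delta"])
    )
    kept = {r[0] for r in rows if not r[1].startswith("dropped")}
    wmap = {w.rsid: w for w in weights}
    values = dosages.values[:, keep_cols].copy()
    mask = dosages.mask[:, keep_cols].copy()
    for k, flip in enumerate(flip_cols):
        if flip:
            values[:, k] = 2.0 - values[:, k]
    values[mask] = 0.0
    kept_order = [w.rsid for w in weights if w.rsid in kept]
    out = DosageMatrix(
        sample_ids=dosages.sample_ids,
        rsids=np.array(kept_order, dtype=object),
        values=values,
        mask=mask,
        coded_allele=np.array([wmap[r].effect_allele for r in kept_order], dtype=object),
        other_allele=np.array([wmap[r].other_allele for r in kept_order], dtype=object),
        chrom=np.array([wmap[r].chrom for r in kept_order], dtype=object),
        pos=np.array([wmap[r].pos for r in kept_order], dtype=int),
    )
    return out, report


def _resolve_alleles(
    w: SnpWeight,
    dm: DosageMatrix,
    j: int,
    obs_freq: float,
    palindromic_maf_limit: float,
) -> tuple[str, bool]:
    """Classify one SNP; returns (action, flip-dosage?)."""
    src_coded = dm.coded_allele[j]
    src_other = dm.other_allele[j]
    if src_coded is None:
        # plain TSV source: no allele metadata, trust the coding
        return "match", False
    if w.is_palindromic or (
        src_other is not None and _COMPLEMENT.get(src_coded) == src_other
    ):
        return _resolve_palindromic(w, src_coded, obs_freq, palindromic_maf_limit)

    pairs = {
        ("match", False): (w.effect_allele, w.other_allele),
        ("allele_flip", True): (w.other_allele, w.effect_allele),
        ("strand_flip", False): _complement_pair(w.effect_allele, w.other_allele),
        ("strand_flip_and_allele_flip", True): _complement_pair(
            w.other_allele if w.other_allele is not None else "",
            w.effect_allele,
        )
        if w.other_allele is not None
        else (None, None),
    }
    for (action, flip), (ea, oa) in pairs.items():
        if ea is None:
            continue
        if w.other_allele is None:
            # minimal weight file: compare coded alleles only
            if src_coded == ea and action in ("match", "strand_flip"):
                return action, flip
        elif (src_coded, src_other) == (ea, oa):
            return action, flip
    return "dropped_unmatched", False


def _resolve_palindromic(
    w: SnpWeight, src_coded: str, obs_freq: float, limit: float
) -> tuple[str, bool]:
    if src_coded not in (w.effect_allele, w.other_allele, _COMPLEMENT[w.effect_allele]):
        return "dropped_unmatched", False
    if not np.isfinite(obs_freq):
        return "dropped_palindromic", False
    obs_minor = min(obs_freq, 1 - obs_freq)
    if w.maf >= limit or obs_minor >= limit:
        return "dropped_palindromic", False
    # frequencies both clearly off 0.5: orient by concordance
    if abs(obs_freq - w.maf) <= abs(obs_freq - (1 - w.maf)):
        return "match", False
    return "allele_flip", True
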
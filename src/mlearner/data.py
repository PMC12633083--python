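"""Domain types and file I/O for summary statistics, scoring files, genotypes
and trial tables.

Conventions fixed here and relied on everywhere else:

* Summary statistics are tab- or whitespace-delimited text with a mandatory
  header; common column aliases (``SNP``/``ID``/``variant_id``, ``A1``/
  ``effect_allele``, ...) are resolved through :data:`COLUMN_ALIASES`.
* Dosage matrices are individuals x variants and count copies of the scoring
  effect allele (0..2).
* PRS standardization always uses the analysis sample's own mean/SD.
"""

from __future__ import annotations

import logging
import math as _math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._utils import check_in_open_unit_interval, standardize

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "SummaryStats",
    "ScoringFile",
    "GenotypeMatrix",
    "TrialDataset",
    "HarmonizedPairs",
    "QcCounts",
    "read_sumstats",
    "write_sumstats",
    "read_scoring_file",
    "read_dosage_matrix",
    "write_dosage_matrix",
    "read_phenotypes",
    "harmonize_variants",
    "qc_filter_variants",
    "score_prs",
    "standardize_treatment",
]

VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC = (frozenset("AT"), frozenset("CG"))


class SumstatsFormatError(ValueError):
    """Malformed summary-statistics file (missing columns, bad rows)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One variant's association record (GWIS interaction or GWAS marginal)."""

    variant_id: str
    allele_effect: str
    allele_other: str
    z: float
    n: int
    beta: float | None = None
    se: float | None = None
    maf: float | None = None
    info: float | None = None
    missing_rate: float | None = None
    hwe_p: float | None = None

    def __post_init__(self):
        for name in ("allele_effect", "allele_other"):
            a = getattr(self, name)
            if a not in VALID_ALLELES:
                raise ValueError(
                    f"variant {self.variant_id}: {name}={a!r} is not a single base A/C/G/T"
                )
        if self.allele_effect == self.allele_other:
            raise ValueError(f"variant {self.variant_id}: alleles must differ")
        if not _math.isfinite(self.z):
            raise ValueError(f"variant {self.variant_id}: non-finite z")
        if self.n <= 0:
            raise ValueError(f"variant {self.variant_id}: sample size must be positive")
        if self.beta is not None and self.se is not None:
            if self.se <= 0:
                raise ValueError(f"variant {self.variant_id}: se must be positive")
            if abs(self.z - self.beta / self.se) > 1e-8 * max(1.0, abs(self.z)):
                raise ValueError(
                    f"variant {self.variant_id}: z inconsistent with beta/se"
                )
        if self.maf is not None and not (0.0 < self.maf <= 0.5):
            raise ValueError(f"variant {self.variant_id}: maf must lie in (0, 0.5]")

    @property
    def is_palindromic(self) -> bool:
        return frozenset((self.allele_effect, self.allele_other)) in _PALINDROMIC


@dataclass
class SummaryStats:
    """A set of per-variant association records of one kind."""

    records: list[VariantRecord]
    kind: str  # "gwis_interaction" | "gwas_marginal"
    trait_label: str = ""

    _KINDS = ("gwis_interaction", "gwas_marginal")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        ids = [r.variant_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ValueError(
                f"duplicate variant ids: {list(dup[dup > 1].index[:5])}"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    @property
    def z(self) -> np.ndarray:
        return np.array([r.z for r in self.records], dtype=float)


@dataclass
class ScoringFile:
    """PRS weights: (variant_id, effect_allele, weight) triples."""

    entries: list[tuple[str, str, float]]
    label: str = ""

    def __post_init__(self):
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("scoring file contains duplicate variant ids")
        for vid, allele, w in self.entries:
            if allele not in VALID_ALLELES:
                raise ValueError(f"scoring entry {vid}: invalid effect allele {allele!r}")
            if not np.isfinite(w):
                raise ValueError(f"scoring entry {vid}: non-finite weight")


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x variants), values in [0, 2].

    ``dosages`` may contain NaN for residual missingness; :func:`score_prs`
    mean-imputes per variant before scoring. ``effect_alleles``, if given,
    names the allele whose copies each column counts.
    """

    dosages: np.ndarray
    variant_ids: list[str]
    mafs: np.ndarray | None = None
    effect_alleles: list[str] | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        if self.dosages.shape[1] != len(self.variant_ids):
            raise ValueError("variant_ids length does not match dosage columns")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValueError(f"{bad} dosage entries outside [0, 2]")
        if self.mafs is not None:
            self.mafs = np.asarray(self.mafs, dtype=float)
            if self.mafs.shape != (self.dosages.shape[1],):
                raise ValueError("mafs length does not match variant count")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def standardized(self) -> np.ndarray:
        """Mean-imputed, per-variant standardized dosage matrix."""
        d = self.dosages.copy()
        col_mean = np.nanmean(d, axis=0)
        nan_r, nan_c = np.where(np.isnan(d))
        if nan_r.size:
            d[nan_r, nan_c] = col_mean[nan_c]
        return standardize(d, axis=0)


@dataclass
class TrialDataset:
    """One randomized trial: outcomes, treatment, standardized PRS features.

    ``design_p`` is the randomization probability P(T=1), known by design and
    used as the propensity score. PRS columns are standardized to mean 0 /
    variance 1 in-sample at construction unless ``standardize_prs=False``.
    Truth attachments (``true_s``, ``true_cate``) are populated by the
    simulation engine for oracle checks and are never read by estimators.
    """

    ids: list[str]
    y: np.ndarray
    t: np.ndarray
    design_p: float
    prs: np.ndarray
    prs_labels: list[str]
    genotypes: GenotypeMatrix | None = None
    true_s: np.ndarray | None = None
    true_cate: np.ndarray | None = None
    extras: dict = field(default_factory=dict)
    standardize_prs: bool = True

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.prs = np.asarray(self.prs, dtype=float)
        n = len(self.ids)
        if not (self.y.shape == self.t.shape == (n,)):
            raise ValueError("ids, y, t must all have the same length")
        if self.prs.ndim != 2 or self.prs.shape[0] != n:
            raise ValueError("prs must be an n x K matrix")
        if self.prs.shape[1] != len(self.prs_labels):
            raise ValueError("prs_labels must match the number of PRS columns")
        if not np.isin(self.t, (0.0, 1.0)).all():
            raise ValueError("treatment must be coded 0/1")
        check_in_open_unit_interval(self.design_p, "design_p")
        if self.standardize_prs and self.prs.shape[0] > 1:
            self.prs = standardize(self.prs, axis=0)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_prs(self) -> int:
        return self.prs.shape[1]

    @property
    def propensity(self) -> float:
        """The known randomization probability used as propensity score."""
        return self.design_p


# ---------------------------------------------------------------------------
# delimited-text readers / writers
# ---------------------------------------------------------------------------

COLUMN_ALIASES = {
    "variant_id": ("variant_id", "snp", "id", "rsid", "markername", "variant"),
    "allele_effect": ("allele_effect", "a1", "effect_allele", "ea", "allele1"),
    "allele_other": ("allele_other", "a2", "other_allele", "oa", "allele2", "allele0"),
    "z": ("z", "zscore", "z_stat", "stat"),
    "beta": ("beta", "b", "effect"),
    "se": ("se", "standard_error", "stderr"),
    "n": ("n", "n_samples", "sample_size", "nobs"),
    "maf": ("maf",),
    "info": ("info", "imputation_quality", "r2"),
    "missing_rate": ("missing_rate", "f_miss", "fmiss"),
    "hwe_p": ("hwe_p", "p_hwe", "hwe"),
}


def _resolve_columns(header: Sequence[str]) -> dict[str, str]:
    lower = {h.lower(): h for h in header}
    resolved: dict[str, str] = {}
    for canon, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    return resolved


def read_sumstats(path: str | Path, kind: str, trait_label: str = "") -> SummaryStats:
    """Read delimited summary statistics into a :class:`SummaryStats`.

    The file must have a header naming at least a variant id, both alleles,
    ``n``, and either ``z`` or (``beta``, ``se``); ``z`` is derived as
    beta/se when absent. Row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")
    cols = _resolve_columns(df.columns)
    mandatory = ["variant_id", "allele_effect", "allele_other", "n"]
    missing = [c for c in mandatory if c not in cols]
    if "z" not in cols and not ("beta" in cols and "se" in cols):
        missing.append("z (or beta+se)")
    if missing:
        raise SumstatsFormatError(
            f"{path.name}: missing mandatory column(s) {missing}; header was {list(df.columns)}"
        )
    records: list[VariantRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        row_d = dict(zip(df.columns, row))

        def get(canon, cast=float, optional=True):
            col = cols.get(canon)
            if col is None:
                return None
            raw = row_d[col]
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw in ("", "NA", "nan"):
                return None
            try:
                return cast(raw)
            except (TypeError, ValueError) as exc:
                raise SumstatsFormatError(
                    f"{path.name} line {idx}: non-numeric value {raw!r} in column {col!r}"
                ) from exc

        beta, se = get("beta"), get("se")
        z = get("z")
        if z is None:
            if beta is None or se is None:
                raise SumstatsFormatError(
                    f"{path.name} line {idx}: neither z nor beta+se available"
                )
            z = beta / se
        try:
            rec = VariantRecord(
                variant_id=str(row_d[cols["variant_id"]]),
                allele_effect=str(row_d[cols["allele_effect"]]).upper(),
                allele_other=str(row_d[cols["allele_other"]]).upper(),
                z=z,
                n=int(float(row_d[cols["n"]])),
                beta=beta,
                se=se,
                maf=get("maf"),
                info=get("info"),
                missing_rate=get("missing_rate"),
                hwe_p=get("hwe_p"),
            )
        except ValueError as exc:
            raise SumstatsFormatError(f"{path.name} line {idx}: {exc}") from exc
        records.append(rec)
    return SummaryStats(records=records, kind=kind, trait_label=trait_label or path.stem)


_WRITE_COLS = ["variant_id", "allele_effect", "allele_other", "z", "n",
               "beta", "se", "maf", "info", "missing_rate", "hwe_p"]


def write_sumstats(stats: SummaryStats, path: str | Path) -> None:
    """Write tab-delimited summary statistics; round-trips bit-exactly."""
    rows = []
    for r in stats.records:
        rows.append({c: getattr(r, c) for c in _WRITE_COLS})
    df = pd.DataFrame(rows, columns=_WRITE_COLS)
    df = df.dropna(axis=1, how="all")  # omit wholly absent optional columns
    df.to_csv(path, sep="\t", index=False)


def read_scoring_file(path: str | Path, label: str = "") -> ScoringFile:
    """Read a PGS-Catalog-style scoring file ('#' comment lines ignored)."""
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", comment="#", dtype=str)
    lower = {h.lower(): h for h in df.columns}
    id_col = next((lower[a] for a in ("rsid", "variant_id", "snp", "id") if a in lower), None)
    ea_col = next((lower[a] for a in ("effect_allele", "a1", "ea") if a in lower), None)
    w_col = next((lower[a] for a in ("effect_weight", "weight", "beta") if a in lower), None)
    if not (id_col and ea_col and w_col):
        raise SumstatsFormatError(
            f"{path.name}: need variant id, effect_allele and effect_weight columns"
        )
    entries = [
        (str(v), str(a).upper(), float(w))
        for v, a, w in zip(df[id_col], df[ea_col], df[w_col])
    ]
    return ScoringFile(entries=entries, label=label or path.stem)


def read_dosage_matrix(path: str | Path, id_column: str = "id") -> tuple[list[str], GenotypeMatrix]:
    """Read a delimited dosage matrix (rows = individuals, cols = variants)."""
    df = pd.read_csv(path, sep=r"\s+")
    if id_column in df.columns:
        ids = df[id_column].astype(str).tolist()
        df = df.drop(columns=[id_column])
    else:
        ids = [str(i) for i in range(len(df))]
    gm = GenotypeMatrix(dosages=df.to_numpy(dtype=float), variant_ids=list(df.columns))
    return ids, gm


def write_dosage_matrix(ids: Sequence[str], gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(gm.dosages, columns=gm.variant_ids)
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False)


def read_vcf_dosages(path: str | Path, field: str = "DS") -> tuple[list[str], GenotypeMatrix]:
    """Optional VCF reader: dosages from the DS FORMAT field or GT calls.

    Dosages count copies of the first ALT allele; multi-allelic sites are
    skipped. Requires ``cyvcf2`` (imported lazily; the delimited-text path
    has no such dependency).
    """
    from cyvcf2 import VCF  # lazy: optional feature

    if field not in ("DS", "GT"):
        raise ValueError("field must be 'DS' or 'GT'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids: list[str] = []
    alleles: list[str] = []
    columns: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            logger.info("skipping multi-allelic site %s", v.ID or v.POS)
            continue
        if field == "DS":
            ds = v.format("DS")
            if ds is None:
                raise SumstatsFormatError(
                    f"{path}: variant {v.ID or v.POS} lacks a DS field"
                )
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gt = np.asarray(v.genotype.array())[:, :2].astype(float)
            gt[gt < 0] = np.nan  # missing calls -> imputed at scoring time
            col = gt.sum(axis=1)
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        alleles.append(str(v.ALT[0]))
        columns.append(col)
    if not columns:
        raise SumstatsFormatError(f"{path}: no usable biallelic variants")
    gm = GenotypeMatrix(
        dosages=np.column_stack(columns), variant_ids=ids,
        effect_alleles=alleles,
    )
    return samples, gm


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype table with columns id, treatment (0/1), outcome."""
    df = pd.read_csv(path, sep=r"\s+")
    lower = {h.lower(): h for h in df.columns}
    need = {"id", "treatment", "outcome"}
    if not need <= set(lower):
        raise SumstatsFormatError(f"phenotype file needs columns {sorted(need)}")
    df = df.rename(columns={lower[k]: k for k in need})
    df["id"] = df["id"].astype(str)
    return df


# ---------------------------------------------------------------------------
# harmonization, QC, scoring, treatment coding
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedPairs:
    """Paired (reference, other) records on shared, allele-consistent variants.

    ``other`` records are returned in the reference's allele orientation: a
    swapped effect/other allele flips the sign of z (and beta).
    """

    reference: list[VariantRecord]
    other: list[VariantRecord]
    n_flipped: int
    n_dropped_palindromic: int
    n_dropped_mismatch: int

    def __len__(self) -> int:
        return len(self.reference)

    @property
    def z_reference(self) -> np.ndarray:
        return np.array([r.z for r in self.reference])

    @property
    def z_other(self) -> np.ndarray:
        return np.array([r.z for r in self.other])


def harmonize_variants(
    reference: SummaryStats,
    other: SummaryStats,
    drop_palindromic: bool = True,
) -> HarmonizedPairs:
    """Align ``other`` to ``reference`` on shared variants.

    Swapped alleles flip the sign of the other study's z; strand-ambiguous
    palindromic variants (A/T, C/G) are dropped by default; allele pairs that
    neither match nor swap are dropped and counted.
    """
    ref_by_id = {r.variant_id: r for r in reference.records}
    paired_ref: list[VariantRecord] = []
    paired_other: list[VariantRecord] = []
    n_flip = n_pal = n_mis = 0
    for rec in other.records:
        ref = ref_by_id.get(rec.variant_id)
        if ref is None:
            continue
        if drop_palindromic and (ref.is_palindromic or rec.is_palindromic):
            n_pal += 1
            continue
        if (rec.allele_effect, rec.allele_other) == (ref.allele_effect, ref.allele_other):
            aligned = rec
        elif (rec.allele_effect, rec.allele_other) == (ref.allele_other, ref.allele_effect):
            n_flip += 1
            aligned = replace(
                rec,
                allele_effect=ref.allele_effect,
                allele_other=ref.allele_other,
                z=-rec.z,
                beta=None if rec.beta is None else -rec.beta,
            )
        else:
            n_mis += 1
            continue
        paired_ref.append(ref)
        paired_other.append(aligned)
    if not paired_ref:
        raise ValueError(
            f"no harmonizable variants shared between {reference.trait_label!r} "
            f"and {other.trait_label!r} ({n_pal} palindromic, {n_mis} mismatched)"
        )
    if n_mis:
        logger.info("harmonize_variants: dropped %d allele-mismatched variants", n_mis)
    return HarmonizedPairs(paired_ref, paired_other, n_flip, n_pal, n_mis)


@dataclass
class QcCounts:
    n_input: int
    n_kept: int
    n_failed_info: int = 0
    n_failed_maf: int = 0
    n_failed_missing: int = 0
    n_failed_hwe: int = 0
    n_missing_field: int = 0


def qc_filter_variants(
    records: Iterable[VariantRecord],
    info_min: float = 0.9,
    maf_min: float = 0.05,
    missing_max: float = 0.01,
    hwe_p_min: float = 1e-6,
    permissive_missing_fields: bool = False,
) -> tuple[list[VariantRecord], QcCounts]:
    """Variant QC: keep info > ``info_min``, MAF >= ``maf_min``, missing rate
    <= ``missing_max`` and HWE p >= ``hwe_p_min``.

    A record lacking a QC field fails that filter unless
    ``permissive_missing_fields`` exempts it.
    """
    records = list(records)
    counts = QcCounts(n_input=len(records), n_kept=0)
    kept: list[VariantRecord] = []
    checks = [
        ("info", lambda v: v > info_min, "n_failed_info"),
        ("maf", lambda v: v >= maf_min, "n_failed_maf"),
        ("missing_rate", lambda v: v <= missing_max, "n_failed_missing"),
        ("hwe_p", lambda v: v >= hwe_p_min, "n_failed_hwe"),
    ]
    for rec in records:
        ok = True
        for attr, passes, counter in checks:
            val = getattr(rec, attr)
            if val is None:
                if not permissive_missing_fields:
                    counts.n_missing_field += 1
                    ok = False
                    break
                continue
            if not passes(val):
                setattr(counts, counter, getattr(counts, counter) + 1)
                ok = False
                break
        if ok:
            kept.append(rec)
    counts.n_kept = len(kept)
    logger.info(
        "qc_filter_variants: kept %d / %d variants", counts.n_kept, counts.n_input
    )
    return kept, counts


def score_prs(
    genotypes: GenotypeMatrix,
    scoring: ScoringFile,
    standardize_output: bool = False,
) -> np.ndarray:
    """Score individuals: sum of dosage x weight over matched variants.

    Variants are matched by id; if the genotype matrix records effect
    alleles, a swapped scoring allele flips the dosage (2 - d). Missing
    dosages are mean-imputed per variant. With ``standardize_output`` the
    returned vector has in-sample mean 0 and variance 1.
    """
    col_of = {vid: j for j, vid in enumerate(genotypes.variant_ids)}
    cols, weights = [], []
    n_unmatched = 0
    for vid, allele, w in scoring.entries:
        j = col_of.get(vid)
        if j is None:
            n_unmatched += 1
            continue
        if genotypes.effect_alleles is not None and genotypes.effect_alleles[j] != allele:
            cols.append(j)
            weights.append(-w)  # flipped allele: d_eff = 2 - d, constant shift dropped
        else:
            cols.append(j)
            weights.append(w)
    if not cols:
        raise ValueError(
            f"score_prs: 0 of {len(scoring.entries)} scoring variants matched "
            f"({n_unmatched} unmatched ids among {genotypes.n_variants} genotyped variants)"
        )
    d = genotypes.dosages[:, cols]
    if np.isnan(d).any():
        col_mean = np.nanmean(d, axis=0)
        nan_r, nan_c = np.where(np.isnan(d))
        d = d.copy()
        d[nan_r, nan_c] = col_mean[nan_c]
        logger.info("score_prs: mean-imputed %d missing dosage entries", nan_r.size)
    w = np.asarray(weights, dtype=float)
    score = d @ w
    # allele flips drop a constant 2*w per flipped variant; irrelevant after
    # centering and immaterial for interaction tests, but restore it for raw
    # scores so that dosage*weight arithmetic matches the definition.
    if genotypes.effect_alleles is not None:
        const = sum(
            2.0 * w_orig
            for (vid, allele, w_orig) in scoring.entries
            if vid in col_of
            and genotypes.effect_alleles[col_of[vid]] != allele
        )
        score = score + const
    if standardize_output:
        score = standardize(score)
    return score


def standardize_treatment(t: np.ndarray, p: float) -> np.ndarray:
    """Map treatment 1 -> sqrt((1-p)/p) and 0 -> -sqrt(p/(1-p)).

    With empirical treated fraction equal to the design probability ``p`` the
    coded vector has mean 0 and variance 1 exactly; the gap between the two
    codes is 1/sqrt(p(1-p)) for any p.
    """
    check_in_open_unit_interval(p, "treatment probability p")
    t = np.asarray(t, dtype=float)
    if not np.isin(t, (0.0, 1.0)).all():
        raise ValueError("treatment vector must be coded 0/1")
    hi = np.sqrt((1.0 - p) / p)
    lo = -np.sqrt(p / (1.0 - p))
    return np.where(t == 1.0, hi, lo)
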
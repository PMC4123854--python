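"""Domain types, file I/O, and complete-case dataset assembly.

Phenotypes are repeated measurements (e.g. FreeSurfer regional volumes or
thicknesses in mm^3 / mm) observed at irregular visit times in months since
baseline.  Genotypes are minor-allele counts in {0, 1, 2}.  Assembly follows
an available-data policy: observations are never imputed; a subject missing
a genotype or any covariate is excluded entirely for that SNP.
"""

from __future__ import annotations

import dataclasses
import io
import os
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_COVARIATES",
    "LongPhenotypeTable",
    "CovariateTable",
    "GenotypeMatrix",
    "AnalysisDataset",
    "ScanRecord",
    "SchemaError",
    "EmptyDatasetError",
    "read_long_phenotypes",
    "read_covariates",
    "read_genotypes",
    "assemble_dataset",
]

#: Canonical covariate column order: handedness (binary), education in
#: years, age at baseline in years, gender (binary), intracranial volume
#: in mm^3.
DEFAULT_COVARIATES = ("handedness", "education_years", "baseline_age", "gender", "icv")

_LONG_COLUMNS = ("subject_id", "visit_month", "phenotype_name", "value")


class SchemaError(ValueError):
    """An input file or table violates the expected schema."""


class EmptyDatasetError(ValueError):
    """Assembly produced no usable observations."""


def _infer_sep(path: str | os.PathLike) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


@dataclasses.dataclass
class LongPhenotypeTable:
    """Per-subject, per-visit phenotype observations in canonical long form.

    ``data`` has columns ``subject_id``, ``visit_month``, ``phenotype_name``,
    ``value``; the key (subject, month, phenotype) is unique, months are
    non-negative, and every retained value is finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_LONG_COLUMNS) - set(self.data.columns)
        if missing:
            raise SchemaError(f"phenotype table missing columns: {sorted(missing)}")
        df = self.data.loc[:, list(_LONG_COLUMNS)].reset_index(drop=True)
        if (df["visit_month"] < 0).any():
            raise SchemaError("visit_month must be non-negative")
        if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
            raise SchemaError("phenotype values must be finite (drop missing rows)")
        if df.duplicated(["subject_id", "visit_month", "phenotype_name"]).any():
            raise SchemaError("duplicate (subject_id, visit_month, phenotype_name) rows")
        self.data = df

    @property
    def phenotype_names(self) -> list[str]:
        return sorted(self.data["phenotype_name"].unique())

    def write(self, path: str | os.PathLike, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index=False)


@dataclasses.dataclass
class CovariateTable:
    """One row per subject; columns are the subject id plus covariates."""

    data: pd.DataFrame
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        if "subject_id" not in self.data.columns:
            raise SchemaError("covariate table requires a subject_id column")
        missing = set(self.covariate_names) - set(self.data.columns)
        if missing:
            raise SchemaError(f"covariate table missing columns: {sorted(missing)}")
        if self.data["subject_id"].duplicated().any():
            raise SchemaError("duplicated subject_id in covariate table")
        self.covariate_names = tuple(self.covariate_names)
        self.data = self.data.loc[:, ["subject_id", *self.covariate_names]].reset_index(drop=True)

    def write(self, path: str | os.PathLike, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index=False)


@dataclasses.dataclass
class GenotypeMatrix:
    """Minor-allele counts (subjects x SNPs) with per-SNP metadata.

    ``counts`` is a float array with entries in {0, 1, 2} or NaN for missing
    genotypes.  ``snp_meta`` is indexed like ``snp_ids`` with columns
    ``chrom``, ``pos`` and optionally ``gene``.
    """

    subject_ids: np.ndarray
    snp_ids: np.ndarray
    counts: np.ndarray
    snp_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise SchemaError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        observed = self.counts[~np.isnan(self.counts)]
        if not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(observed) - {0.0, 1.0, 2.0})
            raise SchemaError(f"genotype counts outside {{0,1,2}}: {bad}")
        if self.snp_meta is None:
            self.snp_meta = pd.DataFrame(
                {"chrom": "NA", "pos": np.arange(1, len(self.snp_ids) + 1)},
                index=pd.Index(self.snp_ids, name="snp_id"),
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column(self, snp_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if idx.size == 0:
            raise KeyError(f"unknown SNP id {snp_id!r}")
        return self.counts[:, idx[0]]

    def minor_allele_freq(self, snp_id: str) -> float:
        col = self.column(snp_id)
        col = col[~np.isnan(col)]
        return float(col.mean() / 2.0) if col.size else float("nan")

    def write_tsv(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(self.counts, columns=self.snp_ids)
        df.insert(0, "subject_id", self.subject_ids)
        with np.errstate(invalid="ignore"):
            df.to_csv(path, sep="\t", index=False, float_format="%.0f")


@dataclasses.dataclass
class AnalysisDataset:
    """Complete-case data for one (SNP, phenotype) analysis.

    Observations are stored flat, sorted by subject then visit time, with
    ``subject_index`` mapping each row to the per-subject arrays ``snp`` and
    ``covariates``.  Every retained row has a finite phenotype; every
    retained subject has a non-missing genotype and full covariates.
    """

    subject_ids: np.ndarray        # (n_subjects,)
    times: np.ndarray              # (N,) months
    y: np.ndarray                  # (N,)
    subject_index: np.ndarray      # (N,) int, contiguous blocks, time-sorted
    snp: np.ndarray                # (n_subjects,) minor-allele counts
    covariates: np.ndarray         # (n_subjects, c)
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES
    phenotype_name: str = "phenotype"
    snp_id: str = "snp"
    baseline_only: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.subject_index = np.asarray(self.subject_index, dtype=np.intp)
        self.snp = np.asarray(self.snp, dtype=float)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        n = len(self.subject_ids)
        if self.covariates.shape[0] != n or self.snp.shape[0] != n:
            raise SchemaError("per-subject arrays inconsistent with subject_ids")
        if self.subject_index.size and (np.diff(self.subject_index) < 0).any():
            raise SchemaError("subject blocks must be contiguous and ordered")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_observations(self) -> int:
        return len(self.y)

    def block_sizes(self) -> np.ndarray:
        return np.bincount(self.subject_index, minlength=self.n_subjects)

    def design_matrix(self, include_time: bool = True) -> tuple[np.ndarray, list[str]]:
        """Row-level design: intercept, SNP, [time, SNP x time], covariates."""
        s = self.snp[self.subject_index]
        cov = self.covariates[self.subject_index]
        cols = [np.ones(self.n_observations), s]
        names = ["intercept", "snp"]
        if include_time:
            cols += [self.times, s * self.times]
            names += ["time", "snp:time"]
        X = np.column_stack(cols + [cov])
        names += list(self.covariate_names)
        return X, names


@dataclasses.dataclass
class ScanRecord:
    """One association-test result within a genome scan."""

    snp_id: str
    phenotype_name: str
    test_name: str
    statistic: float
    df: int
    p_value: float
    n_subjects: int
    n_observations: int
    skip_reason: str | None = None


def read_long_phenotypes(
    path: str | os.PathLike,
    subject_col: str = "subject_id",
    month_col: str = "visit_month",
    sep: str | None = None,
) -> LongPhenotypeTable:
    """Read a delimited phenotype file into canonical long form.

    A file already in long form (the four canonical columns) is taken
    verbatim; otherwise every non-key column is treated as a phenotype and
    the table is melted.  Empty cells are dropped, never imputed.
    """
    sep = sep or _infer_sep(path)
    df = pd.read_csv(path, sep=sep)
    for col in (subject_col, month_col):
        if col not in df.columns:
            raise SchemaError(f"phenotype file lacks required column {col!r}")
    df = df.rename(columns={subject_col: "subject_id", month_col: "visit_month"})
    try:
        df["visit_month"] = pd.to_numeric(df["visit_month"])
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"non-numeric visit month: {exc}") from exc
    if set(_LONG_COLUMNS) <= set(df.columns):
        long = df.loc[:, list(_LONG_COLUMNS)]
    else:
        value_cols = [c for c in df.columns if c not in ("subject_id", "visit_month")]
        if not value_cols:
            raise SchemaError("no phenotype columns found")
        long = df.melt(
            id_vars=["subject_id", "visit_month"],
            value_vars=value_cols,
            var_name="phenotype_name",
            value_name="value",
        )
    long = long.dropna(subset=["value"]).reset_index(drop=True)
    long["value"] = pd.to_numeric(long["value"])
    return LongPhenotypeTable(long)


def read_covariates(
    path: str | os.PathLike,
    covariate_names: Sequence[str] = DEFAULT_COVARIATES,
    subject_col: str = "subject_id",
    sep: str | None = None,
) -> CovariateTable:
    sep = sep or _infer_sep(path)
    df = pd.read_csv(path, sep=sep).rename(columns={subject_col: "subject_id"})
    return CovariateTable(df, tuple(covariate_names))


def _read_genotypes_tsv(path: str | os.PathLike, sep: str | None) -> GenotypeMatrix:
    sep = sep or _infer_sep(path)
    df = pd.read_csv(path, sep=sep)
    if df.columns[0].lower() not in ("subject_id", "subject", "iid", "id"):
        raise SchemaError("first genotype column must be the subject id")
    subject_ids = df.iloc[:, 0].to_numpy()
    counts = df.iloc[:, 1:].to_numpy(dtype=float)
    return GenotypeMatrix(subject_ids, df.columns[1:].to_numpy(), counts)


def _read_genotypes_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read GT fields from a VCF, recoding so counts tag the minor allele.

    The ALT-allele dosage is computed per variant; if the ALT sample
    frequency exceeds 0.5 the coding is flipped (2 - dosage) so that the
    count always refers to the rarer allele.  Half-calls and missing GTs
    become NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = np.asarray(vcf.samples)
    snp_ids, rows, meta = [], [], []
    for i, var in enumerate(vcf):
        gt = np.asarray(var.genotypes, dtype=object)  # (n, ploidy+1)
        a1 = np.array([g[0] for g in gt], dtype=float)
        a2 = np.array([g[1] for g in gt], dtype=float)
        a1[a1 < 0] = np.nan
        a2[a2 < 0] = np.nan
        dosage = a1 + a2  # NaN if either allele missing (half-call or ./.)
        with np.errstate(invalid="ignore"):
            observed = dosage[~np.isnan(dosage)]
        if observed.size and observed.mean() / 2.0 > 0.5:
            dosage = 2.0 - dosage
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(dosage)
        meta.append((var.CHROM, var.POS))
    if not rows:
        raise SchemaError("VCF contains no variants")
    snp_meta = pd.DataFrame(meta, columns=["chrom", "pos"], index=pd.Index(snp_ids, name="snp_id"))
    return GenotypeMatrix(subject_ids, np.asarray(snp_ids), np.column_stack(rows), snp_meta)


def read_genotypes(path: str | os.PathLike, format: str | None = None, sep: str | None = None) -> GenotypeMatrix:
    """Read genotypes from a TSV count matrix or a VCF (GT field only).

    TSV files are taken as-coded (assumed minor-allele counts); only VCF
    input triggers minor-allele recoding.
    """
    if format is None:
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf":
        return _read_genotypes_vcf(path)
    if format == "tsv":
        return _read_genotypes_tsv(path, sep)
    raise ValueError(f"unknown genotype format {format!r}")


def assemble_dataset(
    pheno: LongPhenotypeTable,
    cov: CovariateTable,
    geno: GenotypeMatrix,
    snp_id: str,
    phenotype_name: str,
    baseline_only: bool = False,
) -> AnalysisDataset:
    """Complete-case intersection of phenotype, covariates and one SNP.

    Subjects lacking the genotype or any covariate are excluded; phenotype
    rows are restricted to ``phenotype_name`` (and to visit_month == 0 when
    ``baseline_only``); subjects with no remaining observations are dropped.
    """
    counts = geno.column(snp_id)
    geno_ok = pd.Series(counts, index=geno.subject_ids)
    geno_ok = geno_ok[~geno_ok.isna()]

    cdf = cov.data.dropna(subset=list(cov.covariate_names)).set_index("subject_id")

    pdf = pheno.data[pheno.data["phenotype_name"] == phenotype_name]
    if baseline_only:
        pdf = pdf[pdf["visit_month"] == 0]

    keep = pdf["subject_id"].isin(geno_ok.index) & pdf["subject_id"].isin(cdf.index)
    pdf = pdf.loc[keep].sort_values(["subject_id", "visit_month"], kind="stable")
    if pdf.empty:
        raise EmptyDatasetError(
            f"no complete-case observations for snp={snp_id!r}, phenotype={phenotype_name!r}"
        )

    codes, uniques = pd.factorize(pdf["subject_id"], sort=False)
    subject_ids = np.asarray(uniques)
    return AnalysisDataset(
        subject_ids=subject_ids,
        times=pdf["visit_month"].to_numpy(dtype=float),
        y=pdf["value"].to_numpy(dtype=float),
        subject_index=codes,
        snp=geno_ok.loc[subject_ids].to_numpy(dtype=float),
        covariates=cdf.loc[subject_ids, list(cov.covariate_names)].to_numpy(dtype=float),
        covariate_names=tuple(cov.covariate_names),
        phenotype_name=phenotype_name,
        snp_id=snp_id,
        baseline_only=baseline_only,
    )
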
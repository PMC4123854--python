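"""Genome-scan orchestration and genome-wide summaries.

Loops SNP x phenotype x test for one of five estimators, applies
multiple-testing control (Bonferroni over phenotypes, Benjamini-Hochberg
FDR), computes the genomic inflation factor, optionally adjusts for
population stratification with genotype principal components, and exports
Manhattan/QQ plot tables.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np
import pandas as pd
from scipy import stats

from . import cross_sectional, gee, lmm
from .datamodel import (
    AnalysisDataset,
    CovariateTable,
    EmptyDatasetError,
    GenotypeMatrix,
    LongPhenotypeTable,
    ScanRecord,
    assemble_dataset,
)

__all__ = [
    "ScanTable",
    "PcAdjustment",
    "METHODS",
    "run_scan",
    "bonferroni_threshold",
    "bh_fdr",
    "genomic_lambda",
    "compute_pcs",
    "export_plot_tables",
]

METHODS = ("lmm_rsi", "lmm_ri", "gee_naive", "gee_robust", "baseline")

#: Median of the chi-square distribution with 1 df, to full precision.
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

_RECORD_COLUMNS = [
    "snp_id", "phenotype_name", "test_name", "statistic", "df",
    "p_value", "n_subjects", "n_observations", "skip_reason",
]


@dataclasses.dataclass
class ScanTable:
    """Ordered scan results plus run metadata."""

    records: list[ScanRecord]
    method: str
    tests: tuple[str, ...]
    covariate_names: tuple[str, ...]
    n_phenotypes: int
    n_skipped: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(r) for r in self.records], columns=_RECORD_COLUMNS
        )

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def p_values(self, test: str | None = None) -> np.ndarray:
        recs = [r for r in self.records if r.skip_reason is None]
        if test is not None:
            recs = [r for r in recs if r.test_name == test]
        return np.array([r.p_value for r in recs])


@dataclasses.dataclass
class PcAdjustment:
    """Top-k principal components of the standardized genotype matrix."""

    subject_ids: np.ndarray
    scores: np.ndarray      # (n_subjects, k)
    loadings: np.ndarray    # (n_snps_used, k)
    k: int
    snp_subsample_size: int
    seed: int


def bonferroni_threshold(alpha_single_phenotype: float, n_phenotypes: int) -> float:
    """Family-wise threshold when the same genome is scanned for several
    phenotypes: the single-phenotype level divided by the phenotype count."""
    if not 0.0 < alpha_single_phenotype < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_phenotypes < 1:
        raise ValueError("n_phenotypes must be >= 1")
    return alpha_single_phenotype / n_phenotypes


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return stats.false_discovery_control(p, method="bh")


def genomic_lambda(p: np.ndarray, per_test_df: int | None = None) -> float:
    """Genomic inflation factor from a vector of scan p-values.

    Each p-value is converted to the equivalent 1-df chi-square quantile and
    the median is divided by the 1-df chi-square median (0.4549364...),
    regardless of the originating test's df, which keeps lambda comparable
    across 1-df and 2-df tests.  Passing ``per_test_df`` instead converts on
    that df scale and divides by its own median.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p == 0):
        import warnings

        warnings.warn("p-values of 0 clipped to the smallest positive float")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    df = 1 if per_test_df is None else per_test_df
    q = stats.chi2.isf(p, df)
    return float(np.median(q) / stats.chi2.ppf(0.5, df))


def compute_pcs(
    geno: GenotypeMatrix,
    k: int,
    subsample: int | None = None,
    seed: int = 0,
) -> PcAdjustment:
    """Principal components of the standardized genotype matrix.

    Columns are centered at 2*p_hat and scaled by sqrt(2*p_hat*(1-p_hat))
    with p_hat the sample allele frequency; missing counts are mean-imputed
    for the decomposition only; constant columns are dropped.  Scores are
    the top-k left singular vectors scaled by their singular values.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > geno.n_subjects - 1:
        raise ValueError("k must be <= n_subjects - 1")
    rng = np.random.default_rng(seed)
    n_snps = geno.n_snps
    if subsample is not None and subsample < n_snps:
        cols = np.sort(rng.choice(n_snps, size=subsample, replace=False))
    else:
        cols = np.arange(n_snps)
    G = geno.counts[:, cols].astype(float)
    mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), mean, G)
    phat = mean / 2.0
    sd = np.sqrt(2.0 * phat * (1.0 - phat))
    keep = sd > 0
    Z = (G[:, keep] - mean[keep]) / sd[keep]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    return PcAdjustment(
        subject_ids=geno.subject_ids,
        scores=U[:, :k] * S[:k],
        loadings=Vt[:k].T,
        k=k,
        snp_subsample_size=len(cols),
        seed=seed,
    )


def _with_pcs(cov: CovariateTable, pcs: PcAdjustment) -> CovariateTable:
    df = cov.data.copy()
    scores = pd.DataFrame(
        pcs.scores,
        index=pcs.subject_ids,
        columns=[f"PC{i + 1}" for i in range(pcs.k)],
    )
    merged = df.join(scores, on="subject_id")
    return CovariateTable(merged, tuple(cov.covariate_names) + tuple(scores.columns))


def _analyze(data: AnalysisDataset, method: str, tests: tuple[str, ...]) -> list[lmm.TestResult]:
    if method == "baseline":
        fit = cross_sectional.fit_baseline(data)
        return [cross_sectional.baseline_snp_test(fit)]
    if method in ("lmm_rsi", "lmm_ri"):
        fit = lmm.fit_lmm(data, random_slope=(method == "lmm_rsi"))
        return [lmm.wald_test(fit, t) for t in tests]
    if method in ("gee_naive", "gee_robust"):
        fit = gee.fit_gee_cs(data)
        cov = "robust" if method == "gee_robust" else "naive"
        return [gee.gee_wald(fit, t, cov) for t in tests]
    raise ValueError(f"unknown method {method!r}")


def run_scan(
    pheno: LongPhenotypeTable,
    cov: CovariateTable,
    geno: GenotypeMatrix,
    method: str = "lmm_rsi",
    tests: tuple[str, ...] | None = None,
    pcs: PcAdjustment | None = None,
    phenotypes: tuple[str, ...] | None = None,
    snp_ids: tuple[str, ...] | None = None,
) -> ScanTable:
    """Test every SNP against every phenotype with one estimator.

    Longitudinal methods accept any of the tests {joint, main, interaction};
    the baseline method supports only the 1-df main-effect test.  SNPs that
    are monomorphic in the analyzed subjects are skipped with an explicit
    reason rather than a fabricated p-value.  PC scores, when given, are
    appended to the covariates of every fit.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if tests is None:
        tests = ("main",) if method == "baseline" else ("joint",)
    tests = tuple(tests)
    if method == "baseline":
        if set(tests) - {"main"}:
            raise ValueError("the baseline method supports only the 'main' test")
        tests = ("main",)
    elif set(tests) - {"joint", "main", "interaction"}:
        raise ValueError(f"unknown tests: {set(tests) - {'joint', 'main', 'interaction'}}")

    if pcs is not None:
        cov = _with_pcs(cov, pcs)
    phenotypes = tuple(phenotypes or pheno.phenotype_names)
    snp_ids = tuple(snp_ids or geno.snp_ids)

    records: list[ScanRecord] = []
    n_skipped = 0
    for ph in phenotypes:
        for snp in snp_ids:
            try:
                data = assemble_dataset(pheno, cov, geno, snp, ph,
                                        baseline_only=(method == "baseline"))
            except EmptyDatasetError:
                records.append(ScanRecord(snp, ph, "-", np.nan, 0, np.nan, 0, 0,
                                          skip_reason="no complete-case data"))
                n_skipped += 1
                continue
            if np.nanstd(data.snp) == 0:
                records.append(ScanRecord(snp, ph, "-", np.nan, 0, np.nan,
                                          data.n_subjects, data.n_observations,
                                          skip_reason="monomorphic"))
                n_skipped += 1
                continue
            for res in _analyze(data, method, tests):
                records.append(ScanRecord(snp, ph, res.name, res.statistic,
                                          res.df or 0, res.p_value,
                                          data.n_subjects, data.n_observations))
    return ScanTable(records, method, tests, tuple(cov.covariate_names),
                     len(phenotypes), n_skipped)


def export_plot_tables(
    scan: ScanTable,
    geno: GenotypeMatrix | None = None,
    out_dir: str | os.PathLike | None = None,
    render: bool = False,
) -> dict[str, pd.DataFrame]:
    """Manhattan and QQ tables (and optional rendered PNGs).

    Manhattan: (chrom, pos, snp_id, phenotype, p, -log10 p) sorted by
    position.  QQ: expected -log10((i - 0.5)/n) against observed sorted
    -log10 p.
    """
    df = scan.to_dataframe()
    df = df[df["skip_reason"].isna()].copy()
    if df.empty:
        raise ValueError("scan contains no usable records")
    if geno is not None:
        meta = geno.snp_meta
        df["chrom"] = meta.loc[df["snp_id"], "chrom"].to_numpy()
        df["pos"] = meta.loc[df["snp_id"], "pos"].to_numpy()
    else:
        df["chrom"] = "NA"
        df["pos"] = np.arange(1, len(df) + 1)
    df["neglog10p"] = -np.log10(df["p_value"])
    manhattan = df[["chrom", "pos", "snp_id", "phenotype_name", "p_value", "neglog10p"]]
    manhattan = manhattan.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    obs = np.sort(df["p_value"].to_numpy())
    n = len(obs)
    qq = pd.DataFrame({
        "expected_neglog10p": -np.log10((np.arange(1, n + 1) - 0.5) / n),
        "observed_neglog10p": -np.log10(obs)[::-1],
    })
    tables = {"manhattan": manhattan, "qq": qq}
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for name, tab in tables.items():
            tab.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False)
        if render:
            _render_plots(tables, out_dir)
    return tables


def _render_plots(tables: dict[str, pd.DataFrame], out_dir: str | os.PathLike) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.scatter(range(len(tables["manhattan"])), tables["manhattan"]["neglog10p"], s=4)
    ax.set_xlabel("SNP index")
    ax.set_ylabel("-log10 p")
    fig.savefig(os.path.join(out_dir, "manhattan.png"), dpi=100)
    plt.close(fig)

    qq = tables["qq"]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(qq["expected_neglog10p"], qq["observed_neglog10p"], s=4)
    lim = max(qq["expected_neglog10p"].max(), qq["observed_neglog10p"].max())
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    fig.savefig(os.path.join(out_dir, "qq.png"), dpi=100)
    plt.close(fig)
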
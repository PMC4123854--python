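"""Baseline-only cross-sectional association: ordinary least squares.

The comparator for every longitudinal power claim: the phenotype at the
baseline visit regressed on the minor-allele count and the covariates,

    y_i = b0 + b1 * s_i + sum_k gamma_k x_ik + e_i,

with H0: b1 = 0 tested by a 1-df Wald chi-square (or, optionally, an exact
t reference).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .datamodel import AnalysisDataset
from .lmm import TestResult

__all__ = ["OlsFit", "fit_baseline", "baseline_snp_test"]


@dataclasses.dataclass
class OlsFit:
    coef: np.ndarray
    cov: np.ndarray
    sigma_sq: float
    residual_df: int
    coef_names: tuple[str, ...]
    n_subjects: int


def fit_baseline(data: AnalysisDataset) -> OlsFit:
    """OLS fit of the baseline model; cov = sigma^2 (X'X)^-1.

    Requires one observation per subject (assemble with
    ``baseline_only=True``); raises on rank deficiency, naming the
    collinear columns.
    """
    if not np.all(data.block_sizes() == 1):
        raise ValueError("baseline fit requires exactly one row per subject; "
                         "assemble the dataset with baseline_only=True")
    X, names = data.design_matrix(include_time=False)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more than {p} subjects for the baseline fit")
    Q, R = np.linalg.qr(X)
    rdiag = np.abs(np.diag(R))
    bad = rdiag <= 1e-10 * max(rdiag.max(), 1.0)
    if bad.any():
        cols = [names[j] for j in np.flatnonzero(bad)]
        raise np.linalg.LinAlgError(f"collinear design columns: {cols}")
    qty = Q.T @ data.y
    coef = np.linalg.solve(R, qty)
    rss = float(data.y @ data.y - qty @ qty)
    residual_df = n - p
    sigma_sq = max(rss, 0.0) / residual_df
    Rinv = np.linalg.inv(R)
    cov = sigma_sq * (Rinv @ Rinv.T)
    return OlsFit(coef, 0.5 * (cov + cov.T), sigma_sq, residual_df, tuple(names), n)


def baseline_snp_test(fit: OlsFit, use_t: bool = False) -> TestResult:
    """Two-sided test of the SNP coefficient.

    Default reference is the 1-df chi-square on (b1/se)^2, consistent with
    the asymptotics used for the longitudinal tests; ``use_t`` switches to
    the exact t distribution on the residual degrees of freedom.
    """
    j = fit.coef_names.index("snp")
    z = fit.coef[j] / np.sqrt(fit.cov[j, j])
    if use_t:
        p = float(2.0 * stats.t.sf(abs(z), fit.residual_df))
        return TestResult("baseline_main_t", float(z * z), 1, p)
    w = float(z * z)
    return TestResult("baseline_main", w, 1, float(stats.chi2.sf(w, 1)))
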
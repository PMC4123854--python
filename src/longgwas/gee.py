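"""Marginal GEE with a compound-symmetry working correlation.

The mean model is the same as the mixed model's fixed-effect part
(identity link, Gaussian working variance); within-subject dependence is
captured only through a working exchangeable correlation ``rho``.  Two
covariance estimators for the coefficients are provided: the model-based
("naive") one, valid only if the working correlation is correct, and the
robust sandwich estimator, valid under misspecification.  With missing
visits the working matrices are built at each cluster's observed size;
validity under dropout then rests on MCAR, a stronger assumption than the
MAR required by the likelihood-based mixed model.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

from .datamodel import AnalysisDataset
from .lmm import FixedEffects, TestResult, _wald_from, _WALD_INDEX

__all__ = ["GeeFit", "fit_gee_cs", "gee_wald"]


@dataclasses.dataclass
class GeeFit:
    coef: FixedEffects
    rho: float
    scale: float
    cov_naive: np.ndarray
    cov_robust: np.ndarray
    n_iterations: int
    converged: bool
    n_subjects: int
    n_observations: int
    coef_names: tuple[str, ...] = ()


def _cs_inverse(m: int, rho: float) -> np.ndarray:
    """Closed-form inverse of (1-rho) I + rho J for cluster size m."""
    a = 1.0 / (1.0 - rho)
    b = -rho / ((1.0 - rho) * (1.0 + (m - 1) * rho))
    return a * np.eye(m) + b * np.ones((m, m))


class _SizeGroups:
    """Clusters grouped by size; all same-size clusters share R(rho)."""

    def __init__(self, data: AnalysisDataset, X: np.ndarray):
        sizes = data.block_sizes()
        starts = np.concatenate([[0], np.cumsum(sizes)])
        by_size: dict[int, list[int]] = {}
        for i, m in enumerate(sizes):
            by_size.setdefault(int(m), []).append(i)
        self.groups = []
        for m, subj in sorted(by_size.items()):
            rows = np.concatenate([np.arange(starts[i], starts[i] + m) for i in subj])
            self.groups.append((m, X[rows].reshape(len(subj), m, X.shape[1]),
                                data.y[rows].reshape(len(subj), m)))
        self.sizes = sizes
        self.max_size = int(sizes.max()) if sizes.size else 0
        self.n_pairs = float((sizes * (sizes - 1) / 2).sum())


def fit_gee_cs(
    data: AnalysisDataset,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> GeeFit:
    """Fit the marginal mean model by GEE with exchangeable correlation.

    Alternates (i) a GLS update of the coefficients given (rho, scale) with
    working covariance ``scale * [(1-rho) I + rho J]`` per cluster, and
    (ii) moment updates ``scale = sum(r^2)/N`` and
    ``rho = sum_{j<k} e_j e_k / sum m_i(m_i-1)/2`` over Pearson residuals
    ``e = r / sqrt(scale)`` (simple pooled estimators, no degrees-of-freedom
    correction).  Size-1 clusters contribute to the scale but not to rho;
    if every cluster has size 1, rho = 0 by convention and the fit is OLS.
    """
    if data.n_subjects < 2:
        raise ValueError("GEE needs at least 2 subjects")
    X, names = data.design_matrix(include_time=True)
    g = _SizeGroups(data, X)
    N, p = data.n_observations, X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is not full rank")

    rho_max = 1.0 - 1e-6
    rho_min = -1.0 / max(g.max_size - 1, 1) + 1e-6

    beta = np.linalg.lstsq(X, data.y, rcond=None)[0]
    rho, scale = 0.0, 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # moment updates at current beta
        ss, cross = 0.0, 0.0
        for m, Xg, yg in g.groups:
            r = yg - np.einsum("amp,p->am", Xg, beta)
            ss += float((r * r).sum())
            if m > 1:
                rowsum = r.sum(axis=1)
                cross += 0.5 * float((rowsum**2 - (r * r).sum(axis=1)).sum())
        scale = ss / N
        if g.n_pairs > 0:
            rho = float(np.clip(cross / (scale * g.n_pairs), rho_min, rho_max))
        else:
            rho = 0.0
        # GLS update of beta (scale cancels)
        A = np.zeros((p, p))
        b = np.zeros(p)
        for m, Xg, yg in g.groups:
            Rinv = _cs_inverse(m, rho)
            XR = np.einsum("amp,mk->akp", Xg, Rinv)
            A += np.einsum("akp,akq->pq", XR, Xg)
            b += np.einsum("akp,ak->p", XR, yg)
        beta_new = np.linalg.solve(A, b)
        delta = float(np.max(np.abs(beta_new - beta)) / (1.0 + np.max(np.abs(beta_new))))
        beta = beta_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("GEE did not converge", RuntimeWarning)

    # covariance estimators at the final (beta, rho, scale)
    A = np.zeros((p, p))
    M = np.zeros((p, p))
    for m, Xg, yg in g.groups:
        Rinv = _cs_inverse(m, rho)
        XR = np.einsum("amp,mk->akp", Xg, Rinv)
        A += np.einsum("akp,akq->pq", XR, Xg)
        r = yg - np.einsum("amp,p->am", Xg, beta)
        u = np.einsum("akp,ak->ap", XR, r)  # X_i' R^-1 r_i per cluster
        M += u.T @ u
    bread = np.linalg.inv(A)
    cov_naive = scale * bread
    cov_robust = bread @ M @ bread
    return GeeFit(
        coef=FixedEffects.from_array(beta),
        rho=rho,
        scale=scale,
        cov_naive=0.5 * (cov_naive + cov_naive.T),
        cov_robust=0.5 * (cov_robust + cov_robust.T),
        n_iterations=it,
        converged=converged,
        n_subjects=data.n_subjects,
        n_observations=N,
        coef_names=tuple(names),
    )


def gee_wald(fit: GeeFit, which: str = "joint", cov: str = "robust") -> TestResult:
    """Wald test on the GEE coefficients with the chosen covariance.

    ``cov='robust'`` uses the sandwich estimator, ``cov='naive'`` the
    model-based one; the quadratic forms are those of ``lmm.wald_test``.
    """
    if which not in _WALD_INDEX:
        raise ValueError(f"unknown Wald test {which!r}")
    if cov == "robust":
        c = fit.cov_robust
    elif cov == "naive":
        c = fit.cov_naive
    else:
        raise ValueError(f"cov must be 'naive' or 'robust', got {cov!r}")
    res = _wald_from(fit.coef.as_array(), c, which)
    return TestResult(f"{which}_{cov}", res.statistic, res.df, res.p_value)
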
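"""Linear mixed models for longitudinal SNP association.

The working model for a phenotype value ``y_ij`` of subject ``i`` at time
``t_ij`` (months since baseline) is

    y_ij = b0 + b1 * s_i + b2 * t_ij + b3 * s_i * t_ij
           + sum_k gamma_k * x_ik + u0_i + u2_i * t_ij + e_ij,

with ``s_i`` the minor-allele count, subject random effects
``(u0_i, u2_i) ~ N(0, D)`` where
``D = [[sigma0_sq, sigma02], [sigma02, sigma2_sq]]``, and i.i.d. residuals
``e_ij ~ N(0, sigma_eps_sq)``.  The random-intercept-only special case pins
``sigma2_sq = sigma02 = 0`` and implies a compound-symmetry marginal
covariance.  Association is tested by Wald statistics on (b1, b3), and the
need for the random slope by a likelihood-ratio test whose null distribution
is the boundary mixture ``0.5*chi2(1) + 0.5*chi2(2)``.

Estimation maximizes the marginal (REML or ML) Gaussian likelihood over an
unconstrained parameterization (log standard deviations and an atanh-scaled
intercept-slope correlation), which enforces positive semidefiniteness of D
by construction.  Subjects sharing a visit-time pattern share a marginal
covariance matrix, so likelihood evaluations group subjects by pattern and
whiten each group with a single Cholesky factor.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import linalg, optimize, stats

from .datamodel import AnalysisDataset

__all__ = [
    "FixedEffects",
    "VarianceComponents",
    "LmmFit",
    "TestResult",
    "marginal_covariance",
    "profile_loglik",
    "fit_lmm",
    "wald_test",
    "lrt_random_slope",
    "chibar2_sf",
    "DegenerateDataError",
]

_LOG2PI = np.log(2.0 * np.pi)


class DegenerateDataError(ValueError):
    """The data cannot identify the requested random-effects structure."""


@dataclasses.dataclass
class FixedEffects:
    """Fixed-effect estimates: intercept, SNP main effect (per minor
    allele), time slope (per month), SNP x time interaction, and covariate
    coefficients."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    gamma: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.concatenate([[self.beta0, self.beta1, self.beta2, self.beta3], self.gamma])

    @classmethod
    def from_array(cls, b: np.ndarray) -> "FixedEffects":
        b = np.asarray(b, dtype=float)
        return cls(b[0], b[1], b[2], b[3], b[4:].copy())


@dataclasses.dataclass
class VarianceComponents:
    """Random-effect (co)variances and the residual variance.

    ``sigma0_sq``: random-intercept variance; ``sigma2_sq``: random-slope
    variance (per month^2); ``sigma02``: intercept-slope covariance;
    ``sigma_eps_sq``: residual variance.  D must be PSD and the residual
    variance strictly positive.
    """

    sigma0_sq: float
    sigma2_sq: float
    sigma02: float
    sigma_eps_sq: float

    def validate(self) -> None:
        if self.sigma0_sq < 0 or self.sigma2_sq < 0:
            raise ValueError("random-effect variances must be non-negative")
        if self.sigma_eps_sq <= 0:
            raise ValueError("residual variance must be positive")
        if self.sigma02**2 > self.sigma0_sq * self.sigma2_sq * (1 + 1e-12) + 1e-300:
            raise ValueError("sigma02^2 exceeds sigma0_sq * sigma2_sq (D not PSD)")

    def d_matrix(self) -> np.ndarray:
        return np.array([[self.sigma0_sq, self.sigma02], [self.sigma02, self.sigma2_sq]])


@dataclasses.dataclass
class LmmFit:
    fixed: FixedEffects
    vc: VarianceComponents
    cov_fixed: np.ndarray
    loglik: float
    method: str
    converged: bool
    n_subjects: int
    n_observations: int
    random_slope: bool = True
    coef_names: tuple[str, ...] = ()
    n_restarts_used: int = 0


@dataclasses.dataclass
class TestResult:
    """A test statistic with its reference distribution and p-value.

    ``df`` is the chi-square degrees of freedom, or ``None`` when the null
    is the 50:50 boundary mixture of chi2(1) and chi2(2).
    """

    name: str
    statistic: float
    df: int | None
    p_value: float
    null: str = "chi2"


def marginal_covariance(vc: VarianceComponents, times: np.ndarray) -> np.ndarray:
    """Marginal covariance of one subject's observations at ``times``.

    Var(y_ij)        = sigma0_sq + 2 t_ij sigma02 + t_ij^2 sigma2_sq + sigma_eps_sq
    Cov(y_ij, y_ik)  = sigma0_sq + (t_ij + t_ik) sigma02 + t_ij t_ik sigma2_sq

    With sigma02 = sigma2_sq = 0 this reduces to compound symmetry.
    """
    vc.validate()
    t = np.asarray(times, dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("times must be finite")
    V = (
        vc.sigma0_sq
        + vc.sigma02 * np.add.outer(t, t)
        + vc.sigma2_sq * np.outer(t, t)
    )
    V[np.diag_indices_from(V)] += vc.sigma_eps_sq
    return V


class _GroupedDesign:
    """Per-pattern sufficient statistics for the marginal likelihood.

    Subjects sharing a visit-time pattern share the marginal covariance
    matrix V(t), so the likelihood depends on the data only through the
    pattern-level cross-products

        T[j,k,:,:] = sum_a X_a[j,:]' X_a[k,:],
        U[j,k,:]   = sum_a X_a[j,:] y_a[k],
        W[j,k]     = sum_a y_a[j] y_a[k],

    which are precomputed once; each likelihood evaluation then costs only
    one small Cholesky and a few tensor contractions per pattern.  Design
    columns are standardized to unit root-mean-square internally (estimates
    and the REML determinant are mapped back to the original scale).
    """

    def __init__(self, data: AnalysisDataset, X: np.ndarray):
        N = data.n_observations
        scale = np.linalg.norm(X, axis=0) / np.sqrt(max(N, 1))
        scale[scale == 0] = 1.0
        Xs = X / scale
        self.scale = scale
        self.log_scale_sum = float(np.log(scale).sum())

        sizes = data.block_sizes()
        starts = np.concatenate([[0], np.cumsum(sizes)])
        groups: dict[bytes, list[int]] = {}
        keys: dict[bytes, np.ndarray] = {}
        for i in range(data.n_subjects):
            t = data.times[starts[i]:starts[i + 1]]
            k = t.tobytes()
            groups.setdefault(k, []).append(i)
            keys[k] = t
        # batch patterns of equal block size so one evaluation is a few
        # vectorized calls per distinct size
        by_size: dict[int, list] = {}
        p = Xs.shape[1]
        for k, subj in groups.items():
            t = keys[k]
            m = len(t)
            rows = np.concatenate([np.arange(starts[i], starts[i] + m) for i in subj])
            Xg = Xs[rows].reshape(len(subj), m, p)
            yg = data.y[rows].reshape(len(subj), m)
            T = np.einsum("ajp,akq->jkpq", Xg, Xg).reshape(m * m, p * p)
            U = np.einsum("ajp,ak->jkp", Xg, yg).reshape(m * m, p)
            W = (yg.T @ yg).reshape(m * m)
            by_size.setdefault(m, []).append((t, len(subj), T, U, W))
        self.size_groups = []
        for m, items in sorted(by_size.items()):
            times = np.stack([it[0] for it in items])            # (G, m)
            counts = np.array([it[1] for it in items], float)    # (G,)
            T = np.stack([it[2] for it in items]).reshape(-1, p * p)  # (G*m2, p2)
            U = np.stack([it[3] for it in items]).reshape(-1, p)      # (G*m2, p)
            W = np.stack([it[4] for it in items]).reshape(-1)         # (G*m2,)
            self.size_groups.append((m, times, counts, T, U, W))
        self.N = N
        self.p = p
        self.max_block = int(sizes.max()) if sizes.size else 0

    def accumulate(self, vc: VarianceComponents):
        """(A, b, yvy, logdet) for the scaled design at ``vc``.

        Returns None when some pattern's marginal covariance is not
        positive definite.
        """
        p = self.p
        A = np.zeros(p * p)
        b = np.zeros(p)
        yvy = 0.0
        logdet = 0.0
        for m, times, counts, T, U, W in self.size_groups:
            V = (
                vc.sigma0_sq
                + vc.sigma02 * (times[:, :, None] + times[:, None, :])
                + vc.sigma2_sq * times[:, :, None] * times[:, None, :]
            )
            V[:, np.arange(m), np.arange(m)] += vc.sigma_eps_sq
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return None
            ldiag = np.diagonal(L, axis1=1, axis2=2)
            logdet += 2.0 * float(counts @ np.log(ldiag).sum(axis=1))
            Vinv = np.linalg.inv(V)              # (G, m, m); V is PD here
            v = Vinv.reshape(1, -1)              # (1, G*m2)
            A += (v @ T)[0]
            b += (v @ U)[0]
            yvy += float(v[0] @ W)
        return A.reshape(p, p), b, yvy, logdet


def _criterion(grouped: _GroupedDesign, vc: VarianceComponents, method: str):
    """(criterion, beta, cov_fixed) at fixed variance components.

    Fixed effects are profiled out by GLS.  ``criterion`` is the marginal
    Gaussian log-likelihood (ML) or the REML log-likelihood with the usual
    log|X' V^-1 X| adjustment, including all 2*pi constants.
    """
    N, p = grouped.N, grouped.p
    acc = grouped.accumulate(vc)
    if acc is None:
        return None
    A, b, yvy, logdet = acc
    try:
        cA, low = linalg.cho_factor(A, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "X' V^-1 X singular (rank-deficient design)"
        ) from exc
    beta_s = linalg.cho_solve((cA, low), b)
    quad = max(float(yvy - b @ beta_s), 0.0)
    if method == "ML":
        crit = -0.5 * (N * _LOG2PI + logdet + quad)
    elif method == "REML":
        logdet_a_scaled = 2.0 * np.log(np.diag(cA)).sum()
        logdet_xvx = logdet_a_scaled + 2.0 * grouped.log_scale_sum
        crit = -0.5 * ((N - p) * _LOG2PI + logdet + logdet_xvx + quad)
    else:
        raise ValueError(f"unknown method {method!r}")
    cov_s = linalg.cho_solve((cA, low), np.eye(p))
    beta = beta_s / grouped.scale
    cov_fixed = cov_s / np.outer(grouped.scale, grouped.scale)
    return crit, beta, cov_fixed


def profile_loglik(
    vc: VarianceComponents,
    data: AnalysisDataset,
    method: str = "REML",
    _grouped: _GroupedDesign | None = None,
):
    """Profiled log-likelihood at fixed variance components.

    Returns ``(criterion, FixedEffects, cov_fixed)`` where the fixed effects
    are the GLS estimates given ``vc`` and ``cov_fixed`` their GLS
    covariance.
    """
    vc.validate()
    if _grouped is None:
        X, _ = data.design_matrix(include_time=True)
        _grouped = _GroupedDesign(data, X)
    out = _criterion(_grouped, vc, method)
    if out is None:
        raise ValueError("marginal covariance not positive definite at vc")
    crit, beta, cov_fixed = out
    return crit, FixedEffects.from_array(beta), cov_fixed


def _theta_to_vc(theta: np.ndarray, random_slope: bool) -> VarianceComponents:
    if random_slope:
        s0, s2 = np.exp(theta[0]), np.exp(theta[1])
        rho = np.tanh(theta[2])
        se = np.exp(theta[3])
        return VarianceComponents(s0 * s0, s2 * s2, rho * s0 * s2, se * se)
    s0, se = np.exp(theta[0]), np.exp(theta[1])
    return VarianceComponents(s0 * s0, 0.0, 0.0, se * se)


def _start_values(data: AnalysisDataset, X: np.ndarray, random_slope: bool) -> np.ndarray:
    """Moment-based starting point on the unconstrained scale."""
    beta, *_ = np.linalg.lstsq(X, data.y, rcond=None)
    r = data.y - X @ beta
    tot = max(float(r.var()), 1e-10)
    # split residual variance between subject level and noise
    means = np.bincount(data.subject_index, weights=r, minlength=data.n_subjects)
    sizes = np.maximum(data.block_sizes(), 1)
    between = float(np.var(means / sizes))
    s0 = np.sqrt(max(min(between, 0.9 * tot), 0.05 * tot))
    se = np.sqrt(max(tot - s0 * s0, 0.05 * tot))
    if not random_slope:
        return np.log([s0, se])
    tspan = max(float(data.times.max() - data.times.min()), 1.0)
    s2 = 0.5 * se / tspan  # slope SD that moves ~half a residual SD over the span
    return np.array([np.log(s0), np.log(s2), 0.0, np.log(se)])


_DISPERSED_OFFSETS = [
    np.array([1.0, -1.0, 0.5, -0.5]),
    np.array([-1.0, 1.0, -0.5, 0.5]),
    np.array([2.0, 2.0, 0.0, -1.0]),
]


def fit_lmm(
    data: AnalysisDataset,
    random_slope: bool = True,
    method: str = "REML",
    n_restarts: int = 3,
    tol: float = 1e-11,
) -> LmmFit:
    """Fit the mixed model by maximizing the REML or ML criterion.

    Variance components are optimized on an unconstrained scale
    (log-standard-deviations and atanh-scaled correlation), so the fitted D
    is PSD by construction.  The first start is moment-based; up to
    ``n_restarts`` dispersed restarts are attempted when optimization fails
    to converge.  Non-convergence is reported honestly via ``converged``.
    """
    if method not in ("REML", "ML"):
        raise ValueError(f"unknown method {method!r}")
    sizes = data.block_sizes()
    if data.n_subjects < 2:
        raise DegenerateDataError("need at least 2 subjects")
    if random_slope:
        if (sizes >= 2).sum() < 2:
            raise DegenerateDataError(
                "random-slope model needs >=2 subjects with >=2 visits; "
                "use random_slope=False or the baseline cross-sectional model"
            )
    X, names = data.design_matrix(include_time=True)
    norms = np.linalg.norm(X, axis=0)
    if norms.min() == 0 or np.linalg.matrix_rank(X / norms) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient (constant SNP or collinear covariates)"
        )
    grouped = _GroupedDesign(data, X)
    k = 4 if random_slope else 2

    def negloglik(theta: np.ndarray) -> float:
        vc = _theta_to_vc(theta, random_slope)
        try:
            out = _criterion(grouped, vc, method)
        except np.linalg.LinAlgError:
            return 1e12
        if out is None or not np.isfinite(out[0]):
            return 1e12
        return -out[0]

    theta0 = _start_values(data, X, random_slope)
    bounds = [(-30.0, 30.0)] * k
    if random_slope:
        bounds[2] = (-6.0, 6.0)  # |rho| <= tanh(6) ~ 0.99999

    best = None
    starts = [theta0]
    for off in _DISPERSED_OFFSETS[:n_restarts]:
        starts.append(theta0 + (off if random_slope else off[:2]))
    tried = 0
    for s in starts:
        res = optimize.minimize(
            negloglik, s, method="L-BFGS-B", bounds=bounds,
            options={"ftol": tol, "gtol": 1e-6, "maxiter": 500},
        )
        tried += 1
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if best.success:
            break
    if best is None or not np.isfinite(best.fun):  # pragma: no cover
        raise RuntimeError("optimization failed to produce a finite criterion")

    vc = _theta_to_vc(best.x, random_slope)
    crit, beta, cov_fixed = _criterion(grouped, vc, method)
    if not best.success:
        warnings.warn("mixed-model optimization did not converge", RuntimeWarning)
    return LmmFit(
        fixed=FixedEffects.from_array(beta),
        vc=vc,
        cov_fixed=cov_fixed,
        loglik=crit,
        method=method,
        converged=bool(best.success),
        n_subjects=data.n_subjects,
        n_observations=data.n_observations,
        random_slope=random_slope,
        coef_names=tuple(names),
        n_restarts_used=tried - 1,
    )


_WALD_INDEX = {"joint": (1, 3), "main": (1,), "interaction": (3,)}


def _wald_from(beta: np.ndarray, cov: np.ndarray, which: str) -> TestResult:
    if which not in _WALD_INDEX:
        raise ValueError(f"unknown Wald test {which!r}")
    idx = list(_WALD_INDEX[which])
    b = beta[idx]
    sub = cov[np.ix_(idx, idx)]
    try:
        w = float(b @ np.linalg.solve(sub, b))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular covariance submatrix for {which} test") from exc
    if not np.isfinite(w):
        raise np.linalg.LinAlgError(f"singular covariance submatrix for {which} test")
    df = len(idx)
    return TestResult(which, max(w, 0.0), df, float(stats.chi2.sf(max(w, 0.0), df)))


def wald_test(fit: LmmFit, which: str = "joint") -> TestResult:
    """Wald chi-square test of the SNP effects.

    ``joint``: 2-df test of H0: b1 = b3 = 0 (no SNP main effect and no
    SNP x time interaction); ``main`` / ``interaction``: 1-df tests of the
    individual coefficients.
    """
    return _wald_from(fit.fixed.as_array(), fit.cov_fixed, which)


def chibar2_sf(t: float) -> float:
    """Survival function of the 0.5*chi2(1) + 0.5*chi2(2) boundary mixture."""
    t = max(float(t), 0.0)
    return float(0.5 * stats.chi2.sf(t, 1) + 0.5 * stats.chi2.sf(t, 2))


def lrt_random_slope(data: AnalysisDataset, method: str = "REML") -> TestResult:
    """Likelihood-ratio test of H0: sigma2_sq = sigma02 = 0.

    Both nested fits use the same fixed effects and the same criterion
    (REML by default, which is valid here because the fixed-effect
    structures coincide).  The statistic is floored at zero; the null is the
    Stram-Lee 50:50 mixture of chi2(1) and chi2(2) because the slope
    variance sits on the boundary of its parameter space.
    """
    fit_rsi = fit_lmm(data, random_slope=True, method=method)
    fit_ri = fit_lmm(data, random_slope=False, method=method)
    t = max(0.0, 2.0 * (fit_rsi.loglik - fit_ri.loglik))
    return TestResult("random_slope_lrt", t, None, chibar2_sf(t), null="chibar2_1_2")
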
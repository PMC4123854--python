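import numpy as np
import pytest

from longgwas.datamodel import AnalysisDataset


def make_longitudinal_dataset(
    rng: np.random.Generator,
    n: int = 40,
    max_visits: int = 5,
    sigma0_sq: float = 1.0,
    sigma2_sq: float = 0.25,
    sigma02: float = 0.3,
    sigma_eps_sq: float = 0.49,
) -> AnalysisDataset:
    """Small random-slope dataset on unit scale, for oracle comparisons."""
    sizes = rng.integers(2, max_visits + 1, n)
    subj, times, y = [], [], []
    snp = rng.binomial(2, 0.3, n).astype(float)
    cov = rng.standard_normal((n, 2))
    beta = np.array([1.0, 0.5, -0.2, 0.3, 0.8, -0.5])
    D = np.array([[sigma0_sq, sigma02], [sigma02, sigma2_sq]])
    Lc = np.linalg.cholesky(D)
    for i in range(n):
        t = np.sort(rng.choice(np.arange(0.0, 8.0), sizes[i], replace=False))
        u = Lc @ rng.standard_normal(2)
        mu = beta[0] + beta[1] * snp[i] + beta[2] * t + beta[3] * snp[i] * t + cov[i] @ beta[4:]
        yi = mu + u[0] + u[1] * t + rng.normal(0, np.sqrt(sigma_eps_sq), sizes[i])
        subj += [i] * int(sizes[i])
        times.append(t)
        y.append(yi)
    return AnalysisDataset(
        subject_ids=np.arange(n),
        times=np.concatenate(times),
        y=np.concatenate(y),
        subject_index=np.array(subj),
        snp=snp,
        covariates=cov,
        covariate_names=("c1", "c2"),
    )


def dense_gaussian_loglik(data: AnalysisDataset, vc, method: str = "REML") -> float:
    """Brute-force marginal log-likelihood via one dense block covariance.

    Independent of the fitting code path: builds the full N x N covariance,
    inverts it densely, and uses textbook formulas for the ML and REML
    criteria.
    """
    from longgwas.lmm import marginal_covariance

    X, _ = data.design_matrix()
    N, p = X.shape
    Vb = np.zeros((N, N))
    sizes = data.block_sizes()
    starts = np.concatenate([[0], np.cumsum(sizes)])
    for i in range(data.n_subjects):
        sl = slice(starts[i], starts[i + 1])
        Vb[sl, sl] = marginal_covariance(vc, data.times[sl])
    Vi = np.linalg.inv(Vb)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ data.y)
    r = data.y - X @ beta
    _, ldV = np.linalg.slogdet(Vb)
    quad = r @ Vi @ r
    if method == "ML":
        return float(-0.5 * (N * np.log(2 * np.pi) + ldV + quad))
    _, ldA = np.linalg.slogdet(A)
    return float(-0.5 * ((N - p) * np.log(2 * np.pi) + ldV + ldA + quad))


@pytest.fixture
def toy_dataset() -> AnalysisDataset:
    return make_longitudinal_dataset(np.random.default_rng(7))
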
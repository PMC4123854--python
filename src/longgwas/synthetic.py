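"""Synthetic longitudinal cohorts with ADNI-like structure.

Generates a cohort of elderly subjects observed at a fixed visit grid in
months, with per-visit availability (MCAR by default), Hardy-Weinberg
genotypes at a configurable minor-allele frequency, five demographic
covariates, and phenotypes drawn from the random-intercept+slope mixed
model or its random-intercept-only special case.  The default scales mimic
a left-hippocampal-volume trait (mm^3): population mean near 3400 mm^3,
between-subject SD about 400 mm^3, mean atrophy of a few mm^3 per month.

These defaults are surrogate values on a realistic scale, not estimates
from any real cohort; the calibration claims the package tests (type-I
error of valid tests, inflation of misspecified ones) are robust to them,
whereas absolute power levels are not.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_COVARIATES,
    CovariateTable,
    GenotypeMatrix,
    LongPhenotypeTable,
)
from .lmm import FixedEffects, VarianceComponents

__all__ = [
    "CohortSpec",
    "GenerativeParams",
    "simulate_genotypes",
    "simulate_cohort",
    "default_params",
    "DEFAULT_RETENTION",
    "DEFAULT_VISIT_MONTHS",
]

#: Visit grid (months since baseline) and the per-visit fraction of the
#: cohort with a usable scan, patterned on a 638-subject study arm.
DEFAULT_VISIT_MONTHS = (0.0, 6.0, 12.0, 18.0, 24.0, 36.0, 48.0)
DEFAULT_RETENTION = (0.995, 0.966, 0.90, 0.386, 0.724, 0.412, 0.088)

#: Covariate generators: (kind, params).  Bernoulli for binaries, normal
#: for continuous traits.  Invented plumbing defaults, fully configurable.
DEFAULT_COVARIATE_DISTRIBUTIONS = {
    "handedness": ("bernoulli", {"p": 0.93}),
    "education_years": ("normal", {"mean": 15.0, "sd": 3.0}),
    "baseline_age": ("normal", {"mean": 75.0, "sd": 6.5}),
    "gender": ("bernoulli", {"p": 0.6}),
    "icv": ("normal", {"mean": 1.5e6, "sd": 1.5e5}),
}


@dataclasses.dataclass
class CohortSpec:
    """Design of a synthetic cohort: size, visit grid, availability, MAF."""

    n_subjects: int = 638
    visit_months: tuple[float, ...] = DEFAULT_VISIT_MONTHS
    retention: tuple[float, ...] = DEFAULT_RETENTION
    maf: float = 0.14
    covariate_distributions: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_DISTRIBUTIONS)
    )
    seed: int | None = None
    phenotype_name: str = "LHippVol"
    snp_id: str = "snp1"
    n_snps: int = 1
    exact_counts: bool = False   # fix per-visit counts at round(retention * n)
    dropout_mar: bool = False    # outcome-dependent dropout instead of MCAR

    def __post_init__(self) -> None:
        if len(self.retention) != len(self.visit_months):
            raise ValueError("retention must match visit_months in length")
        if not all(0.0 <= r <= 1.0 for r in self.retention):
            raise ValueError("retention probabilities must lie in [0, 1]")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")


@dataclasses.dataclass
class GenerativeParams:
    """Generating fixed effects and variance components.

    ``model='rsi'`` draws subject effects (u0, u2) ~ N(0, D); ``model='ri'``
    pins the slope variance and covariance at zero.  ``hypothesis='null'``
    forces beta1 = beta3 = 0.
    """

    fixed: FixedEffects
    vc: VarianceComponents
    model: str = "rsi"
    hypothesis: str = "null"

    def __post_init__(self) -> None:
        if self.model not in ("rsi", "ri"):
            raise ValueError("model must be 'rsi' or 'ri'")
        if self.hypothesis not in ("null", "alternative"):
            raise ValueError("hypothesis must be 'null' or 'alternative'")
        if self.hypothesis == "null":
            self.fixed = dataclasses.replace(self.fixed, beta1=0.0, beta3=0.0)
        if self.model == "ri":
            self.vc = dataclasses.replace(self.vc, sigma2_sq=0.0, sigma02=0.0)
        self.vc.validate()


# Surrogate generating values on a left-hippocampus (mm^3) scale: baseline
# mean 3400 mm^3, between-subject SD 400 mm^3, mean atrophy -7 mm^3/month
# with slope SD 8 mm^3/month (a mixed healthy/MCI/dementia cohort spans
# roughly -12 to +2 mm^3/month), residual SD 150 mm^3.  The slope SD is set
# so the random-slope likelihood-ratio signal on a default cohort matches
# what strongly heterogeneous real cohorts show (statistics in the hundreds).
_BASE_FIXED = dict(beta0=3400.0, beta1=60.0, beta2=-7.0, beta3=1.5,
                   gamma=np.array([20.0, 5.0, -15.0, 150.0, 1.5e-3]))
_BASE_VC = dict(sigma0_sq=160_000.0, sigma2_sq=64.0, sigma02=-480.0,
                sigma_eps_sq=22_500.0)


def default_params(scenario: str = "rsi", hypothesis: str = "null") -> GenerativeParams:
    """Documented surrogate generating parameters for the two scenarios.

    ``rsi``: the random-intercept+slope model at the package's default
    hippocampal-scale values.  ``cs``: the random-intercept-only model
    with every fixed effect and variance component halved relative to the
    rsi base, mirroring a half-scale compound-symmetry world.
    """
    if scenario == "rsi":
        return GenerativeParams(
            fixed=FixedEffects(**_BASE_FIXED),
            vc=VarianceComponents(**_BASE_VC),
            model="rsi",
            hypothesis=hypothesis,
        )
    if scenario == "cs":
        f = _BASE_FIXED
        return GenerativeParams(
            fixed=FixedEffects(beta0=f["beta0"] / 2, beta1=f["beta1"] / 2,
                               beta2=f["beta2"] / 2, beta3=f["beta3"] / 2,
                               gamma=f["gamma"] / 2),
            vc=VarianceComponents(sigma0_sq=_BASE_VC["sigma0_sq"] / 2,
                                  sigma2_sq=0.0, sigma02=0.0,
                                  sigma_eps_sq=_BASE_VC["sigma_eps_sq"] / 2),
            model="ri",
            hypothesis=hypothesis,
        )
    raise ValueError(f"unknown scenario {scenario!r}")


def simulate_genotypes(n: int, maf: float, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """I.i.d. Hardy-Weinberg minor-allele counts: Binomial(2, maf)."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    rng = np.random.default_rng(rng)
    return rng.binomial(2, maf, size=n).astype(float)


def _draw_covariates(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    cols = []
    for name in DEFAULT_COVARIATES:
        kind, pars = spec.covariate_distributions[name]
        if kind == "bernoulli":
            cols.append(rng.binomial(1, pars["p"], spec.n_subjects).astype(float))
        elif kind == "normal":
            cols.append(rng.normal(pars["mean"], pars["sd"], spec.n_subjects))
        else:
            raise ValueError(f"unknown covariate distribution kind {kind!r}")
    return np.column_stack(cols)


def _visit_mask(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """(n_subjects, n_visits) availability indicator."""
    n, v = spec.n_subjects, len(spec.visit_months)
    if spec.exact_counts:
        mask = np.zeros((n, v), dtype=bool)
        for j, r in enumerate(spec.retention):
            k = int(round(r * n))
            mask[rng.choice(n, size=k, replace=False), j] = True
        return mask
    return rng.random((n, v)) < np.asarray(spec.retention)


def simulate_cohort(
    spec: CohortSpec,
    params: GenerativeParams,
    seed: int | np.random.Generator | None = None,
) -> tuple[LongPhenotypeTable, CovariateTable, GenotypeMatrix]:
    """Draw one cohort: phenotype long table, covariates, genotype matrix.

    Per subject: genotype s ~ Binomial(2, maf); covariates from the
    configured distributions; random effects (u0, u2) ~ N(0, D) (u2 = 0
    under the random-intercept model); visits retained by independent
    per-visit Bernoulli draws (or fixed counts when ``exact_counts``); and

        y = beta0 + beta1 s + beta2 t + beta3 s t + gamma'x + u0 + u2 t + eps.

    Only the first SNP column affects the phenotype; any further SNPs
    (``n_snps > 1``) are independent null markers for scan calibration.
    Subjects with zero retained visits are dropped, matching observed-data
    analysis.  With ``dropout_mar`` a subject's later visits are instead
    censored after a hazard that increases as the phenotype falls below its
    expected trajectory, violating MCAR but not MAR.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_subjects
    tgrid = np.asarray(spec.visit_months)

    geno = np.column_stack([simulate_genotypes(n, spec.maf, rng) for _ in range(spec.n_snps)])
    cov = _draw_covariates(spec, rng)

    f, vcp = params.fixed, params.vc
    L = np.linalg.cholesky(vcp.d_matrix() + 1e-12 * np.eye(2))
    u = rng.standard_normal((n, 2)) @ L.T
    if params.model == "ri":
        u[:, 1] = 0.0

    s = geno[:, 0]
    mean_fixed = f.beta0 + f.beta1 * s + cov @ f.gamma          # (n,)
    slope = f.beta2 + f.beta3 * s + u[:, 1]                      # (n,)
    yfull = (mean_fixed + u[:, 0])[:, None] + np.outer(slope, tgrid)
    yfull = yfull + rng.normal(0.0, np.sqrt(vcp.sigma_eps_sq), size=yfull.shape)

    mask = _visit_mask(spec, rng)
    if spec.dropout_mar:
        # censor everything after the first visit at which the phenotype has
        # fallen > 1 SD below its subject-specific expectation
        expected = mean_fixed[:, None] + np.outer(f.beta2 + f.beta3 * s, tgrid)
        low = yfull < expected - np.sqrt(vcp.sigma0_sq + vcp.sigma_eps_sq)
        drop = rng.random((n, len(tgrid))) < 0.5 * low
        cens = np.cumsum(np.cumsum(drop, axis=1), axis=1) > 1
        mask &= ~cens

    subj_ids = np.array([f"S{i:04d}" for i in range(n)])
    rows_i, rows_j = np.nonzero(mask)
    pheno = LongPhenotypeTable(pd.DataFrame({
        "subject_id": subj_ids[rows_i],
        "visit_month": tgrid[rows_j],
        "phenotype_name": spec.phenotype_name,
        "value": yfull[rows_i, rows_j],
    }))

    cov_df = pd.DataFrame(cov, columns=list(DEFAULT_COVARIATES))
    cov_df.insert(0, "subject_id", subj_ids)
    snp_ids = np.array([spec.snp_id] + [f"null{k}" for k in range(1, spec.n_snps)])
    gm = GenotypeMatrix(subj_ids, snp_ids, geno)
    return pheno, CovariateTable(cov_df), gm
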
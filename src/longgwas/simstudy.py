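"""Type-I error and power study: replicate cohorts, five estimators.

For each replicate a synthetic cohort is generated and analyzed by up to
five methods: the random-intercept+slope mixed model (LME-RSI), the
random-intercept-only mixed model (LME-RI), GEE with the sandwich
covariance (GEE-Robust), GEE with the model-based covariance (GEE-Naive),
and baseline-only OLS (Baseline).  The longitudinal methods use the 2-df
joint Wald test of the SNP main effect and SNP x time interaction; the
baseline method uses the 1-df main-effect test.  The rejection fraction per
nominal level estimates type-I error under a null scenario and power under
an alternative one.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import cross_sectional, gee, lmm
from .datamodel import assemble_dataset
from .synthetic import CohortSpec, GenerativeParams, simulate_cohort

__all__ = ["SimulationSummary", "run_study", "summarize", "ALL_METHODS"]

ALL_METHODS = ("LME-RSI", "LME-RI", "GEE-Robust", "GEE-Naive", "Baseline")


@dataclasses.dataclass
class SimulationSummary:
    """Empirical rejection rates per method x nominal level."""

    scenario: str
    methods: tuple[str, ...]
    nominal_levels: tuple[float, ...]
    rejection_rate: np.ndarray          # (n_methods, n_levels)
    n_reps: int
    n_nonconverged: dict[str, int]
    seed: int
    valid: bool = True
    test_kind: str = "joint"

    def mc_se(self) -> np.ndarray:
        r = self.rejection_rate
        return np.sqrt(r * (1.0 - r) / self.n_reps)

    def rate(self, method: str, level: float) -> float:
        i = self.methods.index(method)
        j = self.nominal_levels.index(level)
        return float(self.rejection_rate[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rejection_rate, index=list(self.methods),
                          columns=[f"{lv:g}" for lv in self.nominal_levels])
        df.index.name = "method"
        return df


def _replicate_pvalues(
    spec: CohortSpec,
    params: GenerativeParams,
    methods: tuple[str, ...],
    rep_seed: np.random.SeedSequence,
    test_kind: str,
) -> dict[str, float]:
    """One replicate: generate, assemble, analyze; NaN marks a failed fit."""
    rng = np.random.default_rng(rep_seed)
    pheno, cov, geno = simulate_cohort(spec, params, seed=rng)
    out: dict[str, float] = {}

    long_methods = [m for m in methods if m != "Baseline"]
    if long_methods:
        data = assemble_dataset(pheno, cov, geno, spec.snp_id, spec.phenotype_name)
        if "LME-RSI" in methods:
            out["LME-RSI"] = _safe_lmm(data, True, test_kind)
        if "LME-RI" in methods:
            out["LME-RI"] = _safe_lmm(data, False, test_kind)
        if "GEE-Robust" in methods or "GEE-Naive" in methods:
            try:
                gfit = gee.fit_gee_cs(data)
                ok = gfit.converged
            except (np.linalg.LinAlgError, ValueError):
                gfit, ok = None, False
            for name, covkind in (("GEE-Robust", "robust"), ("GEE-Naive", "naive")):
                if name in methods:
                    out[name] = gee.gee_wald(gfit, test_kind, covkind).p_value if ok else np.nan
    if "Baseline" in methods:
        bdata = assemble_dataset(pheno, cov, geno, spec.snp_id, spec.phenotype_name,
                                 baseline_only=True)
        try:
            bfit = cross_sectional.fit_baseline(bdata)
            out["Baseline"] = cross_sectional.baseline_snp_test(bfit).p_value
        except (np.linalg.LinAlgError, ValueError):
            out["Baseline"] = np.nan
    return out


def _safe_lmm(data, random_slope: bool, test_kind: str) -> float:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = lmm.fit_lmm(data, random_slope=random_slope)
        if not fit.converged:
            return np.nan
        return lmm.wald_test(fit, test_kind).p_value
    except (np.linalg.LinAlgError, ValueError):
        return np.nan


def run_study(
    spec: CohortSpec,
    params: GenerativeParams,
    n_reps: int = 1000,
    levels: tuple[float, ...] = (0.01, 0.05, 0.10),
    seed: int = 0,
    methods: tuple[str, ...] = ALL_METHODS,
    test_kind: str = "joint",
    scenario: str | None = None,
) -> SimulationSummary:
    """Replicate the cohort ``n_reps`` times and tabulate rejection rates.

    Per-replicate seeds are spawned deterministically from the master seed,
    so identical seeds give identical summaries.  Fits that fail or do not
    converge are excluded from the denominator for their method; a method
    with more than 5% failures marks the whole summary invalid.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    levels = tuple(levels)
    if not all(0.0 < lv < 1.0 for lv in levels):
        raise ValueError("nominal levels must lie in (0, 1)")
    methods = tuple(methods)
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")

    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    pvals = {m: np.full(n_reps, np.nan) for m in methods}
    for r in range(n_reps):
        res = _replicate_pvalues(spec, params, methods, seeds[r], test_kind)
        for m in methods:
            pvals[m][r] = res.get(m, np.nan)

    rates = np.zeros((len(methods), len(levels)))
    n_nonconv: dict[str, int] = {}
    valid = True
    for i, m in enumerate(methods):
        p = pvals[m]
        bad = int(np.isnan(p).sum())
        n_nonconv[m] = bad
        if bad > 0.05 * n_reps:
            valid = False
        ok = p[~np.isnan(p)]
        if ok.size:
            rates[i] = [(ok < lv).mean() for lv in levels]
    if not valid:
        warnings.warn("more than 5% non-converged fits in at least one method; "
                      "summary flagged invalid", RuntimeWarning)
    return SimulationSummary(
        scenario=scenario or f"{params.model}/{params.hypothesis}",
        methods=methods,
        nominal_levels=levels,
        rejection_rate=rates,
        n_reps=n_reps,
        n_nonconverged=n_nonconv,
        seed=seed,
        valid=valid,
        test_kind=test_kind,
    )


def summarize(summaries: list[SimulationSummary]) -> pd.DataFrame:
    """Side-by-side rejection-rate table over scenarios, with MC standard
    errors; scenarios must share the nominal-level grid."""
    if not summaries:
        raise ValueError("no summaries to merge")
    levels = summaries[0].nominal_levels
    for s in summaries[1:]:
        if s.nominal_levels != levels:
            raise ValueError("incompatible nominal-level grids")
    blocks = []
    for s in summaries:
        se = s.mc_se()
        for i, m in enumerate(s.methods):
            row = {"scenario": s.scenario, "method": m, "n_reps": s.n_reps}
            for j, lv in enumerate(levels):
                row[f"rate@{lv:g}"] = s.rejection_rate[i, j]
                row[f"se@{lv:g}"] = se[i, j]
            blocks.append(row)
    df = pd.DataFrame(blocks)
    dup = df.duplicated(["scenario", "method"])
    if dup.any():
        raise ValueError("duplicate (scenario, method) entries in merge")
    return df
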
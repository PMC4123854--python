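# longgwas

Longitudinal genome-wide association testing for repeated quantitative
phenotypes — brain-imaging traits measured at several follow-up visits being
the motivating case — with the cross-sectional baseline analysis as the
comparator, and a full simulation harness for type-I error and power.

## The problem

Cohort studies such as ADNI image each subject repeatedly over years, yet
most GWAS of such data regress only the baseline measurement on genotype.
A longitudinal model uses every visit and can detect a variant through
*either* a shift in the phenotype level *or* a change in its rate of decline.
`longgwas` implements that analysis as a reusable, tested package:

For subject *i* at visit time *t<sub>ij</sub>* (months since baseline), with
minor-allele count *s<sub>i</sub>* ∈ {0,1,2} and covariates
*x<sub>ik</sub>* (handedness, education, baseline age, gender, intracranial
volume):

```
y_ij = β0 + β1·s_i + β2·t_ij + β3·s_i·t_ij + Σk γk·x_ik + b0_i + b2_i·t_ij + ε_ij
(b0_i, b2_i) ~ N(0, D),   D = [[σ0², σ02], [σ02, σ2²]],   ε_ij ~ N(0, σ²)
```

The induced marginal moments are time-varying,
`Var(y_ij) = σ0² + 2t_ij·σ02 + t_ij²·σ2² + σ²` and
`Cov(y_ij, y_ik) = σ0² + (t_ij+t_ik)·σ02 + t_ij·t_ik·σ2²`,
reducing to compound symmetry when σ02 = σ2² = 0 (the random-intercept-only
special case). Estimation is REML (ML available) with the PSD constraint on
D enforced by construction; association is tested by the 2-df joint Wald
test of H₀: β1 = β3 = 0 (the default), or 1-df tests of β1 or β3 alone.

Around this core the package provides:

- **GEE comparator** — the same mean model fitted marginally with an
  exchangeable working correlation, exposing both the model-based ("naive")
  and sandwich ("robust") covariance (`longgwas.gee`);
- **baseline OLS** — the cross-sectional model at t = 0 (`longgwas.cross_sectional`);
- **boundary LRT** — H₀: σ2² = σ02 = 0 against the 0.5·χ²₁ + 0.5·χ²₂
  mixture null, for deciding whether the random slope is needed;
- **genome-scan orchestration** — SNP × phenotype × test loops, Bonferroni
  and Benjamini–Hochberg control, genomic inflation factor λ, genotype-PC
  stratification adjustment, Manhattan/QQ table export (`longgwas.scan`);
- **synthetic cohorts** — an ADNI-like generator (638 subjects, visits at
  months 0–48 with realistic per-visit availability, Hardy–Weinberg
  genotypes, five covariates) driving everything without any data download
  (`longgwas.synthetic`);
- **simulation studies** — replicate generation and five-method
  type-I-error/power tabulation (`longgwas.simstudy`), plus a `longgwas`
  CLI with `simulate`, `scan`, `simstudy` and `lrt` subcommands.

## Worked example

```python
from longgwas import (CohortSpec, default_params, simulate_cohort,
                      assemble_dataset, fit_lmm, wald_test, lrt_random_slope,
                      fit_baseline, baseline_snp_test)

spec = CohortSpec(seed=42)                      # 638 subjects, ADNI-like visits
params = default_params("rsi", hypothesis="alternative")
pheno, cov, geno = simulate_cohort(spec, params)

data = assemble_dataset(pheno, cov, geno, "snp1", "LHippVol")
fit = fit_lmm(data, random_slope=True)          # REML
joint = wald_test(fit, "joint")

base = assemble_dataset(pheno, cov, geno, "snp1", "LHippVol", baseline_only=True)
bres = baseline_snp_test(fit_baseline(base))
lrt = lrt_random_slope(data)

print(f"n_subjects={fit.n_subjects}, n_observations={fit.n_observations}")
print(f"beta1 (SNP main)        = {fit.fixed.beta1:8.2f} mm^3 per allele")
print(f"beta3 (SNP x time)      = {fit.fixed.beta3:8.3f} mm^3 per allele-month")
print(f"sigma2^2 (slope var)    = {fit.vc.sigma2_sq:8.2f}")
print(f"joint 2-df Wald         = {joint.statistic:.2f}, p = {joint.p_value:.3e}")
print(f"baseline-only OLS test  : chi2 = {bres.statistic:.2f}, p = {bres.p_value:.3e}")
print(f"random-slope LRT        = {lrt.statistic:.1f}, p = {lrt.p_value:.2e}")
```

prints

```
n_subjects=638, n_observations=2876
beta1 (SNP main)        =    95.48 mm^3 per allele
beta3 (SNP x time)      =    2.428 mm^3 per allele-month
sigma2^2 (slope var)    =    63.53
joint 2-df Wald         = 20.76, p = 3.100e-05
baseline-only OLS test  : chi2 = 7.30, p = 6.880e-03
random-slope LRT        = 286.9, p = 2.64e-63
```

Read it as: the simulated variant shifts hippocampal volume by ~95 mm³ per
minor allele and steepens atrophy by ~2.4 mm³/month per allele. The
longitudinal joint test sees both signals (p ≈ 3×10⁻⁵), two orders of
magnitude smaller than the baseline-only test of the same cohort
(p ≈ 7×10⁻³) — the power gain from using every visit. The enormous LRT
statistic says subject-specific slopes are real in these data; fitting a
random-intercept-only model (or GEE with the model-based covariance) here
would misstate the variance of time-dependent contrasts and inflate false
positives, which the simulation harness demonstrates:

```bash
longgwas simstudy --scenario rsi --hypothesis null --reps 300 --seed 7 --out study/
```

The same scan is available from the shell on delimited files
(`longgwas scan --pheno P.tsv --cov C.tsv --geno G.tsv --method lmm_rsi --out out/`),
writing `results.tsv`, `manhattan.tsv`, `qq.tsv` and a `summary.json` with
the genomic inflation factor and Bonferroni threshold.

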
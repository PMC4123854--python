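# Methods

## Models

Three estimators share one mean model for a repeated quantitative phenotype
`y_ij` of subject `i` at visit time `t_ij` (months since baseline):

```
E[y_ij | s_i, x_i] = β0 + β1·s_i + β2·t_ij + β3·s_i·t_ij + Σk γk·x_ik
```

with `s_i` the minor-allele count and five subject-level covariates
(handedness, education years, baseline age, gender, intracranial volume).
They differ in the dependence structure:

1. **Random-intercept + random-slope LMM (the primary estimator).**
   Subject effects `(b0_i, b2_i) ~ N(0, D)` with
   `D = [[σ0², σ02], [σ02, σ2²]]` plus i.i.d. residuals `ε ~ N(0, σ²)`.
   The marginal covariance of a subject's visits is
   `σ0² + (t_j + t_k)σ02 + t_j·t_k·σ2²` off the diagonal, plus `σ²` on it —
   a variance that grows (or shrinks) with time. With `σ2² = σ02 = 0` the
   model collapses to the random-intercept LMM, whose marginal covariance is
   compound-symmetric (constant variance `σ0² + σ²`, constant covariance
   `σ0²`). Fitting the intercept-only model when slopes are heterogeneous
   understates the variance of time-dependent contrasts, which is exactly
   why its SNP tests over-reject in the simulation harness.
2. **GEE with exchangeable working correlation.** The same mean model
   solved marginally; coefficient covariance either model-based ("naive",
   valid only if compound symmetry is true) or sandwich ("robust", valid
   under misspecification, but requiring MCAR dropout rather than the MAR
   that likelihood-based fits tolerate).
3. **Baseline OLS.** The cross-sectional comparator on the `t = 0` rows,
   testing `β1` only.

Association tests: a 2-df Wald statistic on `(β̂1, β̂3)` (the default
"joint" test — a variant can act through the level, the slope, or both),
and 1-df tests of each alone. All p-values use the asymptotic χ² reference;
with ~638 subjects the difference from finite-sample references is
negligible, and an exact-t option exists for the baseline test only.

The need for the random slope itself is tested by a REML likelihood-ratio
statistic between the nested random structures (identical fixed effects).
Because `σ2² = 0` lies on the boundary of the parameter space and `σ02` is
constrained with it, the null distribution is the Stram–Lee 50:50 mixture
`0.5·χ²₁ + 0.5·χ²₂`; the statistic is floored at zero since boundary
estimates can make the larger model's criterion numerically lower by less
than the optimizer tolerance.

## Estimation and numerics

Variance components maximize the REML criterion by default (ML available;
cross-model fixed-effect LRTs would require ML). The optimizer works on an
unconstrained parameterization — `log σ0, log σ2, atanh-scaled ρ, log σ` —
so `D` is positive semidefinite by construction; bounds of ±30 on the log
scale and ±6 on the correlation scale keep evaluations finite. L-BFGS-B
runs from a moment-based start (between-subject variance of OLS residual
means split against the residual variance); up to three dispersed restarts
are attempted only when the first start fails to converge, and the
`converged` flag reports the optimizer's verdict honestly — simulation
summaries exclude and tally non-converged fits, and flag themselves invalid
above a 5% failure rate.

Likelihood evaluations exploit the visit structure: subjects sharing a
visit-time pattern share the marginal covariance matrix, so the criterion
is computed from per-pattern sufficient statistics (cross-products of the
design, response and their mix) precomputed once per dataset; an evaluation
then costs one small Cholesky factorization per pattern batch rather than
any O(N) work. Design columns are standardized to unit root-mean-square
internally (intracranial volume is ~10⁶ mm³ while the intercept is 1), with
estimates, covariance, and the REML determinant mapped back exactly.
Convergence tolerance is 1e-11 on the criterion. The GLS covariance of the
fixed effects at the optimum supplies the Wald tests.

GEE alternates a GLS coefficient update with moment updates
`φ = Σr²/N` and `ρ = Σ_{j<k} e_j e_k / Σ m_i(m_i−1)/2` over Pearson
residuals (the simple pooled convention, no degrees-of-freedom correction;
reference implementations differ here by O(p/N) — the package fixes one
documented convention and verifies the fixed point against an external
reference configured to match). Size-1 clusters contribute to the scale but
not to ρ; ρ is clamped to the admissible range for the largest cluster.
The exchangeable inverse uses its closed form, so cluster updates are exact.

Degenerate inputs are refused rather than silently repaired: constant SNPs
raise a rank error (genome scans convert this into an explicit "monomorphic"
skip record, never a fabricated p-value); all-singleton-cluster data cannot
identify a random slope and raise with a pointer to the intercept-only or
baseline models.

## Genome-scan conventions

- Multiple phenotypes over a genome-wide scan are controlled by Bonferroni:
  the single-phenotype level divided by the phenotype count, with
  `(5e-8, n_phenotypes)` as the documented default convention (thresholds
  are user parameters, not constants of nature); Benjamini–Hochberg FDR is
  available on any p-value vector.
- The genomic inflation factor converts every p-value to a 1-df χ² quantile
  and divides the median by 0.4549364 regardless of the originating test's
  df, keeping λ comparable between 1-df and 2-df scans; per-df conversion is
  a flag.
- Population-structure adjustment: the genotype matrix (optionally a random
  SNP subsample) is centered at `2p̂` and scaled by `sqrt(2p̂(1−p̂))`,
  missing calls mean-imputed *for the decomposition only*, constant columns
  dropped; the top-k left singular scores enter the fits as extra
  covariates. Association tests themselves remain complete-case throughout:
  no phenotype, genotype or covariate value is ever imputed, and a subject
  missing any covariate is excluded entirely.
- Visit times are real months, not visit indices, so irregular schedules
  need no special handling. TSV genotype files are trusted as-coded;
  only VCF input triggers automatic minor-allele recoding (ALT dosage
  flipped when the ALT sample frequency exceeds 0.5; half-calls and missing
  GTs become missing).

## The synthetic cohort

The generator emulates the structure of a longitudinal elderly imaging
cohort: 638 subjects by default, visits at months (0, 6, 12, 18, 24, 36,
48) with per-visit availability (0.995, 0.966, 0.90, 0.386, 0.724, 0.412,
0.088), independent per-visit Bernoulli retention (MCAR) by default, an
`exact_counts` mode that pins the per-visit counts at `round(r·n)`, and an
optional outcome-dependent dropout mode (censoring after the phenotype
falls below its expected trajectory) that violates MCAR but not MAR — the
contrast that separates GEE's validity conditions from the LMM's.
Genotypes are i.i.d. Hardy–Weinberg draws at a configurable MAF (default
0.14, typical of the kind of chromosome-19 dementia-risk variants that
motivate the analysis); covariates are Bernoulli/normal draws with
configurable parameters on realistic demographic scales.

Default generating values sit on a left-hippocampal-volume scale:
`β0 = 3400` mm³, mean atrophy `β2 = −7` mm³/month, `σ0² = 160000`
(between-subject SD 400 mm³), `σ² = 22500` (residual SD 150 mm³), and slope
heterogeneity `σ2² = 64` (SD 8 mm³/month) with `σ02 = −480` (ρ ≈ −0.15,
smaller structures declining faster). The slope variance was set so that
the random-slope LRT on a default cohort lands in the high-200s — the
magnitude real heterogeneous cohorts exhibit — because the entire
misspecification story (how badly the intercept-only model over-rejects)
scales with this signal. Under the alternative hypothesis `β1 = 60` mm³
and `β3 = 1.5` mm³/month, chosen from a back-of-envelope power calculation
to give moderate, non-saturated power at n = 638 so that method comparisons
are informative. The `cs` scenario is the compound-symmetry world:
intercept-only random structure with every fixed effect and variance
component halved relative to the base scenario.

What the generator does *not* emulate: linkage disequilibrium between
SNPs (null markers are independent), genome maps, diagnostic-group mixture
structure, site effects, or measurement-error drift. Consequently the
package's passing calibration tests demonstrate correctness of the
estimators and tests under the stated model, and the *direction and
structure* of the misspecification effects; absolute power numbers are
properties of the surrogate parameters, not of any real cohort.

## Simulation studies

`run_study` generates `n_reps` cohorts (per-replicate seeds spawned
deterministically from one master seed; identical seeds give bit-identical
summaries) and analyzes each with up to five methods — LME-RSI, LME-RI,
GEE-Robust, GEE-Naive, Baseline — using the joint 2-df test for the
longitudinal methods and the 1-df main test for the baseline. Level grids
default to (0.01, 0.05, 0.10); the compound-symmetry scenario adds 0.15.
The test suite runs these studies at 300 replicates with 3-standard-error
binomial tolerances; the acceptance script runs the full 1000. Expected
behaviour, asserted by the suite: the random-slope LMM, robust GEE and
baseline OLS hold their size under both generating models; the
intercept-only LMM and model-based GEE exceed twice the nominal level when
slopes are heterogeneous; under compound-symmetry truth the random-slope
fit loses no measurable power relative to the intercept-only fit; and the
longitudinal joint test dominates the baseline test in power whenever the
variant acts on the slope.

## Known limitations

- Wald inference is asymptotic; no Satterthwaite/Kenward–Roger small-sample
  degrees of freedom (irrelevant at hundreds of subjects, wrong tool below
  ~50).
- GEE offers only the exchangeable working correlation and no small-sample
  sandwich corrections; the sandwich is mildly anti-conservative (empirical
  size ~0.05–0.06 at the 0.05 level across seeds) with several hundred
  unequal clusters, consistent with its known finite-cluster behaviour.
- One SNP at a time; no SNP-set, rare-variant, or LD-aware extensions.
- Gaussian phenotypes only; identity link.
- PLINK binary formats are not read (delimited counts or VCF only).
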
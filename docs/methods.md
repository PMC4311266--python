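# Methods

This note documents the statistical models, numerical choices and known
limitations of the package, in the spirit of a model-documentation page for
a statistics library.

## The two-stage score design

The package assumes the consortium setting in which individual-level data
never cross cohort boundaries. Each cohort fits a covariate-only null model
once and exports, per gene, the score vector `U` and covariance `V`; all
association tests are deterministic functions of these summaries. This is
sufficient for single-variant estimation, SKAT/burden tests, conditional
analysis and leave-one-out scans because all of them are functions of the
first two moments of the score under the null.

### Null models

- *Quantitative, unrelated*: ordinary least squares (via statsmodels), with
  `σ̂² = RSS/(n−p)`.
- *Quantitative, family-structured*: `Y = Xβ + b + ε`, one random intercept
  per sibship. Families are exchangeable blocks, so the marginal covariance
  of a sibship of size k is `σ²(I_k + λJ_k)`, `λ = σ_b²/σ²`. Both the GLS
  solve and the determinants have closed forms per block, and REML reduces
  to a 1-D profiled optimisation over `λ`, handled by a bounded scalar
  minimizer on the log scale (tolerance 1e-8) with the `λ = 0` boundary
  checked explicitly. Singleton "families" retain their own intercept, so
  their marginal variance is `σ²(1+λ)`; this matches what lme4-style mixed
  models fit and keeps the estimate consistent when sibships and singletons
  mix. The implementation is validated against statsmodels MixedLM (REML)
  to 4–5 significant digits in tests.
- *Binary*: logistic regression (statsmodels GLM) after keeping one member
  per family — the convention of removing related individuals before
  case-control analysis.

### Score statistics

For quantitative traits, genotype columns are mean-imputed (missing
dosages), whitened by `Σ(λ)^{-1/2}` when a family fit is present,
residualized on the whitened covariate design, and scored as
`U = G̃ᵀR/σ̂²`, `V = G̃ᵀG̃/σ̂²`. With this scaling `U_j/V_jj` equals the
GLS/OLS slope of the trait on dosage given covariates (checked to 1e-6
relative in tests), and `U_j/√V_jj` is the score z. Binary traits use
`U = G̃ᵀ(y − p̂)`, `V = G̃ᵀWG̃`, `W = p̂(1−p̂)`, with `G̃` residualized under
W-weighting (expected information). Zero-variance variants contribute
exactly zero score and covariance and are flagged.

Dosages are recoded to the cohort minor allele before scoring; a frequency
of exactly 0.5 is left unflipped for determinism, and every flip is logged.

### Filters

Defaults follow the consortium conventions: single-variant tests require
pooled MAC ≥ 20 (counted among cases for binary traits — the MAC
denominator for the binary filter is ambiguous in the source convention, so
the case-side count is used and the full-sample MAF is still reported);
gene-based tests take protein-altering variants (nonsynonymous, splice
site, stop gain/loss) with MAF < 1%, and run only when the cumulative MAC
reaches 20 (quantitative) or 40 (binary). Cohort-stage filters use
cohort-level MAF; meta-stage filters use the allele-count-weighted pooled
MAF, the closest reproducible analogue of a chip-wide jointly-called
frequency.

## Gene-based tests

**SKAT.** `Q = Σ_j w_j² U_j²` with `w_j` the Beta(1,25) density at the
pooled MAF (the "Wu" weight). Under the null, `Q ~ Σ λ_i χ²₁` with `λ` the
eigenvalues of `W V W`. The tail is computed by Imhof's
characteristic-function inversion integral, evaluated with vectorized
Gauss–Legendre panels no wider than a quarter oscillation and truncated
where the integrand envelope bounds the remaining tail below 1e-12·q
(eigenvalues are first normalized by their maximum; the mixture is scale
invariant). When all eigenvalues coincide the mixture collapses to a scaled
chi-square and the closed form is used. Inversion in double precision
cannot resolve tails below ~1e-10 (the answer is a cancellation of two
0.5-scale terms), so when a four-moment pre-estimate or the inversion
itself indicates p < 1e-8, the Lugannani–Rice saddlepoint approximation
takes over; it is relatively accurate in the far tail (within ~10% of a
high-precision convolution oracle at p ≈ 1e-20 in tests, which is the
expected accuracy class of saddlepoint tails). The Liu et al. four-moment
chi-square match is the final fallback. Every result records which method
produced its p-value.

**Burden (WST).** Madsen–Browning weights `w_j = 1/√(n p̂_j (1−p̂_j))` on
pooled all-sample MAF for both trait kinds (the original proposal weights
by control-only frequencies; all-sample pooled MAF is used here for
determinism across trait kinds, and monomorphic variants get weight 0).
`S = wᵀU` is tested as `S/√(wᵀVw)` against the standard normal, two-sided;
the sign of `S` is the aggregate direction.

**Conditional analysis** projects the conditioning variants out of the
scores: `U* = U_g − V_gc V_cc⁻¹ U_c`, `V* = V_gg − V_gc V_cc⁻¹ V_cg`. This
is algebraically identical to score statistics from a null model augmented
with the conditioning genotypes (at the original σ̂² scale), which the
tests verify. Near-singular `V_cc` (condition number > 1e12) is
ridge-stabilized at 1e-8 of its trace. Conditioning candidates within a
region are selected by a half-open ±500 kb window on position.

**Leave-one-out scan** recomputes SKAT once per removed variant, with
weights recomputed on the remaining variants' MAFs, ordered by position.

## Haplotype analysis

**EM dosages.** Individuals are grouped by identical multilocus genotype;
each distinct genotype's compatible ordered haplotype pairs are enumerated
(missing genotypes marginalized over all allele combinations; enumeration
is refused beyond ~25 variants or 2²⁰ expansions). Frequencies start at the
product of marginal allele frequencies — deterministic, no seed
sensitivity — and iterate standard E/M steps until the log-likelihood gain
falls below `tol` (default 1e-8; default iteration cap 1000, and the
pipeline requests 10,000 because near-zero frequencies can decay slowly).
Monotonicity of the log-likelihood is asserted every iteration (with a
1e-9 relative slack for floating-point accumulation). Haplotypes converging
below frequency 1e-6 are pruned and posteriors renormalized, so every
dosage row sums to exactly 2. Individuals heterozygous at ≤1 site are
phase-unambiguous and receive integer dosages.

**Cohort fit.** The trait is regressed on the non-reference expected
dosages (reference = most frequent haplotype, overridable to a
consortium-designated reference — the synthetic generator guarantees all
cohorts share it; re-parameterizing a fit against a different reference is
out of scope and raises). Unrelated samples use least squares; family
cohorts use the same profiled-REML mixed model as the null-model stage. The
reported `γ̂` covariance is the corresponding block of
`σ̂²(XᵀΣ̂⁻¹X)⁻¹` — a plug-in at the fitted variance components (REML;
whether the original applications used ML or propagated
variance-estimation uncertainty is not documented, so plug-in REML is the
package's choice). Collinear dosage columns are resolved by dropping the
rarest offending haplotype, logged on the fit.

**Meta-analysis.** With `S_c` the selection map from the union
(non-reference) haplotype set to cohort c's set,

    I = Σ_c S_cᵀ Σ_c⁻¹ S_c,   γ̂_meta = I⁻¹ Σ_c S_cᵀ Σ_c⁻¹ γ̂_c,
    Cov(γ̂_meta) = I⁻¹,

i.e. multivariate fixed-effects GLS in which a cohort contributes
information only for the haplotypes it observed. A per-coordinate scalar
inverse-variance mode (`mode="ivw"`) is provided for sensitivity checks and
coincides with GLS when all cohort covariances are diagonal. The global
null (all non-reference effects zero) is tested by the Wald statistic
`γ̂ᵀ I γ̂ ~ χ²` with df = |union| − 1; a Wald rather than likelihood-ratio
test because only summary statistics cross the cohort boundary. Haplotypes
with no contributing cohort are excluded with a warning; a singular pooled
information matrix is ridge-stabilized at 1e-10 of its trace. Pooled
haplotype frequencies (for ordering and the report table) are
2n-weighted averages of cohort EM frequencies.

## Derived phenotypes

Pure functions with missing-value propagation (never silent zeros):
insulinogenic index `(ins₃₀−ins₀)/(glu₃₀−glu₀)` (undefined at zero glucose
increment); trapezoid AUC over OGTT excursions, requiring ≥3 time points;
incretin effect `(AUC_oral − AUC_iv)/AUC_oral`; +15/+10 mmHg
systolic/diastolic adjustment for treated blood pressure, guarded by a
table-level provenance flag so the pipeline can apply it exactly once; and
trait transforms (natural log for FI-like traits) recorded in provenance.
Units are carried by convention and left to configuration — the downstream
contract is only that effect sizes are reported per trait unit (or per SD
of a designated reference cohort when configured).

## The synthetic-data generator

The generator defines the study conditions for every test. It draws
haplotype pairs i.i.d. from an explicit pool (Hardy–Weinberg — the standard
assumption of the EM it must exercise), sums alleles to unphased genotypes,
and builds traits as `Xβ + Σ h_m γ_m + b_family + ε` with sibship-shared
intercepts. The default locus architecture has 16 variants: one common
(MAF ≈ 40%) on its own haplotype and 15 rare variants (cumulative MAF 1.6%,
each < 1%), each rare allele confined to a single haplotype — so haplotype
and variant effects are interchangeable by construction, and opposing
directions can be planted per haplotype. Binary traits apply a logistic
link to the same linear predictor with the intercept solved numerically for
a target prevalence (default 0.15, near the study-like case fraction).
Multi-cohort draws may remove haplotypes (never the reference) with
renormalized frequencies, emulating cohorts with partially non-overlapping
haplotype sets; a manifest records what each cohort can observe. All
randomness flows from one integer seed, with the cohort index mixed into
the stream.

What the generator does **not** emulate: linkage disequilibrium beyond
haplotype sharing, genotyping error, ancestry structure or stratification,
chip-versus-sequence platform differences, and phenotype
measurement-error structure. Passing tests therefore demonstrate
correctness of the statistical machinery under its stated model, not
robustness to those real-data complications.

## Problem sizes in the test-suite and acceptance runs

Simulation-based checks use cohort sizes of 300–20,000 and replicate counts
of 60–2,000, chosen so each check has the statistical resolution its
tolerance needs (e.g. 2,000 null replicates bound the type-I-error estimate
at α = 0.05 to a ±0.015 three-sigma band, matching the asserted
[0.035, 0.065] interval). Unbiasedness checks assert recovery within 3
empirical standard errors of the replicate mean. The demo consortium (3 ×
1,500) reproduces the qualitative signature of the real locus — SKAT and
the global haplotype test detect opposing-direction rare effects that the
burden sum cancels — at desk scale; the printed significance levels of the
original analysis additionally require its ~60,000-sample denominator.

## Known limitations

- Relatedness is modelled as exchangeable sibships (one shared intercept),
  not arbitrary kinship matrices.
- No binary-trait haplotype model; the haplotype stage is quantitative-only.
- The saddlepoint far-tail p-values are relatively, not absolutely, exact
  (~10% relative class); p-values above ~1e-8 are exact to ~1e-9 absolute.
- EM haplotype estimation is exact-enumeration based and intended for gene-
  scale variant sets (≤ ~25 sites), not chromosome-scale phasing.
- Allele harmonization across cohorts handles strand-consistent ref/alt
  swaps; ambiguous A/T–C/G strand flips are rejected rather than guessed.
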
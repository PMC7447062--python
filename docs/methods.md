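# Methods

## Model and assumptions

The analytical unit is a pregnancy: a mother–child duo with phased
genotypes over a panel of trait-associated SNPs. Each SNP contributes
three allele indicators — maternal transmitted (h1), maternal
nontransmitted (h2), paternal transmitted (h3) — and each class is
summarized by a weighted score S_hk = Σ_j w_j h_kj with w_j the published
per-allele effect in trait units. Two identities are structural and are
asserted on every score set: S_mat = S_h1 + S_h2 (the mother's genotype
score) and S_fet = S_h1 + S_h3 (the child's).

The joint regression Y ~ S_h1 + S_h2 + S_h3 + Cov separates effect routes
because h2 cannot act through the fetus and h3 cannot act through the
mother. Two assumptions make the contrasts interpretable:

1. **Additivity** of maternal and fetal routes on the transmitted
   haplotype: β_h1 = maternal + fetal.
2. **No parent-of-origin effect**: an allele's fetal effect does not
   depend on which parent transmitted it, and no paternal "genetic
   nurture" path (paternal alleles act only through the fetus).

Under these, the average maternal effect is β_MY = (β_h1 − β_h3 + β_h2)/2
and the average fetal effect β_FY = (β_h1 − β_h2 + β_h3)/2, with
β_MY + β_FY = β_h1 exactly. Contrast variances use the full 3×3
coefficient covariance (c'Σc); a bootstrap check in the test suite
confirms the analytic SE within 15% at n = 5,000.

Linear outcomes are fitted by OLS, the preterm indicator
(gestational days < 259) by maximum-likelihood logistic regression
(IRLS, tolerance 1e-8, 100 iterations; non-convergence and perfect
separation raise). Birth weight and length are adjusted for the first
three orthogonal polynomials of gestational duration, built by QR
factorization of the raw power basis with a deterministic sign convention
(column k correlates positively with days^k). Score models use maternal
age and fetal sex as covariates; maternal height and BMI are deliberately
excluded there because they are downstream of the scores being
instrumented (they remain covariates of the observational
phenotype–outcome models, where the exposure is the phenotype itself).
Listwise deletion is applied per model, never globally.

## Causal estimators

* **Wald ratio**: β̂_XYm = β̂_MY / β̂_MX, where β̂_MX is the score–trait
  coefficient. The SE is the first-order delta method with zero
  numerator–denominator cross-covariance (the two come from different
  regressions; a shared-sample cross-term would shrink the SE slightly,
  so the reported interval is mildly conservative). CI95 is the
  symmetric normal approximation rather than Fieller: the instrument
  strength is guarded (|β̂_MX| > 3 SE, configurable; strict mode raises),
  which keeps the ratio distribution near-normal. Per-SD values multiply
  by the trait SD.
* **TSLS** with S_h2 as instrument: stage 1 regresses the exposure on the
  instrument and covariates, stage 2 the outcome on the fitted exposure;
  coefficient SEs use residuals formed with the observed exposure (the
  proper TSLS variance). Stage-1 partial F < 10 flags a weak instrument.
* **Fetal drive**: the ratio of the paternal-transmitted coefficients,
  β̂_h3(outcome)/β̂_h3(birth weight), times 426 g — one SD of
  gestational-age-adjusted birth weight — giving outcome change per SD of
  fetal growth.

## Genetically confounded associations

Maternal trait → outcome: β̂_XYc = (h²_X / 2) · β̂_FY / β̂_MX. The factor
h²_X/2 is the transmitted half of the trait's additive genetic variance;
dividing by β̂_MX converts from score units to trait units, so the result
is in outcome units per trait unit and the score's arbitrary scale
cancels. In a pure-confounding simulation (no causal maternal path) the
closed form equals the population OLS slope a·f·V/2/Var(X) exactly, and
the test suite verifies the estimate tracks realized slopes within
Monte-Carlo error.

Outcome → adult offspring phenotype, in SD(X′) per SD(Y):
Method 1 is h² · √(Var(X′)/Var(Y)) · (β̂_MY/2 + β̂_FY), which partitions
into a maternal (β̂_MY/2) and a fetal (β̂_FY) component; Method 2 replaces
the bracket with (β̂_h1 + β̂_h3)/2. The two coincide exactly when
β̂_h1 = β̂_h2 + β̂_h3. These formulas presuppose that one score unit
predicts one unit of the adult trait's genetic value; since simulated
weights are on an arbitrary scale, the pipeline first rescales the fit by
the estimated score→adult-trait coefficient. Var(Y) defaults to the
gestation-adjusted outcome variance whenever the fit adjusted for
gestation. SEs propagate the fit covariance through the corresponding
linear combination (Method 1: (¾, −¼, ¼); Method 2: (½, 0, ½)).

## Meta-analysis

Fixed-effect pooling uses inverse-variance weights (pooled = Σwβ/Σw,
SE = 1/√Σw); heterogeneity is Cochran's Q with I² = max(0, (Q−df)/Q).
Random effects use DerSimonian–Laird τ² = max(0, (Q−df)/(Σw − Σw²/Σw)).
Heterogeneity at p_Q < 0.05 is flagged in reports but never switches the
model automatically. Fixed-effect pooling is algebraically a WLS
intercept fit, which the tests assert to 1e-12.

## Pleiotropy tests

Per-SNP allele-class effects come from Y ~ h1_j + h2_j + h3_j + Cov, one
small least-squares fit per SNP (batched numpy; monomorphic SNPs are
skipped and reported). The proportionality model is a zero-intercept
inverse-variance-weighted regression of outcome effects on the published
exposure effects; exposure effects are treated as known constants
(two-sample setting) and no intercept term is fitted. The residual-based
diagnostics are parametric: outcome effects are simulated from
normal(leave-one-out prediction, SE), the observed leave-one-out weighted
RSS is ranked among n_sim ≥ 1000 simulated RSS values (global p, bounded
below by 1/(n_sim+1)), each observed squared residual among its simulated
counterparts (outlier p, Bonferroni-flagged at α/N), and the slope shift
from removing flagged outliers among shifts from removing random subsets
of the same size (distortion p). All three are deterministic under a
fixed seed.

## The simulator

`simulate_duos` generates what the estimators assume: SNPs in linkage
equilibrium with allele frequencies uniform on (0.1, 0.9) and Gaussian
per-allele weights; four parental haplotypes per family; uniform
Mendelian transmission (child genotype = h1 + h3 by construction).
Assortative mating with parameter ρ is a Gaussian-copula rank coupling,
applied both within each parent's two haplotype scores (the equilibrium
footprint — this is what makes corr(S_h1, S_h2) rise with ρ and produces
excess homozygosity) and between the parental total scores. Coupling only
permutes haplotypes across families, so marginal distributions are
preserved and the realized correlation hits ρ within ±0.03 at n = 20,000.

Phenotypes follow the effect structure the analysis estimates. The
maternal trait is X = a·S_mat + environmental noise, with `a` set from
the realized score SD so the score explains exactly the configured
instrument R² and SD(X) equals the trait SD. Gestational duration adds
maternal (causal), fetal (direct) and shared-environment confounding
paths, with residual noise scaled so the marginal SD matches the
configured 11.4 days; a config whose planted effects exceed the variance
budget raises with the attainable bound. Birth weight adds its own
maternal/fetal/confounding components, a fetal-sex shift and a cubic
polynomial of centred gestational days (so the analysis's degree-3
adjustment is exact), with residual noise scaled to the 426 g adjusted
SD. Preterm is the threshold indicator (< 259 days), not a logistic
draw, matching its clinical definition. Fetal drive feeds the
gestation-adjusted growth deviation (in SD) back into the maternal
pregnancy trait. An offspring adult trait with configurable heritability
shares genetics through S_fet for the confounding analyses. All noise is
Gaussian; everything is byte-identical under a fixed (config, seed).

Default parameters describe a blood-pressure-like exposure in a cohort of
10⁴ duos: trait 112 ± 5.8 mmHg, instrument R² 0.02, maternal causal
effect −0.40 d/mmHg on gestation, fetal effects −0.10 d and −4.8 g per
score unit, fetal drive +1.41 mmHg per SD growth, shared-environment
confounding +0.36 d/mmHg (so the observational slope lands near
−0.05 d/mmHg while the causal effect is −0.40), gestation 280 ± 11.4 d,
birth weight 3540 g with adjusted SD 426 g, panel of 86 SNPs, ρ = 0.

What the generator does **not** emulate: linkage disequilibrium between
panel SNPs, imputation or phasing error, genotyping batch effects,
population stratification, non-Gaussian phenotype tails, missing-data
mechanisms beyond missing-completely-at-random, and real between-cohort
heterogeneity (dataset labels split one homogeneous population). Passing
tests therefore certify the estimators under the model's own assumptions,
not robustness to those violations.

## Worked-example fixtures

The published coefficient tables ship as TSVs and the contrast/ratio
arithmetic is recomputed from the printed inputs. Printed numbers are
rounded, so comparisons use a rounding-aware tolerance: inputs with
unit-in-the-last-place u_i entering Σc_i b_i allow Σ|c_i|·f·u_i plus half
the output ULP. The package checks its curated rows at f = 1 (one full
input ULP); the seven rows used by the acceptance reproduction also pass
at f = ½. A handful of printed contrast rows are flagged as not
recoverable from the printed haplotype rows at any rounding tolerance:
those contrasts were pooled across datasets before printing, and pooling
per-dataset contrasts need not equal contrasting pooled coefficients when
dataset availability differs by outcome. The flagged rows are reported
but excluded from the pass/fail contract.

## Numerical choices and degenerate inputs

Designs with condition number above 1e8 (collinear scores, rank-deficient
covariates) raise; constant-score and monomorphic-SNP inputs raise or are
skipped with a report. Mendelian-inconsistent variants are nulled per duo
(contributing zero to all three scores symmetrically, preserving the
dosage identities on observed variants) and duos with more than 5%
inconsistent variants are rejected. The ambiguous mother-het/child-het
case under dosage-only resolution takes the expected value 0.5 on all
three indicators with a flag — unbiased for score sums and free of
differential missingness between haplotypes. Ties in rank couplings are
broken by stable sort order; I² truncates at 0; all Wald p-values are
two-sided.

## Problem sizes used by the test suite

Monte-Carlo suites run at the sizes the checks are calibrated for:
parameter recovery at 100 replicates of n = 20,000 duos × 86 SNPs; null
calibration at 600 replicates of n = 2,000 × 50 SNPs (rejection rates for
both contrasts and the pleiotropy global test within [0.03, 0.07] at
α = 0.05); pleiotropy power at 200 replicates of 50 variants with 3
planted directional outliers; confounding validation at 20 replicates of
n = 5,000. The full suite completes in a few minutes on one CPU.

## Known limitations

Weak instruments make the ratio estimator heavy-tailed; the guard and
the normal CI are pragmatic, not exact. The confounding closed forms
inherit the assumption that all trait-associated variants act on the
outcome like the score SNPs do, and a strict Var(X′)/Var(Y) reading of
the variance ratio. The equilibrium assortative-mating footprint is
approximated by one-generation rank coupling rather than an explicit
multi-generation model. No support for dosage genotypes, multi-allelic
sites, strand flipping of palindromic SNPs, or X-chromosome inheritance.
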
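# Methods

## Model

For a cohort of n children with outcome y (natural log of age-corrected
BMI), fixed-effect design X (intercept plus treatment-coded covariates),
pairwise relatedness matrix K and home-sharing indicator matrix H, the
model is

    y ~ N( X beta,  Sigma ),   Sigma = sigma2_A K + sigma2_C H + sigma2_E I.

K holds expected genome-sharing coefficients assigned from reported
pedigree classes (MZ 1.0, full sibling or DZ twin 0.5, half sibling 0.25,
unrelated 0.0) — no transitive pedigree inference is performed, and an
inconsistent triad (two full-sibling links meeting at a child whose closing
pair is labelled unrelated) is surfaced as a warning, never auto-resolved.
H is 1 exactly for children assigned to the same household, which makes it
a union of all-ones blocks (transitive by construction). Both matrices are
singular in general (MZ pairs duplicate rows of K; every multi-child home
duplicates rows of H); the model stays well posed because sigma2_E I is
always present and positive.

Assumptions inherited from the design: additive gene action only (a
sibling-adoption design cannot separate dominance or epistasis from A),
no gene–environment interaction, no selective placement of adoptees with
respect to the phenotype, cross-sectional measurement. The
reared-by-biological-parent covariate is available as a fixed effect to
absorb passive gene–environment correlation.

## Estimation

Variances are estimated by restricted maximum likelihood,

    l_R(sigma2) = -1/2 [ (n-p) log 2pi + log|Sigma| + log|X' Sigma^-1 X|
                         + y' P y ],
    P = Sigma^-1 - Sigma^-1 X (X' Sigma^-1 X)^-1 X' Sigma^-1,

profiled in the variance ratios gamma_k = sigma2_k / sigma2_E: with
Sigma = sigma2_E (I + sum_k gamma_k M_k), the inner maximizer
sigma2_E(gamma) = y' P0 y / (n - p) is closed-form (P0 the unit-scale
projection), leaving a 2-parameter concentrated criterion. The union of
the K/H sparsity patterns partitions the cohort into small family blocks;
the likelihood, its analytic gradient and the GLS quantities are computed
block-wise with all blocks of equal size batched into single numpy calls.
This makes one fit of a 711-child cohort a few tens of milliseconds and is
what keeps the 999-replicate permutation test and the simulation studies
cheap.

Optimization: multi-start L-BFGS-B on gamma with box bounds [0, 1e8]
(starts 0.2, 2, 20 on each ratio), analytic gradients, ftol 1e-12 /
gtol 1e-9, at most 500 iterations per start, and a bounded Nelder–Mead
polish if the quasi-Newton run ends unconverged. Ratios below 1e-7 are
snapped to an exact 0 and flagged as boundary estimates; a boundary
component is reported as 0 with SE 0 and a zero-width interval. The
box-bound parameterization was chosen over log-ratios so the boundary is
reachable exactly rather than approached asymptotically. Correctness is
cross-checked against a brute-force dense grid over (sigma2_A, sigma2_C,
sigma2_E) on small instances (agreement within 1e-4 log-units) and against
the closed-form iid reduction (sigma2_E = RSS/(n-p) exactly when no
structured component is present).

Fixed effects are GLS at the REML variances,
beta = (X' Sigma^-1 X)^-1 X' Sigma^-1 y, with standard errors from
(X' Sigma^-1 X)^-1 and asymptotic-normal t ratios (no small-sample df
correction). On the ln scale, exp(beta) is the multiplicative effect on
median BMI.

The covariance of the variance-component estimates is the inverse observed
information of the unprofiled restricted likelihood at the optimum,
computed densely once from the standard P-matrix identities
(I_obs[i,j] = y'P M_i P M_j P y - tr(P M_i P M_j)/2). Components at the
zero boundary are excluded from the information matrix and given zero
covariance rows. Near a boundary the observed information can be
indefinite; its spectrum is clipped at a relative floor of 1e-10 before
inversion so the returned covariance is PSD.

## Derived inference

- **Variance proportions.** h2 = sigma2_A/V_p, c2 = sigma2_C/V_p,
  e2 = sigma2_E/V_p (summing to 1 by construction). SEs by the delta
  method with the analytic ratio gradient; 95% intervals are
  estimate ± 1.96·se, deliberately not truncated to [0, 1].
- **Permutation test.** The outcome vector is shuffled uniformly across
  children (K, H, X fixed), the model refitted, and the p-value for each
  component is the plain proportion of permuted estimates at least as large
  as the observed one; the (k+1)/(n+1) variant is available behind a flag.
  The observed statistic and every permuted one are computed by the
  identical single-start procedure on a shared block-structure cache —
  using a better-optimized estimate on the observed side only would bias
  the null distribution. Calibration caveat, measured here: the test is exact
  only when the null makes y exchangeable (sigma2_A = sigma2_C = 0 given
  constant fixed effects) — at 200 null cohorts × 199 permutations the V_A
  rejection rate then sits at the nominal 5%. When testing V_A while a
  real common-environment component remains (sigma2_C > 0), the shuffle
  destroys both structures and the test becomes strongly conservative
  (0/200 rejections at alpha 0.05 in the same experiment). Production runs
  use 999 permutations; the validation studies use 199 to keep the suite
  fast.
- **Structure checks.** Nested random-effect structures are compared by
  chi2 = 2 ΔlR on df = difference in component count with the plain
  upper-tail chi-square p (the boundary-aware 50:50 chi-square mixture is
  available as an option). REML likelihoods are only compared at identical
  fixed effects; differing designs raise.
- **Fixed-effect selection.** All admissible fixed-term subsets (intercept
  always; an interaction only with both mains) are ranked by AIC with
  k = fixed-effect columns + variance parameters. Candidates are refitted
  by full ML for the ranking because restricted likelihoods are not
  comparable across fixed-effect sets; ranking on REML is available via
  `criterion="reml"` but measurably distorts selection (a covariate with
  mean |z| ≈ 3.9 was retained in only ~85% of replicates under REML-AIC
  versus ~100% under ML-AIC). Reported variance components always come
  from REML fits of the selected model. Note that plain AIC retains a
  superfluous 1-df term with asymptotic probability P(chi2_1 > 2) ≈ 0.16;
  that is a property of AIC, not a defect of the implementation.
- **Multiplicity.** Benjamini–Hochberg q-values over the pooled family of
  all fixed-effect and variance-component p-values from the three
  age-group models (per-model families optional), reflecting that the
  subsets share children and are not independent.
- **ICCs.** Double-entry Pearson correlations per pair-class ×
  home-sharing (× age-composition) cell — each pair entered in both member
  orders, making the estimate symmetric in member labels — with
  significance from the one-way between/within-pair ANOVA F. Cells with
  fewer than 3 pairs are flagged undefined.
- **Within-family variance.** Sample variance (divisor n_pairs − 1) of
  per-pair outcome differences, each pair entered once with a fixed
  id-order sign.
- **Residual-spread comparison.** Brown–Forsythe (median-centered Levene)
  test between the residuals of single-component refits of two age-group
  models; the classic mean-centered variant is an option. The age-group
  subsets can share children, so the test is reported as approximate with
  the overlap logged.
- **Power.** Monte-Carlo: scale the cohort composition, simulate at the
  configured true variances, test the component by LRT at alpha, report
  the empirical power curve and the smallest size reaching the target.

## Synthetic cohorts

The generator emulates the sibling-adoption design directly. Family units
are drawn from nine templates (MZ twins adopted together; full sibs
together in the birth home; full sibs reared apart; a full-sib pair
adopted together plus their half sibling with the birth mother; half sibs
together, birth or adoptive; half sibs apart; two or three nonbiological
children adopted together). The default composition solves the design
margins exactly: 711 children, 414 households, 579 pairs (12 MZ / 115
full-or-DZ / 192 half / 260 unrelated), 500 children in adoptive homes and
211 in birth homes. Covariates: sex Bernoulli(0.536); race categorical
(58.8% Caucasian, 21.9% Multiracial, 17.9% African American, remainder
small categories); ethnicity Hispanic 12.9%; birth-home children are
reared by a biological parent, adoptive-home children with probability
0.138. Ages are uniform on [5, 19) for the first child of a unit; sibling
ages offset by |N(3.56, 2.35)| years with random sign, rejection-sampled
into range (truncation pulls the realized mean gap to ~3.1 y).

The outcome is sampled exactly from the model: y = X beta + L z with L the
Cholesky factor of sigma2_A K + sigma2_C H + sigma2_E I and z iid standard
normal — chosen over explicit parental breeding values because it is exact
for arbitrary K at these scales. Defaults: true (sigma2_A, sigma2_C,
sigma2_E) = (0.025, 0.012, 0.003) ln-units² (the middle-childhood working
values of this design), intercept ln 18.4, birth-home effect ln 1.05, race
contrasts ln 1.08 / ln 1.07. A bmi_z column is produced against a synthetic
growth reference placed so the cohort mean sits 0.63 SD above the reference
median, yielding ~15% obesity prevalence; it is labelled synthetic — it is
not the CDC-2000 LMS table, which the preparation module accepts as an
optional CSV for real data.

What the generator does not emulate — and hence what passing recovery
tests do not establish about real cohorts: selective adoption placement,
assortative mating, reporting error in parent-reported height/weight, age
trends in the outcome (an optional age-slope knob exists for
mis-specification studies), attrition, and the study's exact joint
age-composition of pairs (our subset sizes differ from the printed
169/132/278 because ages are uniform).

## Validation scale and numerical choices

The validation studies run at sizes chosen to exercise the estimator
meaningfully on a single CPU: the grid-oracle check uses 20 cohorts of
n ≤ 20 against a 24³ dense grid; parameter recovery uses 200 full-size
(n = 711) cohorts; permutation calibration uses 200 null cohorts of ~85
children with 199 permutations; the covariance-structure check uses a
9-child fixture with 1200 replicates. Cholesky/solve failures on a
non-PD unit-scale covariance raise immediately (no silent jitter); the
generator refuses sigma2_E = 0 with MZ pairs for the same reason.
Convergence tolerances (ftol 1e-12, gtol 1e-9, boundary snap 1e-7) are
tighter than any reported precision.

## Known limitations

- Broad-sense vs narrow-sense: with siblings only, the "A" component is
  additive by construction; non-additive variance, if present, inflates it.
- Delta-method SEs for h2/c2 are asymptotic; with boundary components the
  sampling distribution is mixed and the Wald interval is approximate.
- The permutation test's conservativeness when the other variance
  component is real (see above) means its p-values for V_A in the presence
  of strong C are upper bounds.
- AIC over fixed effects with REML-reported variances mixes two criteria;
  we follow the field's standard resolution (ML for ranking, REML for
  reporting) and document the alternative.
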
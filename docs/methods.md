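# Methods

## Data model and preprocessing

A cohort is a sample × peak table of integrated chromatogram areas (39
peaks GP1–GP39 for total plasma proteins, 24 peaks GP1–GP24 for IgG) plus
per-sample covariates: family id, sex, age, disease status, plate.  The
preprocessing order is fixed and enforced by a state flag on the table:

1. **Total-area normalization.** `value[i,j] = 100·area[i,j]/Σ_j area[i,j]`.
   Percentages, not fractions, so a trait reads directly as "% of total
   chromatogram area".  Rows close to 100 within 1e-9.
2. **Natural log.** Exact zeros (rare for integrated peaks) are imputed as
   half the column's smallest positive value before logging; a strict
   `zero_policy="error"` is available.
3. **ComBat.** Parametric empirical-Bayes location/scale batch adjustment
   (the Johnson–Li–Rabinovic model) via scanpy's implementation, with no
   protected biological covariates by default — correction happens before
   any modelling, so protecting disease status would be a modelling
   choice, and leaving it out risks removing signal if case/control ratios
   differ across plates; callers can pass a covariate matrix.  A single
   batch is an identity pass with a warning.
4. **Rank-based inverse normal transformation.** Per peak,
   Φ⁻¹((rank − ½)/n) on average ranks, then recentred/rescaled to mean 0,
   SD 1 exactly.  Average ranks make ties deterministic; random
   tie-breaking (as in some rank-transform implementations) was rejected
   for reproducibility.  A constant vector is an error.

EB shrinkage is worth a note: with plate effects that are *common* to all
peaks, the across-peak prior variance collapses to sampling noise and
shrinkage deliberately leaves a fraction of each peak's sampling noise
uncorrected — residual between-plate gaps after correction are then
limited by n per plate, not by the algorithm.  With heterogeneous
per-peak plate effects (the realistic case, and what the generator
produces) the prior is wide, shrinkage is mild, and residual gaps are
~0.005 log-units at 100 samples per plate.

## Derived traits

Each trait is the sum of percentages over peaks carrying a structural
feature; galactosylation/sialylation counts exclude high-mannose peaks
(which carry neither), LB covers biantennary complex peaks and HB
tri-/tetra-antennary ones.  Traits are linear in the peak percentages, so
they commute with sample mixing and are computed on the percent-state
table only.  The shipped annotations assign co-eluting peaks the features
of the dominant structure (flagged in the TSV note column); the plasma
panel's GP12, for instance, counts as high-mannose.  The IgG peak whose
structure is undetermined (GP20) is assigned the features of its elution
region (monosialylated digalactosylated, core-fucosylated) so the
sialylation family still partitions the chromatogram; the annotation TSVs
are packaged data and editable if an authoritative composition list is
available.  The IgG trait set {G0,G1,G2,S0,S1,S2,B,CF,HM} covers every
derived trait the IgG analyses report; the plasma set adds G3/G4, S3/S4,
AF, LB/HB.

## Association models

All models take one rank-normalized glycan vector at a time; BH correction
is applied once per panel × model family (all peaks plus derived traits of
one panel form a single family).

**Sex × age group.**  Age groups use sex-specific pubertal cut-offs
(female 6/11/15, male 6/13/17 years; configurable).  The saturated
two-way layout is fit by least squares; post-hoc pairwise contrasts of
cell means (between age groups within sex, and between sexes within age
group) use two-tailed t tests on the pooled residual variance, BH-adjusted
across contrasts.  Cells with fewer than two observations are an error;
levels absent from the data simply produce fewer contrasts.

**Censored autoantibody level.**  `glycan = b₀ + I·b₁·c + (1−I)·b₂ + sex
+ age`, with I = 1 when c is below the assay LOQ — i.e. the slope acts on
quantified levels and b₂ is a constant offset for saturated ("above
LOQ") measurements.  This upper-tail convention is the reverse of common
lower-LOQ handling and is kept as the default (`direction="upper"`)
because it matches the assay saturation scenario the model encodes;
`direction="lower"` gives the conventional form.  If every observation
falls on one side of the LOQ the unidentifiable parameter is dropped and
recorded in the result's warnings.  With no censored observations the
model collapses to ordinary regression on c.

**Autoantibody count.**  The ordered count (1–4) enters as a numeric
score, adjusted for sex and age; the single reported β is the change in
glycan per additional autoantibody.  A trend score was chosen over three
dummy contrasts because the count is ordinal and one slope per glycan is
the quantity of interest.

**Disease status.**  Logistic regression `status ~ glycan + age + sex`
with the glycan standardized, so the OR is per 1 SD.  Default inference
uses family-cluster-robust standard errors: point estimates then coincide
with ordinary logistic regression, and the sandwich variance is valid
under arbitrary within-family dependence without distributional
assumptions on the family effect.  `method="mixed"` instead adds a family
random intercept (the in-package penalized mixed estimator at λ = 0) and
falls back to the cluster-robust fit when the estimated family variance
degenerates to ~0.  Perfect separation triggers a Firth bias-reduced fit
(Jeffreys-prior score correction), flagged in the result.

## The discrimination model

"Logistic elastic net with a family random variable" is not a single
off-the-shelf estimator — penalized GLM software has no random effects
and mixed-model software has no elastic net — so the estimator here is
built from first principles:

- **Objective.**  Mean negative Bernoulli log-likelihood of
  η = β₀ + Xβ + u_fam, plus λ[α‖β_pen‖₁ + (1−α)‖β_pen‖₂²/2] over the
  penalized coefficients (glycans; age and sex are never penalized), plus
  Σ u_f²/(2σ²n) for the family intercepts.
- **Inner solver (σ² fixed).**  Alternate (a) coordinate-descent elastic
  net on the IRLS working response with the current intercepts as offset
  and (b) Newton updates of the family intercepts, each with step-halving
  against the joint objective, so the recorded objective path is monotone
  nonincreasing by construction.  Convergence when no parameter moves more
  than `tol` (default 1e-6).
- **Variance estimation.**  σ² maximizes the penalized marginal likelihood
  with the family integrals evaluated by 15-node adaptive Gauss–Hermite
  quadrature (per-family posterior mode and curvature), searched by bounded
  scalar minimization over log σ and compared against the σ² = 0 boundary.
  This avoids the well-known downward bias of penalized quasi-likelihood
  for binary clusters of size 2–3.  `sigma2=0` in the settings disables the
  random effect and reproduces plain elastic-net logistic regression (at
  λ = 0 it matches an independently coded Newton IRLS fit to <1e-4).
- **Standard errors** are Wald, from the weighted information at
  convergence conditional on the fitted intercepts (plus the ridge part of
  the penalty); they ignore the uncertainty of σ² and of the L1 active
  set, which is acceptable for the unpenalized covariates and stated here
  as a limitation.

**Cross-validation** partitions *families*, never samples: all siblings
share a fold, so sibling correlation cannot leak into the held-out fold
and inflate the AUC (a deliberately conservative choice; folds are a
seeded shuffle of the family list split into k chunks).  Held-out families
are predicted with their random intercept at 0.  **AUC** uses the
Mann–Whitney rank identity (ties count ½); curve points come from the
standard threshold sweep.  The **full-vs-null comparison** resamples
families with replacement, paired (same resample for both score vectors),
recomputes both AUCs per replicate, and reports the two-sided normal
approximation p = 2Φ̄(|Δ|/sd(Δ*)) with a percentile CI; replicates missing
a class are redrawn and counted.  Sample-level resampling is available via
a flag.

Defaults α = 0.1, λ = 10⁻⁴, k = 10, 2000 bootstrap replicates.  λ = 10⁻⁴
on standardized predictors is near-unpenalized: with ~40 predictors and a
few hundred training samples the fold models overfit freely, which is
part of the procedure being reproduced, not a defect; consequences are
quantified below.

## Synthetic cohorts

The generator emulates a family-based registry cohort: each family one
affected proband plus 1–5 unaffected siblings (sibling-count distribution
with mean ≈ 1.3, so 188 families yield ≈ 244 unaffected siblings), ages
uniform on 0.6–19.1 years, sexes Bernoulli(0.5), samples assigned
round-robin to plates.  Log-areas are baseline + family intercept
N(0, 0.3²) + per-plate-and-peak shift N(0, 0.2²) + sex/age/disease terms +
residual N(0, 0.25²); areas are the exponentials, so the model is
multiplicative on the raw scale and the ComBat additive-on-log assumption
is exactly the simulated truth.  The default baseline decays smoothly so a
few major peaks dominate, as in a real chromatogram.

Autoantibody levels for affected children are log-normal(0.5, 0.8²) with
an upper LOQ of 2.5, putting roughly a third of levels at or above the
LOQ — a realistic saturated share for islet autoantibody assays; no
authoritative distributions exist for these assays, so they are exposed in
the config.  The designated peak's log-area receives +b₁c below the LOQ
and +b₂ at or above it, i.e. the generator inverts the censored
regression model, making (b₀, b₁, b₂) recoverable ground truth.
Parameter-recovery checks fit the *raw log-area* of the designated peak:
after compositional closure a peak's log-percentage is coupled to the row
total, which would bias the recovered slope relative to the generating
truth.

What the generator does **not** emulate: genetic relatedness beyond a
shared family intercept, longitudinal sampling, seasonal or storage-time
effects, protein-concentration changes masquerading as glycosylation
changes, chromatogram-level integration error, and missing peaks.
Passing tests therefore certify the statistical machinery under the
stated generative model, not the biology of any real cohort.

## Numerical choices and edge cases

- IRLS weights floored at 1e-5; log-likelihoods computed with
  `logaddexp` for stability at saturated fits.
- Elastic-net coordinate updates use the soft-threshold closed form; an
  infinite-λ fit returns exact zeros.
- Rank-INT and the sex×age model reject constant inputs/empty cells with
  named errors; the peak-table state machine rejects out-of-order
  preprocessing.
- Pipeline stage seeds are SHA-256 hashes of (stage name, global seed)
  reduced below 2³¹, so each stage is reproducible independently of
  execution order.

## Known limitations

- **Null-cohort CV AUC spread.**  On null cohorts of ~400 samples in ~180
  families, the full model's pooled out-of-fold AUC is unbiased (replicate
  mean 0.499 over 50 cohorts) but has replicate SD ≈ 0.037 — larger than
  the ≈ 0.028 expected for an AUC of independent scores — because
  predictions within a fold share one heavily overfit model (λ = 10⁻⁴,
  ~40 predictors) and siblings' predictions correlate.  Roughly 85% of
  null replicates land in [0.45, 0.55]; fold-mean centering does not
  reduce the spread.  Tightening λ or averaging repeated CV would shrink
  it but would depart from the fixed analysis settings.
- Derived-trait membership reflects dominant structures; low-abundance
  co-eluting structures are not split across traits.
- The censored-level model assumes a homoscedastic Gaussian error on the
  (transformed) glycan and a linear effect of the level below the LOQ.
- Mixed-model Wald SEs are conditional (see above); for formal inference
  on single glycans the cluster-robust logistic route is preferred.
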
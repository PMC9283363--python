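# t1dglyco

Statistical analysis of plasma and IgG N-glycan profiles at the onset of
type 1 diabetes, built for researchers analysing HILIC-UPLC glycan peak
tables from family-based case-control cohorts (affected children and their
unaffected siblings).

The package covers the full analysis chain:

- **Preprocessing** — total-area normalization (each peak as a percentage
  of the chromatogram), natural log, ComBat empirical-Bayes batch
  correction across plates, and rank-based inverse normal transformation
  (Blom-type, Φ⁻¹((r − ½)/n), rescaled to mean 0 / SD 1).
- **Derived traits** — shipped annotation schemas for the 39-peak plasma
  and 24-peak IgG panels, from which 15 plasma and 9 IgG derived
  glycosylation traits (galactosylation G0–G4, sialylation S0–S4,
  bisecting GlcNAc B, core/antennary fucose CF/AF, branching LB/HB, high
  mannose HM) are computed as sums of member-peak percentages.
- **Association models** — sex × pubertal-age-group GLM with post-hoc
  pairwise t contrasts; a censored autoantibody-level model
  `glycan = b₀ + I·b₁·c + (1−I)·b₂ + sex + age` with indicator `I = 1`
  when the level c is below the assay's limit of quantification; a linear
  trend on the number of islet autoantibodies (1–4); disease-status
  logistic regression with family-clustered uncertainty, reported as odds
  ratios per 1 SD of glycan; Benjamini–Hochberg control per panel.
- **Discrimination** — elastic-net logistic regression
  (penalty λ[α‖β‖₁ + (1−α)‖β‖₂²/2], defaults α = 0.1, λ = 10⁻⁴) with a
  family random intercept (adaptive Gauss–Hermite variance estimation),
  family-grouped 10-fold cross-validation, ROC/AUC by the Mann–Whitney
  identity, and a paired family-bootstrap comparison (2000 replicates) of
  the full (glycans + age + sex) vs null (age + sex) model.
- **Synthetic cohorts** — a first-class generator of sibling-pair cohorts
  with family random intercepts, plate shifts, sex/age/disease effects and
  right-censored autoantibody levels, so every stage is testable with
  known ground truth.

## Worked example

`examples/05_discrimination.py` simulates a 188-family cohort with
onset-like peak effects, preprocesses it, and runs the full-vs-null
comparison:

```
full model  (glycans + age + sex): out-of-fold AUC = 0.943
null model  (age + sex only):      out-of-fold AUC = 0.471
delta = 0.473, 95% bootstrap CI (0.417, 0.526)
paired family-bootstrap p = 1.58e-66  (2000 replicates)
nonzero glycan coefficients: 39 of 39
```

Age and sex alone carry no signal in this cohort (AUC ≈ 0.5, the
diagonal); adding the 39 directly measured plasma peaks separates affected
children from their unaffected siblings, and the bootstrap p-value says
the AUC gain is far beyond resampling noise. The other example scripts
walk through simulation, preprocessing, derived traits and the
association models in the same style.

The same stages are available from the shell:

```bash
t1dglyco simulate --seed 1 --out-dir run/
t1dglyco preprocess --peaks run/peaks.tsv --meta run/metadata.tsv \
    --out run/normalized.tsv --state rank_normal
t1dglyco traits --peaks run/peaks.tsv --schema plasma --out run/traits.tsv
t1dglyco associate --peaks run/normalized.tsv --meta run/metadata.tsv \
    --traits run/traits.tsv --out run/associations.tsv
t1dglyco discriminate --peaks run/normalized.tsv --meta run/metadata.tsv \
    --out run/report.json
t1dglyco run --config pipeline.yaml   # all of the above, with a manifest
```

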
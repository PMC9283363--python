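"""Glycan-based discrimination: full vs null model.

Fits the elastic-net logistic model with a family random intercept
(alpha = 0.1, lambda = 1e-4), evaluates it by family-grouped 10-fold
cross-validation, and compares the full model (glycans + age + sex)
against the null model (age + sex) with a paired family bootstrap.
"""

from t1dglyco.discriminate import run_full_vs_null
from t1dglyco.preprocess import run_preprocessing
from t1dglyco.simulate import SimulationConfig, plasma_disease_effect, simulate_cohort
from t1dglyco.tables import BatchDesign

cohort = simulate_cohort(
    SimulationConfig(n_families=188, disease_effect=plasma_disease_effect(), seed=6)
)
rank_normal = run_preprocessing(
    cohort.peak_table, BatchDesign.from_metadata(cohort.metadata), until="rank_normal"
)
result = run_full_vs_null(rank_normal, cohort.metadata, n_boot=2000, seed=6)

comp = result["comparison"]
print(f"full model  (glycans + age + sex): out-of-fold AUC = {comp.auc_full:.3f}")
print(f"null model  (age + sex only):      out-of-fold AUC = {comp.auc_null:.3f}")
print(f"delta = {comp.delta:.3f}, 95% bootstrap CI ({comp.ci_low:.3f}, {comp.ci_high:.3f})")
print(f"paired family-bootstrap p = {comp.p:.2e}  ({comp.n_replicates} replicates)")
# Age and sex alone carry no disease signal in this cohort (AUC ~0.5);
# the glycan panel separates affected children from their siblings.
coef = result["model_full"].coef
print(f"nonzero glycan coefficients: {(coef[:-2] != 0).sum()} of {len(coef) - 2}")
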
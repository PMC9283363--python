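"""Per-glycan association models.

Runs the three association analyses on simulated data with known truth:
the censored autoantibody-level model (slope b1 below the assay LOQ,
constant offset b2 at or above it), the autoantibody-count trend, and
family-adjusted disease-status odds ratios with BH correction.
"""

import numpy as np

from t1dglyco.associate import (
    disease_association_panel,
    fit_censored_autoantibody_model,
)
from t1dglyco.preprocess import run_preprocessing
from t1dglyco.simulate import (
    AutoantibodyParams,
    SimulationConfig,
    plasma_disease_effect,
    simulate_autoantibodies,
    simulate_cohort,
)
from t1dglyco.tables import BatchDesign, SampleMetadata

# --- censored autoantibody model -------------------------------------
ab = AutoantibodyParams(b1=0.59, b2=0.8, target_peak="GP13")
cfg = SimulationConfig(
    n_families=300, n_peaks=24, baseline=np.zeros(24),
    family_intercept_sd=0.0, batch_shift_sd=0.0, residual_sd=0.3,
    autoantibody_params=[ab], seed=4,
)
cohort = simulate_cohort(cfg)
meta, peaks = simulate_autoantibodies(cohort.metadata, cohort.peak_table, cfg)
affected = meta.table["status"].to_numpy() == 1
fit = fit_censored_autoantibody_model(
    np.log(peaks.values["GP13"].to_numpy())[affected],
    meta.table["ZnT8R_level"].to_numpy()[affected],
    ab.loq,
    SampleMetadata(meta.table[affected].reset_index(drop=True)),
)
print(f"censored model: b1 = {fit.b1:.3f} (truth 0.59), "
      f"b2 = {fit.b2:.3f} (truth 0.80); "
      f"{fit.n_censored} of {fit.n_censored + fit.n_uncensored} at/above LOQ")
# b1 is the change in log glycan per unit of quantified level; b2 the
# offset for children whose level saturated the assay.

# --- disease-status odds ratios --------------------------------------
cfg2 = SimulationConfig(n_families=188, disease_effect=plasma_disease_effect(), seed=5)
c2 = simulate_cohort(cfg2)
rn = run_preprocessing(c2.peak_table, BatchDesign.from_metadata(c2.metadata),
                       until="rank_normal")
panel = disease_association_panel(rn, c2.metadata)
print("\ntop disease associations (OR per 1 SD of glycan, BH-corrected):")
print(panel.sort_values("p").head(6).round(3).to_string(index=False))
# ORs above 1 mark peaks enriched in affected children; the simulated
# profile raises bisected/high-mannose/sialylated peaks and lowers
# monogalactosylated ones, which is what the table recovers.
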
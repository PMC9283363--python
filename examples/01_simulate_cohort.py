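"""Simulate a sibling-pair glycomics cohort with known ground truth.

Each family holds one affected child and one to five unaffected siblings;
peak areas follow a multiplicative model with family, batch, and
disease terms on the log scale.
"""

import numpy as np

from t1dglyco.simulate import SimulationConfig, plasma_disease_effect, simulate_cohort

config = SimulationConfig(
    n_families=188,  # one affected proband per family
    disease_effect=plasma_disease_effect(0.2),
    seed=1,
)
cohort = simulate_cohort(config)

meta = cohort.metadata.table
print(f"samples: {len(meta)}  (affected {int(meta.status.sum())}, "
      f"unaffected {int((1 - meta.status).sum())})")
print(f"families: {meta.family_id.nunique()}, plates: {meta.batch.nunique()}")
print(f"age range: {meta.age.min():.1f}-{meta.age.max():.1f} years")

# The disease effect is a log-scale shift; check it is visible on peak GP2
logs = np.log(cohort.peak_table.values["GP2"].to_numpy())
gap = logs[meta.status == 1].mean() - logs[meta.status == 0].mean()
print(f"affected-vs-unaffected mean log-area gap on GP2: {gap:.3f} "
      f"(simulated truth {config.disease_effect[1]:.2f})")
# The gap estimates the injected shift up to sampling noise; a cohort of
# this size recovers it to within a few hundredths of a log unit.
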
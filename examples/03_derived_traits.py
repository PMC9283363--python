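"""Compute derived glycosylation traits from peak percentages.

A derived trait sums the percentages of all peaks sharing a structural
feature: G0-G4 galactosylation, S0-S4 sialylation, bisecting GlcNAc (B),
core/antennary fucose (CF/AF), branching (LB/HB) and high mannose (HM).
"""

from t1dglyco.preprocess import normalize_total_area
from t1dglyco.simulate import SimulationConfig, simulate_cohort
from t1dglyco.traits import compute_derived_traits, plasma_annotation, validate_schema

annotation = plasma_annotation()
report = validate_schema(annotation, "plasma")
print(f"plasma schema: {report['n_peaks']} peaks, {report['n_traits']} derived traits")
print("monogalactosylated (G1) member peaks:", ", ".join(annotation.members("G1")))

cohort = simulate_cohort(SimulationConfig(n_families=50, seed=3))
percent = normalize_total_area(cohort.peak_table)
traits = compute_derived_traits(percent, annotation)
print("\nfirst sample's traits (% of total chromatogram area):")
print(traits.iloc[0].round(2).to_string())
# Traits overlap across feature families (a peak can be both bisected and
# core-fucosylated), so they do not sum to 100 across families; within the
# sialylation family S0..S4 + HM they partition the chromatogram.
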
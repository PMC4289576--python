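"""Six-year class transitions on a simulated cohort.

Cross-tabulates wave-1 pooled classes (Robust / Transient / Frail) against
wave-2 outcomes (a class, or dead / lost / refused / unscorable) and prints
row percentages. At defaults these reproduce the configured transition
rows, e.g. about half of the Robust stay Robust and about a third of the
Frail die before wave 2.
"""

from faindex import SimulationConfig, generate_cohort, transition_summary

cohort = generate_cohort(SimulationConfig.defaults(seed=3, n=8000)).table
ts = transition_summary(cohort["pooled_class"], cohort["wave2_outcome"])

print("Counts (wave-1 class x wave-2 outcome):")
print(ts.counts.to_string())
print()
print("Row percentages (each origin class sums to ~100):")
print(ts.row_percent.to_string())
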
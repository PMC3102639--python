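"""Simulate the observer-reliability experiment.

Three observers annotate 25 simulated patients twice each; landmark placement
error of 0.4 mm per coordinate propagates into the angles, and the ICC
quantifies the resulting test-retest and between-observer agreement.
"""

from spinetorsion import (
    CohortParams,
    format_reliability_tables,
    simulate_cohort,
    simulate_observers,
)

cohort = simulate_cohort(CohortParams(seed=42))
table = simulate_observers(cohort, n_observers=3, n_occasions=2,
                           noise_sigma_mm=0.4, seed=43)
print(f"{len(table)} measurement rows (25 subjects x 3 observers x 2 occasions x 2 methods)")
print()
print(format_reliability_tables(table))
print("ICCs near 1 mean landmark noise barely disturbs the ranking of")
print("subjects; the lamina bisector (Ho) is built from four points on short")
print("segments, so it is typically no more reliable than the 30 mm pedicle chord.")
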
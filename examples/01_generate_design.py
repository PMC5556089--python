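"""Generate one subject's pseudo-random tasting design and audit it.

The design crosses 3 price cues with 2 payment conditions, 18 repetitions
each, split over 3 runs of 36 trials, under the ordering constraints used in
cue-expectancy tasting experiments (never the same wine twice in a row, at
most two successive repeats of a price or payment condition).
"""

from mlmed.design import DesignSpec, check_constraints, generate_design

spec = DesignSpec()
table = generate_design(spec, seed=7)

print(f"trials: {len(table)}  runs: {spec.n_runs}  "
      f"per condition: {spec.reps_per_condition}  "
      f"total wine: {spec.total_volume_ml:.0f} ml")
print(table.head(6).to_string(index=False))
print("constraint audit:", check_constraints(table, spec))
# zero violations means the pseudo-randomization constraints all hold
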
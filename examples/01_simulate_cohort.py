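"""Generate a synthetic perfusion cohort and save it in both file layouts.

The default design emulates a thermal-stimulus experiment: 33 subjects
(16 control responders, 17 experimental non-responders), three states
(basal, cold, warm) of 300 samples each, AR(1) noise and a large artifact
burst at each intervention boundary.
"""

from toiseg import SimulationDesign, simulate_cohort, write_cohort_table, write_workbook

design = SimulationDesign(seed=42)
cohort = simulate_cohort(design)

write_cohort_table(cohort, "cohort.tsv")
write_workbook(cohort, "cohort.xlsx")

rec = cohort.records[0]
print(f"cohort: {cohort.n_subjects} subjects, TOIs {cohort.toi_labels}")
print(f"subject 1: {rec.internal_code} ({rec.group} {rec.sex}), ni={rec.n} samples")
print(f"marker blocks: {rec.marker_blocks()}")
# Each subject is one uniformly sampled perfusion trace; the marker blocks
# are the experimenter's (non-optimal) state annotations the pipeline refines.
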
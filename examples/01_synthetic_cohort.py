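"""Generate the default three-group synthetic cohort and inspect it.

The generator emulates a hemodialysis cognitive-impairment study design:
25 healthy controls (HC), 20 patients without cognitive impairment
(MHD_noCI) and 19 with impairment (MHD_CI). Each subject gets a 240x90
matrix of AR(1) BOLD-like signals whose spatial covariance is modular,
with within-module correlation highest in HC and lowest in MHD_CI — the
planted group effect every downstream stage is meant to detect.
"""

import funconn as fc

cohort = fc.generate_cohort(fc.CohortConfig(seed=2021))

print(f"subjects: {len(cohort.series)}")
first = cohort.subject_ids[0]
print(f"time series shape per subject: {cohort.series[first].shape}")
print(f"motion trace shape: {cohort.motion[first].shape}")
print()
print(cohort.meta.groupby("group")[["age", "education", "moca", "sds_score"]]
      .median().round(1))
print()
# The grouping rule is exact: patients with MoCA < 26 are the CI group.
patients = cohort.meta[cohort.meta["group"] != "HC"]
print("MoCA range per patient group:")
print(patients.groupby("group")["moca"].agg(["min", "max"]))
# write_cohort(cohort, "cohort_dir") persists everything as plain text.
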
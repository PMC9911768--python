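"""Geometric systolic strain for a few subjects, against generator truth.

LS and CS are arc-length Cauchy strains on the endocardial parameter
lines; RS is the modified-centerline wall-thickening strain on short-axis
slices. Truth values are the analytic strains of each subject's
parametric deformation.
"""
from bivatlas.strain import compute_strains
from bivatlas.synthetic import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(seed=0))
for i in (0, 1, 2):
    sr = compute_strains(cohort.ed_surfaces[i], cohort.es_surfaces[i])
    truth = cohort.truth[i].strains
    print(cohort.records[i].subject_id)
    for key, val in sr.as_dict().items():
        print(f"  {key}: measured {val:6.1f}%   truth {truth[key]:6.1f}%")
# Negative LS/CS = shortening, positive RS = thickening. Measured values
# scatter around truth with the planted shape variance and vertex noise.
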
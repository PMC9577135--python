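"""Generate a synthetic annotated ROI cohort and inspect its structure.

Builds the desk-scale cohort (24 ROIs over 23 patients, 64 x 64 pixels at
2 um/px, 11 tissue classes plus an unlabeled avoid class) and prints the
pooled class prevalences and the patient-level train/holdout split.
"""

import collections

import numpy as np

import alseg
from alseg.presets import desk_preset

cohort, legend = alseg.generate_cohort(desk_preset(seed=1))
print(f"{len(cohort)} ROIs from {len({s.patient_id for s in cohort})} patients")

counts = collections.Counter()
for s in cohort:
    idx, n = np.unique(s.labels.indices, return_counts=True)
    for i, c in zip(idx, n):
        counts[int(i)] += int(c)
total = sum(counts.values())
print("\npooled class prevalence (fraction of all pixels):")
for i in sorted(counts):
    name = legend.name_of(i) if i != legend.avoid_index else "(avoid / unlabeled)"
    print(f"  {name:<22s} {counts[i] / total:.3f}")

split = alseg.split_by_patient(cohort, n_holdout_patients=3, seed=1)
print(f"\ntrain pool: {len(split.train_pool_ids)} ROIs, holdout: {len(split.holdout_ids)} ROIs")
print("holdout ROIs:", sorted(split.holdout_ids))
# Tumor/stroma/lymphocytes dominate; mucosa/blood/muscle are rare and absent
# from many ROIs — the imbalance that makes sample selection matter.
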
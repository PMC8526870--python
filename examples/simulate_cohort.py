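"""Generate a synthetic term/preterm neonatal cohort with known ground truth.

Builds a 286-parcel cortical parcellation, samples study-like demographics
(term GA 37-42.14 weeks, preterm 23-36.86, age-matched scans at 37-45.14
weeks PMA), and generates the 8-metric parcel-wise feature table with
region-specific age trajectories, sex effects, prematurity-graded group
effects and sparse injected extreme deviations.
"""

import numpy as np

from corticonorm import (
    default_effect_config,
    generate_features,
    generate_parcellation,
    sample_demographics,
)

parcels = generate_parcellation(143, seed=1)
subjects = sample_demographics(n_term=259, n_preterm=76, seed=2)
table, truth = generate_features(subjects, parcels, default_effect_config(seed=3))

term = subjects[subjects.group == "term"]
pre = subjects[subjects.group == "preterm"]
print(f"parcels: {parcels.n_parcels} ({parcels.table.hemisphere.value_counts().to_dict()})")
print(f"subjects: {len(term)} term (GA median {term.ga_birth.median():.2f} w), "
      f"{len(pre)} preterm (GA median {pre.ga_birth.median():.2f} w)")
print(f"feature table: {table.values.shape} (subjects x parcels x metrics)")
j = table.metrics.index("thickness")
print(f"mean cortical thickness {table.values[:, :, j].mean():.3f} mm "
      "(neonatal cortex is ~1.1 mm thick)")
print(f"injected extreme deviations: {truth.n_injected} cells, all in preterm "
      "infants -- the oracle for recovery tests")
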
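"""Group-difference inference with max-statistic permutation correction.

Per-parcel GLM t-statistics for preterm vs term (PMA and sex as nuisance),
with Freedman-Lane permutations and family-wise error correction jointly
across parcels, the 8 metrics and both contrast directions (p_mcfwe).
"""

import numpy as np

from corticonorm import (
    default_effect_config,
    design_group,
    generate_features,
    generate_parcellation,
    permutation_test,
    sample_demographics,
)

parcels = generate_parcellation(20, seed=1)
subjects = sample_demographics(n_term=120, n_preterm=60, seed=2)
table, truth = generate_features(subjects, parcels, default_effect_config(seed=3))

res = permutation_test(table, design_group(subjects), n_perm=2000, seed=4)
print(f"{res.n_perm} permutations, df = {res.df}")
for j, metric in enumerate(table.metrics):
    n_pos = int(res.significant_pos[:, j].sum())
    n_neg = int(res.significant_neg[:, j].sum())
    if n_pos or n_neg:
        strongest = np.abs(res.t[:, j]).argmax()
        print(f"  {metric:10s}: {n_pos:2d} parcels preterm>term, "
              f"{n_neg:2d} preterm<term  (peak t = {res.t[strongest, j]:+.2f}, "
              f"r = {res.r[strongest, j]:+.2f})")
print("significant parcels concentrate where the generator placed preterm "
      "effects (posterior MD up / fICVF down, anterior thickness up, "
      "insular FA up / ODI down); other metrics stay clean.")
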
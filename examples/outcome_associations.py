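"""Relate deviations to gestational age at birth and 18-month outcome.

Parcel-wise Z-scores are tested against GA at birth with the permutation
GLM; whole-cortex atypicality indices are tested with Kendall tau-b
(correlation with GA / BSID-III scores) and Mann-Whitney U (preterm vs
term), with Benjamini-Hochberg FDR over each hypothesis family.
"""

import numpy as np

from corticonorm import (
    atypicality_indices,
    classify_extremes,
    compute_z_scores,
    default_effect_config,
    fit_normative_model,
    generate_features,
    generate_parcellation,
    index_correlation,
    index_group_test,
    predict,
    sample_demographics,
    z_covariate_map,
)

parcels = generate_parcellation(15, seed=1)
subjects = sample_demographics(n_term=100, n_preterm=50, seed=2)
table, _ = generate_features(subjects, parcels, default_effect_config(seed=3))

term_ids = subjects.loc[subjects.group == "term", "subject_id"]
pre_ids = subjects.loc[subjects.group == "preterm", "subject_id"]
model = fit_normative_model(table.subset(term_ids[:75]), restarts=2, seed=4)

scored = table.subset(list(term_ids[75:]) + list(pre_ids))
z = compute_z_scores(predict(model, scored.subjects), scored)
res = z_covariate_map(z, scored.subjects, "ga_birth", n_perm=1000, seed=5)
print(f"GA-association map: {int(res.significant.sum())} significant "
      f"(parcel, metric) cells at p_mcfwe < 0.05 in the combined sample")

idx = atypicality_indices(classify_extremes(z))
ga = scored.subjects.ga_birth.to_numpy()
corr = index_correlation(idx, ga, covariate_name="ga_birth")
sig = corr[corr.p_fdr < 0.05]
print(f"atypicality ~ GA: {len(sig)} of {len(corr)} (metric, sign) indices "
      "FDR-significant; lower GA at birth means higher extreme-deviation "
      "burden in the affected metrics")

groups = scored.subjects.group.to_numpy()
gtest = index_group_test(idx, groups)
print(f"preterm vs term burden: {int((gtest.p_fdr < 0.05).sum())} of "
      f"{len(gtest)} indices differ (Mann-Whitney U, FDR-corrected)")

# BSID-III outcomes are generated independent of the brain by default, so
# their associations should be null
bsid = scored.subjects.bsid_cognitive.to_numpy()
corr_bsid = index_correlation(idx, bsid, covariate_name="bsid_cognitive")
print(f"atypicality ~ 18-month cognition: "
      f"{int((corr_bsid.p_fdr < 0.05).sum())} FDR-significant "
      "(expected 0: outcomes are independent of deviations by construction)")
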
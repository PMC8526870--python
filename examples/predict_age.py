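"""Brain-age prediction from all parcel-wise cortical features.

A random forest predicts PMA at scan from the flattened parcel x metric
feature matrix; training-set linear regression of predictions on true age
provides the error-in-variables correction applied to the hold-out sample.
Feature importance is summarised as the per-metric share of the top decile.
"""

from corticonorm import (
    AgePredConfig,
    default_effect_config,
    evaluate_age_model,
    fit_bias_correction,
    generate_features,
    generate_parcellation,
    sample_demographics,
    split_cohort,
    summarize_importance,
    train_age_model,
)

parcels = generate_parcellation(20, seed=1)
subjects = sample_demographics(n_term=150, n_preterm=0, seed=2)
table, _ = generate_features(subjects, parcels, default_effect_config(seed=3))

split = split_cohort(subjects, 0.25, seed=4)
train = table.subset(split.index[split == "train"])
hold = table.subset(split.index[split == "holdout"])

model = train_age_model(train, AgePredConfig(n_estimators=300, seed=5))
correction = fit_bias_correction(
    model.predict(train.flatten()), train.subjects.pma_scan.to_numpy()
)
report = evaluate_age_model(model, correction, hold,
                            train_subject_ids=train.subject_ids)
print(f"hold-out ({len(hold.subjects)} infants): "
      f"MAE = {report.mae:.2f} weeks, MSE = {report.mse:.2f}, "
      f"rho = {report.spearman_rho:.2f}, R^2 = {report.r_squared:.2f}")

importance = summarize_importance(model, table.metrics)
top = sorted(importance.percentages.items(), key=lambda kv: -kv[1])[:3]
print("top decile of feature importances "
      f"({importance.decile_size} features): "
      + ", ".join(f"{m} {p:.0f}%" for m, p in top))
print("surface area dominates because its age slope is by far the "
      "strongest relative to noise -- the forest ranks it accordingly.")
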
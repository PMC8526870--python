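import numpy as np
import pandas as pd
import pytest

from corticonorm import (
    FeatureTable,
    default_effect_config,
    generate_features,
    generate_parcellation,
    sample_demographics,
)
from corticonorm.normative import fit_normative_model


@pytest.fixture(scope="session")
def small_parcellation():
    return generate_parcellation(10, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_parcellation):
    """80 term + 25 preterm subjects on 20 parcels, default effects."""
    subjects = sample_demographics(80, 25, seed=21)
    cfg = default_effect_config(seed=22)
    table, truth = generate_features(subjects, small_parcellation, cfg)
    return table, truth, cfg


@pytest.fixture(scope="session")
def term_model(small_cohort):
    """GP normative model fitted on 60 of the term subjects; the remaining
    term subjects serve as holdout."""
    table, _, _ = small_cohort
    term = table.subjects[table.subjects["group"] == "term"]
    train_ids = term["subject_id"].iloc[:60]
    hold_ids = term["subject_id"].iloc[60:]
    model = fit_normative_model(table.subset(train_ids), restarts=2, seed=31)
    return model, table.subset(train_ids), table.subset(hold_ids)


def make_single_cell_table(y, pma, sex=None, metric="FA"):
    """A 1-parcel, 1-metric FeatureTable for focused GP tests."""
    n = len(y)
    if sex is None:
        sex = np.zeros(n, dtype=int)
    subjects = pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "group": "term",
            "ga_birth": 38.0,
            "pma_scan": pma,
            "sex": sex,
        }
    )
    parcels = generate_parcellation(7, seed=1)
    single = type(parcels)(parcels.table.iloc[:1].reset_index(drop=True))
    return FeatureTable(
        values=np.asarray(y, dtype=float).reshape(n, 1, 1),
        subjects=subjects,
        parcels=single,
        metrics=(metric,),
    )
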
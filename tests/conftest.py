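import warnings

import numpy as np
import pytest

from mascard.preprocess import (ImputationPolicy, flag_outliers_iqr, impute,
                                zscore_apply, zscore_fit)
from mascard.synth import CohortConfig, CohortTable, generate_cohort

# mean/mode-only imputation: fast and sufficient wherever a test exercises
# selection or modelling rather than the imputer itself
MEAN_MODE = ImputationPolicy(low_threshold=0.19, high_threshold=0.20)


@pytest.fixture(scope="session")
def default_cohort() -> CohortTable:
    """The study-scale cohort: 94 SLE + 94 MAS, 13 predictors + 20 noise."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def prepared_splits(default_cohort):
    """Imputed, winsorized, stratified 80/20 split; raw and Z-scored views."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        completed, _ = impute(default_cohort, MEAN_MODE)
    _, processed = flag_outliers_iqr(completed)
    rng = np.random.default_rng(0)
    test_idx = np.concatenate([
        rng.choice(np.where(processed.label == cls)[0], size=19, replace=False)
        for cls in (0, 1)])
    mask = np.zeros(processed.n_patients, bool)
    mask[test_idx] = True

    def take(m):
        return CohortTable(processed.frame[m].reset_index(drop=True),
                           processed.label[m])
    train, test = take(~mask), take(mask)
    scaler = zscore_fit(train)
    return {"train_raw": train, "test_raw": test,
            "train_z": zscore_apply(train, scaler),
            "test_z": zscore_apply(test, scaler), "scaler": scaler}
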
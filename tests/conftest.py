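import numpy as np
import pandas as pd
import pytest

import lungdose as ld


def merge_scores(cohort: ld.Cohort, model: ld.PCAModel) -> pd.DataFrame:
    """Patients table with the retained PCA score columns merged in."""
    data = cohort.patients.copy()
    for k in range(model.n_components):
        data[f"PCA_{k + 1}"] = model.scores[:, k]
    return data


@pytest.fixture(scope="session")
def cohort644() -> ld.Cohort:
    """Default-configuration synthetic cohort at the study's sample size."""
    return ld.generate_cohort(ld.CohortConfig(n_patients=644, seed=11))


@pytest.fixture(scope="session")
def cohort644_features(cohort644) -> ld.DoseFeatureMatrix:
    return ld.build_feature_matrix(
        cohort644.dvh, cohort644.structure_set, patient_ids=cohort644.patient_ids
    )


@pytest.fixture(scope="session")
def pca644(cohort644_features) -> ld.PCAModel:
    return ld.fit_pca(cohort644_features)


@pytest.fixture(scope="session")
def cohort300() -> ld.Cohort:
    """Smaller complete cohort (no missingness) for fitting fixtures."""
    return ld.generate_cohort(
        ld.CohortConfig(n_patients=300, seed=7, missing_counts={})
    )


@pytest.fixture(scope="session")
def data300(cohort300) -> pd.DataFrame:
    features = ld.build_feature_matrix(
        cohort300.dvh, cohort300.structure_set, patient_ids=cohort300.patient_ids
    )
    model = ld.fit_pca(features)
    return merge_scores(cohort300, model)
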
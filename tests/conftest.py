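import numpy as np
import pytest

import connsig as cs
from connsig.preprocess import run_preprocessing


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def planted_cohort():
    """Small planted cohort with its preprocessed features and LOOCV run.

    R = 20 regions, 12 subjects per group, 5 planted edges per signature
    at delta_r = 0.5 -- big enough for recovery, small enough for speed.
    """
    edge_rng = np.random.default_rng(777)
    state, trait, comp = cs.random_planted_edges(20, 5, 5, 5, edge_rng)
    config = cs.CohortConfig(
        n_per_group=(12, 12, 12),
        n_regions=20,
        n_volumes=120,
        base_correlation=0.1,
        state=cs.PlantedEdgeSet(state, 0.5),
        trait=cs.PlantedEdgeSet(trait, 0.5),
        compensatory=cs.PlantedEdgeSet(comp, 0.5),
        seed=2024,
    )
    cohort = cs.generate_cohort(config)
    clean = [
        run_preprocessing(ts, m) for ts, m in zip(cohort.subjects, cohort.motion)
    ]
    features = cs.feature_matrix(clean)
    labeled = cs.LabeledCohort(
        features=features,
        labels=cohort.labels,
        subject_ids=tuple(ts.subject_id for ts in cohort.subjects),
    )
    cv = cs.loocv(labeled)
    return {
        "config": config,
        "cohort": cohort,
        "features": features,
        "labeled": labeled,
        "cv": cv,
    }
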
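import numpy as np
import pandas as pd
import pytest

from anxrpt.synthetic_data import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-participant cohort with a moderate planted anxiety effect."""
    return generate_cohort(CohortSpec(n_participants=150, seed=7, anxiety_effect=1.2))


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    from anxrpt.rpt_features import compute_profiles

    return compute_profiles(small_cohort.ratings)


@pytest.fixture(scope="session")
def analysis_cohort():
    """An assembled analysis table (features + score) for classifier tests."""
    from anxrpt import pipeline_io, rpt_features, survey_scores

    cohort = generate_cohort(CohortSpec(n_participants=400, seed=11, anxiety_effect=1.2))
    profiles = rpt_features.compute_profiles(cohort.ratings)
    report = rpt_features.apply_rating_exclusions(cohort.ratings, profiles)
    scores = survey_scores.score_stai_table(cohort.stai_items)
    encoded, _ = survey_scores.encode_contextuals(cohort.contextual)
    return pipeline_io.assemble_cohort(profiles, encoded, scores, report.retained_ids)
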
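import numpy as np
import pytest

from ambulate.features import FEATURE_NAMES, featurize_stream
from ambulate.model import AmbulatoryStatusClassifier
from ambulate.pipeline import featurize_cohort, labeled_features
from ambulate.simulate import (CohortConfig, ParticipantProfile,
                               simulate_cohort)
import ambulate.labels as lb


@pytest.fixture(scope="session")
def small_pilot_cohort():
    """A 6-participant, 2-day pilot-like cohort (device step references)."""
    return simulate_cohort(
        CohortConfig(style="pilot_like", n_participants=6, n_days=2), seed=11)


@pytest.fixture(scope="session")
def small_pbhs_cohort():
    """A 6-participant, 2-day PBHS-like cohort (noisy self-report tags)."""
    return simulate_cohort(
        CohortConfig(style="pbhs_like", n_participants=6, n_days=2), seed=12)


@pytest.fixture(scope="session")
def walker_profile():
    return ParticipantProfile(
        participant_id="W1", gender="male", age_years=35,
        mean_daily_walk_minutes=60.0, cadence_hz=1.8, wear_hours_per_day=10.0)


@pytest.fixture(scope="session")
def small_pilot_features(small_pilot_cohort):
    return featurize_cohort(small_pilot_cohort)


@pytest.fixture(scope="session")
def small_labeled(small_pilot_cohort, small_pilot_features):
    labels = lb.device_labels(small_pilot_cohort.steps)
    return labeled_features(small_pilot_features, labels)


@pytest.fixture(scope="session")
def small_model(small_labeled):
    """A classifier fitted on the small pilot cohort (threshold unset)."""
    X = small_labeled[list(FEATURE_NAMES)].to_numpy()
    y = small_labeled["y"].to_numpy()
    return AmbulatoryStatusClassifier(random_state=7).fit(X, y)


@pytest.fixture()
def separable_xy():
    """Two well-separated Gaussian classes in feature space."""
    rng = np.random.default_rng(42)
    n = 5000
    X = np.vstack([rng.normal(0.0, 1.0, size=(n, len(FEATURE_NAMES))),
                   rng.normal(2.5, 1.0, size=(n, len(FEATURE_NAMES)))])
    y = np.repeat([0, 1], n)
    return X, y
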
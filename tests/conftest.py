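import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import vitalalert as va

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def latent_cohort() -> pd.DataFrame:
    """A 600-record synthetic cohort with NEWS2-latent labels."""
    return va.generate_cohort(va.CohortConfig(n=600), seed=11)


@pytest.fixture(scope="session")
def separable_table() -> pd.DataFrame:
    """A linearly separable labelled table in the model feature schema."""
    rng = np.random.default_rng(5)
    n = 400
    labels = rng.integers(0, 2, size=n)
    base = va.generate_cohort(va.CohortConfig(n=n), seed=5)[
        list(va.FEATURE_COLUMNS)
    ]
    # push the two classes far apart along heart rate and resp rate
    table = base.copy()
    table["heart_rate"] = 70.0 + 40.0 * labels + rng.normal(0, 1.0, n)
    table["resp_rate"] = 14.0 + 10.0 * labels + rng.normal(0, 0.5, n)
    table["label"] = labels
    return table


class ConstantClassifier:
    """Predicts one fixed class; stands in for a trained model in pipeline tests."""

    def __init__(self, value: int):
        self.value = value

    def fit(self, X, y):  # pragma: no cover - interface completeness
        return self

    def predict(self, X):
        return np.full(len(X), self.value, dtype=int)


@pytest.fixture
def constant_model_factory():
    def make(value: int) -> va.FittedModel:
        return va.FittedModel(
            spec=va.ClassifierSpec("logistic_regression"),
            estimator=ConstantClassifier(value),
            feature_columns=va.FEATURE_COLUMNS,
        )

    return make
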
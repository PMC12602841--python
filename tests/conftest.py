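import numpy as np
import pytest

from fedbioage.cohorts import CohortSpec, GeneratorTruth, generate_cohort


@pytest.fixture(scope="session")
def truth():
    return GeneratorTruth()


@pytest.fixture(scope="session")
def small_cohort(truth):
    spec = CohortSpec(
        "A", 300, 45, 90, age_mean=65.0, age_sd=10.0, lag_mean=0.5, lag_sd=2.0, seed=11
    )
    return generate_cohort(spec, truth)


@pytest.fixture(scope="session")
def scored_cohort(truth, small_cohort):
    """Cohort with score columns: exact-gap brainage/metaboage, standardized mortality score."""
    from fedbioage.association import add_dummies
    from fedbioage.scorers import (
        score_metabolite_model,
        synthetic_metabohealth_coefficients,
    )

    t = add_dummies(small_cohort)
    t["brainage"] = t["age"] + t["true_brain_gap"]
    t["metaboage"] = t["age"] + t["true_metab_gap"]
    t["metabohealth"] = score_metabolite_model(synthetic_metabohealth_coefficients(truth), t)
    return t


def make_linear_table(n, slope, intercept, noise_sd, seed, n_features=1):
    """Table whose age is a linear function of a single feature (+ noise)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 50, size=(n, n_features))
    age = slope * x[:, 0] + intercept + rng.normal(0, noise_sd, n)
    cols = {f"f{j}": x[:, j] for j in range(n_features)}
    return pd.DataFrame(
        {"participant_id": [f"p{i}" for i in range(n)], "age": age, "sex": rng.integers(0, 2, n), **cols}
    )
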
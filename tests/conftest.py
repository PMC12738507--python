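import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dermconformal as dc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def separable_cohort():
    """Two widely separated classes: any sane classifier is perfect here."""
    spec = dc.CohortSpec(
        class_counts=[60, 60], embed_dim=8, class_separation=10.0, seed=42
    )
    return dc.generate_cohort(spec)


@pytest.fixture(scope="session")
def fitted_results():
    """One moderately hard 4-class cohort, fitted end to end; reused across tests."""
    spec = dc.CohortSpec(
        class_counts=[500, 350, 250, 120], embed_dim=16, class_separation=3.0, seed=7
    )
    records = dc.generate_cohort(spec)
    model = dc.ConformalLesionModel(
        records,
        alpha=0.2,
        config=dc.MLPConfig(input_dim=16, n_blocks=2, epochs=15, seed=11),
        seed=5,
    )
    return model, model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
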
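import numpy as np
import pandas as pd
import pytest

from immunove import StudyTable, TrialConfig, simulate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_table():
    """Six subjects, one biomarker, distinct event times, both arms."""
    return StudyTable(
        pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(6)],
                "arm": ["vaccine", "vaccine", "vaccine", "control", "control", "control"],
                "time": [30.0, 200.0, 450.0, 90.0, 310.0, 520.0],
                "cause": [0, 1, 0, 1, 1, 0],
                "age": [0, 1, 0, 1, 0, 1],
                "titer": [2.5, 0.8, 3.1, 0.0, 0.0, 0.0],
            }
        ),
        covariates=["age"],
        biomarkers=["titer"],
    )


def make_trial(seed, **overrides):
    """Mediated-protection trial under the package's default study conditions."""
    params = dict(
        n_vaccine=300,
        n_control=300,
        mu_vaccine=1.0,
        mu_control=0.0,
        sd_vaccine=1.0,
        sd_control=1.0,
        beta_t=float(np.log(0.5)),
        baseline_rate=1e-4,
        horizon=1095.0,
        seed=seed,
    )
    params.update(overrides)
    cfg = TrialConfig(**params)
    return cfg, simulate_trial(cfg)


@pytest.fixture(scope="session")
def medium_trial():
    cfg, table = make_trial(seed=7, n_vaccine=500, n_control=500)
    return cfg, table
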
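import numpy as np
import pandas as pd
import pytest

from uremia_omics import SynthConfig, generate_cohort, generate_reference_library
from uremia_omics.containers import FeatureTable


def make_table(intensities: dict, roles: dict, meta: dict | None = None,
               subjects: dict | None = None) -> FeatureTable:
    """Assemble a small FeatureTable from plain dicts.

    ``intensities`` maps sample -> list of per-feature values;
    ``meta`` optionally overrides per-feature metadata columns.
    """
    X = pd.DataFrame(intensities)
    n = len(X)
    ids = [f"f{i + 1}" for i in range(n)]
    X.index = ids
    defaults = {
        "mz": np.linspace(100.0, 500.0, n),
        "rt_min": np.linspace(1.0, 30.0, n),
        "mode": ["positive"] * n,
        "peak_width_scans": [10] * n,
        "snr": [20.0] * n,
    }
    defaults.update(meta or {})
    features = pd.DataFrame(defaults, index=ids)
    return FeatureTable(
        features=features,
        intensities=X,
        roles=pd.Series(roles),
        subjects=None if subjects is None else pd.Series(subjects),
    )


@pytest.fixture(scope="session")
def library():
    return generate_reference_library()


@pytest.fixture(scope="session")
def noiseless_cohort():
    cfg = SynthConfig(n_features=200, noise_sigma=0.0, seed=3)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    cfg = SynthConfig(n_features=500, noise_sigma=0.25, seed=11)
    return generate_cohort(cfg)
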
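import numpy as np
import pandas as pd
import pytest

from edrisk import simulate


def make_records(codes, admitted, **overrides):
    """Minimal presentation frame with valid covariates for the given codes."""
    n = len(codes)
    base = {
        "id": [f"T{i:05d}" for i in range(n)],
        "icd10": list(codes),
        "admitted": list(admitted),
        "age": [50.0] * n,
        "sex": ["female"] * n,
        "ethnicity": ["Chinese"] * n,
        "sbp": [120] * n,
        "pulse": [75] * n,
        "temp": [36.8] * n,
        "cci": [0] * n,
        "prior_ed": [0] * n, "prior_inpt": [0] * n, "prior_surg": [0] * n,
        "prior_icu": [0] * n, "prior_hd": [0] * n, "prior_ica": [0] * n,
        "prior_infect": [0] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)[simulate.REGISTRY_COLUMNS]


@pytest.fixture(scope="session")
def small_registry():
    """A modest simulated registry shared by read-only tests."""
    cfg = simulate.SimulationConfig(n_presentations=20_000, seed=11)
    universe = simulate.generate_code_universe(cfg)
    return universe, simulate.generate_presentations(universe, cfg)
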
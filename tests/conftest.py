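import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def make_panels(n: int = 12, seed: int = 5, cohort: str = "healthy") -> pd.DataFrame:
    """Small hand-rolled valid cohort frame (not the simulator), so panel
    tests do not depend on the generative model."""
    rng = np.random.default_rng(seed)
    hdl = rng.uniform(35, 85, n)
    non_hdl = rng.uniform(90, 210, n)
    ldl = non_hdl * rng.uniform(0.6, 0.95, n)
    sdldl = ldl * rng.uniform(0.08, 0.6, n)
    return pd.DataFrame({
        "subject_id": [f"s{i:03d}" for i in range(n)],
        "cohort": cohort,
        "age": rng.integers(25, 75, n),
        "sex": rng.choice(["M", "F"], n),
        "diabetes": False,
        "total_c": non_hdl + hdl,
        "hdl_c": hdl,
        "tg": rng.uniform(40, 400, n),
        "ldl_c": ldl,
        "sdldl_c": sdldl,
        "apob": ldl / rng.uniform(1.0, 1.5, n),
        "ldl_size": rng.uniform(24.5, 27.5, n),
        "hba1c_jds": np.nan,
    })


@pytest.fixture(scope="session")
def panels_small() -> pd.DataFrame:
    return make_panels(n=40, seed=5)


@pytest.fixture(scope="session")
def healthy_sim() -> pd.DataFrame:
    """Moderate simulated healthy cohort shared across tests."""
    from ldlwindow import cohort_preset, generate_cohort
    return generate_cohort(cohort_preset("healthy"), n=5000, seed=11)


@pytest.fixture(scope="session")
def healthy_sim_derived(healthy_sim) -> pd.DataFrame:
    from ldlwindow import derive_panels
    return derive_panels(healthy_sim)
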
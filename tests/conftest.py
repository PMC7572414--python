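import numpy as np
import pandas as pd
import pytest

from pelagidiet.synthetic import StudyConfig, generate_study


@pytest.fixture(scope="session")
def study():
    """Default synthetic study shared across tests (read-only)."""
    return generate_study(StudyConfig(seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture()
def toy_gut():
    """Two sites, four fish, three prey taxa with distinct unit weights."""
    counts = pd.DataFrame(
        [[3, 1, 0], [0, 0, 0], [2, 2, 4], [0, 1, 0]],
        index=["f1", "f2", "f3", "f4"],
        columns=["copepod_sp", "krill_sp", "mollusc_sp"],
    )
    fish = pd.DataFrame({
        "fish_id": ["f1", "f2", "f3", "f4"],
        "species": ["anchovy"] * 4,
        "area": ["GSA07"] * 4,
        "site_id": ["s1", "s1", "s2", "s2"],
    })
    groups = {"copepod_sp": "Calanoids", "krill_sp": "Euphausiacea",
              "mollusc_sp": "Mollusca"}
    weights = {"copepod_sp": 0.005, "krill_sp": 5.0, "mollusc_sp": 0.1}
    return counts, fish, groups, weights
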
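import numpy as np
import pandas as pd
import pytest

from exoantigen.config import SimulationConfig, Thresholds
from exoantigen.synthetic import simulate_proteomics


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale study used by most structural tests."""
    return SimulationConfig(
        n_proteins=300, n_planted_antigens=10, n_case_pools=4, n_control_pools=4,
        n_tracked_particles=400, serology_set_sizes=((6, 6, 4), (5, 5, 0)),
        serology_set_locations=(1000.0, 3000.0), serology_set_scales=(200.0, 600.0),
        n_serology_background=10, seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_proteomics(small_config)


@pytest.fixture(scope="session")
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture()
def compartment_meta():
    """Minimal two-line, five-compartment sample sheet."""
    rows = []
    for line in ("line1", "line2"):
        for comp in ("TCE", "cell_surface", "TEE", "exo_surface", "exo_cargo"):
            rows.append({"sample_id": f"{line}|{comp}", "cell_line": line,
                         "compartment": comp, "group": "cell_line"})
    return pd.DataFrame(rows).set_index("sample_id")
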
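import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from emulgel_rheo import PhasePair, SuspensionSeries, load_table_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return load_table_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return load_table_fixture("table2")


@pytest.fixture(scope="session")
def table3():
    return load_table_fixture("table3")


@pytest.fixture(scope="session")
def table4():
    return load_table_fixture("table4")


@pytest.fixture(scope="session")
def table5():
    return load_table_fixture("table5")


@pytest.fixture(scope="session")
def table6():
    return load_table_fixture("table6")


@pytest.fixture(scope="session")
def suspension_series(table1) -> SuspensionSeries:
    """The measured fiber-suspension series (modulus G*, phase angle)."""
    return SuspensionSeries(
        fiber_fraction=table1["fiber_fraction"].to_numpy(),
        modulus=table1["g_star_pa"].to_numpy(),
        phase_angle=table1["delta_deg"].to_numpy(),
    )


@pytest.fixture(scope="session")
def reference_pair() -> PhasePair:
    """Phase pair of the 3%-fiber emulgel: G_c = 3000 Pa, G_d = 11.1 Pa,
    gamma = 1.40 mN/m, R = 3.0 um."""
    return PhasePair.from_io_units(g_c=3000.0, g_d=11.1, gamma_mn_per_m=1.40,
                                   radius_um=3.0)


@pytest.fixture(scope="session")
def oil_series(table3):
    """(phi, G_r) points of the oil-fraction series, G_c = 3000 Pa."""
    oil = table3[table3["series"] == "oil"]
    phi = oil["oil_volume_fraction"].to_numpy()
    g_r = oil["g_star_pa"].to_numpy() / 3000.0
    return phi, g_r
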
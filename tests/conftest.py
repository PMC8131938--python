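import pytest

from proteanflight.io_formats import Morphology
from proteanflight.synthetic import SimConfig, simulate_campaign


@pytest.fixture(scope="session")
def pigeon():
    """Pigeon-like morphology used across the power-curve tests."""
    return Morphology("p1", mass=0.455, wingspan=0.66, wing_area=0.035)


@pytest.fixture(scope="session")
def campaign():
    """One default synthetic campaign, shared by read-only tests."""
    return simulate_campaign(SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_campaign():
    """A reduced campaign (2 birds x 2 days) for fast file-based tests."""
    return simulate_campaign(SimConfig(seed=7, n_birds=2, flights_per_bird=2,
                                       duration_s=120))


@pytest.fixture()
def gps_csv(tmp_path):
    def make(rows, header="time,lat,lon", name="gps.csv"):
        path = tmp_path / name
        path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
        return path
    return make
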
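import sys
from datetime import datetime, timezone
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make tests/_oracles importable

from dancemap import HiveSite
from dancemap.simulate import SimConfig, simulate_session

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def site() -> HiveSite:
    """Mid-western France study site, 60 fps video, CEST wall clock."""
    return HiveSite(lat_deg=46.15, lon_deg=-0.64, fps=60.0, utc_offset_h=2.0)


@pytest.fixture(scope="session")
def noon_utc() -> datetime:
    return datetime(2022, 6, 21, 12, 0, tzinfo=timezone.utc)


@pytest.fixture(scope="session")
def small_session():
    """A small simulated feeder session (12 dances) with its ground truth."""
    config = SimConfig(n_dances=12, seed=7)
    phases, truth = simulate_session(config)
    return config, phases, truth


@pytest.fixture(scope="session")
def default_session():
    """A full-size simulated session matching the default study conditions."""
    config = SimConfig(seed=3)
    phases, truth = simulate_session(config)
    return config, phases, truth
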
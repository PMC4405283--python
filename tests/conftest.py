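from datetime import datetime

import pytest
from hypothesis import HealthCheck, settings

from triadrem.logger_io import DYADS, ContactInterval, TriadManifest
from triadrem.sample_data import SAMPLE_LOGGER_TEXT, sample_manifest

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def sample_text() -> str:
    return SAMPLE_LOGGER_TEXT


@pytest.fixture
def manifest() -> TriadManifest:
    return sample_manifest()


@pytest.fixture
def plain_manifest() -> TriadManifest:
    """A manifest with time zero at midnight, for arithmetic-friendly tests."""
    return TriadManifest(
        triad_id="t0",
        id_map={"a": 1, "b": 2, "c": 3},
        introduction=datetime(2009, 3, 9, 0, 0, 0),
    )


def make_intervals(layout: dict) -> dict:
    """{(1,2): [(onset, offset), ...]} -> per-dyad ContactInterval dict."""
    return {
        d: [ContactInterval(d, s, e) for s, e in layout.get(d, [])] for d in DYADS
    }


@pytest.fixture
def intervals_factory():
    return make_intervals
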
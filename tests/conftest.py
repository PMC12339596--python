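"""Shared simulated-fleet fixtures.

Fleets are generated once per session; tests that mutate frames must copy.
"""

from __future__ import annotations

import pandas as pd
import pytest

from pmfleet.simulate import (
    DriftRegime,
    FaultSpec,
    FleetSimConfig,
    harmonized_fleet,
    simulate_fleet,
)


@pytest.fixture(scope="session")
def clean_fleet():
    """Six healthy monitors, three co-location days, mixed drift regimes."""
    cfg = FleetSimConfig(
        n_monitors=6,
        n_days=3,
        seed=11,
        drift=DriftRegime(kind="fixed_loss", loss_s=10),
    )
    return simulate_fleet(cfg)


@pytest.fixture(scope="session")
def clean_frames(clean_fleet):
    return {mid: s.data for mid, s in harmonized_fleet(clean_fleet).items()}


@pytest.fixture(scope="session")
def faulty_fleet():
    """Eight monitors with one degraded, one dead-channel and one offset unit."""
    cfg = FleetSimConfig(
        n_monitors=8,
        n_days=3,
        seed=0,
        faults={
            5: FaultSpec.degraded(),
            6: FaultSpec(dead_channel="a"),
            7: FaultSpec(offset=6.0),
        },
    )
    return simulate_fleet(cfg)


@pytest.fixture(scope="session")
def faulty_frames(faulty_fleet):
    return {mid: s.data for mid, s in harmonized_fleet(faulty_fleet).items()}


@pytest.fixture(scope="session")
def recovery_fleet():
    """Twenty healthy monitors over two weeks of 10-min data (gain recovery)."""
    return simulate_fleet(FleetSimConfig(n_monitors=20, n_days=14, seed=7))


@pytest.fixture(scope="session")
def recovery_frames(recovery_fleet):
    return {mid: s.data for mid, s in harmonized_fleet(recovery_fleet).items()}


@pytest.fixture
def day_start():
    return pd.Timestamp("2023-11-13", tz="UTC")
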
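"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from flywaynet.geometry import GeoPoint
from flywaynet.trackio import StationaryEstimate, Thresholds, Track

T0 = datetime(2016, 6, 1, tzinfo=timezone.utc)


def est(lat, lon, start_day, end_day, t0=T0) -> StationaryEstimate:
    """Stationary estimate at (lat, lon) spanning [start_day, end_day]
    in days relative to a reference origin."""
    return StationaryEstimate(
        location=GeoPoint(lat, lon),
        arrival=t0 + timedelta(days=start_day),
        departure=t0 + timedelta(days=end_day),
    )


def track(estimates, breeding=(71.2652, -156.6359), bird_id="b1",
          subspecies="arcticola", complete=True) -> Track:
    return Track(
        bird_id=bird_id,
        subspecies=subspecies,
        breeding_site=GeoPoint(*breeding),
        tracking_year=2016,
        estimates=tuple(estimates),
        complete=complete,
    )


@pytest.fixture
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture
def clean_population():
    """A small corruption-free population: emitted tracks equal the truth."""
    from flywaynet.synthetic import Corruption, make_paper_like_config, simulate_population

    config = make_paper_like_config(
        n_birds={"arcticola": 6, "sakhalina": 6, "kistchinski": 3, "actites": 1},
        corruption=Corruption(
            positional_noise_sd_km=0.0, spurious_stop_rate=0.0, reversal_rate=0.0,
            polar_suppression=False, partial_truncation_prob=0.0,
            prebreeding_stop_prob=0.0,
        ),
        seed=11,
    )
    return simulate_population(config)


@pytest.fixture
def noisy_population():
    """A moderately corrupted population exercising every refinement rule."""
    from flywaynet.synthetic import Corruption, make_paper_like_config, simulate_population

    config = make_paper_like_config(
        n_birds={"arcticola": 12, "sakhalina": 10, "kistchinski": 4, "actites": 1},
        corruption=Corruption(positional_noise_sd_km=150.0),
        seed=23,
    )
    return simulate_population(config)
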
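"""Annual-cycle segmentation and per-period migration parameters."""

from datetime import datetime, timedelta, timezone

import pytest

from flywaynet.geometry import GeoPoint, great_circle_km
from flywaynet.phenology import (
    back_calculate_initiation,
    find_winter_arrival,
    find_winter_end,
    forward_calculate_arrival,
    ordinal_day,
    parameters_table,
    period_parameters,
    segment,
    summarize_parameters,
    within_individual_ratios,
    UnsegmentableTrackError,
)
from flywaynet.refinement import RefinedTrack, refine_track
from flywaynet.trackio import Thresholds

from conftest import T0, est, track


def _refined(estimates, **kwargs):
    t = track(estimates, **kwargs)
    return RefinedTrack(track=t, provenance=())


def test_ordinal_day_leap_normalization():
    assert ordinal_day(datetime(2015, 3, 1, tzinfo=timezone.utc)) == 60
    # leap year: Feb 29 shares Feb 28's index, later days shift down one
    assert ordinal_day(datetime(2016, 2, 28, tzinfo=timezone.utc)) == 59
    assert ordinal_day(datetime(2016, 2, 29, tzinfo=timezone.utc)) == 59
    assert ordinal_day(datetime(2016, 3, 1, tzinfo=timezone.utc)) == 60
    assert ordinal_day(datetime(2016, 12, 31, tzinfo=timezone.utc)) == 365


@pytest.mark.parametrize(
    "dist_km, hours",
    [(580.0, 10.0), (1392.0, 24.0)],  # at the 58 km/h assumed travel rate
)
def test_back_calculation_offsets(dist_km, hours, thresholds):
    b = GeoPoint(0, 0)
    first = est(0, dist_km / 111.19492664455873, 10, 20)
    d = great_circle_km(first.location, b)
    assert d == pytest.approx(dist_km, rel=1e-6)
    init, calculated = back_calculate_initiation(first, b, thresholds)
    assert calculated
    assert (first.arrival - init).total_seconds() / 3600 == pytest.approx(
        hours, rel=1e-6
    )


def test_back_calculation_inside_buffer(thresholds):
    b = GeoPoint(0, 0)
    first = est(0, 200 / 111.195, 10, 20)
    init, calculated = back_calculate_initiation(first, b, thresholds)
    assert not calculated
    assert init == first.departure


def test_forward_calculation_mirrors_back(thresholds):
    b = GeoPoint(0, 0)
    last = est(0, 580 / 111.19492664455873, 100, 120)
    arr, calculated = forward_calculate_arrival(last, b, thresholds)
    assert calculated
    assert (arr - last.departure).total_seconds() / 3600 == pytest.approx(10.0, rel=1e-4)
    near = est(0, 100 / 111.195, 100, 120)
    arr, calculated = forward_calculate_arrival(near, b, thresholds)
    assert not calculated and arr == near.arrival


def test_find_winter_arrival_rules(thresholds):
    assert find_winter_arrival([est(44, 120, 0, 50)], thresholds) == 0
    # a 41-day stop south of the line does not qualify; the next one does
    assert (
        find_winter_arrival([est(44, 120, 0, 41), est(40, 118, 42, 102)], thresholds)
        == 1
    )
    with pytest.raises(UnsegmentableTrackError):
        find_winter_arrival([est(46, 120, 0, 100)], thresholds)


def test_find_winter_end_rules(thresholds):
    single = [est(40, 120, 0, 150), est(50, 125, 152, 156)]
    assert find_winter_end(single, 0, thresholds) == 0
    # a 10-day stop sandwiched between two long southern stops stays winter
    sandwich = [est(40, 120, 0, 60), est(38, 118, 62, 72), est(36, 117, 74, 134)]
    assert find_winter_end(sandwich, 0, thresholds) == 2
    # a trailing short southern stop before heading north opens north migration
    trailing = [est(40, 120, 0, 100), est(38, 122, 102, 122), est(50, 130, 124, 128)]
    assert find_winter_end(trailing, 0, thresholds) == 0


def test_segment_clean_track_recovers_truth(clean_population, thresholds):
    tracks, truths = clean_population
    for t, truth in zip(tracks, truths):
        refined = refine_track(t, thresholds)
        seg = segment(refined, thresholds)
        assert seg.missing_periods == ()
        # an uncorrupted track segments exactly at the true boundaries
        assert seg.winter_arrival == truth.winter_arrival
        assert seg.winter_end == truth.winter_end
        assert abs(
            (seg.south_initiation - truth.south_initiation).total_seconds()
        ) < 86400 * 0.5
        # uncorrupted tracks refine unchanged, so labels align by index;
        # trailing stops inside the breeding buffer are left unlabeled
        assert len(seg.labels) == len(truth.labels)
        for got, expected in zip(seg.labels, truth.labels):
            if got is not None:
                assert got == expected


def test_segment_partial_track(thresholds):
    # tag died after winter arrival: south + winter segmented, north missing
    stops = [est(60, 150, 0, 5), est(40, 120, 10, 60)]
    seg = segment(_refined(stops, complete=False), thresholds)
    assert seg.winter_arrival == stops[1].arrival
    assert "north" in seg.missing_periods
    assert seg.breeding_arrival is None


def test_segment_unsegmentable_track(thresholds):
    stops = [est(60, 150, 0, 5), est(50, 140, 10, 15)]
    seg = segment(_refined(stops, complete=False), thresholds)
    assert set(seg.missing_periods) >= {"winter", "north"}
    assert all(lab == "south" for lab in seg.labels)


def test_labels_partition_complete_track(noisy_population, thresholds):
    tracks, _ = noisy_population
    for t in tracks:
        if not t.complete:
            continue
        refined = refine_track(t, thresholds)
        seg = segment(refined, thresholds)
        if seg.missing_periods:
            continue
        n = len(refined.track.estimates)
        assert len(seg.labels) == n
        labeled = [lab for lab in seg.labels if lab is not None]
        # contiguous blocks in south -> winter -> north order
        order = {"south": 0, "winter": 1, "north": 2}
        ranks = [order[lab] for lab in labeled]
        assert ranks == sorted(ranks)
        assert "winter" in labeled


def test_winter_min_days_monotonicity(noisy_population):
    """Raising the minimum winter duration can only move the detected
    winter arrival later (or make it undefined)."""
    tracks, _ = noisy_population
    for t in tracks:
        refined = refine_track(t)
        base = segment(refined, Thresholds())
        stricter = segment(refined, Thresholds(winter_min_days=60))
        if base.winter_arrival is None:
            continue
        if stricter.winter_arrival is not None:
            assert stricter.winter_arrival >= base.winter_arrival


def test_period_parameters_single_stop_winter(thresholds):
    b = GeoPoint(71.2652, -156.6359)
    stops = [est(60, -165, 0, 5), est(40, 120, 15, 200), est(60, 150, 205, 208)]
    refined = _refined(stops)
    seg = segment(refined, thresholds)
    params = {p.period: p for p in period_parameters(seg, refined, b, thresholds)}
    assert params["winter"].distance_km == 0.0
    assert params["winter"].speed_km_per_day == 0.0
    assert params["winter"].n_stationary == 1


def test_period_distance_additivity(thresholds):
    b = GeoPoint(0, 0)
    deg1000 = 1000 / 111.19492664455873
    deg1500 = 2500 / 111.19492664455873
    stops = [est(0, deg1000, 5, 10), est(0, deg1500, 12, 20), est(0, 40, 25, 100)]
    refined = _refined(stops, breeding=(0, 0))
    seg = segment(refined, thresholds)
    south = next(p for p in period_parameters(seg, refined, b, thresholds)
                 if p.period == "south")
    legs = (
        great_circle_km(b, stops[0].location)
        + great_circle_km(stops[0].location, stops[1].location)
        + great_circle_km(stops[1].location, stops[2].location)
    )
    assert south.distance_km == pytest.approx(legs, rel=1e-9)


def test_direct_flight_zero_stationary(thresholds):
    # breeding -> winter without stopping: 0 south stops, single-leg distance
    b = GeoPoint(52.5, 143.2833)
    stops = [est(35, 126.5, 10, 60), est(23, 116.5, 65, 220), est(50, 141, 225, 230)]
    refined = _refined(stops, breeding=(52.5, 143.2833), subspecies="actites")
    seg = segment(refined, thresholds)
    south = next(p for p in period_parameters(seg, refined, b, thresholds)
                 if p.period == "south")
    assert south.n_stationary == 0
    assert south.distance_km == pytest.approx(
        great_circle_km(b, stops[0].location), rel=1e-9
    )


def test_period_distance_bounds_endpoints(clean_population, thresholds):
    """Minimum migration distance is at least the great-circle distance
    between the period's endpoints (triangle inequality)."""
    tracks, _ = clean_population
    for t in tracks:
        refined = refine_track(t, thresholds)
        seg = segment(refined, thresholds)
        if seg.missing_periods or seg.winter_start_index is None:
            continue
        ests = refined.track.estimates
        south = next(
            (p for p in period_parameters(seg, refined, t.breeding_site, thresholds)
             if p.period == "south"), None)
        if south is None:
            continue
        direct = great_circle_km(
            t.breeding_site, ests[seg.winter_start_index].location
        )
        assert south.distance_km >= direct - 1e-6


def test_within_individual_ratios():
    from flywaynet.phenology import PeriodParameters

    def pp(period, speed, n, durations):
        return PeriodParameters(
            period=period, initiation_date=None, arrival_date=None,
            duration_days=10, distance_km=1000, n_stationary=n,
            stationary_durations=durations, speed_km_per_day=speed,
        )

    r = within_individual_ratios(pp("south", 100, 4, (4, 8)), pp("north", 400, 2, (3,)))
    assert r["speed"] == pytest.approx(4.0)
    assert r["n_stationary"] == pytest.approx(0.5)
    assert r["stop_duration"] == pytest.approx(0.5)
    r0 = within_individual_ratios(pp("south", 0, 0, ()), pp("north", 400, 2, (3,)))
    assert r0["speed"] is None and r0["n_stationary"] is None


def test_parameters_and_summary_tables(noisy_population, thresholds):
    tracks, _ = noisy_population
    refined = [refine_track(t, thresholds) for t in tracks]
    segs = [segment(r, thresholds) for r in refined]
    table = parameters_table(refined, segs, thresholds)
    assert {"south", "winter", "north"} >= set(table["period"])
    assert (table.groupby(["bird_id", "period"]).size() == 1).all()
    summary = summarize_parameters(table)
    assert "n" in summary.columns
    south = summary[summary["period"] == "south"]
    assert (south["duration_days_q25"] <= south["duration_days_median"]).all()
    assert (south["duration_days_median"] <= south["duration_days_q75"]).all()
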
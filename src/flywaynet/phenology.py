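"""Annual-cycle segmentation and per-period migration parameters.

A refined track is divided into south migration, winter, and north
migration (the breeding period lies outside the stop sequence). Boundary
rules, all user-overridable through :class:`~flywaynet.trackio.Thresholds`:

* South migration begins at departure toward the first stop that is south
  of 66.7 N and > 250 km from the breeding site. If that first stop is
  itself > 250 km away, the initiation instant is back-calculated from its
  arrival using an assumed travel rate of 58 km/h over the great-circle
  distance from the breeding site.
* Winter begins at arrival at the first stop south of 45.5 N lasting
  >= 42 days, and ends at the departure from the *last* such stop —
  short stops sandwiched between long southern stops belong to winter,
  while a short southern stop followed only by northern stops opens north
  migration.
* North migration ends at arrival at the first stop < 250 km from the
  breeding site, or is forward-calculated at 58 km/h from the final stop's
  departure when the bird breeds beyond geolocator coverage.

Minimum migration distance per period is the sum of great-circle legs
between consecutive stops of the period, including the breeding-site legs
at either end of the annual cycle and the legs into/out of the wintering
grounds, so that totals describe the full journey between breeding and
wintering grounds. Speed is distance over period duration in days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .geometry import GeoPoint, great_circle_km
from .refinement import RefinedTrack
from .trackio import StationaryEstimate, Thresholds

__all__ = [
    "PERIODS",
    "ordinal_day",
    "Segmentation",
    "PeriodParameters",
    "back_calculate_initiation",
    "forward_calculate_arrival",
    "find_winter_arrival",
    "find_winter_end",
    "segment",
    "period_parameters",
    "within_individual_ratios",
    "parameters_table",
    "summarize_parameters",
]

PERIODS = ("south", "winter", "north")


def ordinal_day(ts: datetime) -> int:
    """Year-independent day index 1..365 with leap normalization: Feb 29
    maps to the index of Feb 28 and all later days shift down by one."""
    doy = ts.timetuple().tm_yday
    year = ts.year
    leap = year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)
    if leap and doy >= 60:
        doy -= 1
    return doy


class UnsegmentableTrackError(ValueError):
    """Raised when a track has no qualifying winter stop."""


@dataclass(frozen=True)
class Segmentation:
    """Period labels per estimate plus the four annual-cycle boundary times.

    ``labels[i]`` is 'south' / 'winter' / 'north', or None for trailing
    stops within the breeding-site buffer after return. Undefined
    boundaries (partial tracks) are None.
    """

    labels: tuple[str | None, ...]
    south_initiation: datetime | None
    back_calculated: bool
    winter_arrival: datetime | None
    winter_end: datetime | None
    breeding_arrival: datetime | None
    forward_calculated: bool
    winter_start_index: int | None = None
    winter_end_index: int | None = None
    missing_periods: tuple[str, ...] = ()


@dataclass(frozen=True)
class PeriodParameters:
    period: str
    initiation_date: datetime | None
    arrival_date: datetime | None
    duration_days: float | None
    distance_km: float
    n_stationary: int
    stationary_durations: tuple[float, ...]
    speed_km_per_day: float | None


def back_calculate_initiation(
    first_estimate: StationaryEstimate,
    breeding_site: GeoPoint,
    thresholds: Thresholds = Thresholds(),
) -> tuple[datetime, bool]:
    """South-migration initiation from the first stop's arrival.

    When the first stop is farther than the breeding buffer, the departure
    instant is back-calculated as arrival minus distance / travel rate;
    otherwise the stop's own departure is used (no calculation, flag False).
    """
    dist = great_circle_km(first_estimate.location, breeding_site)
    if dist > thresholds.breed_buffer_km:
        hours = dist / thresholds.travel_kmh
        return first_estimate.arrival - timedelta(hours=hours), True
    return first_estimate.departure, False


def forward_calculate_arrival(
    last_estimate: StationaryEstimate,
    breeding_site: GeoPoint,
    thresholds: Thresholds = Thresholds(),
) -> tuple[datetime, bool]:
    """Breeding-ground arrival, mirroring :func:`back_calculate_initiation`
    on the final stop's departure (travel time is added)."""
    dist = great_circle_km(last_estimate.location, breeding_site)
    if dist > thresholds.breed_buffer_km:
        hours = dist / thresholds.travel_kmh
        return last_estimate.departure + timedelta(hours=hours), True
    return last_estimate.arrival, False


def find_winter_arrival(
    estimates: tuple[StationaryEstimate, ...] | list[StationaryEstimate],
    thresholds: Thresholds = Thresholds(),
) -> int:
    """Index of the first stop south of winter_lat_deg with duration
    >= winter_min_days. Raises UnsegmentableTrackError if none exists."""
    for i, est in enumerate(estimates):
        if (
            est.location.lat_deg < thresholds.winter_lat_deg
            and est.duration_days >= thresholds.winter_min_days
        ):
            return i
    raise UnsegmentableTrackError("no stop qualifies as a winter arrival")


def find_winter_end(
    estimates,
    winter_start_index: int,
    thresholds: Thresholds = Thresholds(),
) -> int:
    """Index of the stop whose departure ends the winter period: the last
    stop at/after ``winter_start_index`` that is south of winter_lat_deg
    with duration >= winter_min_days. All later stops are north of the
    winter latitude or too short, so they belong to north migration."""
    last = winter_start_index
    for i in range(winter_start_index, len(estimates)):
        est = estimates[i]
        if (
            est.location.lat_deg < thresholds.winter_lat_deg
            and est.duration_days >= thresholds.winter_min_days
        ):
            last = i
    return last


def segment(
    refined: RefinedTrack, thresholds: Thresholds = Thresholds()
) -> Segmentation:
    """Label each refined stop with its annual-cycle period and locate the
    four boundary instants. Partial tracks yield a partial segmentation
    with explicit missing-period markers rather than an error."""
    track = refined.track
    ests = track.estimates
    if not ests:
        return Segmentation(
            labels=(),
            south_initiation=None, back_calculated=False,
            winter_arrival=None, winter_end=None,
            breeding_arrival=None, forward_calculated=False,
            missing_periods=PERIODS,
        )

    south_init, back_calc = back_calculate_initiation(
        ests[0], track.breeding_site, thresholds
    )

    try:
        w_start = find_winter_arrival(ests, thresholds)
    except UnsegmentableTrackError:
        labels = tuple("south" for _ in ests)
        return Segmentation(
            labels=labels,
            south_initiation=south_init, back_calculated=back_calc,
            winter_arrival=None, winter_end=None,
            breeding_arrival=None, forward_calculated=False,
            missing_periods=("winter", "north"),
        )
    w_end = find_winter_end(ests, w_start, thresholds)

    labels: list[str | None] = []
    breeding_arrival: datetime | None = None
    forward_calc = False
    for i, est in enumerate(ests):
        if i < w_start:
            labels.append("south")
        elif i <= w_end:
            labels.append("winter")
        elif breeding_arrival is None and great_circle_km(
            est.location, track.breeding_site
        ) < thresholds.breed_buffer_km:
            # north migration ends at arrival near the breeding site; this
            # and later stops are breeding-period stops, left unlabeled
            breeding_arrival = est.arrival
            labels.append(None)
        elif breeding_arrival is None:
            labels.append("north")
        else:
            labels.append(None)

    missing: list[str] = []
    if track.complete:
        if breeding_arrival is None:
            breeding_arrival, forward_calc = forward_calculate_arrival(
                ests[-1], track.breeding_site, thresholds
            )
    elif breeding_arrival is None:
        missing.append("north")

    return Segmentation(
        labels=tuple(labels),
        south_initiation=south_init, back_calculated=back_calc,
        winter_arrival=ests[w_start].arrival,
        winter_end=ests[w_end].departure,
        breeding_arrival=breeding_arrival, forward_calculated=forward_calc,
        winter_start_index=w_start, winter_end_index=w_end,
        missing_periods=tuple(missing),
    )


def _days(a: datetime, b: datetime) -> float:
    return (b - a).total_seconds() / 86400.0


def period_parameters(
    segmentation: Segmentation,
    refined: RefinedTrack,
    breeding_site: GeoPoint,
    thresholds: Thresholds = Thresholds(),
    include_breeding_legs: bool = True,
) -> list[PeriodParameters]:
    """Per-period migration statistics for one bird.

    South distance includes the breeding-site -> first-stop leg and the
    last-south-stop -> winter-arrival leg; north distance mirrors this
    (winter-terminus -> first north stop, final stop -> breeding site).
    ``include_breeding_legs=False`` restricts sums to within-period legs.
    A direct breeding -> winter flight yields n_stationary = 0 with the
    single-leg distance.
    """
    ests = refined.track.estimates
    seg = segmentation
    out: list[PeriodParameters] = []

    idx = {p: [i for i, lab in enumerate(seg.labels) if lab == p] for p in PERIODS}

    def leg_sum(points: list[GeoPoint]) -> float:
        return sum(
            great_circle_km(points[i], points[i + 1]) for i in range(len(points) - 1)
        )

    # --- south migration
    if "winter" not in seg.missing_periods and seg.winter_start_index is not None:
        south_pts = [ests[i].location for i in idx["south"]]
        pts = list(south_pts)
        if include_breeding_legs:
            pts = [breeding_site] + pts + [ests[seg.winter_start_index].location]
        elif idx["south"]:
            pts = pts + [ests[seg.winter_start_index].location]
        dist = leg_sum(pts)
        dur = (
            _days(seg.south_initiation, seg.winter_arrival)
            if seg.south_initiation and seg.winter_arrival
            else None
        )
        durations = tuple(ests[i].duration_days for i in idx["south"])
        out.append(
            PeriodParameters(
                period="south",
                initiation_date=seg.south_initiation,
                arrival_date=seg.winter_arrival,
                duration_days=dur,
                distance_km=dist,
                n_stationary=len(idx["south"]),
                stationary_durations=durations,
                speed_km_per_day=(dist / dur if dur and dur > 0 else None),
            )
        )

    # --- winter
    if seg.winter_start_index is not None and seg.winter_end_index is not None:
        w_idx = idx["winter"]
        pts = [ests[i].location for i in w_idx]
        dist = leg_sum(pts)
        dur = (
            _days(seg.winter_arrival, seg.winter_end)
            if seg.winter_arrival and seg.winter_end
            else None
        )
        durations = tuple(ests[i].duration_days for i in w_idx)
        out.append(
            PeriodParameters(
                period="winter",
                initiation_date=seg.winter_arrival,
                arrival_date=seg.winter_end,
                duration_days=dur,
                distance_km=dist,
                n_stationary=len(w_idx),
                stationary_durations=durations,
                speed_km_per_day=(
                    (dist / dur) if dur and dur > 0 else (0.0 if dist == 0 else None)
                ),
            )
        )

    # --- north migration
    if "north" not in seg.missing_periods and seg.winter_end_index is not None:
        n_idx = idx["north"]
        pts = [ests[i].location for i in n_idx]
        if include_breeding_legs:
            pts = [ests[seg.winter_end_index].location] + pts + [breeding_site]
        elif n_idx:
            pts = [ests[seg.winter_end_index].location] + pts
        dist = leg_sum(pts)
        dur = (
            _days(seg.winter_end, seg.breeding_arrival)
            if seg.winter_end and seg.breeding_arrival
            else None
        )
        durations = tuple(ests[i].duration_days for i in n_idx)
        out.append(
            PeriodParameters(
                period="north",
                initiation_date=seg.winter_end,
                arrival_date=seg.breeding_arrival,
                duration_days=dur,
                distance_km=dist,
                n_stationary=len(n_idx),
                stationary_durations=durations,
                speed_km_per_day=(dist / dur if dur and dur > 0 else None),
            )
        )
    return out


def within_individual_ratios(
    params_south: PeriodParameters, params_north: PeriodParameters
) -> dict[str, float | None]:
    """North/south ratios per individual for speed, stop count, and median
    stop duration; None where the southern value is zero/undefined."""

    def ratio(n, s):
        if n is None or s is None or s == 0:
            return None
        return n / s

    med_s = (
        float(np.median(params_south.stationary_durations))
        if params_south.stationary_durations
        else None
    )
    med_n = (
        float(np.median(params_north.stationary_durations))
        if params_north.stationary_durations
        else None
    )
    return {
        "speed": ratio(params_north.speed_km_per_day, params_south.speed_km_per_day),
        "n_stationary": ratio(params_north.n_stationary, params_south.n_stationary),
        "stop_duration": ratio(med_n, med_s),
    }


def parameters_table(
    refined_tracks: list[RefinedTrack],
    segmentations: list[Segmentation],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """One row per bird x period with all parameter fields — the tabular
    analogue of the published seasonal summary tables' input."""
    rows = []
    for refined, seg in zip(refined_tracks, segmentations):
        track = refined.track
        for p in period_parameters(seg, refined, track.breeding_site, thresholds):
            rows.append({
                "bird_id": track.bird_id,
                "subspecies": track.subspecies,
                "complete": track.complete,
                "period": p.period,
                "initiation_date": p.initiation_date,
                "arrival_date": p.arrival_date,
                "initiation_ordinal": (
                    ordinal_day(p.initiation_date) if p.initiation_date else math.nan
                ),
                "arrival_ordinal": (
                    ordinal_day(p.arrival_date) if p.arrival_date else math.nan
                ),
                "duration_days": p.duration_days if p.duration_days is not None else math.nan,
                "distance_km": p.distance_km,
                "n_stationary": p.n_stationary,
                "stationary_durations": ";".join(
                    f"{d:.3f}" for d in p.stationary_durations
                ),
                "median_stop_days": (
                    float(np.median(p.stationary_durations))
                    if p.stationary_durations
                    else math.nan
                ),
                "speed_km_per_day": (
                    p.speed_km_per_day if p.speed_km_per_day is not None else math.nan
                ),
            })
    return pd.DataFrame(rows)


def summarize_parameters(table: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR (25th/75th percentile, linear interpolation) of each
    parameter per subspecies x period, with sample sizes, mirroring the
    layout of the published seasonal summary tables."""
    records = []
    metrics = [
        "initiation_ordinal", "arrival_ordinal", "duration_days",
        "distance_km", "n_stationary", "median_stop_days", "speed_km_per_day",
    ]
    for (ssp, period), grp in table.groupby(["subspecies", "period"]):
        rec = {"subspecies": ssp, "period": period, "n": len(grp)}
        for m in metrics:
            vals = grp[m].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                rec[f"{m}_median"] = math.nan
                rec[f"{m}_q25"] = math.nan
                rec[f"{m}_q75"] = math.nan
            else:
                rec[f"{m}_median"] = float(np.median(vals))
                rec[f"{m}_q25"] = float(np.percentile(vals, 25))
                rec[f"{m}_q75"] = float(np.percentile(vals, 75))
        records.append(rec)
    return pd.DataFrame(records)
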
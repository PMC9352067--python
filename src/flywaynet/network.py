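"""Season-specific weighted migratory networks and daily occupancy.

Nodes are flyway regions; a node's weight for a subspecies is the
proportion of that subspecies' complete tracks with at least one stop of
the season in the region. Directed edges connect consecutive distinct
regions in an individual's seasonal itinerary, weighted the same way.
Repeat visits within a season count once per individual (weights measure
proportions of individuals, not of visits), and there are no self-edges.

Daily occupancy gives, for each (region, subspecies, ordinal day 1..365),
the proportion of individuals present — a bird occupies a region on every
day of an assigned stop's [arrival, departure] interval, inclusive; days
in transit count toward no region.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd

from .geometry import great_circle_km
from .phenology import Segmentation, ordinal_day
from .refinement import RefinedTrack
from .regions import FlywayRegion
from .trackio import SUBSPECIES

__all__ = [
    "MigratoryNetwork",
    "assign_regions",
    "build_season_network",
    "daily_occupancy",
    "occupancy_table",
    "summarize_region_use",
]

SEASONS = ("south", "winter", "north")


@dataclass(frozen=True)
class MigratoryNetwork:
    season: str
    node_weights: dict  # region_id -> {subspecies: proportion}
    edge_weights: dict  # (from_region, to_region) -> {subspecies: proportion}
    denominators: dict  # subspecies -> complete-track count


def assign_regions(
    refined_tracks: list[RefinedTrack], regions: list[FlywayRegion]
) -> dict[str, list[int]]:
    """Region id for every estimate of every track.

    Estimates that were cluster members keep their membership; any other
    point goes to the nearest medoid (ties to the lower region id, which
    is also the assignment the clustering itself uses).
    """
    membership = {
        ref: region.region_id for region in regions for ref in region.member_refs
    }
    out: dict[str, list[int]] = {}
    for refined in refined_tracks:
        track = refined.track
        ids = []
        for i, est in enumerate(track.estimates):
            rid = membership.get((track.bird_id, i))
            if rid is None:
                rid = min(
                    regions,
                    key=lambda r: (great_circle_km(est.location, r.medoid), r.region_id),
                ).region_id
            ids.append(rid)
        out[track.bird_id] = ids
    return out


def build_season_network(
    refined_tracks: list[RefinedTrack],
    segmentations: list[Segmentation],
    regions: list[FlywayRegion],
    season: str,
    assignments: dict[str, list[int]] | None = None,
) -> MigratoryNetwork:
    """Network of one season from complete tracks only.

    Per individual, the season's region sequence is taken in stop order
    with consecutive duplicates collapsed; each region counts once toward
    node membership and each ordered consecutive pair once toward an edge.
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    if assignments is None:
        assignments = assign_regions(refined_tracks, regions)

    node_birds: dict[int, dict[str, set]] = {}
    edge_birds: dict[tuple[int, int], dict[str, set]] = {}
    denominators = {s: 0 for s in SUBSPECIES}

    for refined, seg in zip(refined_tracks, segmentations):
        track = refined.track
        if not track.complete or refined.flagged:
            continue
        ssp = track.subspecies
        denominators[ssp] += 1
        seq = [
            assignments[track.bird_id][i]
            for i, lab in enumerate(seg.labels)
            if lab == season
        ]
        collapsed: list[int] = []
        for rid in seq:
            if not collapsed or collapsed[-1] != rid:
                collapsed.append(rid)
        for rid in set(collapsed):
            node_birds.setdefault(rid, {}).setdefault(ssp, set()).add(track.bird_id)
        seen_pairs = set()
        for a, b in zip(collapsed, collapsed[1:]):
            if (a, b) not in seen_pairs:
                seen_pairs.add((a, b))
                edge_birds.setdefault((a, b), {}).setdefault(ssp, set()).add(
                    track.bird_id
                )

    def proportions(by_ssp: dict[str, set]) -> dict[str, float]:
        return {
            s: (len(by_ssp.get(s, ())) / denominators[s]) if denominators[s] else 0.0
            for s in SUBSPECIES
        }

    return MigratoryNetwork(
        season=season,
        node_weights={rid: proportions(v) for rid, v in node_birds.items()},
        edge_weights={pair: proportions(v) for pair, v in edge_birds.items()},
        denominators=denominators,
    )


def daily_occupancy(
    refined_tracks: list[RefinedTrack],
    segmentations: list[Segmentation],
    regions: list[FlywayRegion],
    assignments: dict[str, list[int]] | None = None,
    complete_only: bool = True,
) -> dict[tuple[int, str], np.ndarray]:
    """Per-(region, subspecies) arrays of length 365: the proportion of
    individuals occupying the region on each ordinal day. Stops spanning
    the year boundary wrap across day 365 -> 1."""
    if assignments is None:
        assignments = assign_regions(refined_tracks, regions)
    counts: dict[tuple[int, str], np.ndarray] = {}
    denominators = {s: 0 for s in SUBSPECIES}

    for refined, seg in zip(refined_tracks, segmentations):
        track = refined.track
        if complete_only and (not track.complete or refined.flagged):
            continue
        denominators[track.subspecies] += 1
        # a day split between two stops (depart and arrive on the same
        # calendar day) is credited to the earlier stop only, so a bird
        # never occupies two regions at once
        taken: set[int] = set()
        for i, est in enumerate(track.estimates):
            if seg.labels[i] is None:
                continue
            rid = assignments[track.bird_id][i]
            key = (rid, track.subspecies)
            arr = counts.setdefault(key, np.zeros(365))
            # walk inclusive calendar days; ordinal_day handles leap years
            n_days = int((est.departure.date() - est.arrival.date()).days) + 1
            marked = set()
            for d in range(n_days):
                od = ordinal_day(est.arrival + timedelta(days=d))
                if od not in marked and od not in taken:
                    arr[od - 1] += 1
                    marked.add(od)
            taken |= marked

    out: dict[tuple[int, str], np.ndarray] = {}
    for (rid, ssp), arr in counts.items():
        denom = denominators[ssp]
        out[(rid, ssp)] = arr / denom if denom else arr * 0.0
    return out


def occupancy_table(occupancy: dict[tuple[int, str], np.ndarray]) -> pd.DataFrame:
    """Long-format occupancy: region_id, subspecies, day, proportion
    (zero-proportion days omitted)."""
    rows = []
    for (rid, ssp), arr in sorted(occupancy.items()):
        for day in np.nonzero(arr)[0]:
            rows.append(
                {
                    "region_id": rid,
                    "subspecies": ssp,
                    "day": int(day) + 1,
                    "proportion": float(arr[day]),
                }
            )
    return pd.DataFrame(rows, columns=["region_id", "subspecies", "day", "proportion"])


def summarize_region_use(network: MigratoryNetwork) -> dict[int, dict[str, tuple[int, int]]]:
    """Per region and subspecies, (used, not-used) individual counts ready
    for a 2x2 contingency table; counts sum to the subspecies denominator."""
    out: dict[int, dict[str, tuple[int, int]]] = {}
    for rid, props in network.node_weights.items():
        out[rid] = {}
        for ssp in SUBSPECIES:
            denom = network.denominators.get(ssp, 0)
            used = round(props.get(ssp, 0.0) * denom)
            out[rid][ssp] = (used, denom - used)
    return out
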
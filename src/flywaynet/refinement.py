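"""Rule-based refinement of geolocator migration tracks.

Light-level geolocation is coarse (positional error of hundreds of km) and
the upstream state-space model can emit erratic stops. Refinement applies
three rules, in order:

1. merge consecutive stops closer than 250 km (coordinate averaging on the
   sphere; arrival/departure combined), iterated to a fixed point, and drop
   stops preceding the bird's first move > 250 km from its breeding site;
2. drop stops preceding the bird's first move south of 66.7 N, where
   round-the-clock summer daylight makes light-level positions meaningless;
3. repeatedly remove the interior stop with the sharpest turning angle
   (< 60 degrees), absorbing its time interval into its spatially nearest
   surviving neighbor — except the protected stop: the farthest one from
   the breeding site with a stationary period of >= 42 days, taken to be
   the bird's true winter terminus where a direction reversal is real.

Every mutation is logged as a provenance event; replaying the event list
against the raw estimates reproduces the refined track exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .geometry import GeoPoint, great_circle_km, mean_location, turning_angle_deg
from .trackio import StationaryEstimate, Thresholds, Track

__all__ = [
    "MergeEvent",
    "DropPrebreedingEvent",
    "DropPolarEvent",
    "DropTurningEvent",
    "RefinedTrack",
    "merge_proximal",
    "drop_prebreeding",
    "drop_polar",
    "protected_index",
    "turning_filter",
    "refine_track",
    "replay_provenance",
]


@dataclass(frozen=True)
class MergeEvent:
    """Indices (in the sequence at event time) collapsed into `result`."""

    indices: tuple[int, ...]
    result: StationaryEstimate

    def apply(self, estimates: list[StationaryEstimate]) -> list[StationaryEstimate]:
        lo, hi = self.indices[0], self.indices[-1]
        return estimates[:lo] + [self.result] + estimates[hi + 1:]


@dataclass(frozen=True)
class DropPrebreedingEvent:
    index: int

    def apply(self, estimates: list[StationaryEstimate]) -> list[StationaryEstimate]:
        return estimates[: self.index] + estimates[self.index + 1:]


@dataclass(frozen=True)
class DropPolarEvent:
    index: int

    def apply(self, estimates: list[StationaryEstimate]) -> list[StationaryEstimate]:
        return estimates[: self.index] + estimates[self.index + 1:]


@dataclass(frozen=True)
class DropTurningEvent:
    """Removal of `index`; its interval is absorbed by `absorbed_by`
    (a neighbor index in the pre-removal sequence)."""

    index: int
    absorbed_by: int

    def apply(self, estimates: list[StationaryEstimate]) -> list[StationaryEstimate]:
        removed = estimates[self.index]
        neighbor = estimates[self.absorbed_by]
        extended = replace(
            neighbor,
            arrival=min(neighbor.arrival, removed.arrival),
            departure=max(neighbor.departure, removed.departure),
        )
        out = list(estimates)
        out[self.absorbed_by] = extended
        del out[self.index]
        return out


ProvenanceEvent = MergeEvent | DropPrebreedingEvent | DropPolarEvent | DropTurningEvent


@dataclass(frozen=True)
class RefinedTrack:
    """A track after refinement, with the full event log.

    ``flagged`` marks tracks with no stop of >= 42 days (no safe winter
    terminus for the turning filter); they are carried through but excluded
    from network construction.
    """

    track: Track
    provenance: tuple[ProvenanceEvent, ...]
    flagged: bool = False
    warnings: tuple[str, ...] = ()


def replay_provenance(
    raw: Sequence[StationaryEstimate], provenance: Sequence[ProvenanceEvent]
) -> list[StationaryEstimate]:
    """Apply a provenance log to raw estimates, reproducing the refinement."""
    estimates = list(raw)
    for event in provenance:
        estimates = event.apply(estimates)
    return estimates


def merge_proximal(
    estimates: Sequence[StationaryEstimate],
    thresholds: Thresholds = Thresholds(),
    provenance: list | None = None,
    duration_weighted: bool = False,
) -> list[StationaryEstimate]:
    """Collapse runs of consecutive stops < merge_km apart, to a fixed point.

    A maximal chain of pairwise-close consecutive stops becomes a single
    stop at the spherical mean of its members (optionally weighted by stop
    duration), spanning earliest arrival to latest departure. Because a
    merged centroid can newly fall within merge_km of its neighbor, the
    pass repeats until stable.
    """
    out = list(estimates)
    changed = True
    while changed:
        changed = False
        i = 0
        merged: list[StationaryEstimate] = []
        while i < len(out):
            j = i
            while (
                j + 1 < len(out)
                and great_circle_km(out[j].location, out[j + 1].location)
                < thresholds.merge_km
            ):
                j += 1
            if j > i:
                chain = out[i : j + 1]
                weights = [e.duration_days or 1.0 for e in chain] if duration_weighted else None
                result = StationaryEstimate(
                    location=mean_location([e.location for e in chain], weights),
                    arrival=min(e.arrival for e in chain),
                    departure=max(e.departure for e in chain),
                )
                if provenance is not None:
                    provenance.append(
                        MergeEvent(tuple(range(len(merged), len(merged) + len(chain))), result)
                    )
                # Note: provenance indices refer to the sequence as rebuilt so
                # far plus the untouched tail, which is exactly the state at
                # event time because earlier chains in this pass were already
                # collapsed.
                merged.append(result)
                changed = True
            else:
                merged.append(out[i])
            i = j + 1
        out = merged
    return out


def drop_prebreeding(
    estimates: Sequence[StationaryEstimate],
    breeding_site: GeoPoint,
    thresholds: Thresholds = Thresholds(),
    provenance: list | None = None,
    warnings: list | None = None,
) -> list[StationaryEstimate]:
    """Remove leading stops until the bird has moved > breed_buffer_km from
    its breeding site. Later near-breeding stops are untouched."""
    out = list(estimates)
    first = None
    for i, est in enumerate(out):
        if great_circle_km(est.location, breeding_site) > thresholds.breed_buffer_km:
            first = i
            break
    if first is None:
        if out and warnings is not None:
            warnings.append("no estimate ever exceeded the breeding-site buffer")
        n_drop = len(out)
    else:
        n_drop = first
    for _ in range(n_drop):
        if provenance is not None:
            provenance.append(DropPrebreedingEvent(0))
    return out[n_drop:]


def drop_polar(
    estimates: Sequence[StationaryEstimate],
    thresholds: Thresholds = Thresholds(),
    provenance: list | None = None,
) -> list[StationaryEstimate]:
    """Remove leading stops until the bird is strictly south of the polar
    latitude limit (66.7 N); later high-latitude stops are retained."""
    out = list(estimates)
    first = None
    for i, est in enumerate(out):
        if est.location.lat_deg < thresholds.polar_lat_deg:
            first = i
            break
    n_drop = len(out) if first is None else first
    for _ in range(n_drop):
        if provenance is not None:
            provenance.append(DropPolarEvent(0))
    return out[n_drop:]


def protected_index(
    estimates: Sequence[StationaryEstimate],
    breeding_site: GeoPoint,
    thresholds: Thresholds = Thresholds(),
) -> tuple[int, bool]:
    """Index of the stop farthest from the breeding site among those with a
    stationary period >= winter_min_days — the presumed winter terminus.

    Returns ``(index, flagged)``; if no stop is long enough the overall
    farthest stop is returned and the track is flagged for review.
    """
    if not estimates:
        raise ValueError("protected_index of empty sequence")
    dists = [great_circle_km(e.location, breeding_site) for e in estimates]
    qualifying = [
        i for i, e in enumerate(estimates) if e.duration_days >= thresholds.winter_min_days
    ]
    if qualifying:
        return max(qualifying, key=lambda i: dists[i]), False
    return max(range(len(estimates)), key=lambda i: dists[i]), True


def turning_filter(
    estimates: Sequence[StationaryEstimate],
    breeding_site: GeoPoint,
    thresholds: Thresholds = Thresholds(),
    provenance: list | None = None,
) -> tuple[list[StationaryEstimate], bool]:
    """Remove sharp-turn artifacts (interior angle < turn_min_deg).

    One stop is removed per iteration — the one with the smallest angle —
    and its interval is absorbed into the spatially nearest surviving
    neighbor (ties to the earlier neighbor); angles are then recomputed.
    The first and last stops have no defined angle and are exempt, as is
    the protected winter-terminus stop. Returns the surviving estimates
    and the protection-fallback flag.
    """
    out = list(estimates)
    flagged = False
    if not out:
        return out, flagged
    while len(out) >= 3:
        prot, flagged = protected_index(out, breeding_site, thresholds)
        candidates = []
        for i in range(1, len(out) - 1):
            if i == prot:
                continue
            angle = turning_angle_deg(
                out[i - 1].location, out[i].location, out[i + 1].location
            )
            if angle < thresholds.turn_min_deg:
                candidates.append((angle, i))
        if not candidates:
            break
        _, idx = min(candidates)
        d_prev = great_circle_km(out[idx].location, out[idx - 1].location)
        d_next = great_circle_km(out[idx].location, out[idx + 1].location)
        neighbor = idx - 1 if d_prev <= d_next else idx + 1
        event = DropTurningEvent(index=idx, absorbed_by=neighbor)
        out = event.apply(out)
        if provenance is not None:
            provenance.append(event)
    if out:
        _, flagged = protected_index(out, breeding_site, thresholds)
    return out, flagged


def refine_track(track: Track, thresholds: Thresholds = Thresholds()) -> RefinedTrack:
    """The full 3-step refinement: merge + pre-departure drop, polar drop,
    turning filter; provenance recorded throughout.

    The step sequence is iterated to a fixed point: removing a sharp-turn
    stop can leave its two former neighbors closer than merge_km (or move
    a leading centroid back inside the breeding buffer), so a single pass
    would leave estimates that violate the rules it just applied. Each
    pass strictly shrinks the sequence, so the loop terminates.
    """
    provenance: list[ProvenanceEvent] = []
    warnings: list[str] = []
    estimates = list(track.estimates)
    flagged = False
    while True:
        before = list(estimates)
        estimates = merge_proximal(estimates, thresholds, provenance)
        estimates = drop_prebreeding(
            estimates, track.breeding_site, thresholds, provenance, warnings
        )
        estimates = drop_polar(estimates, thresholds, provenance)
        if estimates:
            estimates, flagged = turning_filter(
                estimates, track.breeding_site, thresholds, provenance
            )
        if estimates == before:
            break
    return RefinedTrack(
        track=track.with_estimates(estimates),
        provenance=tuple(provenance),
        flagged=flagged,
        warnings=tuple(warnings),
    )
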
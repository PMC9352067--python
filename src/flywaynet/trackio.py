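"""Input/output for stationary-estimate tables, sites, config, and GeoJSON.

The canonical interchange format is RFC-4180 CSV (UTF-8) with the exact
header::

    bird_id, subspecies, site_id, breeding_lat, breeding_lon,
    lat, lon, arrival, departure, complete

XLSX is accepted only for ingesting the published supplementary table of
stationary estimates; its column vocabulary is mapped onto the canonical
one in a single alias table (:data:`COLUMN_ALIASES`). Timestamps are UTC
throughout; date-only values are coerced to midnight UTC. Errors are
reported per record (with the offending row number) so one bad row never
silently drops a bird.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field, fields, replace
from datetime import datetime, timezone
from typing import Iterable, Mapping, Sequence, TextIO

from .geometry import GeoPoint

__all__ = [
    "SUBSPECIES",
    "StationaryEstimate",
    "Track",
    "Site",
    "SiteRegistry",
    "builtin_site_registry",
    "deployment_summary",
    "Thresholds",
    "TrackIOError",
    "CSV_COLUMNS",
    "read_stationary_table",
    "write_stationary_table",
    "write_network_geojson",
    "read_network_geojson",
    "read_config",
    "write_config",
    "get_logger",
]

#: The four Dunlin subspecies that migrate along the East Asian-Australasian
#: Flyway, in canonical (alphabetical) order.
SUBSPECIES = ("actites", "arcticola", "kistchinski", "sakhalina")

_LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s %(message)s"


def get_logger(name: str = "flywaynet") -> logging.Logger:
    """Package logger; stage-granularity messages, per-bird warnings."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logger


class TrackIOError(ValueError):
    """A record-level input error; carries the 1-based data row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


@dataclass(frozen=True)
class StationaryEstimate:
    """A geolocator-derived stop: where and when a bird was stationary.

    Upstream processing emits one of these for every interval of >= 2 days
    during which the bird did not move; merged estimates may span longer.
    """

    location: GeoPoint
    arrival: datetime
    departure: datetime

    def __post_init__(self) -> None:
        for name in ("arrival", "departure"):
            ts = getattr(self, name)
            if ts.tzinfo is None:
                object.__setattr__(self, name, ts.replace(tzinfo=timezone.utc))
        if self.departure < self.arrival:
            raise ValueError(
                f"departure {self.departure} precedes arrival {self.arrival}"
            )

    @property
    def duration_days(self) -> float:
        return (self.departure - self.arrival).total_seconds() / 86400.0


@dataclass(frozen=True)
class Track:
    """One bird's ordered stop sequence for a single tracking year."""

    bird_id: str
    subspecies: str
    breeding_site: GeoPoint
    tracking_year: int
    estimates: tuple[StationaryEstimate, ...]
    complete: bool = True
    site_id: str = ""

    def __post_init__(self) -> None:
        if self.subspecies not in SUBSPECIES:
            raise ValueError(f"unknown subspecies {self.subspecies!r}")
        object.__setattr__(self, "estimates", tuple(self.estimates))
        prev = None
        for est in self.estimates:
            if prev is not None:
                if est.arrival < prev.arrival:
                    raise ValueError(f"track {self.bird_id}: estimates not sorted")
                if est.arrival < prev.departure:
                    raise ValueError(
                        f"track {self.bird_id}: overlapping intervals at {est.arrival}"
                    )
            prev = est

    def with_estimates(self, estimates: Sequence[StationaryEstimate]) -> "Track":
        return replace(self, estimates=tuple(estimates))


@dataclass(frozen=True)
class Site:
    site_id: str
    name: str
    location: GeoPoint
    subspecies: str
    #: (deployment-recapture years, n deployed, n complete tracks, n partial)
    deployments: tuple[tuple[str, int, int, int], ...] = ()


class SiteRegistry(Mapping[str, Site]):
    """Mapping site_id -> breeding site, with deployment bookkeeping."""

    def __init__(self, sites: Iterable[Site]):
        self._sites = {s.site_id: s for s in sites}

    def __getitem__(self, key: str) -> Site:
        return self._sites[key]

    def __iter__(self):
        return iter(self._sites)

    def __len__(self) -> int:
        return len(self._sites)

    def for_subspecies(self, subspecies: str) -> list[Site]:
        return [s for s in self._sites.values() if s.subspecies == subspecies]


def builtin_site_registry() -> SiteRegistry:
    """The 8 study breeding sites with their published coordinates and
    per-deployment tag counts (total deployed | complete | partial tracks
    recovered)."""
    rows = [
        ("a", "Utqiagvik, Alaska", 71.2652, -156.6359, "arcticola",
         (("2010-11", 51, 15, 3), ("2016-17", 46, 16, 0),
          ("2017-18", 8, 1, 0), ("2018-19", 40, 10, 1))),
        ("b", "Ikpikpuk River, Alaska", 70.5525, -154.7309, "arcticola",
         (("2010-11", 35, 4, 1),)),
        ("c", "Canning River, Alaska", 70.1180, -145.8506, "arcticola",
         (("2010-11", 22, 3, 2), ("2016-17", 13, 3, 0))),
        ("d", "Chaun Delta, Russia", 68.7750, 170.5495, "sakhalina",
         (("2013-14", 35, 4, 6),)),
        ("e", "Belyaka Spit, Russia", 67.0647, -174.5000, "sakhalina",
         (("2011-12", 10, 4, 1), ("2013-14", 15, 5, 1), ("2016-17", 14, 6, 1))),
        ("f", "Meinypilgyno, Russia", 62.5833, 177.0300, "sakhalina",
         (("2014-15", 5, 3, 0), ("2016-17", 7, 4, 0))),
        ("g", "Cape Pogodny, Russia", 56.2645, 162.5815, "kistchinski",
         (("2017-18", 20, 5, 0),)),
        ("h", "Chaivo Bay, Russia", 52.5000, 143.2833, "actites",
         (("2016-17", 18, 1, 0),)),
    ]
    return SiteRegistry(
        Site(sid, name, GeoPoint(lat, lon), ssp, deps)
        for sid, name, lat, lon, ssp, deps in rows
    )


def deployment_summary(registry: SiteRegistry) -> dict[str, int]:
    """Totals over the registry's deployment records: tags deployed and
    complete/partial migration tracks recovered."""
    deployed = complete = partial = 0
    for site in registry.values():
        for _years, n_dep, n_c, n_p in site.deployments:
            deployed += n_dep
            complete += n_c
            partial += n_p
    return {
        "total_deployed": deployed,
        "complete_tracks": complete,
        "partial_tracks": partial,
    }


@dataclass(frozen=True)
class Thresholds:
    """Every constant the analysis pipeline depends on, user-overridable.

    Units: kilometers, degrees latitude, days, degrees of turning angle,
    km/h. Defaults are the study's published values.
    """

    merge_km: float = 250.0
    breed_buffer_km: float = 250.0
    polar_lat_deg: float = 66.7
    winter_lat_deg: float = 45.5
    winter_min_days: float = 42.0
    turn_min_deg: float = 60.0
    travel_kmh: float = 58.0
    region_median_diam_km: float = 700.0
    min_stationary_days: float = 2.0
    fisher_min_n: int = 25
    wilcoxon_min_n: int = 5

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be strictly positive")


# ---------------------------------------------------------------------------
# Stationary-estimate tables

CSV_COLUMNS = (
    "bird_id", "subspecies", "site_id", "breeding_lat", "breeding_lon",
    "lat", "lon", "arrival", "departure", "complete",
)

#: Alias vocabulary accepted on input (the supplementary-table column names
#: mapped onto the canonical schema). Declared once, here.
COLUMN_ALIASES: dict[str, str] = {
    "bird": "bird_id", "id": "bird_id", "bird_id": "bird_id",
    "subspecies": "subspecies", "ssp": "subspecies", "taxon": "subspecies",
    "site": "site_id", "site_id": "site_id", "capture_site": "site_id",
    "breeding_lat": "breeding_lat", "breeding_latitude": "breeding_lat",
    "capture_lat": "breeding_lat",
    "breeding_lon": "breeding_lon", "breeding_longitude": "breeding_lon",
    "capture_lon": "breeding_lon",
    "lat": "lat", "latitude": "lat", "meanlat": "lat",
    "lon": "lon", "longitude": "lon", "meanlon": "lon",
    "arrival": "arrival", "arrival_date": "arrival", "arrive": "arrival",
    "departure": "departure", "departure_date": "departure", "depart": "departure",
    "complete": "complete", "complete_track": "complete", "track_type": "complete",
}

_REQUIRED = ("bird_id", "subspecies", "breeding_lat", "breeding_lon",
             "lat", "lon", "arrival", "departure", "complete")

_TRUE = {"true", "t", "1", "yes", "y", "complete", "c"}
_FALSE = {"false", "f", "0", "no", "n", "partial", "p"}


def _parse_timestamp(value: str, row: int, col: str) -> datetime:
    text = str(value).strip()
    try:
        ts = datetime.fromisoformat(text.replace("Z", "+00:00"))
    except ValueError:
        raise TrackIOError(f"unparseable timestamp {text!r} in column {col}", row)
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _parse_bool(value, row: int) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise TrackIOError(f"unparseable complete flag {value!r}", row)


def _normalize_header(header: Sequence[str]) -> dict[str, int]:
    mapping: dict[str, int] = {}
    for i, raw in enumerate(header):
        key = str(raw).strip().lower().replace(" ", "_")
        if key in COLUMN_ALIASES:
            mapping[COLUMN_ALIASES[key]] = i
    missing = [c for c in _REQUIRED if c not in mapping]
    if missing:
        raise TrackIOError(f"missing required column(s): {', '.join(missing)}")
    return mapping


def _rows_from_xlsx(source) -> list[list]:
    import openpyxl

    wb = openpyxl.load_workbook(source, read_only=True, data_only=True)
    # Skip any README/notes tab: use the first sheet whose header row maps.
    for sheet in wb.worksheets:
        rows = [[c for c in row] for row in sheet.iter_rows(values_only=True)]
        if not rows:
            continue
        try:
            _normalize_header([str(c) if c is not None else "" for c in rows[0]])
        except TrackIOError:
            continue
        return rows
    raise TrackIOError("no worksheet with a recognizable header found")


def read_stationary_table(source, dialect: str = "csv") -> list[Track]:
    """Parse a stationary-estimate table into one :class:`Track` per bird.

    ``source`` is a path, text stream (csv) or binary stream (xlsx).
    Estimates supplied out of time order are sorted by arrival; overlapping
    intervals within a bird, unknown subspecies, and reversed timestamps
    raise :class:`TrackIOError` naming the offending data row.
    """
    if dialect == "csv":
        if hasattr(source, "read"):
            rows = list(csv.reader(source))
        else:
            with open(source, newline="", encoding="utf-8") as fh:
                rows = list(csv.reader(fh))
    elif dialect == "xlsx":
        rows = _rows_from_xlsx(source)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if not rows:
        raise TrackIOError("empty table")
    colmap = _normalize_header([str(c) for c in rows[0]])

    per_bird: dict[str, dict] = {}
    arrival_row: dict[tuple[str, datetime], int] = {}
    for rownum, row in enumerate(rows[1:], start=1):
        if not row or all(c in (None, "") for c in row):
            continue

        def cell(name: str):
            idx = colmap.get(name)
            if idx is None or idx >= len(row) or row[idx] in (None, ""):
                return None
            return row[idx]

        bird_id = str(cell("bird_id"))
        ssp = str(cell("subspecies")).strip().lower()
        if ssp not in SUBSPECIES:
            raise TrackIOError(f"unknown subspecies {cell('subspecies')!r}", rownum)
        try:
            loc = GeoPoint(float(cell("lat")), float(cell("lon")))
            breeding = GeoPoint(float(cell("breeding_lat")), float(cell("breeding_lon")))
        except (TypeError, ValueError) as exc:
            raise TrackIOError(f"bad coordinate: {exc}", rownum)
        arrival = _parse_timestamp(cell("arrival"), rownum, "arrival")
        departure = _parse_timestamp(cell("departure"), rownum, "departure")
        if departure < arrival:
            raise TrackIOError(
                f"arrival {arrival.date()} after departure {departure.date()}", rownum
            )
        complete = _parse_bool(cell("complete"), rownum)
        site_id = str(cell("site_id") or "")

        entry = per_bird.setdefault(
            bird_id,
            {"subspecies": ssp, "breeding": breeding, "complete": complete,
             "site_id": site_id, "estimates": []},
        )
        if entry["subspecies"] != ssp:
            raise TrackIOError(f"bird {bird_id}: inconsistent subspecies", rownum)
        entry["estimates"].append(StationaryEstimate(loc, arrival, departure))
        arrival_row[(bird_id, arrival)] = rownum

    tracks = []
    for bird_id, entry in per_bird.items():
        ests = sorted(entry["estimates"], key=lambda e: e.arrival)
        for prev, cur in zip(ests, ests[1:]):
            if cur.arrival < prev.departure:
                raise TrackIOError(
                    f"bird {bird_id}: overlapping intervals",
                    arrival_row[(bird_id, cur.arrival)],
                )
        tracks.append(
            Track(
                bird_id=bird_id,
                subspecies=entry["subspecies"],
                breeding_site=entry["breeding"],
                tracking_year=ests[0].arrival.year if ests else 0,
                estimates=tuple(ests),
                complete=entry["complete"],
                site_id=entry["site_id"],
            )
        )
    tracks.sort(key=lambda t: t.bird_id)
    return tracks


def write_stationary_table(tracks: Iterable[Track], sink) -> None:
    """Write tracks in the canonical CSV schema (lossless round trip)."""

    def _write(fh: TextIO) -> None:
        writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for track in tracks:
            for est in track.estimates:
                writer.writerow([
                    track.bird_id, track.subspecies, track.site_id,
                    repr(track.breeding_site.lat_deg), repr(track.breeding_site.lon_deg),
                    repr(est.location.lat_deg), repr(est.location.lon_deg),
                    est.arrival.isoformat(), est.departure.isoformat(),
                    "true" if track.complete else "false",
                ])

    if hasattr(sink, "write"):
        _write(sink)
    else:
        with open(sink, "w", newline="", encoding="utf-8") as fh:
            _write(fh)


# ---------------------------------------------------------------------------
# GeoJSON network export


def write_network_geojson(network, regions, sink) -> None:
    """Serialize a seasonal migratory network as a GeoJSON FeatureCollection.

    Nodes become Point features at region medoids carrying per-subspecies
    use proportions; edges become 2-point LineStrings between medoids.
    Unknown region ids raise ValueError.
    """
    by_id = {r.region_id: r for r in regions}
    features = []
    for region_id in sorted(network.node_weights):
        if region_id not in by_id:
            raise ValueError(f"unknown region id {region_id}")
        region = by_id[region_id]
        features.append({
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [region.medoid.lon_deg, region.medoid.lat_deg],
            },
            "properties": {
                "kind": "node",
                "region_id": region_id,
                "season": network.season,
                "proportions": dict(sorted(network.node_weights[region_id].items())),
            },
        })
    for (src, dst) in sorted(network.edge_weights):
        for rid in (src, dst):
            if rid not in by_id:
                raise ValueError(f"unknown region id {rid}")
        features.append({
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [
                    [by_id[src].medoid.lon_deg, by_id[src].medoid.lat_deg],
                    [by_id[dst].medoid.lon_deg, by_id[dst].medoid.lat_deg],
                ],
            },
            "properties": {
                "kind": "edge",
                "from": src,
                "to": dst,
                "season": network.season,
                "proportions": dict(sorted(network.edge_weights[(src, dst)].items())),
            },
        })
    doc = {"type": "FeatureCollection", "features": features}
    if hasattr(sink, "write"):
        json.dump(doc, sink, indent=1, sort_keys=True)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


def read_network_geojson(source) -> dict:
    """Parse a network FeatureCollection back into node/edge weight maps."""
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source, encoding="utf-8") as fh:
            doc = json.load(fh)
    nodes: dict[int, dict[str, float]] = {}
    edges: dict[tuple[int, int], dict[str, float]] = {}
    season = None
    for feat in doc.get("features", []):
        props = feat["properties"]
        season = props.get("season", season)
        if props["kind"] == "node":
            nodes[props["region_id"]] = props["proportions"]
        else:
            edges[(props["from"], props["to"])] = props["proportions"]
    return {"season": season, "node_weights": nodes, "edge_weights": edges}


# ---------------------------------------------------------------------------
# Configuration

_CONFIG_SECTIONS = ("thresholds", "simulation", "run")


def read_config(source) -> dict:
    """Load a JSON config with sections ``thresholds``, ``simulation``,
    ``run``. Unknown keys are rejected; omitted keys take defaults.

    Returns ``{"thresholds": Thresholds, "simulation": dict, "run": dict}``
    (the simulation section stays a plain mapping; the synthetic module
    turns it into a :class:`~flywaynet.synthetic.SimConfig`).
    """
    if source is None:
        doc = {}
    elif hasattr(source, "read"):
        doc = json.load(source)
    elif isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
        doc = json.loads(source)
    else:
        with open(source, encoding="utf-8") as fh:
            doc = json.load(fh)
    unknown = set(doc) - set(_CONFIG_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")

    tsection = doc.get("thresholds", {})
    valid = {f.name for f in fields(Thresholds)}
    bad = set(tsection) - valid
    if bad:
        raise ValueError(f"unknown threshold key(s): {sorted(bad)}")
    thresholds = Thresholds(**tsection)
    return {
        "thresholds": thresholds,
        "simulation": dict(doc.get("simulation", {})),
        "run": dict(doc.get("run", {})),
    }


def write_config(config: dict, sink) -> None:
    thresholds = config.get("thresholds", Thresholds())
    doc = {
        "thresholds": {f.name: getattr(thresholds, f.name) for f in fields(Thresholds)},
        "simulation": config.get("simulation", {}),
        "run": config.get("run", {}),
    }
    if hasattr(sink, "write"):
        json.dump(doc, sink, indent=1, sort_keys=True)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
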
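"""Diameter-constrained k-medoid (PAM) regionalization of stationary
estimates into flyway regions.

The classic deterministic PAM algorithm is used: greedy BUILD
initialization followed by best-improvement SWAP until no single
medoid <-> non-medoid exchange lowers the total great-circle cost. The
number of regions is not chosen a priori; k is searched upward from 1 and
the first clustering whose *median* cluster diameter (maximum pairwise
member distance, by default) falls below the threshold — 700 km, the
typical accuracy of a geolocator stationary estimate — is accepted. This
gives the coarsest regionalization consistent with the accuracy rule.

Regions are renumbered by medoid latitude then longitude so that ids are
stable under input permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import GeoPoint, pairwise_great_circle_km
from .trackio import Thresholds

__all__ = ["FlywayRegion", "pam", "regionalize", "classify_usage", "region_table"]


@dataclass(frozen=True)
class FlywayRegion:
    region_id: int
    medoid: GeoPoint
    member_refs: tuple[tuple[str, int], ...]
    diameter_km: float
    season_usage: frozenset = frozenset()

    @property
    def migration_only(self) -> bool:
        return bool(self.season_usage) and "winter" not in self.season_usage


def _distance_matrix(points: list[GeoPoint]) -> np.ndarray:
    lat = np.array([p.lat_deg for p in points])
    lon = np.array([p.lon_deg for p in points])
    return pairwise_great_circle_km(lat, lon)


def pam(
    points: list[GeoPoint] | np.ndarray,
    k: int,
    max_iter: int = 200,
) -> tuple[list[int], np.ndarray, float]:
    """Partitioning around medoids on great-circle distances.

    ``points`` may be a list of GeoPoint or a precomputed distance matrix.
    Returns (medoid indices, assignment array of medoid indices per point,
    total cost). Deterministic: BUILD picks the greedy cost-minimizing
    point at every step (lowest index on ties) and SWAP applies the single
    best improving exchange per iteration.
    """
    D = points if isinstance(points, np.ndarray) else _distance_matrix(points)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")

    # On small instances, three distinct deterministic starts make a local
    # optimum very unlikely; for large n a single BUILD start suffices (the
    # k-search cares about the median diameter, not the last few km of cost).
    inits = ("build", "maxmin", "quantile") if n <= 200 else ("build",)
    best = None
    for init in inits:
        medoids, assignment, cost = _pam_single(D, k, init, max_iter)
        if best is None or cost < best[2] - 1e-9:
            best = (medoids, assignment, cost)
    return best


def _pam_init(D: np.ndarray, k: int, kind: str) -> list[int]:
    """Deterministic initializations: greedy BUILD (cost-reduction),
    farthest-first (maxmin), or quantile-spaced seeds over the row-sum
    ordering. All are seed-free, so results stay reproducible."""
    if kind == "quantile":
        order = np.argsort(D.sum(axis=1), kind="stable")
        idx = np.linspace(0, len(order) - 1, k).astype(int)
        return [int(order[i]) for i in idx]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[medoids[0]].copy()
    while len(medoids) < k:
        if kind == "build":
            score = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        else:
            score = nearest.copy()
        score[medoids] = -1.0
        best = int(np.argmax(score))
        medoids.append(best)
        nearest = np.minimum(nearest, D[best])
    return medoids


def _pam_single(D: np.ndarray, k: int, init: str, max_iter: int):
    n = D.shape[0]
    medoids = _pam_init(D, k, init)
    medoid_mask = np.zeros(n, dtype=bool)
    medoid_mask[medoids] = True

    def nearest_two(meds: list[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        sub = D[np.array(meds)]  # (k, n)
        order = np.argsort(sub, axis=0, kind="stable")
        d1 = sub[order[0], np.arange(n)]
        if len(meds) > 1:
            d2 = sub[order[1], np.arange(n)]
        else:
            d2 = np.full(n, np.inf)
        which = np.array(meds)[order[0]]
        return d1, d2, which

    for _ in range(max_iter):
        d1, d2, which = nearest_two(medoids)
        best_delta = -1e-9
        best_swap = None
        candidates = np.where(~medoid_mask)[0]
        if len(candidates) == 0:
            break
        for m in medoids:
            owned = which == m
            # delta(x) for swapping medoid m out and candidate x in
            Dx = D[:, candidates]  # (n, c)
            d1c = d1[:, None]
            d2c = d2[:, None]
            delta = np.where(
                owned[:, None],
                np.minimum(Dx, d2c) - d1c,
                np.minimum(Dx - d1c, 0.0),
            ).sum(axis=0)
            i = int(np.argmin(delta))
            if delta[i] < best_delta:
                best_delta = float(delta[i])
                best_swap = (m, int(candidates[i]))
        if best_swap is None:
            break
        m_out, x_in = best_swap
        medoids[medoids.index(m_out)] = x_in
        medoid_mask[m_out] = False
        medoid_mask[x_in] = True

    d1, _, which = nearest_two(medoids)
    # ties in assignment break to the lower medoid index for determinism
    sub = D[np.array(sorted(medoids))]
    assign_pos = np.argmin(sub, axis=0)
    assignment = np.array(sorted(medoids))[assign_pos]
    cost = float(D[assignment, np.arange(n)].sum())
    return sorted(medoids), assignment, cost


def _cluster_diameter(D: np.ndarray, members: np.ndarray, kind: str) -> float:
    if len(members) <= 1:
        return 0.0
    sub = D[np.ix_(members, members)]
    if kind == "mean":
        m = len(members)
        return float(sub.sum() / (m * (m - 1)))
    return float(sub.max())


def regionalize(
    points: list[GeoPoint],
    thresholds: Thresholds = Thresholds(),
    member_refs: list[tuple[str, int]] | None = None,
    diameter: str = "max",
) -> list[FlywayRegion]:
    """Smallest k (searched 1, 2, 3, ...) whose PAM clustering has median
    cluster diameter < region_median_diam_km. k = n always satisfies the
    rule (all diameters 0), so the search terminates.

    ``diameter`` selects the cluster-diameter statistic: "max" (the
    standard diameter, default) or "mean" pairwise member distance.
    """
    if not points:
        raise ValueError("regionalize of empty point set")
    if member_refs is None:
        member_refs = [("", i) for i in range(len(points))]
    D = _distance_matrix(points)
    n = len(points)
    for k in range(1, n + 1):
        medoids, assignment, _cost = pam(D, k)
        diams = [
            _cluster_diameter(D, np.where(assignment == m)[0], diameter)
            for m in medoids
        ]
        if float(np.median(diams)) < thresholds.region_median_diam_km:
            break

    order = sorted(
        range(len(medoids)),
        key=lambda i: (points[medoids[i]].lat_deg, points[medoids[i]].lon_deg),
    )
    regions = []
    for rid, pos in enumerate(order, start=1):
        m = medoids[pos]
        members = np.where(assignment == m)[0]
        regions.append(
            FlywayRegion(
                region_id=rid,
                medoid=points[m],
                member_refs=tuple(member_refs[i] for i in members),
                diameter_km=_cluster_diameter(D, members, diameter),
            )
        )
    return regions


def classify_usage(
    regions: list[FlywayRegion],
    member_seasons: dict[tuple[str, int], str | None],
) -> list[FlywayRegion]:
    """Fill each region's season usage from its members' period labels.

    A region's usage contains a season iff at least one member estimate is
    labeled with it. Regions whose usage includes winter are winter
    regions; regions used in south/north migration but never in winter are
    migration-only regions. Memberless regions are excluded.
    """
    out = []
    for region in regions:
        seasons = {
            member_seasons.get(ref)
            for ref in region.member_refs
            if member_seasons.get(ref) is not None
        }
        if not region.member_refs:
            continue
        out.append(replace(region, season_usage=frozenset(seasons)))
    return out


def region_table(regions: list[FlywayRegion]):
    """Region summary as a DataFrame: id, medoid, size, diameter, seasons."""
    import pandas as pd

    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "medoid_lat": [r.medoid.lat_deg for r in regions],
            "medoid_lon": [r.medoid.lon_deg for r in regions],
            "n_members": [len(r.member_refs) for r in regions],
            "diameter_km": [r.diameter_km for r in regions],
            "seasons": ["+".join(sorted(r.season_usage)) for r in regions],
        }
    )
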
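"""The comparison battery: pairwise two-tailed Fisher exact tests on
region use, and pairwise Wilcoxon rank-sum tests with Hodges-Lehmann shift
estimates on migration parameters.

Conventions: Fisher two-sided p-values use the probability-mass criterion
(the sum of hypergeometric probabilities of all tables no more probable
than the observed one), matching the standard R implementation. Rank-sum
p-values are exact (null enumeration) for n1 + n2 <= 20 without ties, and
use the normal approximation with tie and continuity corrections
otherwise. The shift estimate is the Hodges-Lehmann median of pairwise
differences (first sample minus second), with a 95% CI from inversion of
the rank-sum statistic. No multiple-testing correction is applied by
default — reported p-values are raw — but a Holm adjustment is available.
"""

from __future__ import annotations

import itertools
import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .trackio import SUBSPECIES, Thresholds

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact_two_tailed",
    "wilcoxon_rank_sum",
    "pairwise_region_tests",
    "pairwise_parameter_tests",
    "holm_adjust",
    "results_table",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = subspecies and columns = (used, not used)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    shift_estimate: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    context: dict = field(default_factory=dict)


def fisher_exact_two_tailed(table: ContingencyTable2x2) -> float:
    """Exact two-sided Fisher p for a 2x2 table (probability-mass method).

    Any zero margin makes the table degenerate; by convention p = 1 is
    returned with a warning.
    """
    if 0 in table.margins:
        _warnings.warn("degenerate 2x2 table (zero margin); p = 1 by convention")
        return 1.0
    _, p = sps.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return min(1.0, float(p))


# --- exact rank-sum null distribution -------------------------------------


def _rank_sum_counts(m: int, n: int) -> np.ndarray:
    """Frequencies of the Mann-Whitney U statistic (0..m*n) under the null:
    the number of ways to choose m ranks out of m+n giving each U value.
    Subset-sum dynamic program over ranks 1..m+n."""
    total = m + n
    max_sum = total * (total + 1) // 2
    dp = np.zeros((m + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for r in range(1, total + 1):
        for k in range(min(m, r), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    offset = m * (m + 1) // 2
    return dp[m, offset : offset + m * n + 1].copy()


def _qwilcox(p: float, m: int, n: int, counts: np.ndarray) -> int:
    """Smallest u with P(U <= u) >= p under the exact null."""
    cdf = np.cumsum(counts) / counts.sum()
    return int(np.searchsorted(cdf, p - 1e-12))


def wilcoxon_rank_sum(
    x, y, alpha: float = 0.05, context: dict | None = None
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test of x vs y with a Hodges-Lehmann
    shift estimate (median of x_i - y_j) and a CI by inversion of the
    rank-sum statistic. Raises ValueError on an empty sample."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    m, n = len(x), len(y)
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    exact = (m + n <= 20) and not has_ties

    if exact:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    u_stat = float(res.statistic)
    p = min(1.0, float(res.pvalue))

    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    shift = float(np.median(diffs))

    mn = m * n
    if exact:
        counts = _rank_sum_counts(m, n)
        qu = _qwilcox(alpha / 2.0, m, n, counts)
        if qu == 0:
            qu = 1
        ql = mn - qu
        ci_low, ci_high = float(diffs[qu - 1]), float(diffs[ql])
    else:
        z = sps.norm.ppf(1.0 - alpha / 2.0)
        sigma = math.sqrt(mn * (m + n + 1) / 12.0)
        k = int(math.floor(mn / 2.0 - z * sigma))
        k = max(k, 0)
        ci_low, ci_high = float(diffs[k]), float(diffs[mn - k - 1])
    # the HL estimate always lies inside the inverted interval, but guard
    # degenerate all-equal samples where every difference coincides
    ci_low = min(ci_low, shift)
    ci_high = max(ci_high, shift)

    return TestResult(
        test="wilcoxon_rank_sum",
        statistic=u_stat,
        p_value=p,
        n1=m,
        n2=n,
        shift_estimate=shift,
        ci_low=ci_low,
        ci_high=ci_high,
        context=context or {},
    )


def pairwise_region_tests(
    use_counts: dict[int, dict[str, tuple[int, int]]],
    thresholds: Thresholds = Thresholds(),
    season: str | None = None,
) -> list[TestResult]:
    """One Fisher test per region per subspecies pair whose sample sizes
    both reach fisher_min_n; smaller pairs are skipped (with the reason
    recorded in the result context as a skipped marker)."""
    results: list[TestResult] = []
    for region_id in sorted(use_counts):
        per_ssp = use_counts[region_id]
        for s1, s2 in itertools.combinations(SUBSPECIES, 2):
            if s1 not in per_ssp or s2 not in per_ssp:
                continue
            (a, b), (c, d) = per_ssp[s1], per_ssp[s2]
            n1, n2 = a + b, c + d
            ctx = {"region_id": region_id, "pair": (s1, s2)}
            if season:
                ctx["season"] = season
            if n1 < thresholds.fisher_min_n or n2 < thresholds.fisher_min_n:
                continue
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                p = fisher_exact_two_tailed(ContingencyTable2x2(a, b, c, d))
            results.append(
                TestResult(
                    test="fisher_exact",
                    statistic=float(a),
                    p_value=p,
                    n1=n1,
                    n2=n2,
                    context=ctx,
                )
            )
    return results


def _unwrap_ordinal(values: np.ndarray) -> np.ndarray:
    """Ordinal days straddling the year boundary are unwrapped by pushing
    early-year values forward one year when the raw spread exceeds half a
    year, so that e.g. Dec 28 and Jan 3 differ by 6 days, not 359."""
    if len(values) and (values.max() - values.min()) > 182.5:
        values = np.where(values < 182.5, values + 365.0, values)
    return values


#: Parameters compared between subspecies. Migration speed is deliberately
#: absent: it confounds distance with fueling time, so only within-
#: individual speed ratios are meaningful (see phenology module).
PARAMETER_COLUMNS = (
    "initiation_ordinal",
    "arrival_ordinal",
    "duration_days",
    "distance_km",
    "n_stationary",
    "median_stop_days",
)

_DATE_COLUMNS = {"initiation_ordinal", "arrival_ordinal"}


def pairwise_parameter_tests(
    table: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> list[TestResult]:
    """Rank-sum tests per parameter x period x qualifying subspecies pair.

    Subspecies with fewer than wilcoxon_min_n individuals overall are
    excluded entirely; a bird missing a parameter (partial track) drops
    out of that test only.
    """
    results: list[TestResult] = []
    counts = table.groupby("subspecies")["bird_id"].nunique()
    eligible = [
        s for s in SUBSPECIES if counts.get(s, 0) >= thresholds.wilcoxon_min_n
    ]
    for period in ("south", "winter", "north"):
        sub = table[table["period"] == period]
        for param in PARAMETER_COLUMNS:
            for s1, s2 in itertools.combinations(eligible, 2):
                v1 = sub.loc[sub["subspecies"] == s1, param].dropna().to_numpy(float)
                v2 = sub.loc[sub["subspecies"] == s2, param].dropna().to_numpy(float)
                if len(v1) < thresholds.wilcoxon_min_n or len(v2) < thresholds.wilcoxon_min_n:
                    continue
                if param in _DATE_COLUMNS:
                    both = _unwrap_ordinal(np.concatenate([v1, v2]))
                    v1, v2 = both[: len(v1)], both[len(v1):]
                results.append(
                    wilcoxon_rank_sum(
                        v1, v2,
                        context={"period": period, "parameter": param, "pair": (s1, s2)},
                    )
                )
    return results


def holm_adjust(results: list[TestResult]) -> list[float]:
    """Holm step-down adjusted p-values (offered as an option; the default
    reporting is raw pairwise p-values)."""
    ps = np.array([r.p_value for r in results])
    order = np.argsort(ps)
    k = len(ps)
    adj = np.empty(k)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (k - rank) * ps[i])
        adj[i] = min(1.0, running)
    return adj.tolist()


def results_table(results: list[TestResult]) -> pd.DataFrame:
    """Flat results table: test, context keys, sizes, estimate, CI, p."""
    rows = []
    for r in results:
        rows.append({
            "test": r.test,
            "season": r.context.get("season", r.context.get("period", "")),
            "target": r.context.get("parameter", r.context.get("region_id", "")),
            "pair": "/".join(r.context.get("pair", ())),
            "n1": r.n1,
            "n2": r.n2,
            "statistic": r.statistic,
            "estimate": r.shift_estimate,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p": r.p_value,
        })
    return pd.DataFrame(
        rows,
        columns=["test", "season", "target", "pair", "n1", "n2", "statistic",
                 "estimate", "ci_low", "ci_high", "p"],
    )
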
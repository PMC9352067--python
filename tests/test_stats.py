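"""Fisher exact and Wilcoxon rank-sum machinery, checked against
independent enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flywaynet.stats import (
    ContingencyTable2x2,
    fisher_exact_two_tailed,
    holm_adjust,
    pairwise_parameter_tests,
    pairwise_region_tests,
    results_table,
    wilcoxon_rank_sum,
)
from flywaynet.trackio import Thresholds


# --- independent oracles ---------------------------------------------------


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration: sum the
    probabilities of all tables with the same margins whose probability
    does not exceed the observed table's (with a small relative slack for
    floating-point ties)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, r1)

    def prob(x):  # P(table with top-left cell x)
        return math.comb(c1, x) * math.comb(n - c1, r1 - x) / denom

    p_obs = prob(a)
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def ranksum_oracle(x, y):
    """Exact two-sided rank-sum p by full enumeration of all C(m+n, m)
    group assignments (no ties assumed)."""
    m, n = len(x), len(y)
    combined = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    u_obs = sum(ranks[v] for v in x) - m * (m + 1) / 2
    us = []
    for subset in itertools.combinations(range(m + n), m):
        u = sum(i + 1 for i in subset) - m * (m + 1) / 2
        us.append(u)
    us = np.array(us)
    total = len(us)
    pl = np.sum(us <= u_obs) / total
    pg = np.sum(us >= u_obs) / total
    return min(1.0, 2 * min(pl, pg))


# --- Fisher ---------------------------------------------------------------


def test_fisher_balanced_table_is_one():
    assert fisher_exact_two_tailed(ContingencyTable2x2(5, 5, 5, 5)) == 1.0


def test_fisher_extreme_table():
    # only the two maximally unbalanced tables are this improbable:
    # p = 2 / C(20, 10)
    p = fisher_exact_two_tailed(ContingencyTable2x2(10, 0, 0, 10))
    assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
    assert p == pytest.approx(1.0825088e-5, rel=1e-6)


def test_fisher_worked_example_against_oracle():
    p = fisher_exact_two_tailed(ContingencyTable2x2(3, 7, 6, 4))
    assert p == pytest.approx(fisher_oracle(3, 7, 6, 4), abs=1e-12)
    # also frozen from R fisher.test
    assert p == pytest.approx(0.369849964277, abs=1e-9)


def test_fisher_zero_margin_convention():
    with pytest.warns(UserWarning):
        assert fisher_exact_two_tailed(ContingencyTable2x2(0, 0, 3, 7)) == 1.0


def test_fisher_swap_invariance():
    tables = [(3, 7, 6, 4), (1, 9, 8, 2), (4, 4, 2, 6)]
    for a, b, c, d in tables:
        p = fisher_exact_two_tailed(ContingencyTable2x2(a, b, c, d))
        assert fisher_exact_two_tailed(ContingencyTable2x2(c, d, a, b)) == pytest.approx(p, abs=1e-12)
        assert fisher_exact_two_tailed(ContingencyTable2x2(b, a, d, c)) == pytest.approx(p, abs=1e-12)


def test_fisher_matches_oracle_on_margin_grid():
    """Every 2x2 table with both row sums <= 8 agrees with the
    hypergeometric enumeration oracle to 1e-12 (the full <= 15 sweep runs
    in the acceptance suite)."""
    for r1 in range(1, 9):
        for r2 in range(1, 9):
            for a in range(r1 + 1):
                for c in range(r2 + 1):
                    t = ContingencyTable2x2(a, r1 - a, c, r2 - c)
                    if 0 in t.margins:
                        continue
                    assert fisher_exact_two_tailed(t) == pytest.approx(
                        fisher_oracle(a, r1 - a, c, r2 - c), abs=1e-12
                    )


def test_contingency_validation():
    with pytest.raises(ValueError):
        ContingencyTable2x2(-1, 2, 3, 4)


# --- Wilcoxon rank-sum ----------------------------------------------------


def test_ranksum_worked_example():
    # the most extreme of the C(6,3) = 20 rankings: p = 2/20 = 0.1
    res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert res.p_value == pytest.approx(0.1, abs=1e-12)
    assert res.shift_estimate == pytest.approx(-3.0)
    # Hodges-Lehmann interval by rank-sum inversion, frozen from
    # R wilcox.test(conf.int=TRUE)
    assert res.ci_low == pytest.approx(-5.0)
    assert res.ci_high == pytest.approx(-1.0)


def test_ranksum_frozen_r_case():
    x = [1.1, 2.3, 3.8, 5.2, 7.1, 8.4, 9.9]
    y = [4.5, 6.6, 10.2, 12.8, 13.1, 15.0, 16.7, 18.2]
    res = wilcoxon_rank_sum(x, y)
    # frozen from R wilcox.test(x, y, conf.int=TRUE)
    assert res.p_value == pytest.approx(0.013986013986, abs=1e-10)
    assert res.shift_estimate == pytest.approx(-7.2)
    assert res.ci_low == pytest.approx(-11.7)
    assert res.ci_high == pytest.approx(-1.8)


def test_ranksum_identical_samples_zero_shift():
    res = wilcoxon_rank_sum([3, 1, 2], [2, 3, 1])
    assert res.shift_estimate == 0.0
    assert res.ci_low <= 0.0 <= res.ci_high


def test_ranksum_empty_sample_errors():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1, 2])


def test_ranksum_matches_permutation_oracle():
    rng = np.random.default_rng(99)
    for _ in range(30):
        m = int(rng.integers(2, 7))
        n = int(rng.integers(2, min(11 - m, 7) + 1))
        x = rng.permutation(np.arange(1, m + n + 1) * 1.0)[:m]
        y = np.setdiff1d(np.arange(1, m + n + 1) * 1.0, x)
        res = wilcoxon_rank_sum(x, y)
        assert res.p_value == pytest.approx(ranksum_oracle(list(x), list(y)), abs=1e-12)


def test_ranksum_monotone_transform_invariance():
    rng = np.random.default_rng(17)
    x = rng.normal(size=8)
    y = rng.normal(loc=0.7, size=9)
    p0 = wilcoxon_rank_sum(x, y).p_value
    assert wilcoxon_rank_sum(np.exp(x), np.exp(y)).p_value == pytest.approx(p0, abs=1e-12)
    assert wilcoxon_rank_sum(3 * x + 5, 3 * y + 5).p_value == pytest.approx(p0, abs=1e-12)


def test_ranksum_exact_vs_normal_approximation():
    """The tie/continuity-corrected normal approximation tracks the exact
    p within 0.02 on random small samples."""
    from scipy import stats as sps

    rng = np.random.default_rng(123)
    worst = 0.0
    for _ in range(200):
        m = int(rng.integers(5, 11))
        n = int(rng.integers(5, 11))
        x = rng.normal(size=m)
        y = rng.normal(loc=rng.uniform(-1, 1), size=n)
        exact = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        approx = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
        worst = max(worst, abs(exact - approx))
    assert worst < 0.02


def test_ranksum_ci_contains_estimate_with_ties():
    x = [1, 2, 2, 3, 5, 5, 8, 9, 11, 12, 13, 15, 16, 17, 18, 20, 21, 22, 23, 24, 25]
    y = [2, 3, 3, 4, 6, 7, 9, 10, 12, 14, 15, 16, 18, 19, 20, 21, 22, 23, 25, 26, 30]
    res = wilcoxon_rank_sum(x, y)  # ties + n > 20 -> asymptotic path
    assert res.ci_low <= res.shift_estimate <= res.ci_high
    assert 0 <= res.p_value <= 1


# --- pairwise batteries ---------------------------------------------------


def test_pairwise_region_tests_threshold_rule():
    counts = {
        1: {"arcticola": (30, 22), "sakhalina": (3, 23), "kistchinski": (2, 3)},
        2: {"arcticola": (0, 52), "sakhalina": (0, 26)},
    }
    results = pairwise_region_tests(counts, Thresholds())
    pairs = {(r.context["region_id"], r.context["pair"]) for r in results}
    # kistchinski (n=5) never qualifies for the 25-individual rule
    assert all("kistchinski" not in p for _, p in pairs)
    assert (1, ("arcticola", "sakhalina")) in pairs
    # a region used by neither subspecies: degenerate table, p = 1
    r2 = next(r for r in results if r.context["region_id"] == 2)
    assert r2.p_value == 1.0


def _params_frame(rng, n_per):
    rows = []
    for ssp, n in n_per.items():
        for i in range(n):
            for period in ("south", "north"):
                rows.append({
                    "bird_id": f"{ssp}{i}",
                    "subspecies": ssp,
                    "period": period,
                    "initiation_ordinal": rng.normal(240, 5),
                    "arrival_ordinal": rng.normal(300, 5),
                    "duration_days": rng.normal(60, 5),
                    "distance_km": rng.normal(7000, 300),
                    "n_stationary": rng.integers(1, 6),
                    "median_stop_days": rng.normal(8, 2),
                })
    return pd.DataFrame(rows)


def test_pairwise_parameter_tests_eligibility():
    rng = np.random.default_rng(1)
    table = _params_frame(
        rng, {"arcticola": 10, "sakhalina": 8, "kistchinski": 5, "actites": 1}
    )
    results = pairwise_parameter_tests(table, Thresholds())
    pairs = {r.context["pair"] for r in results}
    # actites (n=1) excluded entirely; three qualifying pairs remain
    assert pairs == {
        ("arcticola", "kistchinski"),
        ("arcticola", "sakhalina"),
        ("kistchinski", "sakhalina"),
    }
    # 2 periods x 6 parameters x 3 pairs
    assert len(results) == 36


def test_date_unwrap_across_year_boundary():
    # Dec 28 (362) vs Jan 3 (3): a 6-day shift, not 359 days
    x = [360.0, 362.0, 364.0, 365.0, 1.0]
    y = [2.0, 3.0, 5.0, 6.0, 8.0]
    rows = []
    for ssp, vals in (("arcticola", x), ("sakhalina", y)):
        for i, v in enumerate(vals):
            rows.append({
                "bird_id": f"{ssp}{i}", "subspecies": ssp, "period": "south",
                "initiation_ordinal": v, "arrival_ordinal": np.nan,
                "duration_days": np.nan, "distance_km": np.nan,
                "n_stationary": np.nan, "median_stop_days": np.nan,
            })
    results = pairwise_parameter_tests(pd.DataFrame(rows), Thresholds())
    res = next(r for r in results if r.context["parameter"] == "initiation_ordinal")
    assert abs(res.shift_estimate) < 20  # days apart, not ~360


def test_holm_adjustment_monotone():
    rng = np.random.default_rng(5)
    results = [wilcoxon_rank_sum(rng.normal(size=6), rng.normal(size=6))
               for _ in range(5)]
    adj = holm_adjust(results)
    raw = [r.p_value for r in results]
    assert all(a >= p - 1e-12 for a, p in zip(adj, raw))
    assert all(0 <= a <= 1 for a in adj)


def test_results_table_schema():
    res = [wilcoxon_rank_sum([1, 2, 3], [4, 5, 6],
                             context={"period": "south", "parameter": "duration_days",
                                      "pair": ("arcticola", "sakhalina")})]
    table = results_table(res)
    assert list(table.columns) == ["test", "season", "target", "pair", "n1", "n2",
                                   "statistic", "estimate", "ci_low", "ci_high", "p"]
    assert table.loc[0, "pair"] == "arcticola/sakhalina"
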
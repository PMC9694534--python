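import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wibsplus.comparison import (
    HighDayThresholds,
    correlate,
    group_daily,
    high_day_table,
    pair_series,
    sigma_escalation_curve,
)
from wibsplus.errors import InsufficientDataError, ValidationError
from wibsplus.synthetic import (
    FLAT_DIURNAL,
    ClassSpec,
    generate_campaign,
    generate_forced_trigger,
)

DATES = pd.date_range("2017-05-01", periods=10)


def series(values, dates=None):
    dates = dates if dates is not None else DATES[: len(values)]
    return pd.Series(list(values), index=dates)


def pairs_from(x, y):
    index = pd.date_range("2017-05-01", periods=len(x))
    return pd.DataFrame({"hirst": list(x), "wibs": list(y)}, index=index)


def test_pairing_counts_overlap():
    wibs = series(range(10))
    hirst = series(range(10))
    assert len(pair_series(wibs, hirst)) == 10


def test_disjoint_ranges_error():
    wibs = series([1, 2, 3], pd.date_range("2017-05-01", periods=3))
    hirst = series([1, 2, 3], pd.date_range("2018-05-01", periods=3))
    with pytest.raises(InsufficientDataError):
        pair_series(wibs, hirst)


def test_missing_days_shrink_the_pairing():
    wibs = series([1.0, np.nan, 3.0, 4.0, np.nan, 6.0] + [7.0] * 4)
    hirst = series(range(10))
    assert len(pair_series(wibs, hirst)) == 8


def test_long_hirst_table_pairing():
    hirst = pd.DataFrame(
        {
            "date": list(DATES[:5]) * 2,
            "taxon": ["Ascospores"] * 5 + ["Poaceae"] * 5,
            "concentration": range(10),
        }
    )
    wibs = series([10.0] * 5, DATES[:5])
    paired = pair_series(wibs, hirst, taxon="Poaceae")
    assert paired["hirst"].tolist() == [5, 6, 7, 8, 9]
    with pytest.raises(ValidationError):
        pair_series(wibs, hirst, taxon="Quercus")


def test_identity_line_is_perfectly_correlated():
    res = correlate(pairs_from([1, 2, 3, 4], [1, 2, 3, 4]))
    assert res.pearson_r == pytest.approx(1.0)
    assert res.r2_linear == pytest.approx(1.0)


def test_negative_slope_line():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    res = correlate(pairs_from(x, -2 * x + 5))
    assert res.pearson_r == pytest.approx(-1.0)
    assert res.r2_linear == pytest.approx(1.0)


def test_hand_computed_pearson():
    """r for {(1,2),(2,3),(3,5)} from the closed-form sum formula."""
    x, y = [1.0, 2.0, 3.0], [2.0, 3.0, 5.0]
    n = 3
    sx, sy = sum(x), sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    expected = (n * sxy - sx * sy) / math.sqrt(
        (n * sxx - sx**2) * (n * syy - sy**2)
    )
    res = correlate(pairs_from(x, y))
    assert res.pearson_r == pytest.approx(expected, rel=1e-12)


def test_zero_variance_is_undefined():
    with pytest.raises(ValidationError):
        correlate(pairs_from([1, 2, 3], [5, 5, 5]))
    with pytest.raises(InsufficientDataError):
        correlate(pairs_from([1, 2], [1, 2]))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    data=st.lists(
        st.tuples(
            st.floats(min_value=0, max_value=1e4),
            st.floats(min_value=0, max_value=1e4),
        ),
        min_size=4,
        max_size=40,
    )
)
def test_linear_r2_equals_r_squared_and_poly_dominates(data):
    x = np.array([d[0] for d in data])
    y = np.array([d[1] for d in data])
    if np.std(x) < 1e-6 or np.std(y) < 1e-6:
        return
    res = correlate(pairs_from(x, y))
    assert res.r2_linear == pytest.approx(res.pearson_r**2, rel=1e-10, abs=1e-10)
    assert res.r2_poly >= res.r2_linear - 1e-10


def test_outlier_removal_restores_fit():
    x = np.arange(20, dtype=float)
    y = 2 * x + 1
    y[7] = 500.0  # single gross outlier
    res_raw = correlate(pairs_from(x, y))
    res_clean = correlate(pairs_from(x, y), drop_outliers=1)
    assert res_clean.r2_linear > res_raw.r2_linear
    assert res_clean.r2_linear == pytest.approx(1.0)
    assert res_clean.n == 19


def group_table(rows):
    return pd.DataFrame(rows, index=pd.date_range("2017-05-01", periods=len(rows)))


def test_high_day_boundary_is_strict():
    table = group_table(
        [
            {"grass": 51.0, "herb": 0.0, "tree": 0.0, "fungal": 0.0},
            {"grass": 50.0, "herb": 0.0, "tree": 0.0, "fungal": 2500.0},
        ]
    )
    flags, _ = high_day_table(table)
    assert flags.iloc[0]["grass"]
    assert not flags.iloc[1]["grass"]
    assert not flags.iloc[1]["fungal"]  # exactly at threshold is not high


def test_missing_group_named_in_error():
    table = group_table([{"grass": 0.0, "herb": 0.0, "tree": 0.0}])
    with pytest.raises(ValidationError, match="fungal"):
        high_day_table(table)


def test_cooccurrence_counts_match_brute_force():
    """Three crafted days: all-high, none, tree-only; every subset count is
    checked against direct enumeration over days."""
    table = group_table(
        [
            {"grass": 100.0, "herb": 100.0, "tree": 100.0, "fungal": 9000.0},
            {"grass": 0.0, "herb": 0.0, "tree": 0.0, "fungal": 0.0},
            {"grass": 0.0, "herb": 0.0, "tree": 100.0, "fungal": 0.0},
        ]
    )
    thresholds = HighDayThresholds()
    flags, counts = high_day_table(table, thresholds)

    groups = ("grass", "herb", "tree", "fungal")
    expected = {}
    for r in range(1, 5):
        for subset in combinations(groups, r):
            tally = 0
            for _, row in table.iterrows():
                high = {g for g in groups if row[g] > getattr(thresholds, g)}
                if high == set(subset):
                    tally += 1
            expected[frozenset(subset)] = tally
    assert counts == expected
    assert counts[frozenset(groups)] == 1
    assert counts[frozenset({"tree"})] == 1


def test_region_counts_recover_per_group_totals(rng):
    values = {
        g: rng.uniform(0, 2 * t, size=30)
        for g, t in (("grass", 50), ("herb", 80), ("tree", 80), ("fungal", 2500))
    }
    table = group_table([{g: values[g][i] for g in values} for i in range(30)])
    flags, counts = high_day_table(table)
    for g in values:
        total = sum(c for key, c in counts.items() if g in key)
        assert total == flags[g].sum()


def test_group_daily_sums_taxa():
    hirst = pd.DataFrame(
        {
            "date": ["2017-05-01"] * 3,
            "taxon": ["Ascospores", "Cladosporium", "Poaceae"],
            "concentration": [100.0, 50.0, 7.0],
        }
    )
    wide = group_daily(
        hirst,
        {"Ascospores": "fungal", "Cladosporium": "fungal", "Poaceae": "grass"},
    )
    assert wide.iloc[0]["fungal"] == 150.0
    assert wide.iloc[0]["grass"] == 7.0


def _noise_free_campaign(fl1_mean):
    spec = ClassSpec(
        name="spore",
        fl_mean=(fl1_mean, 30, 30, 30, 30), fl_sd=(5, 5, 5, 5, 5),
        size_mean=4.0, size_sd=0.5, af_mean=10.0, af_sd=2.0,
        diurnal=FLAT_DIURNAL, mean_conc=1500.0, day_cv=0.5,
    )
    campaign = generate_campaign([spec], days=8, seed=7)
    ft = generate_forced_trigger([50] * 5, [8] * 5, n=500, seed=8)
    return campaign, ft


def test_signal_far_above_9sigma_is_threshold_invariant():
    """When every particle fluoresces far beyond the 9σ threshold the
    escalation curve returns identical pairings at every multiplier."""
    campaign, ft = _noise_free_campaign(fl1_mean=800.0)
    target = campaign.truth.groupby("date")["true_conc"].sum()
    results = sigma_escalation_curve(
        campaign.particles, ft, target, "fungal_A9",
        flow=campaign.flow, span=campaign.span,
    )
    assert results[3].n == results[6].n == results[9].n
    assert results[3].pearson_r == pytest.approx(results[9].pearson_r, rel=1e-12)
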
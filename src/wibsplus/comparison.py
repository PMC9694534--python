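"""Statistical comparison of WIBS-derived daily series with Hirst counts.

Covers date pairing, Pearson correlation with linear and polynomial
regression, the σ-escalation response of a proxy's correlation, and
high-concentration-day co-occurrence across the four bioaerosol groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregation import ConcentrationSeries, aggregate_concentration, daily
from .calibration import compute_thresholds
from .classification import classify_all
from .errors import InsufficientDataError, ValidationError
from .io import VALID_SIGMA
from .proxy_filters import apply_filter, builtin_proxies

GROUPS = ("grass", "herb", "tree", "fungal")


@dataclass
class ComparisonResult:
    """Correlation/regression summary for one instrument pairing."""

    label: str
    n: int
    pearson_r: float
    r2_linear: float
    r2_poly: float
    poly_degree: int
    linear_coef: tuple[float, float]  # slope, intercept
    poly_coef: tuple[float, ...]

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "pearson_r": self.pearson_r,
            "r2_linear": self.r2_linear,
            "r2_poly": self.r2_poly,
            "poly_degree": self.poly_degree,
        }


@dataclass(frozen=True)
class HighDayThresholds:
    """Daily concentrations above which a group counts as a "high" day
    (strict exceedance). Units: grains/m³ for pollen, spores/m³ for
    fungal."""

    grass: float = 50.0
    herb: float = 80.0
    tree: float = 80.0
    fungal: float = 2500.0

    def __post_init__(self) -> None:
        for g in GROUPS:
            if getattr(self, g) <= 0:
                raise ValidationError(f"high-day threshold for {g} must be > 0")


def pair_series(
    wibs: ConcentrationSeries | pd.Series,
    hirst: pd.DataFrame | pd.Series,
    taxon: str | None = None,
) -> pd.DataFrame:
    """Inner-join a daily WIBS series with a Hirst daily series on date.

    ``hirst`` may be a long (date, taxon, concentration) table together
    with ``taxon``, or a date-indexed series. Missing WIBS days (NaN) are
    excluded; the number of paired days is ``len(result)``.
    """
    wibs_daily = daily(wibs) if isinstance(wibs, ConcentrationSeries) else wibs
    wibs_daily = wibs_daily.dropna()
    wibs_daily.index = pd.to_datetime(wibs_daily.index).normalize()

    if isinstance(hirst, pd.DataFrame):
        if taxon is None:
            raise ValidationError("taxon must be named for a long Hirst table")
        sel = hirst.loc[hirst["taxon"] == taxon]
        if sel.empty:
            raise ValidationError(f"taxon {taxon!r} absent from Hirst table")
        hirst_series = sel.set_index(pd.to_datetime(sel["date"]))["concentration"]
    else:
        hirst_series = hirst.copy()
        hirst_series.index = pd.to_datetime(hirst_series.index).normalize()
    hirst_series = hirst_series.dropna()

    paired = pd.DataFrame({"wibs": wibs_daily, "hirst": hirst_series}).dropna()
    if paired.empty:
        raise InsufficientDataError("no overlapping dates between the two series")
    paired.index.name = "date"
    return paired


def correlate(
    pairs: pd.DataFrame,
    label: str = "",
    poly_degree: int = 2,
    drop_outliers: int = 0,
) -> ComparisonResult:
    """Pearson r with linear and polynomial least-squares regression.

    ``drop_outliers`` removes that many points with the largest absolute
    linear-fit residuals before computing all statistics (off by default).
    """
    x = pairs["hirst"].to_numpy(dtype=float)
    y = pairs["wibs"].to_numpy(dtype=float)
    if drop_outliers:
        if drop_outliers >= len(x) - 2:
            raise InsufficientDataError("too few points after outlier removal")
        coef = np.polyfit(x, y, 1)
        resid = np.abs(y - np.polyval(coef, x))
        keep = np.argsort(resid)[: len(x) - drop_outliers]
        x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise InsufficientDataError("at least 3 paired days required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("undefined correlation: zero variance on one side")

    r = float(stats.pearsonr(x, y).statistic)
    lin = np.polyfit(x, y, 1)
    r2_lin = _r2(y, np.polyval(lin, x))
    deg = min(poly_degree, n - 1)
    poly = np.polyfit(x, y, deg)
    r2_poly = _r2(y, np.polyval(poly, x))
    return ComparisonResult(
        label=label,
        n=n,
        pearson_r=r,
        r2_linear=r2_lin,
        r2_poly=r2_poly,
        poly_degree=deg,
        linear_coef=(float(lin[0]), float(lin[1])),
        poly_coef=tuple(float(c) for c in poly),
    )


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot


def sigma_escalation_curve(
    particles: pd.DataFrame,
    forced_trigger: pd.DataFrame,
    hirst_target: pd.Series,
    proxy_name: str,
    flow: float,
    uptime=None,
    span=None,
    min_coverage: float = 0.75,
    poly_degree: int = 2,
) -> dict[int, ComparisonResult]:
    """Correlation of a proxy's daily series with a target series as the
    fluorescence threshold escalates through 3σ, 6σ and 9σ.

    At each multiplier the particles are re-classified from the same
    forced-trigger background, the 2 µm comparison floor and the proxy are
    re-applied, daily concentrations rebuilt, and the pairing
    re-correlated.
    """
    proxies = builtin_proxies()
    if proxy_name not in proxies:
        raise ValidationError(f"unknown proxy {proxy_name!r}")
    floor = proxies["comparison_floor"]
    results: dict[int, ComparisonResult] = {}
    for k in VALID_SIGMA:
        thresholds = compute_thresholds(forced_trigger, k)
        classified, _ = classify_all(particles, thresholds)
        subset = apply_filter(classified, floor)
        subset = apply_filter(subset, proxies[proxy_name].at_sigma(k))
        series = aggregate_concentration(
            subset, freq="1D", flow=flow, uptime=uptime, span=span,
            name=f"{proxy_name}@{k}sigma", min_coverage=min_coverage,
        )
        pairs = pair_series(series, hirst_target)
        results[k] = correlate(
            pairs, label=f"{proxy_name}@{k}sigma", poly_degree=poly_degree
        )
    return results


def group_daily(
    hirst: pd.DataFrame, taxon_to_group: Mapping[str, str]
) -> pd.DataFrame:
    """Aggregate a long Hirst taxon table into daily group concentrations.

    Returns a date-indexed wide frame with one column per group (taxa
    mapping to the same group are summed per day). Taxa absent from the
    mapping are ignored.
    """
    df = hirst.copy()
    df["group"] = df["taxon"].map(taxon_to_group)
    df = df.dropna(subset=["group"])
    wide = (
        df.groupby([pd.to_datetime(df["date"]).dt.normalize(), "group"])[
            "concentration"
        ]
        .sum()
        .unstack("group")
        .fillna(0.0)
    )
    wide.index.name = "date"
    return wide


def high_day_table(
    groups: pd.DataFrame,
    thresholds: HighDayThresholds | None = None,
) -> tuple[pd.DataFrame, dict[frozenset, int]]:
    """Flag high-concentration days per group and count co-occurrences.

    ``groups`` is a date-indexed wide frame with columns grass, herb,
    tree, fungal. A day is "high" for a group iff its concentration
    strictly exceeds that group's threshold. The second return value maps
    every nonempty subset of groups to the number of days on which exactly
    that subset was high (the disjoint regions of an Euler diagram).
    """
    thresholds = thresholds or HighDayThresholds()
    missing = [g for g in GROUPS if g not in groups.columns]
    if missing:
        raise ValidationError(f"missing group column(s): {', '.join(missing)}")
    flags = pd.DataFrame(
        {g: groups[g] > getattr(thresholds, g) for g in GROUPS},
        index=groups.index,
    )
    counts: dict[frozenset, int] = {}
    for r in range(1, len(GROUPS) + 1):
        for subset in combinations(GROUPS, r):
            key = frozenset(subset)
            exact = flags.apply(
                lambda row: set(g for g in GROUPS if row[g]) == set(subset), axis=1
            )
            counts[key] = int(exact.sum())
    return flags, counts
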
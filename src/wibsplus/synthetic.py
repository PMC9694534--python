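"""Synthetic WIBS-4+ campaigns with known ground truth.

The generator emulates a spring/early-summer monitoring campaign at a
semi-urban site: class-conditional fluorescence, size and asymmetry
distributions for fungal spores, tree/herb/grass pollen, an anthropogenic
interferent and non-fluorescent dust; diurnal emission patterns; day-to-day
concentration variability; instrument capture efficiency (large grains are
undersampled); Poisson counting; and a paired Hirst-style observation model
with multiplicative counting error.

Every draw is reproducible from (scenario, seed). True class labels travel
in a separate table, never in the particle stream itself, so the analysis
pipeline stays label-blind.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import CampaignConfig, FLUOR_CHANNELS

SECONDS_PER_HOUR = 3600


@dataclass(frozen=True)
class ClassSpec:
    """Generative model of one particle class.

    Fluorescence intensities are truncated normals in detector units
    (truncated at zero and at the saturation ceiling); size is a truncated
    normal in µm within the instrument range; AF a truncated normal ≥ 0.
    ``diurnal`` gives 24 hourly emission weights summing to 1.
    ``mean_conc`` is the mean true airborne concentration (per m³) and
    ``day_cv`` its day-to-day lognormal coefficient of variation.
    ``capture_efficiency`` thins the truly airborne concentration to what
    the instrument detects (models undersampling of large grains).
    ``taxon``/``group`` name the Hirst taxon and bioaerosol group the class
    reports to; ``None`` for classes the Hirst operator does not count.
    """

    name: str
    fl_mean: tuple[float, float, float, float, float]
    fl_sd: tuple[float, float, float, float, float]
    size_mean: float
    size_sd: float
    af_mean: float
    af_sd: float
    diurnal: tuple[float, ...]
    mean_conc: float
    day_cv: float
    capture_efficiency: float = 1.0
    taxon: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.capture_efficiency <= 1.0):
            raise ValidationError(
                f"class {self.name!r}: capture_efficiency must be in (0, 1]"
            )
        if len(self.diurnal) != 24 or not np.isclose(sum(self.diurnal), 1.0):
            raise ValidationError(
                f"class {self.name!r}: diurnal weights must be 24 values summing to 1"
            )
        if any(s < 0 for s in self.fl_sd) or self.size_sd < 0 or self.af_sd < 0:
            raise ValidationError(f"class {self.name!r}: spreads must be >= 0")
        if self.mean_conc < 0 or self.day_cv < 0:
            raise ValidationError(
                f"class {self.name!r}: mean_conc and day_cv must be >= 0"
            )


@dataclass(frozen=True)
class HirstObservationSpec:
    """Observation model of the Hirst volumetric method: multiplicative
    lognormal counting error (mean 1) with coefficient of variation
    ``cv`` applied to the true daily taxon concentration."""

    cv: float = 0.30
    flow: float = 10.0  # L/min

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValidationError("counting-error CV must be >= 0")
        if self.flow <= 0:
            raise ValidationError("Hirst flow must be positive")


@dataclass
class CampaignData:
    """A generated campaign: the label-blind particle stream, the true
    class label per particle (side table, aligned by row position), and
    the per-(day, class) truth table."""

    particles: pd.DataFrame
    labels: pd.Series
    truth: pd.DataFrame
    start: pd.Timestamp
    days: int
    flow: float
    downtime_days: tuple[pd.Timestamp, ...] = ()

    @property
    def uptime(self) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        """Operating intervals implied by the downtime days."""
        down = set(pd.Timestamp(d).normalize() for d in self.downtime_days)
        intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = []
        cursor = None
        for offset in range(self.days):
            day = self.start + pd.Timedelta(days=offset)
            if day in down:
                if cursor is not None:
                    intervals.append((cursor, day))
                    cursor = None
            elif cursor is None:
                cursor = day
        if cursor is not None:
            intervals.append((cursor, self.start + pd.Timedelta(days=self.days)))
        return intervals

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return (self.start, self.start + pd.Timedelta(days=self.days))


def _truncnorm(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    n: int,
    lo: float = 0.0,
    hi: float = np.inf,
) -> np.ndarray:
    if sd == 0:
        return np.full(n, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative lognormal factors with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def generate_forced_trigger(
    noise_mean: Sequence[float],
    noise_sd: Sequence[float],
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Particle-free background firings: per-channel independent draws
    from a normal truncated at zero."""
    if n < 2:
        raise ValidationError("at least 2 forced-trigger records required")
    if len(noise_mean) != 5 or len(noise_sd) != 5:
        raise ValidationError("noise_mean and noise_sd must have 5 entries")
    if any(s < 0 for s in noise_sd):
        raise ValidationError("noise standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    data = {
        ch: _truncnorm(rng, float(m), float(s), n)
        for ch, m, s in zip(FLUOR_CHANNELS, noise_mean, noise_sd)
    }
    return pd.DataFrame(data)


def generate_campaign(
    specs: Sequence[ClassSpec],
    days: int,
    seed: int,
    start: str | pd.Timestamp = "2017-04-21",
    flow: float = 0.23,
    size_max: float = 40.0,
    saturation_ceiling: float = 2047.0,
    downtime_days: Sequence[pd.Timestamp] = (),
) -> CampaignData:
    """Generate a particle stream and its per-(day, class) truth table.

    For each day and class: a true concentration is drawn around the
    class mean (lognormal day-to-day variation), thinned by the capture
    efficiency, converted to an expected count through the sampled air
    volume (flow × 24 h), and realised as a Poisson count. Particle
    timestamps follow the class's hourly emission weights; sizes, AF and
    intensities are drawn from the class distributions. Days in
    ``downtime_days`` record truth but emit no particles.
    """
    if not specs:
        raise ValidationError("at least one class spec required")
    if days < 1:
        raise ValidationError("days must be >= 1")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("class names must be unique")
    start = pd.Timestamp(start).normalize()
    down = set(pd.Timestamp(d).normalize() for d in downtime_days)
    rng = np.random.default_rng(seed)
    volume_per_day = flow * 1440.0 / 1000.0  # m³ sampled per day

    truth_rows = []
    frames = []
    label_chunks = []
    for offset in range(days):
        day = start + pd.Timedelta(days=offset)
        in_downtime = day in down
        for spec in specs:
            true_conc = spec.mean_conc * _lognormal_unit_mean(rng, spec.day_cv, 1)[0]
            detected_conc = true_conc * spec.capture_efficiency
            lam = 0.0 if in_downtime else detected_conc * volume_per_day
            count = int(rng.poisson(lam)) if lam > 0 else 0
            truth_rows.append(
                {
                    "date": day,
                    "class": spec.name,
                    "taxon": spec.taxon,
                    "group": spec.group,
                    "true_conc": true_conc,
                    "detected_conc": detected_conc,
                    "expected_count": lam,
                    "n_detected": count,
                    "downtime": in_downtime,
                }
            )
            if count == 0:
                continue
            hours = rng.choice(24, size=count, p=np.asarray(spec.diurnal))
            seconds = rng.random(count) * SECONDS_PER_HOUR
            timestamps = (
                day
                + pd.to_timedelta(hours, unit="h")
                + pd.to_timedelta(seconds, unit="s")
            )
            fl = {
                ch: np.minimum(
                    _truncnorm(rng, spec.fl_mean[i], spec.fl_sd[i], count),
                    saturation_ceiling,
                )
                for i, ch in enumerate(FLUOR_CHANNELS)
            }
            frames.append(
                pd.DataFrame(
                    {
                        "timestamp": timestamps,
                        "size": _truncnorm(
                            rng, spec.size_mean, spec.size_sd, count,
                            lo=0.5, hi=size_max,
                        ),
                        "af": _truncnorm(rng, spec.af_mean, spec.af_sd, count),
                        **fl,
                    }
                )
            )
            label_chunks.append(np.full(count, spec.name, dtype=object))

    truth = pd.DataFrame(truth_rows)
    if frames:
        particles = pd.concat(frames, ignore_index=True)
        labels = pd.Series(np.concatenate(label_chunks), name="true_class")
        order = particles["timestamp"].sort_values(kind="mergesort").index
        particles = particles.loc[order].reset_index(drop=True)
        labels = labels.loc[order].reset_index(drop=True)
    else:
        particles = pd.DataFrame(
            columns=["timestamp", "size", "af", *FLUOR_CHANNELS]
        )
        labels = pd.Series(dtype=object, name="true_class")
    particles.attrs["flow"] = flow
    return CampaignData(
        particles=particles,
        labels=labels,
        truth=truth,
        start=start,
        days=days,
        flow=flow,
        downtime_days=tuple(sorted(down)),
    )


def observe_hirst(
    truth: pd.DataFrame,
    spec: HirstObservationSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Hirst-style daily taxon table from a campaign truth table.

    True concentrations are summed per (date, taxon) over the classes the
    operator counts (taxon not null), then perturbed by a multiplicative
    lognormal counting error with the configured CV (mean 1, so the
    observation is unbiased).
    """
    spec = spec or HirstObservationSpec()
    if truth.empty:
        raise ValidationError("truth table is empty")
    counted = truth.dropna(subset=["taxon"])
    agg = (
        counted.groupby(["date", "taxon"], sort=True)["true_conc"]
        .sum()
        .reset_index()
    )
    rng = np.random.default_rng(seed)
    factors = _lognormal_unit_mean(rng, spec.cv, len(agg))
    agg["concentration"] = np.maximum(agg["true_conc"] * factors, 0.0)
    return agg.loc[:, ["date", "taxon", "concentration"]]


def _diurnal(peak_hour: float, width: float) -> tuple[float, ...]:
    """Circular-Gaussian hourly emission weights peaking at ``peak_hour``."""
    hours = np.arange(24)
    delta = np.minimum(np.abs(hours - peak_hour), 24 - np.abs(hours - peak_hour))
    w = np.exp(-0.5 * (delta / width) ** 2)
    w = w / w.sum()
    return tuple(float(x) for x in w)


FLAT_DIURNAL = tuple([1.0 / 24] * 24)

#: Forced-trigger background per channel (detector units) for the default
#: scenario; 3σ thresholds land near 74/82/66/74/72 and 9σ near
#: 122/136/108/122/120.
DEFAULT_FT_MEAN = (50.0, 55.0, 45.0, 50.0, 48.0)
DEFAULT_FT_SD = (8.0, 9.0, 7.0, 8.0, 8.0)


def default_class_specs() -> dict[str, ClassSpec]:
    """The seven particle classes of the default scenario.

    Fungal spores fluoresce in FL1 (ascospores partly also FL2, giving an
    A/AB mix that shifts toward A as the threshold escalates) with an
    early-morning emission peak. Tree pollen is large (> 25 µm), strongly
    fluorescent in all of FL1–FL3 (ABC) and in both chlorophyll-band
    channels (DE). Herb and grass pollen carry FL4-only (D) chlorophyll
    signatures at 10–15 µm and > 10 µm respectively; grass is heavily
    undersampled (capture efficiency 0.35). The anthropogenic interferent
    fluoresces in FL1/FL2 at intensities between the 3σ and 9σ
    thresholds, so threshold escalation removes it; dust is
    non-fluorescent.
    """
    specs = [
        ClassSpec(
            name="fungal_ascospore",
            fl_mean=(600, 150, 40, 35, 35), fl_sd=(150, 80, 15, 12, 12),
            size_mean=3.0, size_sd=0.8, af_mean=10.0, af_sd=4.0,
            diurnal=_diurnal(5, 3), mean_conc=2000.0, day_cv=0.6,
            capture_efficiency=1.0, taxon="Ascospores", group="fungal",
        ),
        ClassSpec(
            name="fungal_cladosporium",
            fl_mean=(500, 55, 40, 35, 35), fl_sd=(120, 18, 15, 12, 12),
            size_mean=6.0, size_sd=1.5, af_mean=12.0, af_sd=5.0,
            diurnal=_diurnal(6, 4), mean_conc=1000.0, day_cv=0.6,
            capture_efficiency=1.0, taxon="Cladosporium", group="fungal",
        ),
        ClassSpec(
            name="tree_pollen",
            fl_mean=(1500, 1800, 1700, 900, 800), fl_sd=(250, 300, 300, 200, 180),
            size_mean=30.0, size_sd=3.0, af_mean=20.0, af_sd=6.0,
            diurnal=_diurnal(13, 4), mean_conc=120.0, day_cv=0.8,
            capture_efficiency=0.9, taxon="Quercus", group="tree",
        ),
        ClassSpec(
            name="herb_pollen",
            fl_mean=(300, 1500, 1450, 650, 50), fl_sd=(100, 250, 250, 150, 15),
            size_mean=12.5, size_sd=1.2, af_mean=16.0, af_sd=5.0,
            diurnal=_diurnal(14, 4), mean_conc=60.0, day_cv=0.9,
            capture_efficiency=0.8, taxon="Urticaceae", group="herb",
        ),
        ClassSpec(
            name="grass_pollen",
            fl_mean=(300, 1600, 1500, 700, 50), fl_sd=(100, 250, 250, 160, 15),
            size_mean=32.0, size_sd=5.0, af_mean=14.0, af_sd=5.0,
            diurnal=_diurnal(15, 4), mean_conc=40.0, day_cv=1.0,
            capture_efficiency=0.35, taxon="Poaceae", group="grass",
        ),
        ClassSpec(
            name="interferent_B",
            fl_mean=(78, 100, 40, 30, 30), fl_sd=(15, 25, 12, 10, 10),
            size_mean=3.0, size_sd=1.0, af_mean=8.0, af_sd=3.0,
            diurnal=_diurnal(12, 5), mean_conc=2000.0, day_cv=0.5,
            capture_efficiency=1.0, taxon=None, group=None,
        ),
        ClassSpec(
            name="dust_nonfluorescent",
            fl_mean=(45, 50, 40, 45, 45), fl_sd=(10, 10, 10, 10, 10),
            size_mean=4.0, size_sd=2.0, af_mean=25.0, af_sd=10.0,
            diurnal=FLAT_DIURNAL, mean_conc=5000.0, day_cv=0.4,
            capture_efficiency=1.0, taxon=None, group=None,
        ),
    ]
    return {s.name: s for s in specs}


@dataclass
class ScenarioBundle:
    """Everything a pipeline run needs: forced-trigger background, the
    campaign (particles + labels + truth), the paired Hirst observations
    and the campaign configuration."""

    forced_trigger: pd.DataFrame
    campaign: CampaignData
    hirst: pd.DataFrame
    config: CampaignConfig
    class_specs: dict[str, ClassSpec]
    hirst_spec: HirstObservationSpec
    seed: int


def default_scenario(
    seed: int,
    days: int = 50,
    start: str = "2017-04-21",
    n_forced_trigger: int = 2000,
) -> ScenarioBundle:
    """A documented ~50-day campaign with all seven default classes and a
    5-day power-loss gap two weeks in (truth and Hirst observations
    continue through the gap; the particle stream stops).

    All randomness derives from ``seed``; regenerating with the same seed
    reproduces the bundle exactly.
    """
    root = np.random.default_rng(seed)
    ft_seed, campaign_seed, hirst_seed = root.integers(0, 2**31 - 1, size=3)
    config = CampaignConfig()
    specs = default_class_specs()
    start_ts = pd.Timestamp(start)
    downtime = [start_ts + pd.Timedelta(days=14 + i) for i in range(5)]
    downtime = [d for d in downtime if d < start_ts + pd.Timedelta(days=days)]
    forced_trigger = generate_forced_trigger(
        DEFAULT_FT_MEAN, DEFAULT_FT_SD, n=n_forced_trigger, seed=int(ft_seed)
    )
    campaign = generate_campaign(
        list(specs.values()),
        days=days,
        seed=int(campaign_seed),
        start=start_ts,
        flow=config.wibs_flow,
        size_max=config.size_max,
        saturation_ceiling=config.saturation_ceiling,
        downtime_days=downtime,
    )
    hirst_spec = HirstObservationSpec()
    hirst = observe_hirst(campaign.truth, hirst_spec, seed=int(hirst_seed))
    return ScenarioBundle(
        forced_trigger=forced_trigger,
        campaign=campaign,
        hirst=hirst,
        config=config,
        class_specs=specs,
        hirst_spec=hirst_spec,
        seed=seed,
    )


def true_group_daily(truth: pd.DataFrame) -> pd.DataFrame:
    """True daily concentration per bioaerosol group (date-indexed wide
    frame), from the generator's truth table."""
    counted = truth.dropna(subset=["group"])
    wide = (
        counted.groupby(["date", "group"])["true_conc"].sum().unstack("group")
    )
    wide.index = pd.to_datetime(wide.index)
    wide.index.name = "date"
    return wide.fillna(0.0)


def true_class_daily(truth: pd.DataFrame, column: str = "true_conc") -> pd.DataFrame:
    """Daily true (or detected) concentration per class, wide by class."""
    wide = truth.groupby(["date", "class"])[column].sum().unstack("class")
    wide.index = pd.to_datetime(wide.index)
    wide.index.name = "date"
    return wide.fillna(0.0)
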
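"""Named bioaerosol proxy selections over classified particles.

Each proxy is a conjunction of criteria — allowed Perring classes, allowed
chlorophyll-band classes, a size window and per-channel minimum raw
intensities — applied to a collection classified at a stated σ multiplier.

Boundary conventions are centralised here and documented per proxy:
"greater than X µm" is strict, "less than X µm" is strict, and a printed
range like "10–15 µm" is closed on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import FLUOR_CHANNELS


@dataclass(frozen=True)
class FilterSpec:
    """A conjunctive particle selection rule.

    ``sigma`` is the σ multiplier the particles must have been classified
    at; ``None`` means the rule is σ-agnostic (pure size/intensity cuts).
    ``size_lo``/``size_hi`` bound the optical size in µm, with endpoint
    inclusion controlled by ``lo_inclusive``/``hi_inclusive``.
    """

    name: str
    perring: frozenset | None = None
    chloro: frozenset | None = None
    size_lo: float | None = None
    size_hi: float | None = None
    lo_inclusive: bool = True
    hi_inclusive: bool = False
    min_intensity: Mapping[str, float] | None = None
    sigma: int | None = 3

    def __post_init__(self) -> None:
        if (
            self.perring is None
            and self.chloro is None
            and self.size_lo is None
            and self.size_hi is None
            and not self.min_intensity
        ):
            raise ValidationError(f"filter {self.name!r} has no criteria")
        if (
            self.size_lo is not None
            and self.size_hi is not None
            and not self.size_lo < self.size_hi
        ):
            raise ValidationError(f"filter {self.name!r}: size_lo must be < size_hi")
        if self.min_intensity:
            for ch, v in self.min_intensity.items():
                if ch not in FLUOR_CHANNELS:
                    raise ValidationError(f"unknown channel {ch!r} in {self.name!r}")
                if v < 0:
                    raise ValidationError(f"negative intensity minimum in {self.name!r}")

    def mask(self, classified: pd.DataFrame) -> pd.Series:
        """Boolean row mask of the rule over a classified collection."""
        m = pd.Series(True, index=classified.index)
        if self.perring is not None:
            m &= classified["perring_class"].isin(self.perring)
        if self.chloro is not None:
            m &= classified["chloro_class"].isin(self.chloro)
        if self.size_lo is not None:
            m &= (
                classified["size"] >= self.size_lo
                if self.lo_inclusive
                else classified["size"] > self.size_lo
            )
        if self.size_hi is not None:
            m &= (
                classified["size"] <= self.size_hi
                if self.hi_inclusive
                else classified["size"] < self.size_hi
            )
        if self.min_intensity:
            for ch, v in self.min_intensity.items():
                m &= classified[ch] > v
        return m

    def at_sigma(self, k: int) -> "FilterSpec":
        """The same rule bound to a different σ multiplier."""
        return replace(self, sigma=k)


def builtin_proxies() -> dict[str, FilterSpec]:
    """The named proxy selections used for fungal-spore and pollen series.

    * ``comparison_floor`` — drop particles below 2 µm before any
      instrument comparison (the impaction method is inefficient below
      that size); σ-agnostic.
    * ``fungal_A9`` — class A at 9σ, ≥ 2 µm: fungal spores with the
      threshold escalated to suppress weakly fluorescent interferents.
    * ``fungal_AplusAB`` — classes A and AB at 3σ, ≥ 2 µm: the combined
      fungal-spore proxy.
    * ``ascospore`` — A+AB below 5 µm.
    * ``cladosporium`` — A below 10 µm.
    * ``total_pollen`` — above 2 µm with raw FL2 and FL3 intensity above
      1300 (pollen fluoresces most strongly in those channels).
    * ``tree_pollen`` — ABC above 25 µm (large tree pollen grains).
    * ``herb_pollen`` — chlorophyll class D, 10–15 µm (Urticaceae-like).
    * ``grass_pollen`` — chlorophyll class D above 10 µm.
    """
    specs = [
        FilterSpec("comparison_floor", size_lo=2.0, lo_inclusive=True, sigma=None),
        FilterSpec("fungal_A9", perring=frozenset({"A"}), size_lo=2.0,
                   lo_inclusive=True, sigma=9),
        FilterSpec("fungal_AplusAB", perring=frozenset({"A", "AB"}),
                   size_lo=2.0, lo_inclusive=True, sigma=3),
        FilterSpec("ascospore", perring=frozenset({"A", "AB"}),
                   size_hi=5.0, hi_inclusive=False, sigma=3),
        FilterSpec("cladosporium", perring=frozenset({"A"}),
                   size_hi=10.0, hi_inclusive=False, sigma=3),
        FilterSpec("total_pollen", size_lo=2.0, lo_inclusive=False,
                   min_intensity={"fl2": 1300.0, "fl3": 1300.0}, sigma=3),
        FilterSpec("tree_pollen", perring=frozenset({"ABC"}),
                   size_lo=25.0, lo_inclusive=False, sigma=3),
        FilterSpec("herb_pollen", chloro=frozenset({"D"}), size_lo=10.0,
                   size_hi=15.0, lo_inclusive=True, hi_inclusive=True, sigma=3),
        FilterSpec("grass_pollen", chloro=frozenset({"D"}), size_lo=10.0,
                   lo_inclusive=False, sigma=3),
    ]
    return {s.name: s for s in specs}


def apply_filter(classified: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Select the subset of a classified collection satisfying ``spec``.

    The collection must have been classified at the σ multiplier the spec
    requires (``df.attrs["sigma"]``); a mismatch is a configuration error,
    not a silent reinterpretation.
    """
    if spec.sigma is not None:
        observed = classified.attrs.get("sigma")
        if observed is None:
            raise ConfigurationError(
                f"filter {spec.name!r} requires classification at {spec.sigma}σ "
                "but the collection carries no σ annotation"
            )
        if observed != spec.sigma:
            raise ConfigurationError(
                f"filter {spec.name!r} requires {spec.sigma}σ classification, "
                f"collection was classified at {observed}σ"
            )
    subset = classified.loc[spec.mask(classified)].copy()
    subset.attrs = dict(classified.attrs)
    return subset
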
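"""End-to-end analysis of a synthetic campaign.

Chains every stage — simulate, calibrate, classify, filter, aggregate,
compare, cluster — on the default scenario and collects the headline
quantities in one JSON-serialisable report. This is the entry point the
reproduction script uses and a convenient smoke test for the whole
package.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .aggregation import aggregate_concentration, daily, diurnal_profile
from .calibration import compute_thresholds
from .classification import classify_all
from .clustering import intra_category_cluster, map_clusters_to_taxa
from .comparison import (
    HighDayThresholds,
    correlate,
    group_daily,
    high_day_table,
    pair_series,
    sigma_escalation_curve,
)
from .proxy_filters import apply_filter, builtin_proxies
from .synthetic import default_scenario, true_class_daily, true_group_daily

#: Which reference series each proxy is evaluated against. "pollen" is
#: the sum of the tree, herb and grass group series.
PROXY_TARGETS = {
    "fungal_AplusAB": "fungal",
    "ascospore": "Ascospores",
    "cladosporium": "Cladosporium",
    "total_pollen": "pollen",
    "tree_pollen": "tree",
    "herb_pollen": "herb",
    "grass_pollen": "grass",
}

TAXON_TO_GROUP = {
    "Ascospores": "fungal",
    "Cladosporium": "fungal",
    "Quercus": "tree",
    "Urticaceae": "herb",
    "Poaceae": "grass",
}


def _reference_series(bundle) -> dict[str, pd.Series]:
    """True daily series per group, taxon and total pollen."""
    groups = true_group_daily(bundle.campaign.truth)
    refs = {g: groups[g] for g in groups.columns}
    refs["pollen"] = groups[["tree", "herb", "grass"]].sum(axis=1)
    taxa = (
        bundle.campaign.truth.dropna(subset=["taxon"])
        .groupby(["date", "taxon"])["true_conc"]
        .sum()
        .unstack("taxon")
    )
    for taxon in taxa.columns:
        refs[taxon] = taxa[taxon]
    return refs


def run_default_analysis(
    seed: int,
    days: int = 50,
    k_range: Iterable[int] = range(2, 13),
    restarts: int = 10,
) -> dict:
    """Simulate the default scenario and run the full analysis.

    Returns a nested dict of plain Python numbers suitable for
    ``json.dump``; identical seeds yield identical reports.
    """
    bundle = default_scenario(seed, days=days)
    campaign = bundle.campaign
    flow = bundle.config.wibs_flow
    uptime = campaign.uptime
    span = campaign.span
    refs = _reference_series(bundle)

    thresholds3 = compute_thresholds(bundle.forced_trigger, k=3)
    classified3, summary = classify_all(
        campaign.particles, thresholds3, bundle.config.fluorescence_basis
    )
    proxies = builtin_proxies()
    floor = apply_filter(classified3, proxies["comparison_floor"])

    report: dict = {
        "seed": seed,
        "days": days,
        "n_particles": summary.n_total,
        "fluorescent_fraction": summary.fluorescent_fraction,
        "perring_pct_of_fluorescent": {
            cls: float(summary.perring.loc[cls, "frac_fluorescent"] * 100)
            for cls in ("A", "B", "C", "AB", "AC", "BC", "ABC")
        },
        "thresholds_3sigma": {
            ch: float(v) for ch, v in thresholds3.thresholds.items()
        },
    }

    # Daily proxy series at 3σ against their true reference series.
    proxy_stats: dict = {}
    for name, target in PROXY_TARGETS.items():
        subset = apply_filter(floor, proxies[name])
        series = aggregate_concentration(
            subset, freq="1D", flow=flow, uptime=uptime, span=span, name=name
        )
        pairs = pair_series(series, refs[target])
        proxy_stats[name] = correlate(pairs, label=f"{name}~{target}").as_dict()
    report["proxies_vs_truth"] = proxy_stats

    # Threshold escalation of the class-A fungal proxy.
    escalation = sigma_escalation_curve(
        campaign.particles,
        bundle.forced_trigger,
        refs["fungal"],
        "fungal_A9",
        flow=flow,
        uptime=uptime,
        span=span,
    )
    report["sigma_escalation_fungal_A"] = {
        str(k): res.as_dict() for k, res in escalation.items()
    }

    # Diurnal cycle of the combined fungal proxy.
    fungal_hourly = aggregate_concentration(
        apply_filter(floor, proxies["fungal_AplusAB"]),
        freq="1h", flow=flow, uptime=uptime, span=span, name="fungal_AplusAB",
    )
    profile = diurnal_profile(fungal_hourly)
    report["fungal_diurnal_peak_hour"] = profile.peak_hour()

    # High-day co-occurrence from the Hirst observations.
    hirst_groups = group_daily(bundle.hirst, TAXON_TO_GROUP)
    flags, cooccurrence = high_day_table(hirst_groups, HighDayThresholds())
    report["high_days_per_group"] = {
        g: int(flags[g].sum()) for g in flags.columns
    }
    report["high_day_all_four"] = int(
        cooccurrence[frozenset({"grass", "herb", "tree", "fungal"})]
    )

    # Intra-categorical clustering: fungal candidates and pollen candidates,
    # mapped back to the Hirst group series.
    hirst_ref = hirst_groups.copy()
    cluster_report = {}
    for proxy_name, targets in (
        ("fungal_AplusAB", ["fungal"]),
        ("total_pollen", ["tree", "herb", "grass"]),
    ):
        model, clustered = intra_category_cluster(
            floor, proxies[proxy_name], k_range=k_range, seed=seed,
            restarts=restarts,
        )
        _, best = map_clusters_to_taxa(
            clustered, hirst_ref[targets], flow=flow, uptime=uptime, span=span
        )
        cluster_report[proxy_name] = {
            "k": model.k,
            "ch_index": model.ch_index,
            "best_union": {
                t: {"clusters": list(map(int, v["clusters"])), "r2": v["r2"]}
                for t, v in best.items()
            },
        }
    report["intra_category_clustering"] = cluster_report
    return report
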
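"""K-means clustering of fluorescent particles in scaled feature space.

Particles are clustered on the seven per-event observables — the five
fluorescence intensities, optical size and asymmetry factor — after
z-score standardisation. The number of clusters is selected by maximising
the Calinski–Harabasz index (between- over within-cluster dispersion,
normalised by degrees of freedom). Intra-categorical clustering first
restricts to a named proxy selection (e.g. the A+AB fungal candidates) and
then clusters within it, which can isolate sub-populations that track a
reference taxon better than the whole selection does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .aggregation import aggregate_concentration, daily
from .comparison import correlate, pair_series
from .errors import ConfigurationError, InsufficientDataError, ValidationError
from .proxy_filters import FilterSpec, apply_filter, builtin_proxies

#: Features used for clustering, in canonical order.
CLUSTER_FEATURES = ("fl1", "fl2", "fl3", "fl4", "fl5", "size", "af")


@dataclass
class ScalingParams:
    """Z-score parameters per retained feature; constant features are
    dropped (they carry no cluster information)."""

    mean: pd.Series
    sd: pd.Series
    dropped: tuple[str, ...] = ()

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.mean.index)


@dataclass
class ClusterModel:
    """A fitted k-means solution in scaled feature space."""

    k: int
    scaling: ScalingParams
    centroids: np.ndarray  # (k, n_features), scaled space
    labels: np.ndarray
    sizes: np.ndarray
    inertia: float
    ch_index: float
    seed: int
    restarts: int


def scale_features(
    particles: pd.DataFrame, features: Sequence[str] = CLUSTER_FEATURES
) -> tuple[pd.DataFrame, ScalingParams]:
    """Standardise each feature to mean 0, sample sd 1.

    Constant (zero-variance) features are dropped with a warning.
    """
    if len(particles) < 2:
        raise InsufficientDataError("at least 2 particles required for scaling")
    X = particles.loc[:, list(features)].astype(float)
    mean = X.mean()
    sd = X.std(ddof=1)
    dropped = tuple(sd.index[sd == 0])
    if dropped:
        warnings.warn(
            f"dropping constant feature(s) before clustering: {', '.join(dropped)}",
            stacklevel=2,
        )
    keep = [f for f in features if f not in dropped]
    if not keep:
        raise InsufficientDataError("all features are constant; nothing to cluster")
    scaled = (X[keep] - mean[keep]) / sd[keep]
    params = ScalingParams(mean=mean[keep], sd=sd[keep], dropped=dropped)
    return scaled, params


def fit_kmeans(
    scaled: pd.DataFrame,
    k: int,
    seed: int,
    restarts: int = 10,
    scaling: ScalingParams | None = None,
) -> ClusterModel:
    """Best-of-``restarts`` k-means fit; deterministic given ``seed``."""
    n = len(scaled)
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of particles ({n})")
    if k < 2:
        raise ValidationError("k must be at least 2")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(scaled.to_numpy())
    ch = (
        float(calinski_harabasz_score(scaled.to_numpy(), labels))
        if 2 <= k < n
        else float("nan")
    )
    sizes = np.bincount(labels, minlength=k)
    if scaling is None:
        scaling = ScalingParams(
            mean=pd.Series(0.0, index=scaled.columns),
            sd=pd.Series(1.0, index=scaled.columns),
        )
    return ClusterModel(
        k=k,
        scaling=scaling,
        centroids=km.cluster_centers_,
        labels=labels,
        sizes=sizes,
        inertia=float(km.inertia_),
        ch_index=ch,
        seed=seed,
        restarts=restarts,
    )


def select_k(
    scaled: pd.DataFrame,
    k_range: Iterable[int] = range(2, 13),
    seed: int = 0,
    restarts: int = 10,
) -> tuple[int, dict[int, float]]:
    """Calinski–Harabasz model selection over a range of cluster counts.

    Returns the k maximising the index (smallest k wins ties) and the
    index value per candidate k. Candidates outside [2, n−1] are skipped.
    """
    n = len(scaled)
    candidates = [k for k in k_range if 2 <= k <= n - 1]
    if not candidates:
        raise ValidationError("no admissible k in the requested range")
    scores: dict[int, float] = {}
    for k in candidates:
        model = fit_kmeans(scaled, k, seed=seed, restarts=restarts)
        scores[k] = model.ch_index
    best = max(sorted(scores), key=lambda k: scores[k])
    return best, scores


def intra_category_cluster(
    classified: pd.DataFrame,
    preselection: FilterSpec | str,
    k_range: Iterable[int] = range(2, 13),
    seed: int = 0,
    restarts: int = 10,
) -> tuple[ClusterModel, pd.DataFrame]:
    """Cluster within a proxy selection: filter → scale → select k → fit.

    Returns the fitted model and the selected subset with a ``cluster``
    column appended.
    """
    if isinstance(preselection, str):
        try:
            preselection = builtin_proxies()[preselection]
        except KeyError:
            raise ValidationError(f"unknown proxy {preselection!r}") from None
    subset = apply_filter(classified, preselection)
    if subset.empty:
        raise InsufficientDataError(
            f"preselection {preselection.name!r} matched no particles"
        )
    scaled, params = scale_features(subset)
    best_k, _ = select_k(scaled, k_range=k_range, seed=seed, restarts=restarts)
    model = fit_kmeans(scaled, best_k, seed=seed, restarts=restarts, scaling=params)
    out = subset.copy()
    out["cluster"] = model.labels
    out.attrs = dict(subset.attrs)
    return model, out


def map_clusters_to_taxa(
    clustered: pd.DataFrame,
    reference: pd.DataFrame,
    flow: float,
    uptime=None,
    span=None,
    min_coverage: float = 0.75,
    union_cap: int = 2,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Correlate per-cluster daily concentrations with reference series.

    Parameters
    ----------
    clustered
        Particle subset with ``timestamp`` and ``cluster`` columns.
    reference
        Date-indexed wide frame, one column per taxon/group series.
    union_cap
        Maximum number of clusters whose summed concentration is offered
        as a combined proxy per taxon (greedy forward selection; the
        union is kept only if it improves on the best single cluster).

    Returns the (cluster × taxon) Pearson-r table — NaN where the taxon
    series is constant and the correlation undefined — and, per taxon,
    the best cluster union with its linear R².
    """
    cluster_ids = sorted(int(c) for c in pd.unique(clustered["cluster"]))
    series = {}
    for c in cluster_ids:
        sel = clustered.loc[clustered["cluster"] == c]
        series[c] = daily(
            aggregate_concentration(
                sel, freq="1D", flow=flow, uptime=uptime, span=span,
                name=f"cluster{c}", min_coverage=min_coverage,
            )
        )
    r_rows = {}
    best: dict[str, dict] = {}
    for taxon in reference.columns:
        target = reference[taxon].dropna()
        if target.nunique() <= 1:
            warnings.warn(
                f"reference series {taxon!r} is constant; correlation undefined",
                stacklevel=2,
            )
            r_rows[taxon] = {c: np.nan for c in cluster_ids}
            continue
        r_col = {}
        r2_single = {}
        for c in cluster_ids:
            try:
                pairs = pair_series(series[c], target)
                res = correlate(pairs, label=f"cluster{c}~{taxon}")
                r_col[c] = res.pearson_r
                r2_single[c] = res.r2_linear
            except (InsufficientDataError, ValidationError):
                r_col[c] = np.nan
        r_rows[taxon] = r_col
        defined = [c for c in cluster_ids if not np.isnan(r_col[c])]
        if not defined:
            continue
        chosen = [max(defined, key=lambda c: r2_single[c])]
        best_r2 = r2_single[chosen[0]]
        while len(chosen) < union_cap:
            remaining = [c for c in defined if c not in chosen]
            if not remaining:
                break
            trial_scores = {}
            for c in remaining:
                combined = sum(series[cc] for cc in chosen + [c])
                pairs = pair_series(combined, target)
                trial_scores[c] = correlate(pairs).r2_linear
            addition = max(sorted(trial_scores), key=lambda c: trial_scores[c])
            if trial_scores[addition] > best_r2:
                chosen.append(addition)
                best_r2 = trial_scores[addition]
            else:
                break
        best[taxon] = {"clusters": tuple(chosen), "r2": float(best_r2)}
    r_table = pd.DataFrame(r_rows, index=cluster_ids)
    r_table.index.name = "cluster"
    return r_table, best
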
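import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from wibsplus.classification import classify_all
from wibsplus.clustering import (
    CLUSTER_FEATURES,
    fit_kmeans,
    intra_category_cluster,
    map_clusters_to_taxa,
    scale_features,
    select_k,
)
from wibsplus.errors import InsufficientDataError, ValidationError
from wibsplus.proxy_filters import builtin_proxies

from conftest import make_particles, make_thresholds


def feature_frame(X):
    return pd.DataFrame(X, columns=list(CLUSTER_FEATURES)[: X.shape[1]])


def blob_frame(rng, centers, n_per=40, sd=0.05):
    """Tight Gaussian blobs in the full 7-feature space."""
    chunks, labels = [], []
    for i, center in enumerate(centers):
        chunks.append(rng.normal(center, sd, size=(n_per, len(center))))
        labels.extend([i] * n_per)
    X = np.vstack(chunks)
    return feature_frame(X), np.array(labels)


def test_zscore_definition():
    df = feature_frame(np.array([[2.0], [4.0], [6.0]]))
    scaled, params = scale_features(df, features=["fl1"])
    assert scaled["fl1"].mean() == pytest.approx(0.0, abs=1e-12)
    assert scaled["fl1"].std(ddof=1) == pytest.approx(1.0)
    assert params.mean["fl1"] == 4.0


def test_constant_feature_dropped_with_warning():
    X = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
    df = feature_frame(X)
    with pytest.warns(UserWarning, match="fl2"):
        scaled, params = scale_features(df, features=["fl1", "fl2"])
    assert list(scaled.columns) == ["fl1"]
    assert params.dropped == ("fl2",)


def test_wildly_different_scales_equalised(rng):
    X = np.column_stack([rng.normal(0, 1, 100), rng.normal(0, 100, 100)])
    scaled, _ = scale_features(feature_frame(X), features=["fl1", "fl2"])
    assert scaled["fl1"].std(ddof=1) == pytest.approx(1.0)
    assert scaled["fl2"].std(ddof=1) == pytest.approx(1.0)


def test_two_point_masses_recovered_exactly(rng):
    df, truth = blob_frame(rng, [np.zeros(7), np.full(7, 10.0)], sd=0.0)
    model = fit_kmeans(df, k=2, seed=0)
    assert adjusted_rand_score(truth, model.labels) == 1.0
    assert sorted(model.sizes) == [40, 40]


def test_same_seed_same_assignment(rng):
    df, _ = blob_frame(rng, [np.zeros(7), np.full(7, 3.0), np.full(7, -3.0)])
    a = fit_kmeans(df, k=3, seed=11)
    b = fit_kmeans(df, k=3, seed=11)
    assert np.array_equal(a.labels, b.labels)
    assert a.inertia == b.inertia


def test_three_separated_blobs_select_three(rng):
    df, truth = blob_frame(
        rng, [np.zeros(7), np.full(7, 10.0), np.full(7, -10.0)], sd=1.0
    )
    scaled, _ = scale_features(df)
    best, scores = select_k(scaled, k_range=range(2, 7), seed=3)
    assert best == 3
    model = fit_kmeans(scaled, k=3, seed=3)
    assert adjusted_rand_score(truth, model.labels) >= 0.99


def brute_force_ch(X, labels):
    """Calinski–Harabasz from its definition: between-group dispersion over
    within-group dispersion, each normalised by degrees of freedom."""
    X = np.asarray(X, dtype=float)
    n, k = len(X), len(np.unique(labels))
    grand = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for c in np.unique(labels):
        members = X[labels == c]
        centroid = members.mean(axis=0)
        between += len(members) * np.sum((centroid - grand) ** 2)
        within += np.sum((members - centroid) ** 2)
    return (between / (k - 1)) / (within / (n - k))


def test_ch_index_matches_brute_force(rng):
    df, _ = blob_frame(rng, [np.zeros(7), np.full(7, 4.0)], n_per=25, sd=1.0)
    model = fit_kmeans(df, k=2, seed=5)
    expected = brute_force_ch(df.to_numpy(), model.labels)
    assert model.ch_index == pytest.approx(expected, rel=1e-10)


def test_k_equal_n_minus_one_is_finite(rng):
    df = feature_frame(rng.normal(size=(8, 7)))
    model = fit_kmeans(df, k=7, seed=0)
    assert np.isfinite(model.ch_index)


def test_degenerate_clustering_has_zero_ch():
    """If every centroid coincides with the grand mean the between-group
    dispersion, and hence the index, is zero."""
    X = np.array([[1.0, 0], [-1.0, 0], [1.0, 0], [-1.0, 0]])
    labels = np.array([0, 0, 1, 1])  # both cluster means at the origin
    assert brute_force_ch(X, labels) == 0.0


def test_k_bounds_enforced(rng):
    df = feature_frame(rng.normal(size=(5, 7)))
    with pytest.raises(ValidationError):
        fit_kmeans(df, k=6, seed=0)
    with pytest.raises(ValidationError):
        select_k(df, k_range=range(20, 25), seed=0)


def test_restarts_never_worsen_objective(rng):
    df, _ = blob_frame(rng, [np.zeros(7), np.full(7, 2.0), np.full(7, 5.0)], sd=1.5)
    single = fit_kmeans(df, k=3, seed=9, restarts=1)
    many = fit_kmeans(df, k=3, seed=9, restarts=10)
    assert many.inertia <= single.inertia + 1e-9


def _classified_campaign(rng, n=300):
    rows = []
    for _ in range(n):
        kind = rng.choice(["a_small", "ab_small", "other"])
        if kind == "a_small":
            rows.append({"fl1": 200.0, "size": 3.0, "af": 8.0})
        elif kind == "ab_small":
            rows.append({"fl1": 200.0, "fl2": 200.0, "size": 4.0, "af": 12.0})
        else:
            rows.append({"size": 6.0})
    particles = make_particles(rows, step="5min")
    classified, _ = classify_all(particles, make_thresholds())
    return classified


def test_intra_category_clusters_within_the_preselection(rng):
    classified = _classified_campaign(rng)
    model, clustered = intra_category_cluster(
        classified, "fungal_AplusAB", k_range=range(2, 5), seed=1
    )
    assert set(clustered["perring_class"]) <= {"A", "AB"}
    assert len(clustered) == model.sizes.sum()


def test_empty_preselection_names_the_proxy(rng):
    classified = _classified_campaign(rng)
    with pytest.raises(InsufficientDataError, match="tree_pollen"):
        intra_category_cluster(classified, "tree_pollen", k_range=range(2, 4), seed=1)
    with pytest.raises(ValidationError, match="nonexistent"):
        intra_category_cluster(classified, "nonexistent", seed=1)


def _clustered_two_populations(rng, days=12):
    """Two temporally distinct particle populations pre-labelled as two
    clusters, plus matching reference series."""
    start = pd.Timestamp("2017-05-01")
    rows, clusters = [], []
    daily_a = rng.integers(5, 50, size=days)
    daily_b = rng.integers(5, 50, size=days)
    for d in range(days):
        day = start + pd.Timedelta(days=d)
        for _ in range(int(daily_a[d])):
            rows.append({"timestamp": day + pd.Timedelta(minutes=float(rng.uniform(0, 1440)))})
            clusters.append(0)
        for _ in range(int(daily_b[d])):
            rows.append({"timestamp": day + pd.Timedelta(minutes=float(rng.uniform(0, 1440)))})
            clusters.append(1)
    clustered = make_particles(rows)
    clustered["cluster"] = clusters
    dates = pd.date_range(start, periods=days)
    reference = pd.DataFrame(
        {
            "alpha": daily_a.astype(float),
            "beta": daily_b.astype(float),
            "flat": np.ones(days),
        },
        index=dates,
    )
    return clustered, reference, (start, start + pd.Timedelta(days=days))


def test_cluster_taxon_mapping_finds_the_matching_cluster(rng):
    clustered, reference, span = _clustered_two_populations(rng)
    r_table, best = map_clusters_to_taxa(
        clustered, reference[["alpha", "beta"]], flow=0.23, span=span
    )
    assert r_table.loc[0, "alpha"] > r_table.loc[1, "alpha"]
    assert r_table.loc[1, "beta"] > r_table.loc[0, "beta"]
    assert 0 in best["alpha"]["clusters"]


def test_constant_reference_series_flagged(rng):
    clustered, reference, span = _clustered_two_populations(rng)
    with pytest.warns(UserWarning, match="flat"):
        r_table, best = map_clusters_to_taxa(
            clustered, reference[["flat"]], flow=0.23, span=span
        )
    assert r_table["flat"].isna().all()
    assert "flat" not in best


def test_union_never_below_best_single(rng):
    clustered, reference, span = _clustered_two_populations(rng)
    reference = reference.copy()
    reference["both"] = reference["alpha"] + reference["beta"]
    r_table, best = map_clusters_to_taxa(
        clustered, reference[["both"]], flow=0.23, span=span, union_cap=2
    )
    singles = []
    for c in (0, 1):
        sel = clustered.loc[clustered["cluster"] == c]
        from wibsplus.aggregation import aggregate_concentration
        from wibsplus.comparison import correlate, pair_series

        s = aggregate_concentration(sel, "1D", 0.23, span=span)
        singles.append(correlate(pair_series(s, reference["both"])).r2_linear)
    assert best["both"]["r2"] >= max(singles) - 1e-12
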
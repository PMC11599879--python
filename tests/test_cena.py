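import math

import numpy as np
import pytest

from mcpi import (
    RegionRecord,
    bootstrap_membership,
    cluster_cells,
    cluster_profiles,
    cosangle,
    exchange_matrix,
    growth_percent,
    labels_by_epoch,
    normalize_features,
    pairwise_cosangle,
)


def make_records(values, epochs=(2007, 2019)):
    """values: dict region_id -> {epoch: (amw, ach, ndvi)}"""
    recs = []
    for rid, by_epoch in values.items():
        for e in epochs:
            amw, ach, ndvi = by_epoch[e]
            recs.append(RegionRecord(rid, e, amw, ach, ndvi, m=5, n=5))
    return recs


def archetype_records(archetypes, n_per, rng=None, jitter=0.0, moves=None):
    """Regions per archetype; ``moves`` maps region_id -> epoch-2019 archetype."""
    moves = moves or {}
    recs = []
    rid = 0
    for ai, (amw, ach, ndvi) in enumerate(archetypes):
        for _ in range(n_per):
            for e in (2007, 2019):
                src = archetypes[moves[rid]] if (e == 2019 and rid in moves) else (amw, ach, ndvi)
                f = 1.0 + (rng.uniform(-jitter, jitter, 3) if jitter else np.zeros(3))
                recs.append(
                    RegionRecord(rid, e, src[0] * f[0], src[1] * f[1], min(src[2] * f[2], 0.99), 5, 5)
                )
            rid += 1
    return recs


# Eight (AMW m, ACH m, NDVI) archetypes whose min-max-normalized profiles
# point in well-separated directions (pairwise cosangle >= ~0.06): the angle
# metric only sees direction, so archetypes must differ in factor *ratios*,
# not just magnitudes.
_ARCH_NORM = [
    (0.074, 0.246, 0.574),
    (0.243, 0.494, 0.460),
    (0.480, 0.207, 0.511),
    (0.128, 0.537, 0.827),
    (0.722, 0.563, 0.048),
    (0.794, 0.248, 0.220),
    (0.423, 0.242, 0.909),
    (0.741, 0.960, 0.229),
]
ARCHETYPES = [(300 + a * 2700, 1.5 + b * 10.5, 0.45 + c * 0.45) for a, b, c in _ARCH_NORM]


# -- normalization ----------------------------------------------------------


def test_minmax_scaling_pools_epochs():
    recs = make_records(
        {
            0: {2007: (2.0, 2.0, 0.2), 2019: (10.0, 10.0, 0.8)},
            1: {2007: (6.0, 6.0, 0.5), 2019: (6.0, 6.0, 0.5)},
        }
    )
    X = normalize_features(recs)
    mid = X.data[(X.region_ids == 1)]
    np.testing.assert_allclose(mid, 0.5)


def test_identical_epochs_give_identical_rows():
    recs = make_records({i: {2007: (i + 1.0, 2.0, 0.5), 2019: (i + 1.0, 2.0, 0.5)} for i in range(4)})
    X = normalize_features(recs)
    a = X.data[X.epochs == 2007]
    b = X.data[X.epochs == 2019]
    np.testing.assert_array_equal(a, b)


def test_pooled_differs_from_per_epoch_normalization():
    # epoch-shifted heights: pooled scaling sees one range, per-epoch two
    recs = make_records(
        {
            0: {2007: (1.0, 2.0, 0.5), 2019: (1.0, 12.0, 0.5)},
            1: {2007: (2.0, 4.0, 0.6), 2019: (2.0, 14.0, 0.6)},
        }
    )
    X = normalize_features(recs)
    ach = X.data[:, 1]
    per_epoch = []
    for e in (2007, 2019):
        sub = np.array([r.ach_m for r in recs if r.epoch == e], dtype=float)
        per_epoch.extend((sub - sub.min()) / (sub.max() - sub.min()))
    assert not np.allclose(np.sort(ach), np.sort(per_epoch))


def test_single_epoch_rejected():
    recs = [RegionRecord(0, 2019, 1.0, 1.0, 0.5, 1, 1)] * 3
    with pytest.raises(ValueError):
        normalize_features(recs)


# -- cosangle ---------------------------------------------------------------


def test_cosangle_values():
    assert cosangle([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0, abs=1e-12)
    assert cosangle([1, 0], [0, 1]) == pytest.approx(1.0)
    assert cosangle([1, 0], [1, 1]) == pytest.approx(1 - 1 / math.sqrt(2), abs=1e-9)
    assert cosangle([1, 0], [1, 1], variant="sqrt") == pytest.approx(
        math.sqrt(2 * (1 - 1 / math.sqrt(2))), abs=1e-9
    )
    with pytest.raises(ValueError):
        cosangle([0, 0], [1, 1])


def test_pairwise_matches_scalar():
    rng = np.random.default_rng(0)
    X = rng.random((6, 3)) + 0.05
    D = pairwise_cosangle(X)
    assert D[2, 4] == pytest.approx(cosangle(X[2], X[4]), abs=1e-12)
    assert (np.diag(D) == 0).all()


# -- clustering -------------------------------------------------------------


def test_k1_collapses_to_single_medoid():
    rng = np.random.default_rng(1)
    X = rng.random((10, 3)) + 0.1
    model = cluster_cells(X, k=1)
    assert set(model.labels) == {1}
    D = pairwise_cosangle(X)
    assert D[model.medoid_indices[0]].sum() == pytest.approx(D.sum(axis=1).min())


def test_duplicated_rows_preserve_partition():
    rng = np.random.default_rng(2)
    base = rng.random((12, 3)) + 0.1
    m1 = cluster_cells(base, k=3)
    m2 = cluster_cells(np.vstack([base, base]), k=3)
    # duplicates land in the cluster of their originals
    assert (m2.labels[:12] == m2.labels[12:]).all()
    same = (m1.labels == m2.labels[:12]).all()
    assert same


def test_archetype_recovery_and_label_order():
    rng = np.random.default_rng(3)
    recs = archetype_records(ARCHETYPES, n_per=6, rng=rng, jitter=0.03)
    X = normalize_features(recs)
    model = cluster_cells(X, k=8)
    # labels sorted by mean normalized ACH descending
    ach = X.data[:, 1]
    means = [ach[model.labels == c].mean() for c in range(1, 9)]
    assert means == sorted(means, reverse=True)


def test_too_few_rows_rejected():
    with pytest.raises(ValueError):
        cluster_cells(np.ones((3, 3)), k=8)


# -- bootstrap membership ---------------------------------------------------


def test_single_rep_is_one_hot():
    rng = np.random.default_rng(4)
    recs = archetype_records(ARCHETYPES[:4], n_per=5, rng=rng, jitter=0.02)
    X = normalize_features(recs)
    model = cluster_cells(X, k=4)
    mem = bootstrap_membership(X, model, reps=1, seed=0)
    assert set(np.unique(mem.probabilities)) <= {0.0, 1.0}
    np.testing.assert_allclose(mem.probabilities.sum(axis=1), 1.0)


def test_separated_clusters_have_confident_membership():
    rng = np.random.default_rng(5)
    recs = archetype_records(ARCHETYPES[:4], n_per=6, rng=rng, jitter=0.01)
    X = normalize_features(recs)
    model = cluster_cells(X, k=4)
    mem = bootstrap_membership(X, model, reps=30, seed=1)
    assert mem.probabilities.max(axis=1).min() >= 0.99


def test_overlapping_clusters_are_fuzzy():
    rng = np.random.default_rng(6)
    X = np.vstack(
        [rng.normal(loc, 0.25, size=(15, 3)) for loc in ([0.4, 0.5, 0.6], [0.5, 0.5, 0.5])]
    ).clip(0.05, 1.0)
    model = cluster_cells(X, k=2)
    mem = bootstrap_membership(X, model, reps=40, seed=2)
    assert mem.probabilities.max(axis=1).min() < 0.9
    with pytest.raises(ValueError):
        bootstrap_membership(X, model, reps=0)


# -- exchange matrix --------------------------------------------------------


def test_identity_exchange_is_diagonal():
    labels = {f"r{i}": (i % 3) + 1 for i in range(9)}
    ex = exchange_matrix(labels, labels, k=3)
    assert (ex.matrix == np.diag([3, 3, 3])).all()


def test_counting_example():
    # 3 regions move cluster 1 -> 2, two stay in 1
    la = {"a": 1, "b": 1, "c": 1, "d": 1, "e": 1}
    lb = {"a": 2, "b": 2, "c": 2, "d": 1, "e": 1}
    ex = exchange_matrix(la, lb, k=2)
    assert ex.matrix[0, 1] == 3 and ex.matrix[0, 0] == 2
    edges = ex.edges()
    assert edges.to_dict("records") == [{"source": 1, "target": 2, "count": 3}]


def test_marginals_conserved_on_random_labelings():
    rng = np.random.default_rng(7)
    k = 5
    regions = [f"g{i}" for i in range(40)]
    la = {r: int(rng.integers(1, k + 1)) for r in regions}
    lb = {r: int(rng.integers(1, k + 1)) for r in regions}
    ex = exchange_matrix(la, lb, k=k)
    for c in range(1, k + 1):
        assert ex.row_sums[c - 1] == sum(v == c for v in la.values())
        assert ex.col_sums[c - 1] == sum(v == c for v in lb.values())
    assert ex.total == len(regions)


def test_mismatched_region_sets_rejected():
    with pytest.raises(ValueError):
        exchange_matrix({"a": 1}, {"b": 1}, k=2)


# -- profiles ---------------------------------------------------------------


def test_single_cluster_profile_is_global_mean():
    rng = np.random.default_rng(8)
    recs = archetype_records(ARCHETYPES[:2], n_per=4, rng=rng, jitter=0.05)
    X = normalize_features(recs)
    model = cluster_cells(X, k=1)
    prof = cluster_profiles(model, X)
    assert prof.loc[1, "amw_m"] == pytest.approx(np.mean([r.amw_m for r in recs]))
    assert prof.loc[1, "size"] == len(recs)


def test_growth_percent_definition():
    assert growth_percent(2, 18) == pytest.approx(800.0)
    assert growth_percent(5, 5) == 0.0
    with pytest.raises(ValueError):
        growth_percent(0, 3)


def test_planted_migration_recovered_noiselessly():
    moves = {0: 7, 1: 7, 2: 7}  # three archetype-0 regions fall to archetype 7
    recs = archetype_records(ARCHETYPES, n_per=4, rng=None, jitter=0.0, moves=moves)
    X = normalize_features(recs)
    model = cluster_cells(X, k=8)
    la = labels_by_epoch(X, model, 2007)
    lb = labels_by_epoch(X, model, 2019)
    ex = exchange_matrix(la, lb, k=8, epoch_a=2007, epoch_b=2019)
    src, dst = la[0], lb[0]
    assert src != dst
    assert ex.matrix[src - 1, dst - 1] == 3
    off = ex.matrix.copy()
    np.fill_diagonal(off, 0)
    assert off.sum() == 3  # no spurious flows
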
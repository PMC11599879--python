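"""Cluster Exchange Network Analysis (CENA).

Pooled-epoch factor profiles (normalized AMW, ACH, NDVI for every region
in both epochs) are partitioned once into k clusters (default 8) by
k-medoids under a cosine-angle ("cosangle") distance, mirroring a
one-level run of ordered partitioning clustering; fuzzy cluster
allegiances come from non-parametric bootstrap re-clustering; and the
cross-epoch movement of regions between clusters is tabulated as a k x k
exchange matrix whose off-diagonal entries are the directed flows of an
exchange network.

Cluster labels are 1-based and ordered by mean normalized canopy height,
descending, so cluster numbering is reproducible across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .transects import RegionRecord

__all__ = [
    "FeatureMatrix",
    "ClusterModel",
    "MembershipMatrix",
    "ExchangeMatrix",
    "normalize_features",
    "cosangle",
    "pairwise_cosangle",
    "cluster_cells",
    "bootstrap_membership",
    "exchange_matrix",
    "cluster_profiles",
    "growth_percent",
]

FACTOR_COLUMNS = ("amw_m", "ach_m", "ndvi")


@dataclass
class FeatureMatrix:
    """Rows = (region, epoch); columns = normalized AMW, ACH, NDVI in [0, 1]."""

    data: np.ndarray  # (n, 3)
    region_ids: np.ndarray
    epochs: np.ndarray
    records: list[RegionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != len(FACTOR_COLUMNS):
            raise ValueError("feature matrix must be (n, 3)")
        if np.isnan(self.data).any():
            raise ValueError("feature matrix must not contain missing values")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def rows_for_epoch(self, epoch) -> np.ndarray:
        return np.nonzero(self.epochs == epoch)[0]


def normalize_features(records: Sequence[RegionRecord]) -> FeatureMatrix:
    """Min-max scale AMW/ACH/NDVI over the pooled multi-epoch record set.

    Pooling across epochs keeps the two years on one scale so clusters are
    comparable between them; a factor constant across the pool maps to 0.
    """
    if not records:
        raise ValueError("no records")
    epochs = np.array([r.epoch for r in records])
    if np.unique(epochs).size < 2:
        raise ValueError("normalization pools epochs: need records from at least two epochs")
    raw = np.array([[getattr(r, c) for c in FACTOR_COLUMNS] for r in records], dtype=float)
    if np.isnan(raw).any():
        raise ValueError("records contain missing factor values")
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    span = hi - lo
    scaled = np.where(span > 0, (raw - lo) / np.where(span > 0, span, 1.0), 0.0)
    return FeatureMatrix(
        data=scaled,
        region_ids=np.array([r.region_id for r in records]),
        epochs=epochs,
        records=list(records),
    )


def cosangle(x, y, variant: str = "one_minus_cos") -> float:
    """Cosine-angle distance between two factor vectors.

    ``one_minus_cos``: d = 1 - cos(x, y), in [0, 2].
    ``sqrt``: d = sqrt(2 (1 - cos)), the chord form used by some ordered
    partitioning implementations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx_, ny_ = np.linalg.norm(x), np.linalg.norm(y)
    if nx_ == 0 or ny_ == 0:
        raise ValueError("cosangle is undefined for a zero vector")
    c = float(np.clip(x @ y / (nx_ * ny_), -1.0, 1.0))
    if variant == "one_minus_cos":
        return 1.0 - c
    if variant == "sqrt":
        return float(np.sqrt(2.0 * (1.0 - c)))
    raise ValueError(f"unknown cosangle variant {variant!r}")


def pairwise_cosangle(X: np.ndarray, variant: str = "one_minus_cos") -> np.ndarray:
    """Full pairwise cosangle distance matrix for the rows of X."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ValueError(
            f"{int((norms == 0).sum())} zero-norm rows: cosangle is undefined for them"
        )
    G = np.clip((X / norms[:, None]) @ (X / norms[:, None]).T, -1.0, 1.0)
    D = 1.0 - G
    np.fill_diagonal(D, 0.0)
    if variant == "sqrt":
        D = np.sqrt(2.0 * np.maximum(D, 0.0))
    elif variant != "one_minus_cos":
        raise ValueError(f"unknown cosangle variant {variant!r}")
    return D


@dataclass
class ClusterModel:
    """One-level k-medoids partition of the pooled feature rows."""

    k: int
    medoid_indices: np.ndarray  # row indices into the feature matrix, one per cluster
    medoid_vectors: np.ndarray  # (k, 3)
    labels: np.ndarray  # 1..k per row
    metric: str
    inertia: float  # sum of within-cluster distances to the medoid

    def __post_init__(self) -> None:
        counts = np.bincount(self.labels, minlength=self.k + 1)[1:]
        if (counts == 0).any():
            raise ValueError("every cluster must be non-empty")
        for ci, mi in enumerate(self.medoid_indices, start=1):
            if self.labels[mi] != ci:
                raise ValueError("each medoid must carry its own cluster's label")


class MembershipMatrix:
    """Bootstrap fuzzy-membership probabilities, rows summing to 1."""

    def __init__(self, probabilities: np.ndarray, reps: int):
        p = np.asarray(probabilities, dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("membership probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")
        self.probabilities = p
        self.reps = reps

    @property
    def hard_labels(self) -> np.ndarray:
        return self.probabilities.argmax(axis=1) + 1


def _pam(D: np.ndarray, k: int, max_iter: int = 200) -> np.ndarray:
    """PAM (build + swap) on a precomputed distance matrix; returns medoid indices.

    Deterministic: the greedy build and first-improvement-free best-swap
    loop break ties toward the lowest index.
    """
    n = D.shape[0]
    # BUILD: start from the most central point, then greedily add
    medoids = [int(D.sum(axis=1).argmin())]
    dist_to_nearest = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dist_to_nearest[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(gains.argmax())
        medoids.append(best)
        dist_to_nearest = np.minimum(dist_to_nearest, D[best])
    medoids = np.array(sorted(medoids))

    def cost(meds: np.ndarray) -> float:
        return float(D[meds].min(axis=0).sum())

    current = cost(medoids)
    for _ in range(max_iter):
        best_cost, best_swap = current, None
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        for i, m in enumerate(medoids):
            for h in non_medoids:
                trial = medoids.copy()
                trial[i] = h
                c = cost(trial)
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (i, h)
        if best_swap is None:
            break
        medoids = medoids.copy()
        medoids[best_swap[0]] = best_swap[1]
        medoids.sort()
        current = best_cost
    return medoids


def _labels_from_medoids(D: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    return D[medoids].argmin(axis=0)


def cluster_cells(
    X: FeatureMatrix | np.ndarray,
    k: int = 8,
    seed: int | None = None,
    metric: str = "one_minus_cos",
) -> ClusterModel:
    """Partition pooled feature rows into k clusters by cosangle k-medoids.

    The PAM procedure is deterministic; ``seed`` is accepted for interface
    symmetry with the bootstrap.  Clusters are relabeled 1..k by mean
    normalized canopy height, descending.
    """
    data = X.data if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n = data.shape[0]
    if n < k:
        raise ValueError(f"insufficient data: {n} rows for k = {k} clusters")
    norms = np.linalg.norm(data, axis=1)
    nz = np.nonzero(norms > 0)[0]
    if nz.size < n:
        warnings.warn(
            f"{n - nz.size} zero-norm rows have no direction and are excluded from the "
            "cosangle fit; they are assigned to the Euclidean-nearest medoid afterwards"
        )
    if nz.size < k:
        raise ValueError(f"insufficient data: {nz.size} non-zero rows for k = {k} clusters")
    D_nz = pairwise_cosangle(data[nz], metric)
    medoids_nz = _pam(D_nz, k)
    medoids = nz[medoids_nz]
    raw_labels = np.empty(n, dtype=int)
    raw_labels[nz] = _labels_from_medoids(D_nz, medoids_nz)
    zero_rows = np.setdiff1d(np.arange(n), nz)
    if zero_rows.size:
        d_euc = np.linalg.norm(data[zero_rows][:, None, :] - data[medoids][None, :, :], axis=2)
        raw_labels[zero_rows] = d_euc.argmin(axis=1)

    ach_col = FACTOR_COLUMNS.index("ach_m")
    means = np.array([data[raw_labels == c, ach_col].mean() for c in range(k)])
    order = np.argsort(-means, kind="stable")  # descending mean normalized ACH
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[raw_labels]
    medoid_indices = medoids[order]

    return ClusterModel(
        k=k,
        medoid_indices=medoid_indices,
        medoid_vectors=data[medoid_indices],
        labels=labels,
        metric=metric,
        inertia=float(D_nz[medoids_nz].min(axis=0).sum()),
    )


def bootstrap_membership(
    X: FeatureMatrix | np.ndarray,
    model: ClusterModel,
    reps: int = 200,
    seed: int = 0,
) -> MembershipMatrix:
    """Fuzzy cluster allegiances by non-parametric bootstrap.

    Each replicate resamples rows with replacement, re-fits the k medoids
    on the resample, matches the new medoids to the original clusters by
    medoid-to-medoid distance (greedy, ties to the lowest index), and
    assigns every original row to its nearest matched medoid.  Memberships
    are assignment frequencies across replicates.
    """
    if reps < 1:
        raise ValueError("bootstrap reps must be >= 1")
    data = X.data if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n_total = data.shape[0]
    norms = np.linalg.norm(data, axis=1)
    nz = np.nonzero(norms > 0)[0]
    if nz.size < n_total:
        warnings.warn(
            f"{n_total - nz.size} zero-norm rows keep their fitted label with probability 1"
        )
    n = nz.size
    D = pairwise_cosangle(data[nz], model.metric)
    # medoid positions within the non-zero subset (model medoids are never zero rows)
    medoid_pos = np.searchsorted(nz, model.medoid_indices)
    rng = np.random.default_rng(seed)
    counts_nz = np.zeros((n, model.k), dtype=float)
    for _ in range(reps):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.unique(idx).size >= model.k:
                break
        sub = np.unique(idx)  # PAM needs distinct rows; multiplicity shifts are minor
        Dsub = D[np.ix_(sub, sub)]
        meds_local = _pam(Dsub, model.k)
        meds = sub[meds_local]  # row ids (within the non-zero subset) of replicate medoids
        # greedy matching of replicate medoids to original clusters
        cost = D[np.ix_(medoid_pos, meds)]
        mapping = {}
        used_rows, used_cols = set(), set()
        for _ in range(model.k):
            best = None
            for i in range(model.k):
                if i in used_rows:
                    continue
                for j in range(model.k):
                    if j in used_cols:
                        continue
                    if best is None or cost[i, j] < cost[best]:
                        best = (i, j)
            used_rows.add(best[0])
            used_cols.add(best[1])
            mapping[best[1]] = best[0]  # replicate medoid j -> original cluster i
        assign = D[meds].argmin(axis=0)
        for row in range(n):
            counts_nz[row, mapping[assign[row]]] += 1.0
    counts = np.zeros((n_total, model.k), dtype=float)
    counts[nz] = counts_nz
    zero_rows = np.setdiff1d(np.arange(n_total), nz)
    counts[zero_rows, model.labels[zero_rows] - 1] = reps
    return MembershipMatrix(counts / reps, reps=reps)


@dataclass
class ExchangeMatrix:
    """k x k counts of regions by epoch-A cluster (rows) vs epoch-B (columns)."""

    matrix: np.ndarray
    k: int
    epoch_a: int | str = "A"
    epoch_b: int | str = "B"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape != (self.k, self.k) or (m < 0).any():
            raise ValueError("exchange matrix must be k x k with non-negative counts")
        self.matrix = m.astype(int)

    @property
    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    @property
    def common(self) -> np.ndarray:
        """Per-cluster count of regions that kept their cluster (diagonal)."""
        return np.diag(self.matrix)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(range(1, self.k + 1), name=f"cluster_{self.epoch_a}")
        cols = pd.Index(range(1, self.k + 1), name=f"cluster_{self.epoch_b}")
        return pd.DataFrame(self.matrix, index=idx, columns=cols)

    def edges(self) -> pd.DataFrame:
        """Directed off-diagonal flows as (source, target, count) rows."""
        rows = [
            {"source": i + 1, "target": j + 1, "count": int(self.matrix[i, j])}
            for i in range(self.k)
            for j in range(self.k)
            if i != j and self.matrix[i, j] > 0
        ]
        return pd.DataFrame(rows, columns=["source", "target", "count"])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for c in range(1, self.k + 1):
            g.add_node(c, common=int(self.matrix[c - 1, c - 1]))
        for e in self.edges().itertuples(index=False):
            g.add_edge(e.source, e.target, count=e.count)
        return g


def exchange_matrix(
    labels_a: Mapping, labels_b: Mapping, k: int, epoch_a="A", epoch_b="B"
) -> ExchangeMatrix:
    """Cross-tabulate cluster labels of the common region set across epochs."""
    keys_a, keys_b = set(labels_a), set(labels_b)
    if keys_a != keys_b:
        raise ValueError(
            f"mismatched region sets: {len(keys_a - keys_b)} only in A, "
            f"{len(keys_b - keys_a)} only in B"
        )
    m = np.zeros((k, k), dtype=int)
    for region in labels_a:
        la, lb = int(labels_a[region]), int(labels_b[region])
        if not (1 <= la <= k and 1 <= lb <= k):
            raise ValueError(f"label out of range 1..{k} for region {region}")
        m[la - 1, lb - 1] += 1
    return ExchangeMatrix(m, k, epoch_a, epoch_b)


def labels_by_epoch(X: FeatureMatrix, model: ClusterModel, epoch) -> dict:
    """Map region_id -> cluster label for one epoch's rows."""
    rows = X.rows_for_epoch(epoch)
    return {X.region_ids[i]: int(model.labels[i]) for i in rows}


def cluster_profiles(model: ClusterModel, X: FeatureMatrix) -> pd.DataFrame:
    """Per-cluster mean raw and normalized factors, mean MCPI, and sizes.

    Requires the FeatureMatrix built by :func:`normalize_features` (it
    carries the source records).  Clusters appear in label order, which is
    already sorted by mean normalized ACH descending.
    """
    if not X.records:
        raise ValueError("feature matrix carries no source records")
    raw = pd.DataFrame([vars(r) for r in X.records])
    raw["cluster"] = model.labels
    for j, c in enumerate(FACTOR_COLUMNS):
        raw[f"norm_{c}"] = X.data[:, j]
    agg = {c: "mean" for c in FACTOR_COLUMNS}
    agg.update({f"norm_{c}": "mean" for c in FACTOR_COLUMNS})
    if raw["mcpi"].notna().all():
        agg["mcpi"] = "mean"
    prof = raw.groupby("cluster").agg(agg)
    prof["size"] = raw.groupby("cluster").size()
    return prof


def growth_percent(size_a: int, size_b: int) -> float:
    """Percent growth of a cluster between epochs: (B - A) / A * 100."""
    if size_a <= 0:
        raise ValueError("epoch-A size must be positive")
    return (size_b - size_a) / size_a * 100.0
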
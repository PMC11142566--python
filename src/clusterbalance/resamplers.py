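"""From-scratch resamplers for imbalanced binary tables.

Implements the four classical balancers used as baselines and as building
blocks of the cluster-wise method:

* :func:`smote` — synthetic minority oversampling by segment interpolation,
* :func:`enn_clean` — edited-nearest-neighbour deletion (3 neighbours),
* :func:`knn_clean` — the same editing rule with 5 neighbours,
* :func:`nearmiss` — NearMiss-1 majority undersampling,

plus the two non-clustered hybrids :func:`smote_enn` and :func:`smote_knn`.

All distances are Euclidean on the feature matrix as given (callers are
expected to standardize first); labels never enter the metric.  Every
operation is deterministic given the data and ``ResampleConfig.seed``.

Neighbour queries are exact with a fixed tie rule: candidates sort by
(distance, then row index) ascending.  Editing deletions are computed against
the original table and applied simultaneously, so the result does not depend
on row order of evaluation; a tied neighbour vote keeps the row (deletion
requires strict majority disagreement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .tabular import LabeledTable


class ResampleError(ValueError):
    pass


@dataclass(frozen=True)
class ResampleConfig:
    """Neighbour counts and seeding for the resamplers.

    ``k_neighbors1`` is the SMOTE interpolation neighbour count (default 5).
    ``k_neighbors2`` is the editing neighbour count; ``None`` resolves to the
    conventional default of the editor in use (3 for ENN, 5 for KNN editing).
    ``strategy="equalize"`` makes the post-SMOTE minority count equal the
    majority count.
    """

    k_neighbors1: int = 5
    k_neighbors2: int | None = None
    metric: str = "euclidean"
    seed: int = 0
    strategy: str = "equalize"

    def __post_init__(self) -> None:
        if self.k_neighbors1 < 1:
            raise ResampleError("k_neighbors1 must be >= 1")
        if self.k_neighbors2 is not None and self.k_neighbors2 < 1:
            raise ResampleError("k_neighbors2 must be >= 1")
        if self.strategy != "equalize":
            raise ResampleError(f"unknown strategy {self.strategy!r}")

    def editing_k(self, editor: str) -> int:
        if self.k_neighbors2 is not None:
            return self.k_neighbors2
        return {"enn": 3, "knn": 5}[editor]


@dataclass(frozen=True)
class NeighborIndex:
    """Per-query neighbour lists (row indices into the candidate matrix)."""

    indices: np.ndarray   # (n_queries, k) int
    distances: np.ndarray  # (n_queries, k) float


def knn_query(
    X: np.ndarray,
    queries: np.ndarray,
    k: int,
    exclude_self: bool = False,
    metric: str = "euclidean",
    chunk: int = 512,
) -> NeighborIndex:
    """Exact k-nearest-neighbour query with a deterministic tie rule.

    With ``exclude_self=True`` each query is excluded from its own candidate
    list: positionally when ``queries`` is aligned with ``X`` row-for-row,
    otherwise by exact row match (first matching candidate).
    """
    X = np.asarray(X, float)
    Q = np.asarray(queries, float)
    n_cand = X.shape[0] - (1 if exclude_self else 0)
    if k > n_cand:
        raise ResampleError(f"k={k} exceeds available candidates ({n_cand})")
    aligned = Q.shape[0] == X.shape[0]
    self_idx = None
    if exclude_self and not aligned:
        self_idx = np.full(Q.shape[0], -1)
        for i, q in enumerate(Q):
            hits = np.flatnonzero((X == q).all(axis=1))
            if hits.size:
                self_idx[i] = hits[0]

    idx_out = np.empty((Q.shape[0], k), dtype=int)
    dist_out = np.empty((Q.shape[0], k), dtype=float)
    order_tiebreak = np.arange(X.shape[0])
    for start in range(0, Q.shape[0], chunk):
        stop = min(start + chunk, Q.shape[0])
        D = cdist(Q[start:stop], X, metric=metric)
        if exclude_self:
            local = np.arange(stop - start)
            rows = np.arange(start, stop) if aligned else self_idx[start:stop]
            ok = rows >= 0
            D[local[ok], rows[ok]] = np.inf
        for i in range(stop - start):
            # lexsort: primary key distance, secondary key row index
            order = np.lexsort((order_tiebreak, D[i]))[:k]
            idx_out[start + i] = order
            dist_out[start + i] = D[i, order]
    return NeighborIndex(idx_out, dist_out)


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoteProvenance:
    """Generating pair and interpolation weight of each synthetic row.

    Indices refer to rows of the input training table.
    """

    parent_a: np.ndarray
    parent_b: np.ndarray
    lam: np.ndarray


def _class_split(table: LabeledTable) -> tuple[int, int, np.ndarray, np.ndarray]:
    c0, c1 = table.class_counts
    if c1 <= c0:
        minority_label, majority_label = 1, 0
    else:
        minority_label, majority_label = 0, 1
    min_idx = np.flatnonzero(table.y == minority_label)
    maj_idx = np.flatnonzero(table.y == majority_label)
    return minority_label, majority_label, min_idx, maj_idx


def smote(
    train: LabeledTable,
    cfg: ResampleConfig = ResampleConfig(),
    return_provenance: bool = False,
):
    """Oversample the minority class by interpolating neighbour pairs.

    Each synthetic row is ``s = x + lam * (n - x)`` with ``lam ~ U[0, 1)``,
    ``x`` a minority row and ``n`` one of its ``k_neighbors1`` nearest
    minority neighbours.  (x, n) pairs are drawn uniformly until the target
    count is met; under ``strategy="equalize"`` that raises the minority count
    to the majority count.  Majority rows and all original rows pass through
    verbatim, synthetic rows are appended.
    """
    minority_label, _, min_idx, maj_idx = _class_split(train)
    n_min, n_maj = min_idx.size, maj_idx.size
    n_syn = n_maj - n_min
    if n_syn == 0:
        prov = SmoteProvenance(*[np.empty(0, int)] * 2, np.empty(0))
        return (train, prov) if return_provenance else train
    if n_min < 2:
        raise ResampleError("cannot interpolate: minority class has < 2 rows")

    k = min(cfg.k_neighbors1, n_min - 1)
    Xmin = train.X[min_idx]
    nn = knn_query(Xmin, Xmin, k, exclude_self=True, metric=cfg.metric)

    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, n_min, size=n_syn)
    pick = rng.integers(0, k, size=n_syn)
    lam = rng.random(n_syn)
    neigh = nn.indices[base, pick]
    S = Xmin[base] + lam[:, None] * (Xmin[neigh] - Xmin[base])

    X = np.vstack([train.X, S])
    y = np.concatenate([train.y, np.full(n_syn, minority_label)])
    out = LabeledTable(X, y, train.schema)
    if return_provenance:
        return out, SmoteProvenance(min_idx[base], min_idx[neigh], lam)
    return out


# ---------------------------------------------------------------------------
# Editing (ENN / KNN)
# ---------------------------------------------------------------------------

def _edit(table: LabeledTable, k: int, metric: str) -> LabeledTable:
    if table.n <= k:
        raise ResampleError(f"editing needs n > k (n={table.n}, k={k})")
    c0, c1 = table.class_counts
    if c0 == 0 or c1 == 0:
        return table  # single class: no disagreement possible
    nn = knn_query(table.X, table.X, k, exclude_self=True, metric=metric)
    neigh_labels = table.y[nn.indices]
    disagree = (neigh_labels != table.y[:, None]).sum(axis=1)
    # delete iff a strict majority of the k neighbours carries the other label
    keep = ~(2 * disagree > k)
    kept = table.subset(np.flatnonzero(keep))
    k0, k1 = kept.class_counts
    if (c0 and not k0) or (c1 and not k1):
        warnings.warn("editing emptied a class", stacklevel=3)
    return kept


def enn_clean(table: LabeledTable, cfg: ResampleConfig = ResampleConfig()) -> LabeledTable:
    """Edited-nearest-neighbour cleaning (default 3 neighbours), both classes."""
    return _edit(table, cfg.editing_k("enn"), cfg.metric)


def knn_clean(table: LabeledTable, cfg: ResampleConfig = ResampleConfig()) -> LabeledTable:
    """The same disagreement-deletion rule with 5 neighbours by default."""
    return _edit(table, cfg.editing_k("knn"), cfg.metric)


# ---------------------------------------------------------------------------
# NearMiss
# ---------------------------------------------------------------------------

def nearmiss(
    train: LabeledTable,
    cfg: ResampleConfig = ResampleConfig(),
    n_ref_neighbors: int = 3,
) -> LabeledTable:
    """NearMiss-1 undersampling of the majority class.

    Each majority row is scored by its mean distance to its
    ``n_ref_neighbors`` nearest minority rows; the minority-count rows with
    the smallest score are kept (ties to the lower row index).  Minority rows
    are untouched and original row order is preserved.
    """
    _, _, min_idx, maj_idx = _class_split(train)
    if min_idx.size == 0 or maj_idx.size == 0:
        raise ResampleError("nearmiss needs both classes non-empty")
    if maj_idx.size <= min_idx.size:
        return train
    k = min(n_ref_neighbors, min_idx.size)
    nn = knn_query(train.X[min_idx], train.X[maj_idx], k, metric=cfg.metric)
    scores = nn.distances.mean(axis=1)
    order = np.lexsort((np.arange(maj_idx.size), scores))[: min_idx.size]
    keep = np.sort(np.concatenate([maj_idx[np.sort(order)], min_idx]))
    return train.subset(keep)


# ---------------------------------------------------------------------------
# Hybrids
# ---------------------------------------------------------------------------

def smote_enn(train: LabeledTable, cfg: ResampleConfig = ResampleConfig()) -> LabeledTable:
    """SMOTE to parity, then ENN editing of the union of real + synthetic rows."""
    return enn_clean(smote(train, cfg), cfg)


def smote_knn(train: LabeledTable, cfg: ResampleConfig = ResampleConfig()) -> LabeledTable:
    """SMOTE to parity, then 5-neighbour editing of the union."""
    return knn_clean(smote(train, cfg), cfg)
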
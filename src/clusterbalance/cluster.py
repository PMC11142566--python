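"""K-means + per-cluster SMOTE + nearest-neighbour editing.

The balancing procedure:

1. pick the number of clusters ``k`` by an elbow scan over the within-cluster
   sum of squared distances (SSD),
2. partition the *training* features (labels excluded) into ``k`` clusters,
3. inside each cluster, SMOTE the locally under-represented class up to the
   local majority count,
4. edit noisy rows with ENN (3 neighbours) or the 5-neighbour variant —
   per cluster by default, or once on the merged table (``scope="global"``),
5. merge clusters into the balanced training table.

Held-out data never enters: the orchestrator accepts a single training table
and is a pure function of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans

from .resamplers import ResampleConfig, SmoteProvenance, enn_clean, knn_clean, smote
from .tabular import LabeledTable


class ClusterError(ValueError):
    pass


@dataclass(frozen=True)
class KMeansResult:
    centroids: np.ndarray       # (k, d)
    assignments: np.ndarray     # (n,)
    ssd: float                  # sum of squared distances to assigned centroid
    iterations: int
    converged: bool

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def kmeans(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
    restarts: int = 1,
) -> KMeansResult:
    """Seeded Lloyd iterations from k-means++ starts (best of ``restarts``)."""
    X = np.asarray(X, float)
    if k > X.shape[0]:
        raise ClusterError(f"k={k} exceeds n={X.shape[0]}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(X)
    return KMeansResult(
        centroids=km.cluster_centers_,
        assignments=km.labels_,
        ssd=float(km.inertia_),
        iterations=int(km.n_iter_),
        converged=int(km.n_iter_) < max_iter,
    )


@dataclass(frozen=True)
class ElbowScan:
    ks: np.ndarray
    ssds: np.ndarray
    chosen_k: int
    method: str
    flat_curve: bool


def elbow_k(
    X: np.ndarray,
    k_max: int = 10,
    seed: int = 0,
    restarts: int = 5,
    method: str = "second_difference",
) -> ElbowScan:
    """SSD scan over ``k = 1..k_max`` and elbow choice.

    ``method="second_difference"`` (default) picks the k maximizing the
    discrete curvature of ``log SSD(k)``, hence ``chosen_k in [2, k_max-1]``.
    The log scale makes "sharpest decrease" a statement about relative drops,
    so the rule is insensitive to the overall SSD magnitude and to unequal
    cluster spacings.  ``method="knee"`` picks the point farthest from the
    chord joining the scan's endpoints.  A flat-curve flag is raised when no
    single k dominates the curvature (the sharpest drop is less than twice
    the runner-up), as happens on unclustered data.
    """
    if k_max < 3:
        raise ClusterError("k_max must be >= 3")
    ks = np.arange(1, k_max + 1)
    ssds = np.array([kmeans(X, k, seed=seed, restarts=restarts).ssd for k in ks])

    if np.any(np.diff(ssds) > 1e-9 * max(ssds[0], 1.0)):
        warnings.warn("SSD sequence is not nonincreasing (restart noise)", stacklevel=2)

    log_ssds = np.log(np.maximum(ssds, 1e-12 * max(ssds[0], 1.0)))
    d2 = log_ssds[:-2] - 2.0 * log_ssds[1:-1] + log_ssds[2:]  # curvature at 2..k_max-1
    if method == "second_difference":
        best = int(np.argmax(d2))
        chosen = int(ks[1 + best])
    elif method == "knee":
        # distance from each (k, ssd) to the chord (k=1, ssd[0]) -- (k_max, ssd[-1])
        p0 = np.array([ks[0], ssds[0] / max(ssds[0], 1.0)])
        p1 = np.array([ks[-1], ssds[-1] / max(ssds[0], 1.0)])
        pts = np.column_stack([ks, ssds / max(ssds[0], 1.0)])
        chord = p1 - p0
        cross = np.abs(chord[0] * (pts[:, 1] - p0[1]) - chord[1] * (pts[:, 0] - p0[0]))
        chosen = int(ks[int(np.argmax(cross[1:-1])) + 1])
    else:
        raise ClusterError(f"unknown elbow method {method!r}")

    d2_sorted = np.sort(d2)[::-1]
    flat = bool(d2_sorted.size >= 2 and d2_sorted[0] < 2.0 * max(d2_sorted[1], 0.0)) or (
        d2_sorted.size >= 1 and d2_sorted[0] <= 0.0
    )
    if flat:
        warnings.warn("flat SSD curve: elbow is weakly determined", stacklevel=2)
    return ElbowScan(ks, ssds, chosen, method, flat)


@dataclass
class BalanceReport:
    """Bookkeeping of one cluster-wise balancing run."""

    chosen_k: int
    seed: int
    editor: str
    scope: str
    pre_counts: tuple[int, int]
    post_counts: tuple[int, int]
    per_cluster_pre: list[tuple[int, int]]
    per_cluster_post: list[tuple[int, int]]
    removed_by_editing: int
    post_smote_counts: tuple[int, int]
    ratio_warning: bool
    elbow: ElbowScan = field(repr=False, default=None)
    provenance: SmoteProvenance | None = field(repr=False, default=None)
    provenance_clusters: np.ndarray | None = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "chosen_k": self.chosen_k,
            "seed": self.seed,
            "editor": self.editor,
            "scope": self.scope,
            "pre_counts": list(self.pre_counts),
            "post_smote_counts": list(self.post_smote_counts),
            "post_counts": list(self.post_counts),
            "per_cluster_pre": [list(c) for c in self.per_cluster_pre],
            "per_cluster_post": [list(c) for c in self.per_cluster_post],
            "removed_by_editing": self.removed_by_editing,
            "ratio_warning": self.ratio_warning,
            "elbow_ssds": [float(s) for s in self.elbow.ssds] if self.elbow else None,
        }


_EDITORS = {"enn": enn_clean, "knn": knn_clean}

#: widest acceptable post-balancing majority/minority ratio
BALANCE_TOLERANCE = 1.25


def cluster_balance(
    train: LabeledTable,
    editor: str = "enn",
    cfg: ResampleConfig = ResampleConfig(),
    k_max: int = 10,
    scope: str = "per_cluster",
    restarts: int = 5,
) -> tuple[LabeledTable, BalanceReport]:
    """Balance a training table cluster-wise; see module docstring.

    Returns the merged balanced table and a :class:`BalanceReport` carrying
    per-cluster counts and, for every synthetic row, the generating minority
    pair (as row indices into ``train``) and its cluster.
    """
    if editor not in _EDITORS:
        raise ClusterError(f"editor must be one of {sorted(_EDITORS)}")
    if scope not in ("per_cluster", "global"):
        raise ClusterError("scope must be 'per_cluster' or 'global'")
    c0, c1 = train.class_counts
    if c0 == 0 or c1 == 0:
        raise ClusterError("training table must contain both classes")

    scan = elbow_k(train.X, k_max=k_max, seed=cfg.seed, restarts=restarts)
    km = kmeans(train.X, scan.chosen_k, seed=cfg.seed, restarts=restarts)

    edit = _EDITORS[editor]
    pieces: list[LabeledTable] = []
    pre_counts, post_counts = [], []
    prov_a, prov_b, prov_lam, prov_cl = [], [], [], []
    post_smote_total = np.zeros(2, int)

    for cl in range(km.k):
        rows = np.flatnonzero(km.assignments == cl)
        sub = train.subset(rows)
        s0, s1 = sub.class_counts
        pre_counts.append((s0, s1))
        local_min = min(s0, s1)
        local_maj = max(s0, s1)
        if local_min >= 2 and local_maj > local_min:
            boosted, prov = smote(
                sub, replace(cfg, seed=cfg.seed + cl + 1), return_provenance=True
            )
            prov_a.append(rows[prov.parent_a])
            prov_b.append(rows[prov.parent_b])
            prov_lam.append(prov.lam)
            prov_cl.append(np.full(prov.lam.size, cl))
        else:
            boosted = sub  # too few minority rows (or single class): pass through
        post_smote_total += np.array(boosted.class_counts)
        if scope == "per_cluster" and boosted.n > cfg.editing_k(editor):
            cleaned = edit(boosted, cfg)
        else:
            cleaned = boosted
        post_counts.append(cleaned.class_counts)
        pieces.append(cleaned)

    merged = LabeledTable(
        np.vstack([p.X for p in pieces]),
        np.concatenate([p.y for p in pieces]),
        train.schema,
    )
    if scope == "global":
        merged = edit(merged, cfg)
        post_counts = [merged.class_counts]

    n_removed = int(post_smote_total.sum() - merged.n)
    m0, m1 = merged.class_counts
    ratio = max(m0, m1) / max(min(m0, m1), 1)
    ratio_warning = ratio > BALANCE_TOLERANCE
    if ratio_warning:
        warnings.warn(
            f"post-balancing class ratio {ratio:.2f} exceeds {BALANCE_TOLERANCE}",
            stacklevel=2,
        )

    prov = SmoteProvenance(
        np.concatenate(prov_a) if prov_a else np.empty(0, int),
        np.concatenate(prov_b) if prov_b else np.empty(0, int),
        np.concatenate(prov_lam) if prov_lam else np.empty(0),
    )
    report = BalanceReport(
        chosen_k=scan.chosen_k,
        seed=cfg.seed,
        editor=editor,
        scope=scope,
        pre_counts=(c0, c1),
        post_counts=(m0, m1),
        per_cluster_pre=pre_counts,
        per_cluster_post=post_counts,
        removed_by_editing=n_removed,
        post_smote_counts=(int(post_smote_total[0]), int(post_smote_total[1])),
        ratio_warning=ratio_warning,
        elbow=scan,
        provenance=prov,
        provenance_clusters=np.concatenate(prov_cl) if prov_cl else np.empty(0, int),
    )
    return merged, report


def plot_elbow(scan: ElbowScan, ax=None):
    """SSD-vs-k curve with the chosen elbow marked (matplotlib Axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(scan.ks, scan.ssds, marker="o")
    ax.axvline(scan.chosen_k, linestyle="--", color="grey")
    ax.set_xlabel("k")
    ax.set_ylabel("within-cluster SSD")
    ax.set_title(f"elbow scan (chosen k = {scan.chosen_k})")
    return ax
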
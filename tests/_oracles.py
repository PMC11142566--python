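"""Exhaustive-scan reference implementations used only as test oracles.

Everything here is written in the most literal way possible (python sorts,
explicit loops) and shares no code path with the package.
"""

import numpy as np


def pairwise_sq(A, B):
    return ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)


def brute_knn(X, queries, k, exclude_self=False):
    """Neighbour lists by explicit (distance, index) python sort."""
    D = np.sqrt(pairwise_sq(np.asarray(queries, float), np.asarray(X, float)))
    out = []
    for i in range(D.shape[0]):
        cand = [(D[i, j], j) for j in range(D.shape[1]) if not (exclude_self and j == i)]
        cand.sort()
        out.append([j for _, j in cand[:k]])
    return np.array(out)


def brute_edit(X, y, k):
    """Row indices kept by the disagreement-deletion rule (simultaneous)."""
    nn = brute_knn(X, X, k, exclude_self=True)
    keep = []
    for i in range(len(y)):
        labels = [y[j] for j in nn[i]]
        disagree = sum(1 for l in labels if l != y[i])
        if not disagree * 2 > k:
            keep.append(i)
    return np.array(keep, int)


def brute_nearmiss(X, y, n_ref=3):
    """Majority row indices kept by NearMiss-1 (mean distance to the n_ref
    nearest minority rows, smallest first, ties to lower index)."""
    y = np.asarray(y)
    min_label = 1 if (y == 1).sum() <= (y == 0).sum() else 0
    min_idx = [i for i in range(len(y)) if y[i] == min_label]
    maj_idx = [i for i in range(len(y)) if y[i] != min_label]
    if len(maj_idx) <= len(min_idx):
        return np.array(sorted(maj_idx), int)
    D = np.sqrt(pairwise_sq(np.asarray(X, float), np.asarray(X, float)))
    scored = []
    for pos, i in enumerate(maj_idx):
        dists = sorted(D[i, j] for j in min_idx)[: min(n_ref, len(min_idx))]
        scored.append((sum(dists) / len(dists), pos, i))
    scored.sort()
    kept = sorted(i for _, _, i in scored[: len(min_idx)])
    return np.array(kept, int)


def rank_sum_auc(y, scores):
    """AUC as the normalized Mann-Whitney U statistic (midranks for ties)."""
    from scipy.stats import mannwhitneyu

    y = np.asarray(y)
    pos = np.asarray(scores)[y == 1]
    neg = np.asarray(scores)[y == 0]
    u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return u / (len(pos) * len(neg))
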
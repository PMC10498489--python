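"""Cluster-aware splitting, balanced undersampling and nearest-neighbour checks.

The train/test split respects chemical-series structure: compounds are
first clustered by affinity propagation on a Tanimoto similarity matrix,
then sampled within each cluster so that roughly 70% of every cluster
lands in the training set (proportionate stratified sampling). A
nearest-neighbour concordance table between the two sets diagnoses
whether the split preserved structure–activity consistency.

Balanced undersampling deletes majority-class (inactive) compounds until
the classes are even, removing them proportionally across k-means
structural clusters so every chemotype keeps representatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AffinityPropagation, KMeans

from .chemistry import bulk_tanimoto

__all__ = [
    "SplitResult",
    "cluster_structures",
    "stratified_split",
    "balanced_undersample",
    "nearest_neighbor_table",
    "confusion_percentages",
]


@dataclass
class SplitResult:
    train_ids: list
    test_ids: list
    cluster_labels: dict
    method: str
    seed: int


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_structures(
    fingerprints: np.ndarray,
    damping: float = 0.9,
    preference: "float | None" = None,
    seed: int = 0,
    max_iter: int = 500,
) -> np.ndarray:
    """Affinity-propagation clustering on the Tanimoto similarity matrix.

    The preference defaults to the median pairwise similarity. Libraries
    with duplicate structures produce exactly tied similarities on which
    the message passing can oscillate indefinitely, so a tiny seeded
    symmetric jitter (1e-6, far below any meaningful Tanimoto difference)
    is added to break ties deterministically. On non-convergence the
    damping is raised stepwise towards 0.99 before giving up.
    """
    fps = np.asarray(fingerprints)
    if len(fps) < 2:
        raise ValueError("need at least 2 compounds to cluster")
    sim = bulk_tanimoto(fps, fps)
    if preference is None:
        preference = float(np.median(sim))
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-1e-6, 1e-6, size=sim.shape)
    sim = sim + (jitter + jitter.T) / 2

    for damp in (damping, 0.95, 0.99):
        if damp < damping:
            continue
        ap = AffinityPropagation(
            affinity="precomputed",
            damping=damp,
            preference=preference,
            max_iter=max_iter,
            random_state=seed,
        )
        labels = ap.fit_predict(sim)
        if ap.n_iter_ < max_iter and len(ap.cluster_centers_indices_) > 0:
            return labels
    raise RuntimeError("affinity propagation failed to converge up to damping 0.99")


# ---------------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------------

def stratified_split(
    ids: "list | np.ndarray",
    cluster_labels: "list | np.ndarray",
    train_frac: float = 0.70,
    seed: int = 0,
) -> SplitResult:
    """Proportionate stratified random sampling of a train set by cluster.

    Within each cluster, ``floor(train_frac * size)`` compounds are drawn
    to train, then clusters with the largest fractional remainders receive
    one extra until the global training count reaches
    ``round(train_frac * n)``. Singleton clusters are assigned wholly to
    train (there is nothing representative to hold out from them).
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0,1), got {train_frac}")
    ids = np.asarray(ids)
    labels = np.asarray(cluster_labels)
    if len(ids) != len(labels):
        raise ValueError("ids and cluster_labels must align")
    rng = np.random.default_rng(seed)

    clusters = {}
    for cid in np.unique(labels):
        members = ids[labels == cid]
        clusters[cid] = members

    target_total = int(round(train_frac * len(ids)))
    base, remainders = {}, {}
    for cid, members in clusters.items():
        if len(members) == 1:
            base[cid] = 1
            remainders[cid] = -1.0  # never topped up
            continue
        exact = train_frac * len(members)
        base[cid] = int(np.floor(exact))
        remainders[cid] = exact - base[cid]

    shortfall = target_total - sum(base.values())
    order = sorted(clusters, key=lambda c: (-remainders[c], c))
    for cid in order:
        if shortfall <= 0:
            break
        if remainders[cid] < 0 or base[cid] >= len(clusters[cid]):
            continue
        base[cid] += 1
        shortfall -= 1

    train_ids: list = []
    for cid in sorted(clusters):
        members = np.sort(clusters[cid])
        take = min(base[cid], len(members))
        picked = rng.choice(members, size=take, replace=False)
        train_ids.extend(picked.tolist())

    train_set = set(train_ids)
    test_ids = [i for i in ids.tolist() if i not in train_set]
    return SplitResult(
        train_ids=sorted(train_ids),
        test_ids=sorted(test_ids),
        cluster_labels={i: int(c) for i, c in zip(ids.tolist(), labels.tolist())},
        method="affinity-propagation+stratified",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# balanced undersampling
# ---------------------------------------------------------------------------

def balanced_undersample(
    records: pd.DataFrame,
    fingerprints: np.ndarray,
    label_col: str = "label",
    n_structural_clusters: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Delete majority-class compounds until both classes are equal in number.

    The majority class is undersampled proportionally across k-means
    structural clusters of its fingerprints, so each chemotype keeps a
    representative share. The result has exactly ``2 * minority count``
    rows and is a row subset of the input.
    """
    labels = records[label_col].to_numpy()
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present for undersampling")
    minority, majority = classes[np.argmin(counts)], classes[np.argmax(counts)]
    n_min = int(counts.min())
    if counts.min() == counts.max():
        return records.copy()

    maj_mask = labels == majority
    maj_idx = np.flatnonzero(maj_mask)
    fps_maj = np.asarray(fingerprints, dtype=np.float64)[maj_idx]

    k = min(n_structural_clusters, len(maj_idx))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    maj_clusters = km.fit_predict(fps_maj)

    # proportional keep quota per structural cluster (largest remainder)
    rng = np.random.default_rng(seed)
    sizes = np.bincount(maj_clusters, minlength=k)
    exact = sizes * (n_min / len(maj_idx))
    quota = np.floor(exact).astype(int)
    rest = n_min - quota.sum()
    for c in np.argsort(-(exact - quota))[:rest]:
        quota[c] += 1

    keep_maj: list[int] = []
    for c in range(k):
        members = maj_idx[maj_clusters == c]
        take = min(quota[c], len(members))
        keep_maj.extend(rng.choice(members, size=take, replace=False).tolist())
    # top up if some cluster was smaller than its quota
    if len(keep_maj) < n_min:
        pool = np.setdiff1d(maj_idx, keep_maj)
        extra = rng.choice(pool, size=n_min - len(keep_maj), replace=False)
        keep_maj.extend(extra.tolist())

    keep = np.sort(np.concatenate([np.flatnonzero(~maj_mask), np.array(keep_maj, dtype=int)]))
    return records.iloc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# nearest-neighbour diagnostics
# ---------------------------------------------------------------------------

def nearest_neighbor_table(
    test_fps: np.ndarray,
    test_labels: "np.ndarray | list",
    train_fps: np.ndarray,
    train_labels: "np.ndarray | list",
) -> np.ndarray:
    """2x2 counts of (test label) x (nearest training neighbour label).

    Rows: test compound active / inactive; columns: neighbour active /
    inactive. Nearest-neighbour ties resolve to the lowest train index.
    """
    if len(train_fps) == 0:
        raise ValueError("empty training set")
    test_labels = np.asarray(test_labels, dtype=bool)
    train_labels = np.asarray(train_labels, dtype=bool)
    sim = bulk_tanimoto(np.asarray(test_fps), np.asarray(train_fps))
    nn = sim.argmax(axis=1)  # argmax takes the lowest index on ties
    nn_active = train_labels[nn]

    table = np.zeros((2, 2), dtype=int)
    for t, n in zip(test_labels, nn_active):
        table[0 if t else 1, 0 if n else 1] += 1
    return table


def confusion_percentages(matrix: "np.ndarray | tuple") -> dict:
    """Percentages of the NN concordance table cells over the grand total.

    Input order: (active/active, active/inactive, inactive/active,
    inactive/inactive) or the equivalent 2x2 array. Values are rounded to
    2 decimals for reporting.
    """
    m = np.asarray(matrix, dtype=float).reshape(2, 2)
    total = m.sum()
    if total <= 0:
        raise ValueError("empty table")
    pct = m / total * 100.0
    return {
        "concordant": round(float(pct[0, 0] + pct[1, 1]), 2),
        "active_with_inactive_nn": round(float(pct[0, 1]), 2),
        "inactive_with_active_nn": round(float(pct[1, 0]), 2),
    }
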
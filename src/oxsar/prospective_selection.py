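"""Reference chemical space and budgeted prospective compound selection.

A reference chemical space is built once from a curated reference
collection: fingerprint bits are centred and scaled to unit variance
(constant bits dropped), projected onto the first two principal
components, and the 2D scores clustered with k-means (k = 6, k-means++
initialization, best of 100 restarts). Any compound can then be
projected into the space and assigned the nearest of the six centroids.

Screening compounds are classified as similar (max Tc >= 0.7 to the
training set) or dissimilar (max Tc <= 0.3); the intermediate band is
excluded. Candidates must pass a concordance/AD filter whose thresholds
depend on the (similarity, predicted activity) category — 70%/70% for
similar actives, 80%/80% for dissimilar actives, 90%/90% for similar
inactives and 100%/100% for dissimilar inactives, reflecting the higher
prior odds of inactivity. Survivors are grouped by similarity class x
predicted activity x space cluster (up to 24 groups) and each group is
capped at 25 compounds via 5 k-means subclusters contributing 5
compounds each (nearest to the subcentroid).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .chemistry import max_tanimoto

__all__ = [
    "ReferenceSpace",
    "CONCORDANCE_THRESHOLDS",
    "build_reference_space",
    "similarity_class",
    "subsample_dissimilar",
    "concordance_filter",
    "capped_group_selection",
    "assemble_validation_set",
]

#: (similarity class, predicted activity) -> (min concordance fraction, min AD fraction)
CONCORDANCE_THRESHOLDS: dict[tuple[str, str], tuple[float, float]] = {
    ("similar", "active"): (0.70, 0.70),
    ("dissimilar", "active"): (0.80, 0.80),
    ("similar", "inactive"): (0.90, 0.90),
    ("dissimilar", "inactive"): (1.00, 1.00),
}


# ---------------------------------------------------------------------------
# reference space
# ---------------------------------------------------------------------------

@dataclass
class ReferenceSpace:
    """Frozen projection: per-bit scaler, 2 PCA loadings, 6 centroids."""

    kept_bits: np.ndarray       # indices of non-constant fingerprint bits
    mean: np.ndarray            # per-kept-bit mean
    scale: np.ndarray           # per-kept-bit standard deviation
    basis: np.ndarray           # (2, n_kept) orthonormal loadings
    centroids: np.ndarray       # (k, 2)
    seed: int

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def project(self, fingerprints: np.ndarray) -> pd.DataFrame:
        """Project fingerprints to (pc1, pc2, cluster); ties to the lowest index."""
        fps = np.asarray(fingerprints, dtype=float)
        if fps.ndim != 2 or fps.shape[1] <= self.kept_bits.max():
            raise ValueError("fingerprint spec does not match the reference space")
        if len(fps) == 0:
            return pd.DataFrame(columns=["pc1", "pc2", "cluster"])
        Xs = (fps[:, self.kept_bits] - self.mean) / self.scale
        scores = Xs @ self.basis.T
        d2 = ((scores[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        clusters = d2.argmin(axis=1)  # argmin resolves ties to the lowest cluster
        return pd.DataFrame({"pc1": scores[:, 0], "pc2": scores[:, 1], "cluster": clusters})

    def to_json(self, path) -> None:
        payload = {
            "kept_bits": self.kept_bits.tolist(),
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "basis": self.basis.tolist(),
            "centroids": self.centroids.tolist(),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ReferenceSpace":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            kept_bits=np.asarray(d["kept_bits"], dtype=int),
            mean=np.asarray(d["mean"]),
            scale=np.asarray(d["scale"]),
            basis=np.asarray(d["basis"]),
            centroids=np.asarray(d["centroids"]),
            seed=int(d["seed"]),
        )


def build_reference_space(
    reference_fps: np.ndarray, k: int = 6, restarts: int = 100, seed: int = 0
) -> ReferenceSpace:
    """PCA(2) + k-means(k) reference chemical space from reference fingerprints.

    Constant bits are dropped before unit-variance scaling; k-means uses
    k-means++ initialization and keeps the best of ``restarts`` runs by
    inertia.
    """
    fps = np.asarray(reference_fps, dtype=float)
    if len(fps) < k:
        raise ValueError(f"need at least k={k} compounds")
    variable = fps.std(axis=0) > 0
    if variable.sum() < 2:
        raise ValueError("fingerprint matrix has rank < 2 after dropping constant bits")
    kept = np.flatnonzero(variable)
    sub = fps[:, kept]
    mean, scale = sub.mean(axis=0), sub.std(axis=0)
    Xs = (sub - mean) / scale

    pca = PCA(n_components=2, random_state=seed)
    scores = pca.fit_transform(Xs)
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    km.fit(scores)
    # stable cluster numbering: order centroids by (pc1, pc2)
    order = np.lexsort((km.cluster_centers_[:, 1], km.cluster_centers_[:, 0]))
    return ReferenceSpace(
        kept_bits=kept,
        mean=mean,
        scale=scale,
        basis=pca.components_,
        centroids=km.cluster_centers_[order],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# similarity classes and subsampling
# ---------------------------------------------------------------------------

def similarity_class(
    fps: np.ndarray, training_fps: np.ndarray, similar_cut: float = 0.7, dissimilar_cut: float = 0.3
) -> pd.DataFrame:
    """Classify compounds by max Tanimoto to the training set.

    Returns columns ``max_tc`` and ``sim_class`` in
    {similar, dissimilar, excluded}; the open interval between the cuts
    is excluded.
    """
    if len(training_fps) == 0:
        raise ValueError("empty training set")
    if len(fps) == 0:
        return pd.DataFrame(columns=["max_tc", "sim_class"])
    mx, _ = max_tanimoto(np.asarray(fps), np.asarray(training_fps))
    cls = np.where(mx >= similar_cut, "similar", np.where(mx <= dissimilar_cut, "dissimilar", "excluded"))
    return pd.DataFrame({"max_tc": mx, "sim_class": cls})


def subsample_dissimilar(ids: "list | np.ndarray", n: int = 20000, seed: int = 0) -> np.ndarray:
    """Uniform without-replacement subsample of ids (identity when n >= len)."""
    ids = np.asarray(ids)
    if n >= len(ids):
        return ids.copy()
    rng = np.random.default_rng(seed)
    return rng.choice(ids, size=n, replace=False)


# ---------------------------------------------------------------------------
# concordance filter
# ---------------------------------------------------------------------------

def concordance_filter(
    labels_active: "np.ndarray | list",
    in_ad: "np.ndarray | list",
    sim_class: str,
    predicted_activity: str,
    thresholds: dict = CONCORDANCE_THRESHOLDS,
) -> bool:
    """Pass/fail for one compound given its per-model votes and AD flags.

    ``labels_active`` are the boolean votes of all models; concordance is
    the fraction voting for ``predicted_activity``, and the AD fraction is
    over all models. Both must reach the category's thresholds.
    """
    votes = np.asarray(labels_active, dtype=bool)
    ad = np.asarray(in_ad, dtype=bool)
    if votes.size == 0:
        raise ValueError("no model votes")
    conc_thr, ad_thr = thresholds[(sim_class, predicted_activity)]
    agree = votes.mean() if predicted_activity == "active" else 1.0 - votes.mean()
    return bool(agree >= conc_thr and ad.mean() >= ad_thr)


# ---------------------------------------------------------------------------
# capped group selection
# ---------------------------------------------------------------------------

def capped_group_selection(
    member_ids: "np.ndarray | list",
    member_fps: np.ndarray,
    cap: int = 25,
    n_subclusters: int = 5,
    per_subcluster: int = 5,
    seed: int = 0,
) -> list:
    """Budgeted pick from one selection group.

    Groups below the cap are taken whole. Larger groups are split into
    ``n_subclusters`` k-means subclusters on their fingerprints and each
    contributes its ``per_subcluster`` members nearest to the subcentroid
    (all of them when smaller), deterministically.
    """
    ids = np.asarray(member_ids)
    if len(ids) == 0:
        return []
    if len(ids) < cap:
        return ids.tolist()
    fps = np.asarray(member_fps, dtype=float)
    km = KMeans(n_clusters=n_subclusters, n_init=10, random_state=seed)
    sub = km.fit_predict(fps)
    selected: list = []
    for c in range(n_subclusters):
        members = np.flatnonzero(sub == c)
        if members.size == 0:
            continue
        d = np.linalg.norm(fps[members] - km.cluster_centers_[c], axis=1)
        order = members[np.lexsort((ids[members].astype(str), d))]
        selected.extend(ids[order[:per_subcluster]].tolist())
    return selected


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def assemble_validation_set(
    screening: pd.DataFrame,
    screening_fps: np.ndarray,
    space: ReferenceSpace,
    training_fps: np.ndarray,
    model_predictions: "dict[str, tuple]",
    subsample_n: int = 20000,
    cap: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end prospective selection over a screening library.

    ``model_predictions`` maps model name -> (labels_active, in_ad) arrays
    aligned with ``screening``. Steps: similarity classification against
    the training set; random subsampling of the dissimilar class to
    ``subsample_n``; projection into the reference space; per-compound
    consensus label (simple majority of votes, ties active); concordance/AD
    filtering per category; grouping into (similarity x activity x cluster)
    groups; capped per-group selection.

    Returns ``(selection, groups)``: the flat per-compound selection table
    and the per-group summary (members vs selected counts).
    """
    screening = screening.reset_index(drop=True)
    fps = np.asarray(screening_fps)
    simcls = similarity_class(fps, training_fps)

    keep = simcls["sim_class"].to_numpy() != "excluded"
    dis = np.flatnonzero(simcls["sim_class"].to_numpy() == "dissimilar")
    if len(dis) > subsample_n:
        keep_dis = set(subsample_dissimilar(dis, subsample_n, seed=seed).tolist())
        dis_set = set(dis.tolist())
        keep &= np.array(
            [(i not in dis_set) or (i in keep_dis) for i in range(len(screening))]
        )

    idx = np.flatnonzero(keep)
    proj = space.project(fps[idx])

    votes = {name: (np.asarray(lab, dtype=bool)[idx], np.asarray(ad, dtype=bool)[idx])
             for name, (lab, ad) in model_predictions.items()}
    n_models = len(votes)
    vote_matrix = np.vstack([lab for lab, _ in votes.values()])
    ad_matrix = np.vstack([ad for _, ad in votes.values()])
    frac_active = vote_matrix.mean(axis=0)
    predicted = np.where(frac_active >= 0.5, "active", "inactive")
    concord = np.where(predicted == "active", frac_active, 1.0 - frac_active)
    ad_frac = ad_matrix.mean(axis=0)

    table = pd.DataFrame({
        "compound_id": screening.loc[idx, "compound_id"].to_numpy(),
        "sim_class": simcls.loc[idx, "sim_class"].to_numpy(),
        "max_tc": simcls.loc[idx, "max_tc"].to_numpy(),
        "cluster": proj["cluster"].to_numpy(),
        "pc1": proj["pc1"].to_numpy(),
        "pc2": proj["pc2"].to_numpy(),
        "predicted_activity": predicted,
        "concordance": concord,
        "ad_fraction": ad_frac,
        "_row": idx,
    })

    passes = np.array([
        concordance_filter(vote_matrix[:, i], ad_matrix[:, i], sc, pa)
        for i, (sc, pa) in enumerate(zip(table["sim_class"], table["predicted_activity"]))
    ])
    table = table[passes].reset_index(drop=True)

    group_rows, selected_frames = [], []
    for (sc, pa, cl), grp in table.groupby(["sim_class", "predicted_activity", "cluster"], sort=True):
        chosen = capped_group_selection(
            grp["compound_id"].to_numpy(), fps[grp["_row"].to_numpy()], cap=cap, seed=seed
        )
        group_rows.append({
            "sim_class": sc, "predicted_activity": pa, "cluster": int(cl),
            "n_members": len(grp), "n_selected": len(chosen),
        })
        sel = grp[grp["compound_id"].isin(chosen)].copy()
        selected_frames.append(sel)

    groups = pd.DataFrame(group_rows)
    selection = (
        pd.concat(selected_frames, ignore_index=True).drop(columns="_row")
        if selected_frames
        else table.head(0).drop(columns="_row")
    )
    return selection, groups
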
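"""Confusion-based metrics, AD coverage, stratified scoring and error census.

Metrics are computed over in-applicability-domain compounds only: a
conformal model that abstains on a compound (non-singleton prediction
set) is neither rewarded nor punished for it, and the abstention rate is
reported separately as AD coverage. MCC uses the zero-denominator
convention (any zero factor => MCC = 0), which keeps one-class strata
well defined; balanced accuracy is undefined (NaN) when a class is
absent from the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemistry import bulk_tanimoto

__all__ = [
    "MetricsReport",
    "confusion",
    "metrics",
    "stratified_metrics",
    "misprediction_census",
    "inactive_active_ratio",
]


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sn: float
    sp: float
    acc: float
    bacc: float
    mcc: float
    ad_coverage: float = 1.0
    slice_name: str = "all"

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "SN": self.sn, "SP": self.sp, "ACC": self.acc, "BACC": self.bacc,
            "AD": self.ad_coverage, "MCC": self.mcc, "slice": self.slice_name,
        }


def confusion(
    y_true: "np.ndarray | list",
    y_pred: "np.ndarray | list",
    in_ad: "np.ndarray | list | None" = None,
) -> tuple[int, int, int, int, float]:
    """Confusion counts over in-AD items plus the AD coverage fraction."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if in_ad is None:
        in_ad = np.ones_like(y_true, dtype=bool)
    in_ad = np.asarray(in_ad, dtype=bool)
    if in_ad.shape != y_true.shape:
        raise ValueError("in_ad length differs")

    t, p = y_true[in_ad], y_pred[in_ad]
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    fn = int(np.sum(t & ~p))
    coverage = float(in_ad.mean()) if len(in_ad) else 0.0
    return tp, fp, tn, fn, coverage


def metrics(tp: int, fp: int, tn: int, fn: int, ad_coverage: float = 1.0, slice_name: str = "all") -> MetricsReport:
    """Standard binary-classification metrics from confusion counts.

    SN = tp/(tp+fn), SP = tn/(tn+fp), ACC, BACC = (SN+SP)/2 and MCC.
    A zero factor in the MCC denominator yields MCC = 0; SN/SP are 0.0
    when their denominator is empty, and BACC is NaN when a truth class
    is absent.
    """
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    sn = tp / (tp + fn) if (tp + fn) else 0.0
    sp = tn / (tn + fp) if (tn + fp) else 0.0
    acc = (tp + tn) / total
    bacc = (sn + sp) / 2 if (tp + fn) and (tn + fp) else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return MetricsReport(tp, fp, tn, fn, float(sn), float(sp), float(acc), float(bacc), float(mcc), ad_coverage, slice_name)


def score_predictions(
    y_true, y_pred, in_ad=None, slice_name: str = "all"
) -> MetricsReport:
    """Convenience: confusion + metrics in one call."""
    tp, fp, tn, fn, cov = confusion(y_true, y_pred, in_ad)
    if tp + fp + tn + fn == 0:
        return MetricsReport(0, 0, 0, 0, 0.0, 0.0, float("nan"), float("nan"), 0.0, cov, slice_name)
    return metrics(tp, fp, tn, fn, cov, slice_name)


# ---------------------------------------------------------------------------
# stratified evaluation
# ---------------------------------------------------------------------------

def stratified_metrics(
    y_true: "np.ndarray | list",
    predictions: "dict[str, tuple]",
    strata: "np.ndarray | list",
) -> pd.DataFrame:
    """Per-stratum mean +/- sd of each metric across models.

    ``predictions`` maps model name -> (y_pred, in_ad) with in_ad possibly
    None. Returns one row per stratum with mean and sd columns for
    SN/SP/ACC/BACC/MCC and for the in-AD active/inactive counts. Strata
    where BACC is undefined for every model report NaN means (rendered NA).
    """
    y_true = np.asarray(y_true, dtype=bool)
    strata = np.asarray(strata)
    rows = []
    for stratum in pd.unique(strata):
        mask = strata == stratum
        per_model = []
        for name, (y_pred, in_ad) in predictions.items():
            y_pred = np.asarray(y_pred, dtype=bool)
            ad = np.ones(mask.sum(), dtype=bool) if in_ad is None else np.asarray(in_ad, dtype=bool)[mask]
            rep = score_predictions(y_true[mask], y_pred[mask], ad, slice_name=str(stratum))
            n_act = int(np.sum(y_true[mask] & ad))
            n_inact = int(np.sum(~y_true[mask] & ad))
            per_model.append((rep, n_act, n_inact))
        def agg(vals):
            arr = np.asarray(vals, dtype=float)
            if np.all(np.isnan(arr)):
                return float("nan"), float("nan")
            return float(np.nanmean(arr)), float(np.nanstd(arr))
        row = {"stratum": stratum, "n": int(mask.sum())}
        for key, getter in [
            ("SN", lambda r: r[0].sn), ("SP", lambda r: r[0].sp), ("ACC", lambda r: r[0].acc),
            ("BACC", lambda r: r[0].bacc), ("MCC", lambda r: r[0].mcc),
            ("n_actives", lambda r: r[1]), ("n_inactives", lambda r: r[2]),
        ]:
            mean, sd = agg([getter(pm) for pm in per_model])
            row[f"{key}_mean"], row[f"{key}_sd"] = mean, sd
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# error census
# ---------------------------------------------------------------------------

def misprediction_census(
    y_true: "np.ndarray | list",
    predictions: "dict[str, np.ndarray]",
    compound_ids: "np.ndarray | list",
    test_fps: "np.ndarray | None" = None,
    train_fps: "np.ndarray | None" = None,
    train_ids: "np.ndarray | list | None" = None,
    train_zscores: "np.ndarray | list | None" = None,
    top_n: int = 5,
    n_neighbors: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count erroneous model predictions per compound; profile the worst offenders.

    Returns ``(census, neighbours)``: the census has one row per test
    compound with its error count in [0, n_models]; for the ``top_n``
    compounds with the most consensual mispredictions, the five most
    similar training compounds are listed with their Tanimoto similarity
    (descending; ties by id) and response Z-scores when provided.
    """
    y_true = np.asarray(y_true, dtype=bool)
    ids = np.asarray(compound_ids)
    errors = np.zeros(len(y_true), dtype=int)
    for y_pred in predictions.values():
        errors += (np.asarray(y_pred, dtype=bool) != y_true).astype(int)
    census = pd.DataFrame(
        {"compound_id": ids, "n_errors": errors, "n_models": len(predictions), "label_active": y_true}
    ).sort_values(["n_errors", "compound_id"], ascending=[False, True]).reset_index(drop=True)

    if test_fps is None or train_fps is None or train_ids is None:
        return census, pd.DataFrame()

    train_ids = np.asarray(train_ids)
    zs = None if train_zscores is None else np.asarray(train_zscores, dtype=float)
    worst = census.head(top_n)["compound_id"].to_numpy()
    pos = {cid: i for i, cid in enumerate(ids)}
    neigh_rows = []
    sim = bulk_tanimoto(np.asarray(test_fps)[[pos[c] for c in worst]], np.asarray(train_fps))
    for r, cid in enumerate(worst):
        order = sorted(range(sim.shape[1]), key=lambda j: (-sim[r, j], str(train_ids[j])))
        for rank, j in enumerate(order[:n_neighbors], start=1):
            neigh_rows.append({
                "compound_id": cid, "rank": rank, "neighbor_id": train_ids[j],
                "tanimoto": float(sim[r, j]),
                "neighbor_zscore": float(zs[j]) if zs is not None else float("nan"),
            })
    return census, pd.DataFrame(neigh_rows)


def select_models(
    metrics_table: pd.DataFrame,
    min_sn: float = 0.50,
    min_sp: float = 0.50,
    max_models: int = 11,
    min_models: int = 3,
) -> list[str]:
    """Pick the models worth carrying into prospective prediction.

    Models with sensitivity or specificity below 0.50 are disregarded; the
    survivors are ranked by MCC and capped at ``max_models``. If fewer than
    ``min_models`` survive the hard filter, the top MCC models are taken
    instead so a consensus remains possible.
    """
    df = metrics_table.sort_values("MCC", ascending=False)
    ok = df[(df["SN"] >= min_sn) & (df["SP"] >= min_sp)]
    if len(ok) < min_models:
        ok = df.head(min_models)
    return ok["model"].head(max_models).tolist()


def inactive_active_ratio(n_active: int, n_total: int, decimals: int = 2) -> float:
    """Inactive:active ratio of a tested set, e.g. 19 actives of 160 -> 7.42."""
    if not 0 < n_active <= n_total:
        raise ValueError("need 0 < n_active <= n_total")
    return round((n_total - n_active) / n_active, decimals)
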
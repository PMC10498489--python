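"""Train the model zoo and predict the holdout and screening sets.

Fits the full roster (forests, balanced forest, SVM, naive Bayes, kNN,
PLS, logistic, boosted trees, decision tree, conformal wrappers, and the
randomized-descriptor baseline) on the training split, then stores
per-compound predictions for the holdout test set and the screening
collection so the later stages are pure table operations.

Reads: results/curated.csv, results/split.json, results/screening.csv
Writes: results/test_predictions.csv, results/screening_predictions.csv
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from oxsar import chemistry as chem
from oxsar import model_zoo as mz

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

curated = pd.read_csv(args.out / "curated.csv")
with open(args.out / "split.json") as fh:
    split = json.load(fh)
train_mask = curated["compound_id"].isin(split["train_ids"]).to_numpy()
y = (curated["label"] == "active").to_numpy()

fp = chem.fingerprint_matrix(curated["smiles_std"], chem.FCFP6_2048).astype(float)
desc = chem.descriptor_table(curated["smiles_std"])
kept_cols = chem.prune_descriptors(desc.to_numpy())
desc = desc.iloc[:, kept_cols].to_numpy()
mean, sd = desc[train_mask].mean(axis=0), desc[train_mask].std(axis=0)
sd[sd == 0] = 1.0

reps_train = {"fingerprint": fp[train_mask], "physchem": (desc[train_mask] - mean) / sd}
suite = mz.fit_suite(reps_train, y[train_mask], seed=args.seed)

def predict_all(reps):
    rows = {}
    for name, member in suite.items():
        labels, in_ad = member.predict(reps)
        rows[f"{name}_label"] = labels.astype(int)
        rows[f"{name}_in_ad"] = in_ad.astype(int)
        rows[f"{name}_proba"] = member.predict_proba(reps)
    return pd.DataFrame(rows)

reps_test = {"fingerprint": fp[~train_mask], "physchem": (desc[~train_mask] - mean) / sd}
test_pred = predict_all(reps_test)
test_pred.insert(0, "compound_id", curated["compound_id"].to_numpy()[~train_mask])
test_pred.to_csv(args.out / "test_predictions.csv", index=False)

screening = pd.read_csv(args.out / "screening.csv")
scr_fp = chem.fingerprint_matrix(screening["smiles"], chem.FCFP6_2048).astype(float)
scr_desc = (chem.descriptor_table(screening["smiles"]).iloc[:, kept_cols].to_numpy() - mean) / sd
scr_pred = predict_all({"fingerprint": scr_fp, "physchem": scr_desc})
scr_pred.insert(0, "compound_id", screening["compound_id"])
scr_pred.to_csv(args.out / "screening_predictions.csv", index=False)

print(f"trained {len(suite)} models on {train_mask.sum()} compounds")
print(f"predicted {len(test_pred)} holdout and {len(scr_pred)} screening compounds")
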
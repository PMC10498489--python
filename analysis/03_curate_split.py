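"""Standardize structures, cluster the library and derive the 70/30 split.

Structures are neutralized/desalted, affinity propagation clusters the
feature-class fingerprints, and proportionate stratified sampling takes
~70% of every cluster into training. The nearest-neighbour concordance
table diagnoses whether the split preserves structure-activity
consistency.

Reads: results/library.csv, results/activity_calls.csv
Writes: results/curated.csv, results/split.json, results/nn_table.json
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from oxsar import chemistry as chem
from oxsar import dataset_split as ds

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

library = pd.read_csv(args.out / "library.csv")
calls = pd.read_csv(args.out / "activity_calls.csv")
curated = library.merge(calls[["compound_id", "median_zscore", "label"]], on="compound_id")

std, rejected = [], 0
for smi in curated["smiles"]:
    try:
        std.append(chem.standardize(smi))
    except chem.StandardizationError:
        std.append("")
        rejected += 1
curated["smiles_std"] = std
curated = curated[curated["smiles_std"] != ""].reset_index(drop=True)
curated["crippen_logp"] = [chem.crippen_logp(s) for s in curated["smiles_std"]]
curated.to_csv(args.out / "curated.csv", index=False)

fp_space = chem.fingerprint_matrix(curated["smiles_std"], chem.FCFP4_1024)
clusters = ds.cluster_structures(fp_space, seed=args.seed)
split = ds.stratified_split(curated["compound_id"].to_numpy(), clusters, 0.70, args.seed)
with open(args.out / "split.json", "w") as fh:
    json.dump({"train_ids": split.train_ids, "test_ids": split.test_ids,
               "cluster_labels": {k: int(v) for k, v in split.cluster_labels.items()}}, fh)

fp_model = chem.fingerprint_matrix(curated["smiles_std"], chem.FCFP6_2048)
train_mask = curated["compound_id"].isin(split.train_ids).to_numpy()
y = (curated["label"] == "active").to_numpy()
nn = ds.nearest_neighbor_table(fp_model[~train_mask], y[~train_mask],
                               fp_model[train_mask], y[train_mask])
pct = ds.confusion_percentages(nn)
with open(args.out / "nn_table.json", "w") as fh:
    json.dump({"counts": nn.tolist(), **pct}, fh, indent=2)

print(f"curated {len(curated)} compounds ({rejected} rejected)")
print(f"split: {len(split.train_ids)} train / {len(split.test_ids)} test "
      f"over {len(set(split.cluster_labels.values()))} clusters")
print(f"NN concordance {pct['concordant']:.2f}%; active-with-inactive-NN "
      f"{pct['active_with_inactive_nn']:.2f}%, inactive-with-active-NN "
      f"{pct['inactive_with_active_nn']:.2f}%")
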
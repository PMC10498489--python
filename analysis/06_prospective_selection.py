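"""Select a budgeted prospective validation set and test it in silico.

Builds the PCA + k-means(6) reference chemical space from the curated
library, classifies screening compounds by similarity to the training
set (Tc >= 0.7 similar / <= 0.3 dissimilar), filters by per-category
prediction concordance and applicability-domain inclusion (70/80/90/100%),
caps every (similarity x activity x cluster) group at 25 compounds via
5x5 subclustering, then "tests" the selected compounds against the
generator's latent-activity oracle and reports prospective performance
overall, per space cluster and per Crippen log P bin.

Reads: results/curated.csv, results/split.json, results/screening.csv,
       results/screening_predictions.csv, results/selected_models.json
Writes: results/reference_space.json, results/selection.csv,
        results/selection_groups.csv, results/prospective_metrics.csv,
        results/prospective_by_cluster.csv, results/prospective_by_logp.csv
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from oxsar import chemistry as chem
from oxsar import evaluation as ev
from oxsar import prospective_selection as ps
from oxsar import synthetic_data as sd

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

curated = pd.read_csv(args.out / "curated.csv")
with open(args.out / "split.json") as fh:
    split = json.load(fh)
with open(args.out / "selected_models.json") as fh:
    selected_models = json.load(fh)["selected"]
train_mask = curated["compound_id"].isin(split["train_ids"]).to_numpy()

fp_space = chem.fingerprint_matrix(curated["smiles_std"], chem.FCFP4_1024)
space = ps.build_reference_space(fp_space, k=6, restarts=100, seed=args.seed)
space.to_json(args.out / "reference_space.json")

screening = pd.read_csv(args.out / "screening.csv")
scr_pred = pd.read_csv(args.out / "screening_predictions.csv")
predictions = {
    m: (scr_pred[f"{m}_label"].to_numpy(dtype=bool), scr_pred[f"{m}_in_ad"].to_numpy(dtype=bool))
    for m in selected_models
}
scr_fp_space = chem.fingerprint_matrix(screening["smiles"], chem.FCFP4_1024)

selection, groups = ps.assemble_validation_set(
    screening, scr_fp_space, space, fp_space[train_mask], predictions, seed=args.seed
)
selection.to_csv(args.out / "selection.csv", index=False)
groups.to_csv(args.out / "selection_groups.csv", index=False)

# in-silico prospective validation against the latent-activity oracle
idx = screening.set_index("compound_id").index.get_indexer(selection["compound_id"])
smiles = screening["smiles"].to_numpy()[idx]
y_prosp = sd.assign_latent_activity(smiles, seed=args.seed + 7, label_noise=0.05)
prosp_preds = {m: (lab[idx], ad[idx]) for m, (lab, ad) in predictions.items()}

rows = []
for m, (lab, ad) in prosp_preds.items():
    rep = ev.score_predictions(y_prosp, lab, ad)
    rows.append({"model": m, **{k: v for k, v in rep.as_dict().items() if k != "slice"}})
prosp = pd.DataFrame(rows).sort_values("MCC", ascending=False).reset_index(drop=True)
prosp.to_csv(args.out / "prospective_metrics.csv", index=False)

by_cluster = ev.stratified_metrics(y_prosp, prosp_preds, selection["cluster"].to_numpy())
by_cluster.to_csv(args.out / "prospective_by_cluster.csv", index=False)
logp_bins = np.array([chem.logp_bin(chem.crippen_logp(s)) for s in smiles])
by_logp = ev.stratified_metrics(y_prosp, prosp_preds, logp_bins)
by_logp.to_csv(args.out / "prospective_by_logp.csv", index=False)

n_act = int(y_prosp.sum())
print(groups.to_string(index=False))
print(f"\nselected {len(selection)} compounds in {len(groups)} groups (cap 25)")
if 0 < n_act < len(y_prosp):
    print(f"prospective set: {n_act} actives / {len(y_prosp) - n_act} inactives "
          f"(1:{ev.inactive_active_ratio(n_act, len(y_prosp))})")
print(f"mean prospective MCC across models: {prosp['MCC'].mean():.3f}")
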
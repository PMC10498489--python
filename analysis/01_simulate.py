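"""Generate the synthetic study inputs.

Emulates the three data sources the analysis needs: a ~2,200-compound
drug-like library with ~14% oxidative-stress actives driven by planted
redox-alert substructures, triplicate reporter-plate readouts with QC
artifacts, and a 20,000-compound diverse screening collection containing
analogs of and chemotypes dissimilar to the library.

Writes: results/library.csv, results/wells.csv, results/artifact_truth.csv,
results/screening.csv
"""

import argparse
from pathlib import Path

from oxsar import synthetic_data as sd

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--n-compounds", type=int, default=2191)
parser.add_argument("--screening-n", type=int, default=20000)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

library = sd.generate_library(
    sd.SyntheticLibrarySpec(n_compounds=args.n_compounds, seed=args.seed)
)
wells, truth = sd.generate_well_data(
    library, library["latent_active"], sd.PlateSimSpec(seed=args.seed + 1)
)
screening = sd.generate_screening_library(
    args.screening_n, library, analog_fraction=0.3, seed=args.seed + 2
)

library.to_csv(args.out / "library.csv", index=False)
wells.to_csv(args.out / "wells.csv", index=False)
truth.to_csv(args.out / "artifact_truth.csv", index=False)
screening.to_csv(args.out / "screening.csv", index=False)

n_act = int(library["latent_active"].sum())
print(
    f"library: {len(library)} compounds, {n_act} latent actives "
    f"({n_act / max(len(library), 1):.1%}), {int(library['has_alert'].sum())} alert-bearing"
)
print(f"plates: {len(wells)} wells over {wells['replicate'].nunique()} replicates, "
      f"{(truth['artifact'] != 'none').sum()} artifact wells")
print(f"screening: {len(screening)} compounds")
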
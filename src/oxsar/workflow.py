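"""End-to-end pipeline orchestration from a single config.

Stages: simulate -> call-activity -> curate -> split -> train -> evaluate
-> select -> evaluate-prospective. Every stage consumes the serialized
outputs of earlier stages and writes its own artifacts into the run
directory; a JSON manifest records seeds and SHA-256 hashes of every
written file, so a rerun with the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemistry as chem
from . import dataset_split as ds
from . import evaluation as ev
from . import imaging_activity as ia
from . import model_zoo as mz
from . import prospective_selection as ps
from . import synthetic_data as sd

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Full configuration of one pipeline run; every stage seed is explicit."""

    seed: int = 0
    # library
    n_compounds: int = 2191
    active_fraction: float = 316 / 2191
    label_noise: float = 0.05
    # plates
    n_replicates: int = 3
    effect_size: float = 3.0
    artifact_rate: float = 0.02
    # split
    train_frac: float = 0.70
    # models
    significance: float = 0.25
    registry: "list[dict] | None" = None
    # screening / selection
    screening_n: int = 20000
    analog_fraction: float = 0.3
    subsample_n: int = 20000
    selection_cap: int = 25
    # per-stage seed offsets derived from the global seed
    stage_seeds: dict = field(default_factory=dict)

    def seed_for(self, stage: str) -> int:
        if stage in self.stage_seeds:
            return int(self.stage_seeds[stage])
        offset = {"simulate": 1, "plates": 2, "split": 3, "train": 4, "screening": 5, "select": 6, "prospective": 7}[stage]
        return (self.seed * 10007 + offset) % (2**31 - 1)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "seed" not in payload:
            raise ValueError("config must set an explicit 'seed'")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    def model_registry(self) -> list[mz.ModelConfig]:
        if self.registry is None:
            return mz.default_registry(self.significance)
        return [mz.ModelConfig(**entry) for entry in self.registry]


def _consensus(predictions: dict, members: list) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote consensus with abstention semantics.

    Out-of-AD members abstain from the vote; ties resolve to active. The
    consensus itself is in-AD when at least half of its members are.
    """
    vote_m = np.vstack([predictions[m][0] for m in members])
    ad_m = np.vstack([predictions[m][1] for m in members])
    n = vote_m.shape[1]
    labels = np.zeros(n, dtype=bool)
    for i in range(n):
        voting = ad_m[:, i]
        votes = vote_m[voting, i] if voting.any() else vote_m[:, i]
        labels[i] = votes.mean() >= 0.5
    in_ad = ad_m.mean(axis=0) >= 0.5
    return labels, in_ad


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest["files"][path.name] = _sha256(path)


def run_pipeline(config: RunConfig, outdir: "str | Path") -> dict:
    """Execute the whole analysis; returns (and writes) the run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    # -- simulate ----------------------------------------------------------
    lib_spec = sd.SyntheticLibrarySpec(
        n_compounds=config.n_compounds,
        active_fraction=config.active_fraction,
        label_noise=config.label_noise,
        seed=config.seed_for("simulate"),
    )
    library = sd.generate_library(lib_spec)
    plate_spec = sd.PlateSimSpec(
        n_replicates=config.n_replicates,
        effect_size=config.effect_size,
        artifact_rate=config.artifact_rate,
        seed=config.seed_for("plates"),
    )
    wells, artifact_truth = sd.generate_well_data(library, library["latent_active"], plate_spec)
    _write(library, out / "library.csv", manifest)
    _write(wells, out / "wells.csv", manifest)
    _write(artifact_truth, out / "artifact_truth.csv", manifest)
    manifest["stages"]["simulate"] = {"n_compounds": len(library), "n_wells": len(wells)}

    # -- call activity -----------------------------------------------------
    calls, not_evaluable = ia.call_activity_table(wells)
    _write(calls, out / "activity_calls.csv", manifest)
    manifest["stages"]["call_activity"] = {
        "n_called": len(calls),
        "n_active": int((calls["label"] == "active").sum()),
        "n_not_evaluable": len(not_evaluable),
    }

    # -- curate ------------------------------------------------------------
    curated = library.merge(calls[["compound_id", "median_zscore", "label"]], on="compound_id")
    std, reasons = [], []
    for smi in curated["smiles"]:
        try:
            std.append(chem.standardize(smi))
            reasons.append("")
        except chem.StandardizationError as err:
            std.append("")
            reasons.append(err.reason)
    curated["smiles_std"] = std
    curated = curated[curated["smiles_std"] != ""].reset_index(drop=True)
    curated["crippen_logp"] = [chem.crippen_logp(s) for s in curated["smiles_std"]]
    _write(curated, out / "curated.csv", manifest)
    manifest["stages"]["curate"] = {"n_curated": len(curated)}

    fp_model = chem.fingerprint_matrix(curated["smiles_std"], chem.FCFP6_2048)
    fp_space = chem.fingerprint_matrix(curated["smiles_std"], chem.FCFP4_1024)
    desc = chem.descriptor_table(curated["smiles_std"])
    kept_cols = chem.prune_descriptors(desc.to_numpy())
    desc_pruned = desc.iloc[:, kept_cols]
    y = (curated["label"] == "active").to_numpy()

    # -- split -------------------------------------------------------------
    clusters = ds.cluster_structures(fp_space, seed=config.seed_for("split"))
    split = ds.stratified_split(
        curated["compound_id"].to_numpy(), clusters, config.train_frac, config.seed_for("split")
    )
    train_mask = curated["compound_id"].isin(split.train_ids).to_numpy()
    with open(out / "split.json", "w") as fh:
        json.dump(
            {"train_ids": split.train_ids, "test_ids": split.test_ids,
             "cluster_labels": {k: int(v) for k, v in split.cluster_labels.items()}},
            fh,
        )
    manifest["files"]["split.json"] = _sha256(out / "split.json")
    manifest["stages"]["split"] = {
        "n_train": len(split.train_ids), "n_test": len(split.test_ids),
        "n_clusters": int(len(np.unique(clusters))),
    }

    # nearest-neighbour concordance diagnostic
    nn = ds.nearest_neighbor_table(
        fp_model[~train_mask], y[~train_mask], fp_model[train_mask], y[train_mask]
    )
    nn_pct = ds.confusion_percentages(nn)
    manifest["stages"]["nn_table"] = {"counts": nn.tolist(), **nn_pct}

    # -- train -------------------------------------------------------------
    desc_train = desc_pruned.to_numpy()[train_mask]
    scaler_mean = desc_train.mean(axis=0)
    scaler_sd = desc_train.std(axis=0)
    scaler_sd[scaler_sd == 0] = 1.0
    reps_train = {
        "fingerprint": fp_model[train_mask].astype(float),
        "physchem": (desc_train - scaler_mean) / scaler_sd,
    }
    suite = mz.fit_suite(reps_train, y[train_mask], config.model_registry(), config.seed_for("train"))
    manifest["stages"]["train"] = {"models": list(suite)}

    # -- evaluate ----------------------------------------------------------
    reps_test = {
        "fingerprint": fp_model[~train_mask].astype(float),
        "physchem": (desc_pruned.to_numpy()[~train_mask] - scaler_mean) / scaler_sd,
    }
    rows, predictions, probas = [], {}, {}
    for name, member in suite.items():
        labels, in_ad = member.predict(reps_test)
        predictions[name] = (labels, in_ad)
        probas[name] = member.predict_proba(reps_test)
        rep = ev.score_predictions(y[~train_mask], labels, in_ad)
        rows.append({"model": name, **{k: v for k, v in rep.as_dict().items() if k != "slice"}})

    # probability ensembles over the whole zoo and a consensus label vote
    # (out-of-AD members abstain; consensus AD = at least half in AD)
    proba_matrix = np.vstack(list(probas.values()))
    for stat in ("mean", "median"):
        p = np.array([mz.probability_ensemble(proba_matrix[:, i], stat) for i in range(proba_matrix.shape[1])])
        labels = p >= 0.5
        predictions[f"ensemble_{stat}"] = (labels, np.ones_like(labels, dtype=bool))
        rep = ev.score_predictions(y[~train_mask], labels)
        rows.append({"model": f"ensemble_{stat}", **{k: v for k, v in rep.as_dict().items() if k != "slice"}})
    cons_labels, cons_ad = _consensus(predictions, list(suite))
    predictions["consensus_vote"] = (cons_labels, cons_ad)
    rep = ev.score_predictions(y[~train_mask], cons_labels, cons_ad)
    rows.append({"model": "consensus_vote", **{k: v for k, v in rep.as_dict().items() if k != "slice"}})

    model_metrics = pd.DataFrame(rows).sort_values("MCC", ascending=False).reset_index(drop=True)
    _write(model_metrics, out / "model_metrics.csv", manifest)

    # model selection for prospective prediction (SN/SP >= 0.5, best MCC)
    base_metrics = model_metrics[model_metrics["model"].isin(list(suite))]
    selected_models = ev.select_models(base_metrics)
    manifest["stages"]["model_selection"] = {"selected": selected_models}

    census, neighbours = ev.misprediction_census(
        y[~train_mask],
        {n: p[0] for n, p in predictions.items()},
        curated["compound_id"].to_numpy()[~train_mask],
        test_fps=fp_model[~train_mask],
        train_fps=fp_model[train_mask],
        train_ids=curated["compound_id"].to_numpy()[train_mask],
        train_zscores=curated["median_zscore"].to_numpy()[train_mask],
    )
    _write(census, out / "error_census.csv", manifest)
    _write(neighbours, out / "error_neighbours.csv", manifest)

    # -- select ------------------------------------------------------------
    space = ps.build_reference_space(fp_space, seed=config.seed_for("select"))
    space.to_json(out / "reference_space.json")
    manifest["files"]["reference_space.json"] = _sha256(out / "reference_space.json")

    screening = sd.generate_screening_library(
        config.screening_n, library, config.analog_fraction, seed=config.seed_for("screening")
    )
    scr_fp_space = chem.fingerprint_matrix(screening["smiles"], chem.FCFP4_1024)
    scr_fp_model = chem.fingerprint_matrix(screening["smiles"], chem.FCFP6_2048)
    scr_desc = (chem.descriptor_table(screening["smiles"]).iloc[:, kept_cols].to_numpy() - scaler_mean) / scaler_sd
    reps_scr = {"fingerprint": scr_fp_model.astype(float), "physchem": scr_desc}
    scr_predictions = {name: suite[name].predict(reps_scr) for name in selected_models}
    scr_predictions["consensus_vote"] = _consensus(scr_predictions, selected_models)

    selection, groups = ps.assemble_validation_set(
        screening, scr_fp_space, space, fp_space[train_mask],
        scr_predictions, config.subsample_n, config.selection_cap, config.seed_for("select"),
    )
    _write(selection, out / "selection.csv", manifest)
    _write(groups, out / "selection_groups.csv", manifest)
    manifest["stages"]["select"] = {
        "n_groups": len(groups), "n_selected": len(selection),
    }

    # -- evaluate prospective ---------------------------------------------
    if len(selection):
        sel_idx = screening.set_index("compound_id").index.get_indexer(selection["compound_id"])
        sel_smiles = screening["smiles"].to_numpy()[sel_idx]
        y_prosp = sd.assign_latent_activity(
            sel_smiles, seed=config.seed_for("prospective"), label_noise=config.label_noise
        )
        prosp_preds = {
            name: (labels[sel_idx], in_ad[sel_idx]) for name, (labels, in_ad) in scr_predictions.items()
        }
        prows = []
        for name, (labels, in_ad) in prosp_preds.items():
            rep = ev.score_predictions(y_prosp, labels, in_ad)
            prows.append({"model": name, **{k: v for k, v in rep.as_dict().items() if k != "slice"}})
        prosp_metrics = pd.DataFrame(prows).sort_values("MCC", ascending=False).reset_index(drop=True)
        _write(prosp_metrics, out / "prospective_metrics.csv", manifest)

        by_cluster = ev.stratified_metrics(y_prosp, prosp_preds, selection["cluster"].to_numpy())
        _write(by_cluster, out / "prospective_by_cluster.csv", manifest)
        logp_bins = np.array([chem.logp_bin(chem.crippen_logp(s)) for s in sel_smiles])
        by_logp = ev.stratified_metrics(y_prosp, prosp_preds, logp_bins)
        _write(by_logp, out / "prospective_by_logp.csv", manifest)
        manifest["stages"]["prospective"] = {
            "n_tested": int(len(y_prosp)),
            "n_active": int(y_prosp.sum()),
            "inactive_active_ratio": (
                ev.inactive_active_ratio(int(y_prosp.sum()), len(y_prosp)) if y_prosp.sum() else None
            ),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
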
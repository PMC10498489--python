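"""Repeatable benchmark computations on the synthetic study conditions.

These drive both the acceptance checks and the headline numbers of the
analysis: conformal validity of the Mondrian wrappers, separation between
real-descriptor models and the randomized-descriptor baseline, and the
integrity of the prospective selection pipeline. Each function generates
its own inputs from seeds and returns a plain dict of measured
quantities.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import matthews_corrcoef

from . import chemistry as chem
from . import model_zoo as mz
from . import prospective_selection as ps
from . import synthetic_data as sd

__all__ = [
    "conformal_validity_benchmark",
    "signal_vs_null_benchmark",
    "selection_audit_benchmark",
]


def _split_indices(n: int, train_frac: float, rng: np.random.Generator):
    perm = rng.permutation(n)
    cut = int(round(train_frac * n))
    return perm[:cut], perm[cut:]


def conformal_validity_benchmark(
    n_compounds: int = 2000,
    n_seeds: int = 20,
    eps_levels: tuple = (0.25, 0.30),
    train_frac: float = 0.70,
    algorithm: str = "random-forest",
    seed: int = 0,
) -> dict:
    """Class-conditional error rates of Mondrian prediction sets.

    Each repetition draws a fresh library and a random 70/30 split, so the
    pooled repetitions are independent and the binomial Monte-Carlo sigma
    of the pooled error rate is exact. Returns pooled per-class error
    rates, their sigma, and a one-sided KS p-value for super-uniformity
    of the true-class p-values.
    """
    errors = {eps: {0: [0, 0], 1: [0, 0]} for eps in eps_levels}  # class -> [errs, n]
    p_true_all = []
    rng = np.random.default_rng(seed + 1)
    for rep in range(n_seeds):
        lib = sd.generate_library(
            sd.SyntheticLibrarySpec(n_compounds=n_compounds, seed=seed + 101 * rep)
        )
        X = chem.fingerprint_matrix(lib["smiles"], chem.FCFP6_2048).astype(float)
        y = lib["latent_active"].to_numpy().astype(int)
        tr, te = _split_indices(len(y), train_frac, rng)
        mcp = mz.MondrianConformalClassifier(
            algorithm, "fingerprint", eps_levels[0], seed=seed + rep
        ).fit(X[tr], y[tr])
        pv = mcp.pvalues(X[te])
        p_true = np.where(y[te] == 1, pv[:, 1], pv[:, 0])
        p_true_all.append(p_true)
        for eps in eps_levels:
            for cls in (0, 1):
                mask = y[te] == cls
                # class excluded from the set <=> its p-value <= eps
                errors[eps][cls][0] += int(np.sum(p_true[mask] <= eps))
                errors[eps][cls][1] += int(mask.sum())

    out = {"n_compounds": n_compounds, "n_seeds": n_seeds}
    for eps in eps_levels:
        for cls, name in ((1, "active"), (0, "inactive")):
            errs, n = errors[eps][cls]
            rate = errs / n
            sigma = float(np.sqrt(eps * (1 - eps) / n))
            key = f"eps{int(round(eps * 100))}_{name}"
            out[f"{key}_error"] = rate
            out[f"{key}_sigma"] = sigma
            out[f"{key}_bound"] = eps + 3 * sigma

    p_all = np.concatenate(p_true_all)
    ks = stats.kstest(p_all, "uniform", alternative="greater")
    out["ks_pvalue_superuniform"] = float(ks.pvalue)
    return out


def signal_vs_null_benchmark(
    n_compounds: int = 2191,
    n_seeds: int = 20,
    train_frac: float = 0.70,
    seed: int = 0,
) -> dict:
    """Held-out MCC of a real-descriptor model vs the randomized baseline.

    The real model (random forest on feature-class fingerprints) is
    scored on one canonical 70/30 split; the randomized-descriptor
    baseline is refitted and scored across ``n_seeds`` splits, and the
    largest |MCC| it ever reaches is reported alongside the mean.
    """
    lib = sd.generate_library(
        sd.SyntheticLibrarySpec(n_compounds=n_compounds, seed=seed)
    )
    X = chem.fingerprint_matrix(lib["smiles"], chem.FCFP6_2048).astype(float)
    y = lib["latent_active"].to_numpy().astype(int)

    rng = np.random.default_rng(seed + 1)
    tr, te = _split_indices(len(y), train_frac, rng)
    real = mz.fit_classifier(X[tr], y[tr], "random-forest", "fingerprint", seed=seed)
    real_mcc = matthews_corrcoef(y[te], real.predict(X[te]).astype(int))

    null_mccs = []
    for rep in range(n_seeds):
        tr, te = _split_indices(len(y), train_frac, rng)
        base = mz.fit_classifier(
            X[tr], y[tr], "randomized-baseline", "randomized", seed=seed + rep
        )
        null_mccs.append(matthews_corrcoef(y[te], base.predict(X[te]).astype(int)))
    null_mccs = np.asarray(null_mccs)

    return {
        "n_compounds": n_compounds,
        "n_seeds": n_seeds,
        "real_model_mcc": float(real_mcc),
        "null_mcc_mean": float(null_mccs.mean()),
        "null_mcc_max_abs": float(np.abs(null_mccs).max()),
    }


def selection_audit_benchmark(
    screening_n: int = 20000,
    library_n: int = 500,
    subsample_n: int = 20000,
    seed: int = 0,
) -> dict:
    """Integrity audit of the prospective selection pipeline at scale.

    Builds a training library and reference space, trains a compact model
    panel, generates a ``screening_n``-compound collection, runs the full
    selection, re-audits every selected compound against its category's
    concordance/AD thresholds, and reruns the selection to verify
    bit-identical output.
    """
    lib = sd.generate_library(sd.SyntheticLibrarySpec(n_compounds=library_n, seed=seed))
    fp_model = chem.fingerprint_matrix(lib["smiles"], chem.FCFP6_2048).astype(float)
    fp_space = chem.fingerprint_matrix(lib["smiles"], chem.FCFP4_1024)
    y = lib["latent_active"].to_numpy().astype(int)

    registry = [
        mz.ModelConfig("cp_rf_fp", "random-forest", "fingerprint", True, 0.25),
        mz.ModelConfig("rf_fp", "random-forest", "fingerprint", False),
        mz.ModelConfig("logistic_fp", "logistic", "fingerprint", False),
        mz.ModelConfig("nb_fp", "naive-bayes", "fingerprint", False),
    ]
    suite = {}
    for cfg in registry:
        if cfg.conformal:
            model = mz.MondrianConformalClassifier(
                cfg.algorithm, cfg.representation, cfg.significance, seed=seed
            ).fit(fp_model, y)
        else:
            model = mz.fit_classifier(fp_model, y, cfg.algorithm, cfg.representation, seed)
        suite[cfg.name] = mz.SuiteMember(cfg, model)

    space = ps.build_reference_space(fp_space, k=6, restarts=100, seed=seed)
    screening = sd.generate_screening_library(screening_n, lib, analog_fraction=0.3, seed=seed + 1)
    scr_fp_space = chem.fingerprint_matrix(screening["smiles"], chem.FCFP4_1024)
    scr_fp_model = chem.fingerprint_matrix(screening["smiles"], chem.FCFP6_2048).astype(float)
    reps = {"fingerprint": scr_fp_model, "physchem": scr_fp_model}
    predictions = {name: member.predict(reps) for name, member in suite.items()}

    sel, groups = ps.assemble_validation_set(
        screening, scr_fp_space, space, fp_space, predictions,
        subsample_n=subsample_n, seed=seed,
    )
    sel2, groups2 = ps.assemble_validation_set(
        screening, scr_fp_space, space, fp_space, predictions,
        subsample_n=subsample_n, seed=seed,
    )

    order = {cid: i for i, cid in enumerate(screening["compound_id"])}
    audit_ok = True
    for _, row in sel.iterrows():
        i = order[row["compound_id"]]
        votes = np.array([predictions[m][0][i] for m in predictions])
        ad = np.array([predictions[m][1][i] for m in predictions])
        if not ps.concordance_filter(votes, ad, row["sim_class"], row["predicted_activity"]):
            audit_ok = False

    return {
        "screening_n": screening_n,
        "n_groups": int(len(groups)),
        "max_group_selected": int(groups["n_selected"].max()) if len(groups) else 0,
        "n_selected_total": int(len(sel)),
        "audit_pass": bool(audit_ok),
        "bit_identical_rerun": bool(
            sel.to_csv(index=False) == sel2.to_csv(index=False)
            and groups.to_csv(index=False) == groups2.to_csv(index=False)
        ),
    }
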
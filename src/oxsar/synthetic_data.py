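"""Synthetic compound libraries, reporter-plate readouts and screening sets.

The downstream pipeline (activity calling, QSAR model zoo, prospective
selection) needs three kinds of input data:

* a drug-like library of a few thousand compounds in which a minority is
  active in an oxidative-stress reporter assay, the activity being driven
  by redox-alert substructures (quinones, catechols, nitroaromatics,
  Michael acceptors ...) plus label noise;
* triplicate plate-based GFP-intensity readouts for that library,
  including occasional QC artifacts (sparse wells, saturated wells);
* a large diverse screening collection containing close analogs of the
  training library, chemotypes dissimilar to it, and some compounds of
  intermediate similarity.

This module generates all three from explicit seeds. Molecules are built
from a scaffold + substituent grammar and validated with RDKit, so every
emitted SMILES is chemically meaningful. Activity is Bernoulli with a
high success probability for alert-bearing compounds and a low baseline
otherwise, calibrated so that the realized active fraction matches the
requested one after label flipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

__all__ = [
    "SyntheticLibrarySpec",
    "PlateSimSpec",
    "P_ACTIVE_GIVEN_ALERT",
    "P_ACTIVE_GIVEN_NO_ALERT",
    "ALERT_MOTIFS",
    "generate_library",
    "generate_well_data",
    "generate_screening_library",
]

# ---------------------------------------------------------------------------
# molecular grammar
# ---------------------------------------------------------------------------

#: benign aromatic / heteroaromatic scaffolds with two substitution sites
_BENIGN_SCAFFOLDS = [
    "c1cc({0})cc({1})c1",                  # 1,3-disubstituted benzene
    "c1cc({0})ccc1{1}",                    # 1,4-disubstituted benzene
    "c1ccc({0})nc1{1}",                    # pyridine
    "c1cnc({0})nc1{1}",                    # pyrimidine
    "c1cc({0})c2ccccc2c1{1}",              # naphthalene
    "c1cc({0})c2[nH]c({1})cc2c1",          # indole
    "c1csc({0})c1{1}",                     # thiophene
    "c1cc({0})on1",                        # isoxazole (single site; {1} unused)
    "C1CCN(C(=O)c2ccc({0})cc2{1})CC1",     # aroyl piperidine
    "O=C(Nc1ccc({0})cc1)c1ccc({1})cc1",    # benzanilide
    "c1cc({0})nc(N2CCOCC2)c1{1}",          # morpholino pyridine
    "O=S(=O)(N)c1ccc({0})cc1{1}",          # benzenesulfonamide
]

#: benign substituents (attached as SMILES branches)
_BENIGN_SUBS = [
    "", "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC", "N(C)C",
    "Cl", "F", "Br", "C(F)(F)F", "C#N", "C(=O)N", "C(=O)OC", "CO",
    "S(=O)(=O)N", "CC(=O)N", "OC(F)F",
]

#: redox-alert motifs: name -> (scaffold templates | substituents) planting
#: the alert. Templates carry one or two sites; substituent alerts decorate
#: a benign scaffold.
ALERT_MOTIFS: dict[str, dict] = {
    "para_quinone": {"scaffolds": ["O=C1C({0})=CC(=O)C({1})=C1", "O=C1C=CC(=O)c2cc({0})ccc12"]},
    "catechol": {"scaffolds": ["Oc1ccc({0})cc1O", "Oc1cc({0})ccc1O"]},
    "hydroquinone": {"scaffolds": ["Oc1ccc(O)c({0})c1"]},
    "nitroaromatic": {"substituent": "[N+](=O)[O-]"},
    "michael_acceptor": {"substituent": "C(=O)C=C"},
    "aromatic_aldehyde": {"substituent": "C=O"},
}

#: per-motif activity log-odds offsets (added to the alert base rate); the
#: quinoid motifs are the strongest inducers, mirroring the relative potency
#: of direct redox cyclers over soft electrophiles.
_ALERT_LOGODDS = {
    "para_quinone": 1.2,
    "catechol": 0.9,
    "hydroquinone": 0.9,
    "nitroaromatic": 0.5,
    "michael_acceptor": 0.6,
    "aromatic_aldehyde": 0.3,
}

#: latent activity probabilities conditioned on alert presence (before the
#: per-motif offset and before label flipping)
P_ACTIVE_GIVEN_ALERT = 0.85
P_ACTIVE_GIVEN_NO_ALERT = 0.03

#: aliphatic / alicyclic chemotypes disjoint from the training grammar,
#: used for the dissimilar portion of screening sets
_DISJOINT_SCAFFOLDS = [
    "C1CCC({0})CC1",                       # cyclohexane
    "C1CCC(CC1)N({0})C(=O)C{1}",           # N-acyl cyclohexylamine
    "OCC(O)C(O)C({0})O",                   # polyol chain
    "CCCCCCC({0})CC(=O)OC{1}",             # aliphatic ester
    "C1CCC2(CC1)CCC({0})CC2",              # spiro bicycloalkane
    "N1CCC(CC1)CCNC(=O)C({0})C{1}",        # piperidine alkyl amide
    "CC(C)(C)CC(C)({0})CC(N){1}",          # neopentyl amine chain
    "O1CCOC(C1)C({0})CC{1}",               # dioxane ether
]

_DISJOINT_SUBS = ["", "C", "CC", "O", "OC", "N", "CO", "CC(C)O", "CCN", "OCC(=O)O"]


def _render(template: str, subs: tuple[str, str]) -> str | None:
    """Fill a scaffold template with substituents and canonicalize; None if invalid."""
    n_sites = 2 if "{1}" in template else 1
    smi = template.format(*subs[:n_sites]) if n_sites == 2 else template.format(subs[0])
    smi = smi.replace("()", "")
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticLibrarySpec:
    """Parameters of a synthetic drug-like library.

    ``active_fraction`` is the target marginal probability of the emitted
    activity flag, after label noise; the alert-planting rate is calibrated
    to hit it. Fixed seed implies byte-identical output.
    """

    n_compounds: int = 2191
    active_fraction: float = 316 / 2191
    alert_motifs: tuple[str, ...] = tuple(ALERT_MOTIFS)
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds < 0:
            raise ValueError(f"n_compounds must be >= 0, got {self.n_compounds}")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError(f"active_fraction must be in [0,1], got {self.active_fraction}")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError(f"label_noise must be in [0, 0.5), got {self.label_noise}")
        unknown = set(self.alert_motifs) - set(ALERT_MOTIFS)
        if unknown:
            raise ValueError(f"unknown alert motifs: {sorted(unknown)}")
        if self.label_noise >= self.active_fraction > 0:
            raise ValueError(
                "label_noise must be below active_fraction for the calibration to be solvable"
            )


def _alert_probability(spec: SyntheticLibrarySpec) -> float:
    """Alert-planting rate that makes the marginal flag rate equal active_fraction."""
    if spec.active_fraction == 0:
        return 0.0
    nu = spec.label_noise
    p_latent = (spec.active_fraction - nu) / (1.0 - 2.0 * nu)
    p_alert = (p_latent - P_ACTIVE_GIVEN_NO_ALERT) / (
        P_ACTIVE_GIVEN_ALERT - P_ACTIVE_GIVEN_NO_ALERT
    )
    return float(np.clip(p_alert, 0.0, 1.0))


def _motif_activity_prob(motif: str) -> float:
    """Latent activity probability of a compound carrying a given alert motif."""
    base = np.log(P_ACTIVE_GIVEN_ALERT / (1 - P_ACTIVE_GIVEN_ALERT))
    # offsets are centred so the mean across motifs stays near the base rate
    centred = _ALERT_LOGODDS[motif] - float(np.mean(list(_ALERT_LOGODDS.values())))
    return float(1.0 / (1.0 + np.exp(-(base + centred))))


def _make_benign(rng: np.random.Generator) -> str:
    while True:
        template = _BENIGN_SCAFFOLDS[rng.integers(len(_BENIGN_SCAFFOLDS))]
        subs = tuple(_BENIGN_SUBS[i] for i in rng.integers(len(_BENIGN_SUBS), size=2))
        smi = _render(template, subs)
        if smi is not None:
            return smi


def _make_alerted(motif: str, rng: np.random.Generator) -> str:
    info = ALERT_MOTIFS[motif]
    while True:
        if "scaffolds" in info:
            template = info["scaffolds"][rng.integers(len(info["scaffolds"]))]
            subs = tuple(_BENIGN_SUBS[i] for i in rng.integers(len(_BENIGN_SUBS), size=2))
        else:
            template = _BENIGN_SCAFFOLDS[rng.integers(len(_BENIGN_SCAFFOLDS))]
            other = _BENIGN_SUBS[rng.integers(len(_BENIGN_SUBS))]
            subs = (info["substituent"], other)
        smi = _render(template, subs)
        if smi is not None:
            return smi


def generate_library(spec: SyntheticLibrarySpec) -> pd.DataFrame:
    """Generate a drug-like library with planted redox alerts.

    Returns a frame with columns ``compound_id``, ``smiles``,
    ``latent_active`` (the noisy activity flag used as experimental label
    downstream) and ``has_alert`` / ``alert_motif`` (generator ground truth,
    for diagnostics and tests).
    """
    rng = np.random.default_rng(spec.seed)
    p_alert = _alert_probability(spec)
    motifs = list(spec.alert_motifs)

    rows = []
    for i in range(spec.n_compounds):
        has_alert = bool(rng.random() < p_alert) and len(motifs) > 0
        if has_alert:
            motif = motifs[rng.integers(len(motifs))]
            smi = _make_alerted(motif, rng)
            p_act = _motif_activity_prob(motif)
        else:
            motif = ""
            smi = _make_benign(rng)
            p_act = P_ACTIVE_GIVEN_NO_ALERT
        latent = bool(rng.random() < p_act)
        if rng.random() < spec.label_noise:
            latent = not latent
        rows.append((f"SYN{i:06d}", smi, latent, bool(has_alert), motif))

    return pd.DataFrame(
        rows, columns=["compound_id", "smiles", "latent_active", "has_alert", "alert_motif"]
    )


# ---------------------------------------------------------------------------
# plate simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateSimSpec:
    """Parameters of the reporter-plate intensity simulation.

    Baseline well intensity is log-normal with a per-plate multiplicative
    random effect, which is what makes per-plate robust normalization
    necessary downstream. ``effect_size`` multiplies the intensity of
    wells containing active compounds (1.0 = null assay). Artifact wells
    are flagged in the returned ground truth.
    """

    n_replicates: int = 3
    wells_per_plate: int = 96
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 0.25
    plate_effect_sd: float = 0.10
    effect_size: float = 3.0
    artifact_rate: float = 0.02
    mean_cell_count: float = 1500.0
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.wells_per_plate < 1:
            raise ValueError("wells_per_plate must be >= 1")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0,1]")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")


def _well_name(i: int) -> str:
    return f"{chr(ord('A') + i // 12)}{i % 12 + 1:02d}"


def generate_well_data(
    library: pd.DataFrame, latent_flags: "pd.Series | np.ndarray", spec: PlateSimSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate replicate plates of GFP-intensity readouts for a library.

    Every compound appears exactly once per replicate. Returns
    ``(wells, artifact_truth)``: the well table with columns
    (plate_id, well, compound_id, replicate, cell_count, gfp_intensity)
    and a sidecar with the ground-truth artifact type per well
    (``none`` / ``low_cells`` / ``high_intensity``).
    """
    flags = np.asarray(latent_flags, dtype=bool)
    if len(flags) != len(library):
        raise ValueError("latent_flags length must match the library")
    rng = np.random.default_rng(spec.seed)

    well_rows, truth_rows = [], []
    ids = library["compound_id"].to_numpy()
    for rep in range(1, spec.n_replicates + 1):
        for plate_start in range(0, len(library), spec.wells_per_plate):
            plate_idx = np.arange(plate_start, min(plate_start + spec.wells_per_plate, len(library)))
            plate_id = f"R{rep}_P{plate_start // spec.wells_per_plate + 1:03d}"
            plate_effect = rng.normal(0.0, spec.plate_effect_sd)
            for w, ci in enumerate(plate_idx):
                log_i = spec.baseline_log_mean + plate_effect + rng.normal(0.0, spec.baseline_log_sd)
                intensity = float(np.exp(log_i))
                if flags[ci]:
                    intensity *= spec.effect_size
                cells = int(rng.poisson(spec.mean_cell_count))
                artifact = "none"
                if rng.random() < spec.artifact_rate:
                    if rng.random() < 0.5:
                        artifact = "low_cells"
                        cells = int(rng.integers(5, 100))
                    else:
                        artifact = "high_intensity"
                        intensity *= float(rng.uniform(15.0, 30.0))
                well = _well_name(w)
                well_rows.append((plate_id, well, ids[ci], rep, cells, intensity))
                truth_rows.append((plate_id, well, ids[ci], rep, artifact))

    wells = pd.DataFrame(
        well_rows,
        columns=["plate_id", "well", "compound_id", "replicate", "cell_count", "gfp_intensity"],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["plate_id", "well", "compound_id", "replicate", "artifact"]
    )
    return wells, truth


# ---------------------------------------------------------------------------
# screening collection
# ---------------------------------------------------------------------------

def _methylate_aromatic(smiles: str, rng: np.random.Generator) -> str | None:
    """Attach a methyl to a random unsubstituted aromatic CH (single-edit analog)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    sites = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetSymbol() == "C" and a.GetTotalNumHs() > 0
    ]
    if not sites:
        return None
    em = Chem.RWMol(mol)
    new_atom = em.AddAtom(Chem.Atom(6))
    em.AddBond(int(sites[rng.integers(len(sites))]), new_atom, Chem.BondType.SINGLE)
    try:
        out = em.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


_HALOGENS = {"F": 9, "Cl": 17, "Br": 35}


def _swap_halogen(smiles: str, rng: np.random.Generator) -> str | None:
    """Swap one halogen for another (feature-class fingerprints see them alike)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    sites = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() in _HALOGENS]
    if not sites:
        return None
    em = Chem.RWMol(mol)
    atom = em.GetAtomWithIdx(int(sites[rng.integers(len(sites))]))
    choices = [z for s, z in _HALOGENS.items() if s != atom.GetSymbol()]
    atom.SetAtomicNum(int(choices[rng.integers(len(choices))]))
    try:
        out = em.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


def _make_analog(training_smiles: np.ndarray, rng: np.random.Generator) -> str:
    """Single-edit analog of a random training compound (max-Tc >= 0.7 enriched)."""
    while True:
        parent = str(training_smiles[rng.integers(len(training_smiles))])
        edit = rng.random()
        if edit < 0.5:
            # halogen swaps are invisible to feature-class fingerprints
            out = _swap_halogen(parent, rng) or parent
        elif edit < 0.75:
            out = parent  # re-issued structure: a trivial analog
        else:
            out = _methylate_aromatic(parent, rng) or parent
        if out is not None:
            return out


def _make_disjoint(rng: np.random.Generator) -> str:
    while True:
        template = _DISJOINT_SCAFFOLDS[rng.integers(len(_DISJOINT_SCAFFOLDS))]
        subs = tuple(_DISJOINT_SUBS[i] for i in rng.integers(len(_DISJOINT_SUBS), size=2))
        smi = _render(template, subs)
        if smi is not None:
            return smi


def _make_intermediate(rng: np.random.Generator) -> str:
    """Hybrid of aromatic training grammar and aliphatic chains: 0.3 < Tc < 0.7 enriched."""
    while True:
        arom = _BENIGN_SCAFFOLDS[rng.integers(len(_BENIGN_SCAFFOLDS))]
        chain = _DISJOINT_SUBS[rng.integers(len(_DISJOINT_SUBS))]
        tail = ["CCCCCC(=O)O", "CCOCCOCC", "CC(C)CC(C)(C)C", "CCCN1CCCC1"][rng.integers(4)]
        smi = _render(arom, (tail, chain))
        if smi is not None:
            return smi


def generate_screening_library(
    n: int,
    training_library: pd.DataFrame,
    analog_fraction: float = 0.3,
    seed: int = 0,
    intermediate_fraction: float = 0.1,
) -> pd.DataFrame:
    """Generate a diverse screening collection relative to a training library.

    ``analog_fraction`` of the compounds are single-edit analogs of training
    compounds (enriched in max-Tc >= 0.7 to the training set),
    ``intermediate_fraction`` are hybrid structures in the 0.3-0.7 band, and
    the remainder are drawn from chemotypes disjoint from the training
    grammar (enriched in max-Tc <= 0.3). Returns (compound_id, smiles).
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if not 0.0 <= analog_fraction <= 1.0:
        raise ValueError("analog_fraction must be in [0,1]")
    if analog_fraction + intermediate_fraction > 1.0:
        raise ValueError("analog_fraction + intermediate_fraction must be <= 1")
    if analog_fraction > 0 and len(training_library) == 0:
        raise ValueError("analog generation needs a non-empty training library")

    rng = np.random.default_rng(seed)
    training_smiles = training_library["smiles"].to_numpy() if len(training_library) else np.array([])

    rows = []
    for i in range(n):
        u = rng.random()
        if u < analog_fraction:
            smi = _make_analog(training_smiles, rng)
        elif u < analog_fraction + intermediate_fraction:
            smi = _make_intermediate(rng)
        else:
            smi = _make_disjoint(rng)
        rows.append((f"SCR{i:07d}", smi))
    return pd.DataFrame(rows, columns=["compound_id", "smiles"])


# ---------------------------------------------------------------------------
# latent-activity oracle for arbitrary structures
# ---------------------------------------------------------------------------

#: substructure queries recognizing the planted alert motifs in any SMILES
ALERT_SMARTS = {
    "para_quinone": "O=C1C=CC(=O)C=C1",
    "catechol": "[OX2H]c1ccccc1[OX2H]",
    "hydroquinone": "[OX2H]c1ccc([OX2H])cc1",
    "nitroaromatic": "c[N+](=O)[O-]",
    "michael_acceptor": "[CX3]=[CX3][CX3]=O",
    "aromatic_aldehyde": "c[CX3H1]=O",
}
_ALERT_QUERIES = {name: Chem.MolFromSmarts(s) for name, s in ALERT_SMARTS.items()}


def alert_flags(smiles_list: "list[str] | pd.Series") -> pd.DataFrame:
    """Per-motif substructure matches for a list of SMILES (plus ``any_alert``)."""
    rows = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            rows.append({name: False for name in _ALERT_QUERIES} | {"any_alert": False})
            continue
        hits = {name: mol.HasSubstructMatch(q) for name, q in _ALERT_QUERIES.items()}
        hits["any_alert"] = any(hits.values())
        rows.append(hits)
    return pd.DataFrame(rows)


def assign_latent_activity(
    smiles_list: "list[str] | pd.Series", seed: int = 0, label_noise: float = 0.0
) -> np.ndarray:
    """Latent activity flags for arbitrary structures under the planted mechanism.

    Uses the same conditional probabilities as :func:`generate_library`
    (strongest matched motif decides), so screening compounds selected for
    prospective validation can be "experimentally tested" in silico.
    """
    rng = np.random.default_rng(seed)
    flags = alert_flags(smiles_list)
    out = np.zeros(len(flags), dtype=bool)
    for i, row in flags.iterrows():
        matched = [m for m in _ALERT_QUERIES if row[m]]
        if matched:
            p = max(_motif_activity_prob(m) for m in matched)
        else:
            p = P_ACTIVE_GIVEN_NO_ALERT
        active = bool(rng.random() < p)
        if label_noise and rng.random() < label_noise:
            active = not active
        out[i] = active
    return out


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def write_library(library: pd.DataFrame, path) -> None:
    library[["compound_id", "smiles", "latent_active"]].to_csv(path, index=False)


def write_wells(wells: pd.DataFrame, path) -> None:
    wells.to_csv(path, index=False)
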
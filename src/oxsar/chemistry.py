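"""Structure standardization, fingerprints, descriptors and similarity.

This module is the shared representation layer for the whole pipeline:
every compound that enters modeling or chemical-space analysis passes
through :func:`standardize` first, and all similarity computations use
the bit-vector fingerprints produced by :func:`fingerprint`.

Fingerprints come in two flavours, both circular (Morgan-type):

* element-based (ECFP-class), keyed on atomic identity, and
* feature-based (FCFP-class), keyed on pharmacophoric atom classes
  (donor, acceptor, aromatic, halogen, basic, acidic),

folded to a fixed power-of-two length. Feature-based fingerprints with
radius 2 on 1024 bits drive the reference chemical space and similarity
classes; radius 3 on 2048 bits drives modeling descriptors and
nearest-neighbour diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "FingerprintSpec",
    "FCFP4_1024",
    "FCFP6_2048",
    "StandardizationError",
    "standardize",
    "fingerprint",
    "fingerprint_matrix",
    "tanimoto",
    "bulk_tanimoto",
    "max_tanimoto",
    "physchem_descriptors",
    "descriptor_table",
    "DESCRIPTOR_NAMES",
    "crippen_logp",
    "logp_bin",
    "prune_descriptors",
]


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

class StandardizationError(ValueError):
    """Raised when a structure cannot be standardized.

    ``reason`` is one of ``parse``, ``inorganic``, ``organometallic``
    or ``mixture``.
    """

    def __init__(self, reason: str, message: str):
        self.reason = reason
        super().__init__(f"{reason}: {message}")


#: metals whose carbon bonds mark a compound as organometallic
_METALS = frozenset(
    "Li Be Na Mg Al K Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Rb Sr Y Zr Nb Mo Tc "
    "Ru Rh Pd Ag Cd In Sn Sb Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb "
    "Lu Hf Ta W Re Os Ir Pt Au Hg Tl Pb Bi Po".split()
)

#: small organic fragments treated as counterions / salt formers when a
#: larger organic component is present (canonical SMILES keys)
_ORGANIC_COUNTERIONS = frozenset(
    Chem.CanonSmiles(s)
    for s in [
        "CC(=O)O", "CC(=O)[O-]",           # acetate
        "OC(=O)C(=O)O",                      # oxalate
        "OC(=O)/C=C/C(=O)O", "OC(=O)/C=C\\C(=O)O",  # fumarate / maleate
        "OC(=O)CC(O)(CC(=O)O)C(=O)O",        # citrate
        "OC(=O)C(O)C(O)C(=O)O",              # tartrate
        "CS(=O)(=O)O",                        # mesylate
        "Cc1ccc(cc1)S(=O)(=O)O",             # tosylate
        "C(=O)O", "OC=O",                     # formate
        "OCC(O)CO",                           # glycerol (solvate)
        "CO", "CCO",                          # solvents
        "CN(C)C",                             # trimethylamine
    ]
)

_UNCHARGER = rdMolStandardize.Uncharger()


def _is_organic(frag: Chem.Mol) -> bool:
    return any(a.GetSymbol() == "C" for a in frag.GetAtoms())


def _has_metal_carbon_bond(mol: Chem.Mol) -> bool:
    for bond in mol.GetBonds():
        syms = {bond.GetBeginAtom().GetSymbol(), bond.GetEndAtom().GetSymbol()}
        if syms & _METALS and "C" in syms:
            return True
    return False


def standardize(smiles_raw: str) -> str:
    """Standardize a raw SMILES into a canonical, neutral, single-component form.

    Charges are neutralized where chemically valid, recognized counterions and
    inorganic salt partners are stripped, and the canonical SMILES of the
    remaining organic component is returned.

    Raises
    ------
    StandardizationError
        with reason ``parse`` (unparseable input), ``inorganic`` (no
        carbon-containing component), ``organometallic`` (metal–carbon
        bond) or ``mixture`` (two or more non-salt organic components).
    """
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise StandardizationError("parse", f"unparseable SMILES {smiles_raw!r}")

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    organic = [f for f in frags if _is_organic(f)]
    if not organic:
        raise StandardizationError("inorganic", f"no organic component in {smiles_raw!r}")

    if len(organic) > 1:
        # keep the main component only if every other organic piece is a
        # recognized salt former; otherwise the input is a true mixture
        keyed = sorted(organic, key=lambda m: m.GetNumHeavyAtoms(), reverse=True)
        main, rest = keyed[0], keyed[1:]
        for frag in rest:
            neutral = _UNCHARGER.uncharge(frag)
            if Chem.MolToSmiles(neutral) not in _ORGANIC_COUNTERIONS:
                raise StandardizationError(
                    "mixture", f"multiple organic components in {smiles_raw!r}"
                )
        organic = [main]

    mol = organic[0]
    if _has_metal_carbon_bond(mol):
        raise StandardizationError("organometallic", f"metal–carbon bond in {smiles_raw!r}")

    mol = _UNCHARGER.uncharge(mol)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FingerprintSpec:
    """Circular fingerprint parameters.

    ``features=True`` selects pharmacophoric atom classes (FCFP-class)
    instead of element identities (ECFP-class).
    """

    radius: int = 2
    n_bits: int = 1024
    features: bool = True

    def __post_init__(self):
        if self.n_bits & (self.n_bits - 1) or self.n_bits <= 0:
            raise ValueError(f"n_bits must be a power of two, got {self.n_bits}")
        if self.radius not in (2, 3):
            raise ValueError(f"radius must be 2 or 3, got {self.radius}")

    @property
    def name(self) -> str:
        kind = "fcfp" if self.features else "ecfp"
        return f"{kind}{2 * self.radius}_{self.n_bits}"


#: feature-class radius-2 fingerprint on 1024 bits — reference chemical space
FCFP4_1024 = FingerprintSpec(radius=2, n_bits=1024, features=True)
#: feature-class radius-3 fingerprint on 2048 bits — modeling / nearest neighbours
FCFP6_2048 = FingerprintSpec(radius=3, n_bits=2048, features=True)

_GENERATORS: dict[FingerprintSpec, object] = {}


def _generator(spec: FingerprintSpec):
    gen = _GENERATORS.get(spec)
    if gen is None:
        kwargs = dict(radius=spec.radius, fpSize=spec.n_bits)
        if spec.features:
            kwargs["atomInvariantsGenerator"] = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
        gen = rdFingerprintGenerator.GetMorganGenerator(**kwargs)
        _GENERATORS[spec] = gen
    return gen


def fingerprint(smiles_std: str, spec: FingerprintSpec = FCFP4_1024) -> np.ndarray:
    """Folded circular fingerprint of a standardized SMILES as a uint8 0/1 vector."""
    mol = Chem.MolFromSmiles(smiles_std)
    if mol is None:
        raise StandardizationError("parse", f"unparseable SMILES {smiles_std!r}")
    bv = _generator(spec).GetFingerprint(mol)
    arr = np.zeros(spec.n_bits, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return arr


def fingerprint_matrix(smiles: "list[str] | pd.Series", spec: FingerprintSpec = FCFP4_1024) -> np.ndarray:
    """Stack fingerprints of many molecules into an (n, n_bits) uint8 matrix."""
    return np.vstack([fingerprint(s, spec) for s in smiles]) if len(smiles) else np.zeros((0, spec.n_bits), dtype=np.uint8)


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| of two equal-length bit vectors.

    Two all-zero vectors are defined as identical (Tc = 1.0).
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def bulk_tanimoto(query: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto matrix (n_query, n_reference) via a single matmul."""
    q = np.asarray(query, dtype=np.float32)
    r = np.asarray(reference, dtype=np.float32)
    # popcounts are small exact integers in float32; divide in float64 so
    # boundary ratios like 7/10 compare exactly against 0.7
    inter = (q @ r.T).astype(np.float64)
    union = q.sum(axis=1, dtype=np.float64)[:, None] + r.sum(axis=1, dtype=np.float64)[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


def max_tanimoto(query: np.ndarray, reference: np.ndarray, chunk: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Max Tanimoto of each query row against a reference matrix.

    Returns (max similarity, index of the nearest reference row; ties resolve
    to the lowest index, which argmax guarantees).
    Chunked so large screening sets stay within memory.
    """
    q = np.asarray(query, dtype=np.float32)
    best = np.empty(len(q), dtype=np.float64)
    idx = np.empty(len(q), dtype=np.int64)
    for lo in range(0, len(q), chunk):
        sim = bulk_tanimoto(q[lo : lo + chunk], reference)
        idx[lo : lo + chunk] = sim.argmax(axis=1)
        best[lo : lo + chunk] = sim.max(axis=1)
    return best, idx


# ---------------------------------------------------------------------------
# physicochemical descriptors
# ---------------------------------------------------------------------------

_DESCRIPTOR_FUNCS = {
    "mw": Descriptors.MolWt,
    "logp": Crippen.MolLogP,
    "mr": Crippen.MolMR,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "hbd": Lipinski.NumHDonors,
    "hba": Lipinski.NumHAcceptors,
    "rotatable_bonds": Lipinski.NumRotatableBonds,
    "heavy_atoms": Descriptors.HeavyAtomCount,
    "rings": rdMolDescriptors.CalcNumRings,
    "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings,
    "aliphatic_rings": rdMolDescriptors.CalcNumAliphaticRings,
    "saturated_rings": rdMolDescriptors.CalcNumSaturatedRings,
    "frac_csp3": rdMolDescriptors.CalcFractionCSP3,
    "n_heteroatoms": rdMolDescriptors.CalcNumHeteroatoms,
    "n_n": lambda m: sum(a.GetSymbol() == "N" for a in m.GetAtoms()),
    "n_o": lambda m: sum(a.GetSymbol() == "O" for a in m.GetAtoms()),
    "n_s": lambda m: sum(a.GetSymbol() == "S" for a in m.GetAtoms()),
    "n_halogen": lambda m: sum(a.GetSymbol() in ("F", "Cl", "Br", "I") for a in m.GetAtoms()),
    "formal_charge": Chem.GetFormalCharge,
    "n_amide_bonds": rdMolDescriptors.CalcNumAmideBonds,
    "balaban_j": Descriptors.BalabanJ,
    "bertz_ct": Descriptors.BertzCT,
    "kappa1": rdMolDescriptors.CalcKappa1,
    "kappa2": rdMolDescriptors.CalcKappa2,
    "chi0v": rdMolDescriptors.CalcChi0v,
    "chi1v": rdMolDescriptors.CalcChi1v,
    "labute_asa": rdMolDescriptors.CalcLabuteASA,
    "max_partial_charge": Descriptors.MaxPartialCharge,
    "min_partial_charge": Descriptors.MinPartialCharge,
}

DESCRIPTOR_NAMES: tuple[str, ...] = tuple(_DESCRIPTOR_FUNCS)


def physchem_descriptors(smiles_std: str) -> pd.Series:
    """Open 2D physicochemical descriptor vector (length ≥ 20), deterministic."""
    mol = Chem.MolFromSmiles(smiles_std)
    if mol is None:
        raise StandardizationError("parse", f"unparseable SMILES {smiles_std!r}")
    values = {}
    for name, func in _DESCRIPTOR_FUNCS.items():
        try:
            v = float(func(mol))
        except Exception:
            v = 0.0
        values[name] = v if np.isfinite(v) else 0.0
    return pd.Series(values, dtype=float)


def descriptor_table(smiles: "list[str] | pd.Series") -> pd.DataFrame:
    """Physicochemical descriptor matrix for many molecules."""
    if len(smiles) == 0:
        return pd.DataFrame(columns=list(DESCRIPTOR_NAMES), dtype=float)
    return pd.DataFrame([physchem_descriptors(s) for s in smiles]).reset_index(drop=True)


def crippen_logp(smiles_std: str) -> float:
    """Crippen atom-contribution estimate of octanol/water log P.

    Atoms without a specific published contribution fall into the generic
    wildcard class of the parameterization.
    """
    mol = Chem.MolFromSmiles(smiles_std)
    if mol is None:
        raise StandardizationError("parse", f"unparseable SMILES {smiles_std!r}")
    return float(Crippen.MolLogP(mol))


def logp_bin(logp: float) -> int:
    """Assign a log P value to one of four lipophilicity bins.

    Bins: 1 = (−∞, 0], 2 = (0, 2.5], 3 = (2.5, 5], 4 = (5, ∞). The
    boundary value 5.0 belongs to bin 3.
    """
    if not np.isfinite(logp):
        raise ValueError(f"log P must be finite, got {logp}")
    if logp <= 0:
        return 1
    if logp <= 2.5:
        return 2
    if logp <= 5:
        return 3
    return 4


# ---------------------------------------------------------------------------
# descriptor pruning
# ---------------------------------------------------------------------------

def prune_descriptors(
    matrix: np.ndarray,
    corr_threshold: float = 0.90,
    semiconstant_frac: float = 0.95,
) -> list[int]:
    """Column indices retained after constant / semi-constant / correlation pruning.

    Constant columns are dropped, as are columns whose modal value accounts
    for at least ``semiconstant_frac`` of the rows. Of any remaining pair
    with |Pearson r| strictly above ``corr_threshold``, the lower-index
    column is kept. The returned index list is increasing.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] == 0:
        raise ValueError("descriptor matrix must have >= 2 rows and >= 1 column")
    n = X.shape[0]

    kept: list[int] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        _, counts = np.unique(col, return_counts=True)
        if counts.max() / n >= semiconstant_frac or counts.size == 1:
            continue
        kept.append(j)
    if not kept:
        return []

    sub = X[:, kept]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))

    final: list[int] = []
    for pos, j in enumerate(kept):
        if all(abs(corr[pos, prev]) <= corr_threshold for prev in range(pos) if kept[prev] in final):
            final.append(j)
    return final
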
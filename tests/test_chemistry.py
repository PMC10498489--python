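"""Representation layer: standardization, fingerprints, descriptors, pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from oxsar import chemistry as chem


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

class TestStandardize:
    def test_inorganic_salt_rejected(self):
        with pytest.raises(chem.StandardizationError) as err:
            chem.standardize("[Na+].[Cl-]")
        assert err.value.reason == "inorganic"

    def test_neutralize_and_strip_counterion(self):
        # sodium acetate -> acetic acid (neutralized, counterion removed)
        assert chem.standardize("CC(=O)[O-].[Na+]") == Chem.CanonSmiles("CC(=O)O")

    def test_amine_hydrochloride(self):
        assert chem.standardize("CC[NH3+].[Cl-]") == Chem.CanonSmiles("CCN")

    def test_mixture_rejected(self):
        two_drugs = "c1ccc(CC(=O)Nc2ccccc2)cc1.c1ccc(-c2ccccn2)cc1"
        with pytest.raises(chem.StandardizationError) as err:
            chem.standardize(two_drugs)
        assert err.value.reason == "mixture"

    def test_organic_with_salt_former_kept(self):
        # drug-sized base with an acetate salt former keeps the base
        out = chem.standardize("c1ccc(CCN)cc1.CC(=O)O")
        assert out == Chem.CanonSmiles("NCCc1ccccc1")

    def test_organometallic_rejected(self):
        with pytest.raises(chem.StandardizationError) as err:
            chem.standardize("C[Hg]C")
        assert err.value.reason == "organometallic"

    def test_parse_failure(self):
        with pytest.raises(chem.StandardizationError) as err:
            chem.standardize("not-a-smiles((")
        assert err.value.reason == "parse"

    @pytest.mark.parametrize(
        "smiles",
        ["CC(=O)[O-].[Na+]", "c1ccccc1C(=O)O", "CC[NH3+].[Cl-]", "OC(=O)c1ccccc1O"],
    )
    def test_idempotent(self, smiles):
        once = chem.standardize(smiles)
        assert chem.standardize(once) == once


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

def _n_atom_environments(smiles: str, radius: int) -> int:
    """Enumeration oracle: circular atom environments existing up to a radius.

    Every fingerprint bit originates from some atom's environment at some
    radius, so the number of (atom, radius) environments that actually
    exist in the molecule bounds the popcount from above.
    """
    mol = Chem.MolFromSmiles(smiles)
    count = 0
    for atom in range(mol.GetNumAtoms()):
        count += 1  # radius-0 environment always exists
        for r in range(1, radius + 1):
            if Chem.FindAtomEnvironmentOfRadiusN(mol, r, atom):
                count += 1
    return count


class TestFingerprint:
    def test_canonicalization_invariance(self):
        a = chem.fingerprint(Chem.CanonSmiles("c1ccccc1CCO"))
        b = chem.fingerprint(Chem.CanonSmiles("OCCc1ccccc1"))
        assert np.array_equal(a, b)

    def test_distinct_molecules_differ(self):
        benzene = chem.fingerprint("c1ccccc1", chem.FingerprintSpec(2, 1024, features=False))
        pyridine = chem.fingerprint("c1ccncc1", chem.FingerprintSpec(2, 1024, features=False))
        assert not np.array_equal(benzene, pyridine)

    @pytest.mark.parametrize("smiles", ["CCO", "c1ccccc1C(=O)O", "CN1CCC[C@H]1c1cccnc1"])
    def test_popcount_bounded_by_environment_count(self, smiles):
        for spec in (chem.FCFP4_1024, chem.FCFP6_2048):
            fp = chem.fingerprint(smiles, spec)
            assert fp.sum() <= _n_atom_environments(smiles, spec.radius)

    def test_n_bits_must_be_power_of_two(self):
        with pytest.raises(ValueError):
            chem.FingerprintSpec(radius=2, n_bits=1000)


# ---------------------------------------------------------------------------
# tanimoto
# ---------------------------------------------------------------------------

class TestTanimoto:
    def test_identical_vectors(self):
        a = np.array([1, 0, 1, 1], dtype=np.uint8)
        assert chem.tanimoto(a, a) == 1.0

    def test_disjoint_vectors(self):
        assert chem.tanimoto(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 0.0

    def test_quarter_overlap(self):
        # |intersection| = 1, |union| = 4
        a = np.array([1, 1, 0, 0, 0])
        b = np.array([1, 0, 1, 1, 0])
        assert chem.tanimoto(a, b) == 0.25

    def test_all_zero_convention(self):
        z = np.zeros(8)
        assert chem.tanimoto(z, z) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            chem.tanimoto(np.ones(4), np.ones(5))

    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_bounds(self, abits, bbits):
        a = np.array([(abits >> i) & 1 for i in range(16)], dtype=np.uint8)
        b = np.array([(bbits >> i) & 1 for i in range(16)], dtype=np.uint8)
        t = chem.tanimoto(a, b)
        assert t == chem.tanimoto(b, a)
        assert 0.0 <= t <= 1.0

    def test_bulk_matches_scalar(self, small_fps):
        sub = small_fps[:20]
        bulk = chem.bulk_tanimoto(sub, sub)
        for i in range(0, 20, 5):
            for j in range(0, 20, 7):
                assert bulk[i, j] == pytest.approx(chem.tanimoto(sub[i], sub[j]))


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

class TestPhyschem:
    def test_methane(self):
        d = chem.physchem_descriptors("C")
        assert d["rotatable_bonds"] == 0
        assert d["rings"] == 0

    def test_deterministic(self):
        s = "CC(=O)Nc1ccc(O)cc1"
        assert chem.physchem_descriptors(s).equals(chem.physchem_descriptors(s))

    def test_molecular_weight_ordering(self):
        # formula-mass oracle: hexanol = ethanol + 4 x CH2 (14.027 u each)
        ethanol = chem.physchem_descriptors("CCO")["mw"]
        hexanol = chem.physchem_descriptors("CCCCCCO")["mw"]
        assert hexanol > ethanol
        assert hexanol - ethanol == pytest.approx(4 * 14.027, abs=0.01)

    def test_at_least_twenty_descriptors(self):
        assert len(chem.DESCRIPTOR_NAMES) >= 20


class TestCrippenLogp:
    def test_lipophilicity_ordering(self):
        assert chem.crippen_logp("CCCCCC") > chem.crippen_logp("CCO")

    @pytest.mark.parametrize(
        "smiles, expected",
        [
            # frozen from an independent atom-contribution implementation of
            # the same published parameter table (Open Babel 3.1.1)
            ("CCO", -0.0014),
            ("c1ccc(O)cc1", 1.3922),
            ("CCCCCC", 2.5866),
            ("CC(=O)O", 0.0909),
            ("c1ccc2[nH]ccc2c1", 2.1679),
        ],
    )
    def test_against_independent_contribution_sum(self, smiles, expected):
        assert chem.crippen_logp(smiles) == pytest.approx(expected, abs=1e-3)

    def test_salt_stripped_acid_finite(self):
        assert np.isfinite(chem.crippen_logp("CC(=O)O"))


class TestLogpBin:
    @pytest.mark.parametrize(
        "value, expected",
        [(-3.0, 1), (0.0, 1), (0.1, 2), (2.5, 2), (2.6, 3), (5.0, 3), (5.1, 4)],
    )
    def test_bins(self, value, expected):
        assert chem.logp_bin(value) == expected

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            chem.logp_bin(float("nan"))


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

class TestPruneDescriptors:
    def test_constant_column_removed(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(size=50), np.full(50, 3.0), rng.normal(size=50)])
        assert chem.prune_descriptors(X) == [0, 2]

    def test_semiconstant_column_removed(self):
        rng = np.random.default_rng(1)
        col = np.zeros(100)
        col[:4] = 1.0  # modal frequency 96% >= 95%
        X = np.column_stack([rng.normal(size=100), col])
        assert chem.prune_descriptors(X) == [0]

    def test_high_correlation_keeps_lower_index(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=200)
        b = a + rng.normal(scale=0.05, size=200)  # |r| ~ 0.999
        X = np.column_stack([a, b, rng.normal(size=200)])
        assert chem.prune_descriptors(X) == [0, 2]

    def test_exact_threshold_keeps_both(self):
        # construct |r| = 0.90 exactly: corr(x, 0.9x + sqrt(1-0.81)z) with
        # x, z orthonormal columns
        n = 100
        x = np.sin(np.arange(n))
        z = np.cos(np.arange(n) * 1.7)
        x = (x - x.mean()) / x.std()
        z = (z - z.mean()) / z.std()
        z = z - (z @ x) / (x @ x) * x
        z = (z - z.mean()) / z.std()
        y = 0.9 * x + np.sqrt(1 - 0.81) * z
        r = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(0.90, abs=1e-9)
        assert chem.prune_descriptors(np.column_stack([x, y])) == [0, 1]

    def test_no_surviving_pair_above_threshold(self, small_library):
        desc = chem.descriptor_table(small_library["smiles"].head(100)).to_numpy()
        kept = chem.prune_descriptors(desc)
        sub = desc[:, kept]
        corr = np.corrcoef(sub, rowvar=False)
        off = corr[~np.eye(len(kept), dtype=bool)]
        assert np.all(np.abs(off) <= 0.90 + 1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            chem.prune_descriptors(np.zeros((1, 3)))
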
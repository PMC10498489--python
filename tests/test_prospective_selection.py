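"""Reference chemical space, similarity classes, concordance and selection."""

import numpy as np
import pytest

from oxsar import chemistry as chem
from oxsar import prospective_selection as ps


@pytest.fixture(scope="module")
def three_families():
    """Three well-separated synthetic chemotype families."""
    fam_a = [f"c1ccc(OC{'C' * i})cc1" for i in range(12)]
    fam_b = [f"C1CCC(CC1)NC(=O)C{'C' * i}" for i in range(12)]
    fam_c = [f"c1ccc2[nH]c(C{'C' * i})cc2c1" for i in range(12)]
    smiles = fam_a + fam_b + fam_c
    fps = chem.fingerprint_matrix(smiles, chem.FCFP4_1024)
    truth = np.repeat([0, 1, 2], 12)
    return fps, truth


class TestReferenceSpace:
    def test_planted_families_recovered(self, three_families):
        fps, truth = three_families
        space = ps.build_reference_space(fps, k=3, restarts=20, seed=0)
        got = space.project(fps)["cluster"].to_numpy()
        # every family maps to a single cluster and clusters don't merge
        mapping = {}
        for fam in range(3):
            labs = np.unique(got[truth == fam])
            assert len(labs) == 1
            mapping[fam] = labs[0]
        assert len(set(mapping.values())) == 3

    def test_projection_scores_centered(self, three_families):
        fps, _ = three_families
        space = ps.build_reference_space(fps, k=3, restarts=10, seed=0)
        proj = space.project(fps)
        assert abs(proj["pc1"].mean()) < 1e-8
        assert abs(proj["pc2"].mean()) < 1e-8

    def test_deterministic(self, three_families):
        fps, _ = three_families
        a = ps.build_reference_space(fps, k=3, restarts=10, seed=4)
        b = ps.build_reference_space(fps, k=3, restarts=10, seed=4)
        assert np.array_equal(a.centroids, b.centroids)

    def test_projection_consistent_with_build(self, small_fps):
        space = ps.build_reference_space(small_fps, k=6, restarts=20, seed=1)
        proj1 = space.project(small_fps)
        proj2 = space.project(small_fps)
        assert proj1.equals(proj2)

    def test_equidistant_point_takes_lowest_cluster(self):
        space = ps.ReferenceSpace(
            kept_bits=np.arange(2),
            mean=np.zeros(2),
            scale=np.ones(2),
            basis=np.eye(2),
            centroids=np.array([[1.0, 0.0], [3.0, 0.0], [-1.0, 0.0], [2.0, 5.0]]),
            seed=0,
        )
        proj = space.project(np.array([[2.0, 0.0]]))  # equidistant to 0 and 1
        assert proj["cluster"].iloc[0] == 0

    def test_empty_input(self, three_families):
        fps, _ = three_families
        space = ps.build_reference_space(fps, k=3, restarts=10, seed=0)
        assert len(space.project(np.zeros((0, fps.shape[1])))) == 0

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            ps.build_reference_space(np.ones((10, 8)), k=2, restarts=5, seed=0)

    def test_json_roundtrip(self, three_families, tmp_path):
        fps, _ = three_families
        space = ps.build_reference_space(fps, k=3, restarts=10, seed=0)
        space.to_json(tmp_path / "space.json")
        loaded = ps.ReferenceSpace.from_json(tmp_path / "space.json")
        assert loaded.project(fps).equals(space.project(fps))


class TestSimilarityClass:
    def _fp_with_overlap(self, n_shared, n_extra_a, n_extra_b, length=64):
        a = np.zeros(length, dtype=np.uint8)
        b = np.zeros(length, dtype=np.uint8)
        a[:n_shared] = 1
        b[:n_shared] = 1
        a[n_shared : n_shared + n_extra_a] = 1
        b[n_shared + n_extra_a : n_shared + n_extra_a + n_extra_b] = 1
        return a, b

    @pytest.mark.parametrize(
        "n_shared, extra_a, extra_b, expected",
        [
            (7, 3, 0, "similar"),     # Tc = 7/10 = 0.70: boundary inclusive
            (3, 7, 0, "dissimilar"),  # Tc = 3/10 = 0.30: boundary inclusive
            (5, 5, 0, "excluded"),    # Tc = 0.50
        ],
    )
    def test_boundaries(self, n_shared, extra_a, extra_b, expected):
        a, b = self._fp_with_overlap(n_shared, extra_a, extra_b)
        out = ps.similarity_class(a[None, :], b[None, :])
        assert out["sim_class"].iloc[0] == expected

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            ps.similarity_class(np.ones((1, 8)), np.zeros((0, 8)))


class TestSubsampleDissimilar:
    def test_subset_size_and_uniqueness(self):
        out = ps.subsample_dissimilar(np.arange(30), n=10, seed=0)
        assert len(out) == 10 and len(np.unique(out)) == 10

    def test_identity_when_n_large(self):
        ids = np.arange(5)
        assert np.array_equal(ps.subsample_dissimilar(ids, n=10, seed=0), ids)

    def test_deterministic(self):
        a = ps.subsample_dissimilar(np.arange(100), n=20, seed=3)
        b = ps.subsample_dissimilar(np.arange(100), n=20, seed=3)
        assert np.array_equal(a, b)


class TestConcordanceFilter:
    def test_similar_active_passes_at_70(self):
        votes = [True] * 9 + [False] * 3          # 75% concordant active
        ad = [True] * 10 + [False] * 2            # 83% in AD
        assert ps.concordance_filter(votes, ad, "similar", "active")

    def test_same_compound_fails_as_dissimilar_active(self):
        votes = [True] * 9 + [False] * 3
        ad = [True] * 10 + [False] * 2
        assert not ps.concordance_filter(votes, ad, "dissimilar", "active")

    def test_dissimilar_inactive_needs_unanimity(self):
        votes = [False] * 11 + [True]             # one dissenting model
        ad = [True] * 12
        assert not ps.concordance_filter(votes, ad, "dissimilar", "inactive")
        assert ps.concordance_filter([False] * 12, ad, "dissimilar", "inactive")

    def test_no_votes_rejected(self):
        with pytest.raises(ValueError):
            ps.concordance_filter([], [], "similar", "active")


class TestCappedGroupSelection:
    def test_large_group_capped_at_25(self):
        rng = np.random.default_rng(0)
        fps = rng.integers(0, 2, size=(130, 64))
        ids = np.array([f"c{i}" for i in range(130)])
        out = ps.capped_group_selection(ids, fps, seed=0)
        assert len(out) == 25
        assert len(set(out)) == 25
        assert set(out) <= set(ids)

    def test_small_group_taken_whole(self):
        rng = np.random.default_rng(1)
        fps = rng.integers(0, 2, size=(18, 64))
        ids = np.array([f"c{i}" for i in range(18)])
        assert sorted(ps.capped_group_selection(ids, fps, seed=0)) == sorted(ids)

    def test_empty_group(self):
        assert ps.capped_group_selection([], np.zeros((0, 8)), seed=0) == []

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        fps = rng.integers(0, 2, size=(60, 32))
        ids = np.array([f"c{i}" for i in range(60)])
        assert ps.capped_group_selection(ids, fps, seed=5) == ps.capped_group_selection(ids, fps, seed=5)


class TestAssembleValidationSet:
    @pytest.fixture(scope="class")
    def assembled(self, small_library, small_fps):
        from oxsar import synthetic_data as sd

        space = ps.build_reference_space(small_fps, k=6, restarts=20, seed=0)
        screening = sd.generate_screening_library(600, small_library, analog_fraction=0.4, seed=3)
        scr_fps = chem.fingerprint_matrix(screening["smiles"], chem.FCFP4_1024)
        rng = np.random.default_rng(4)
        # three synthetic "models": high-agreement votes with occasional dissent
        base = rng.random(600) < 0.35
        preds = {}
        for m in range(5):
            flip = rng.random(600) < 0.08
            preds[f"m{m}"] = (np.where(flip, ~base, base), rng.random(600) < 0.9)
        sel, groups = ps.assemble_validation_set(
            screening, scr_fps, space, small_fps, preds, subsample_n=400, seed=0
        )
        return sel, groups, preds, screening

    def test_group_count_and_caps(self, assembled):
        sel, groups, _, _ = assembled
        assert len(groups) <= 24
        assert (groups["n_selected"] <= 25).all()
        assert groups["n_selected"].sum() == len(sel)

    def test_selected_compounds_pass_their_thresholds_on_reaudit(self, assembled):
        sel, _, preds, screening = assembled
        order = {cid: i for i, cid in enumerate(screening["compound_id"])}
        for _, row in sel.iterrows():
            i = order[row["compound_id"]]
            votes = np.array([preds[m][0][i] for m in preds])
            ad = np.array([preds[m][1][i] for m in preds])
            assert ps.concordance_filter(votes, ad, row["sim_class"], row["predicted_activity"])

    def test_groups_disjoint(self, assembled):
        sel, _, _, _ = assembled
        assert sel["compound_id"].is_unique

    def test_excluded_band_absent(self, assembled):
        sel, _, _, _ = assembled
        assert set(sel["sim_class"]) <= {"similar", "dissimilar"}
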
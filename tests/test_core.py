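import math
import warnings

import numpy as np
import pytest

from jple import core
from jple.core import (
    AugmentationEntry,
    Embedding,
    build_augmented_profiles,
    decode_global,
    decode_local,
    e_dist,
    embed_protein,
    embed_rna,
    fit_joint,
    preprocess,
    protein_query,
    rna_query,
    select_dimension,
)
from jple.featurize import RBR, build_rbr, peptide_profile
from jple.io import DomainAnnotation, KmerMatrix, ProteinRecord
from tests.conftest import random_matrices


def lstsq_oracle(A, y):
    """Dense brute-force least squares via the SVD pseudoinverse."""
    return np.linalg.pinv(A) @ y


class TestPreprocess:
    def test_zero_variance_column_dropped(self):
        P = KmerMatrix(["a", "b", "c"], ["t1", "t2"],
                       np.array([[1.0, 0.0], [1.0, 2.0], [1.0, 1.0]]))
        R = KmerMatrix(["a", "b", "c"], ["k1"], np.array([[0.0], [1.0], [2.0]]))
        tm = preprocess(P, R)
        assert tm.kept_P.tolist() == [False, True]

    def test_two_point_column_closed_form(self):
        P = KmerMatrix(["a", "b"], ["t1"], np.array([[0.0], [2.0]]))
        R = KmerMatrix(["a", "b"], ["k1"], np.array([[1.0], [3.0]]))
        tm = preprocess(P, R)
        np.testing.assert_allclose(
            tm.P[:, 0], [-1 / math.sqrt(2), 1 / math.sqrt(2)]
        )

    def test_kept_columns_mean_zero_unit_norm(self, rng):
        P, R = random_matrices(rng, n=10, p=20, r=15)
        tm = preprocess(P, R)
        for block in (tm.P, tm.R):
            np.testing.assert_allclose(block.mean(axis=0), 0, atol=1e-10)
            np.testing.assert_allclose(
                np.linalg.norm(block, axis=0), 1, atol=1e-10
            )

    def test_errors(self, rng):
        P, R = random_matrices(rng, n=1)
        with pytest.raises(ValueError, match="2 training rows"):
            preprocess(P, R)
        P2 = KmerMatrix(["a", "b"], ["t1"], np.ones((2, 1)))
        R2 = KmerMatrix(["a", "b"], ["k1"], np.array([[0.0], [1.0]]))
        with pytest.raises(ValueError, match="zero variance"):
            preprocess(P2, R2)


class TestSelectDimension:
    def test_exact_rank_recovered(self, rng):
        low = rng.normal(size=(10, 3)) @ rng.normal(size=(3, 30))
        assert select_dimension(low, pcc_min=0.999999) == 3

    def test_pcc_one_needs_full_rank(self, rng):
        R = rng.normal(size=(6, 12))
        assert select_dimension(R, pcc_min=1.0) == 6

    def test_matches_brute_force_scan(self, rng):
        signal = rng.normal(size=(12, 5)) @ rng.normal(size=(5, 40))
        R = signal + 0.05 * rng.normal(size=signal.shape)
        d = select_dimension(R, pcc_min=0.95)
        # independent scan: smallest d where min row PCC >= 0.95
        U, S, Vt = np.linalg.svd(R, full_matrices=False)
        for k in range(1, len(S) + 1):
            recon = U[:, :k] @ np.diag(S[:k]) @ Vt[:k]
            pccs = [np.corrcoef(R[i], recon[i])[0, 1] for i in range(len(R))]
            if min(pccs) >= 0.95:
                assert d == k
                break
        else:
            pytest.fail("scan never reached the target")

    def test_invalid_pcc_rejected(self, rng):
        with pytest.raises(ValueError):
            select_dimension(rng.normal(size=(4, 6)), pcc_min=1.5)


class TestFitJoint:
    def test_variance_conservation(self, rng):
        P, R = random_matrices(rng, n=10, p=25, r=20)
        tm = preprocess(P, R)
        model = fit_joint(tm, d=5)
        total = model.scores.sum()
        assert abs(total - np.trace(tm.R @ tm.R.T)) < 1e-8

    def test_signal_axis_selected_first(self, rng):
        """With pure-noise P and rank-1 R, the retained component carries
        nearly all RNA variance."""
        n = 20
        u = rng.normal(size=n)
        v = rng.normal(size=30)
        P = KmerMatrix([f"r{i}" for i in range(n)],
                       [f"p{j}" for j in range(40)],
                       0.01 * rng.normal(size=(n, 40)))
        R = KmerMatrix([f"r{i}" for i in range(n)],
                       [f"k{j}" for j in range(30)], np.outer(u, v))
        tm = preprocess(P, R)
        model = fit_joint(tm, d=1)
        var_R = np.trace(tm.R @ tm.R.T)
        explained = (model.S[0] ** 2) * np.linalg.norm(model.Vr[:, 0]) ** 2
        assert explained / var_R > 0.99

    def test_retained_scores_monotone_and_dominant(self, rng):
        P, R = random_matrices(rng)
        tm = preprocess(P, R)
        model = fit_joint(tm, d=4)
        retained = [
            model.S[j] ** 2 * np.linalg.norm(model.Vr[:, j]) ** 2
            for j in range(4)
        ]
        assert all(retained[i] >= retained[i + 1] - 1e-12 for i in range(3))
        dropped_max = np.sort(model.scores)[::-1][4]
        assert retained[-1] >= dropped_max - 1e-12

    def test_orthonormal_stacked_basis(self, rng):
        P, R = random_matrices(rng)
        tm = preprocess(P, R)
        model = fit_joint(tm, d=6)
        V = np.vstack([model.Vp, model.Vr])
        np.testing.assert_allclose(V.T @ V, np.eye(6), atol=1e-8)

    def test_d_above_rank_rejected(self, rng):
        P, R = random_matrices(rng, n=5)
        with pytest.raises(ValueError, match="rank"):
            fit_joint(preprocess(P, R), d=10)

    def test_full_rank_round_trip(self, rng):
        P, R = random_matrices(rng, n=8, p=12, r=10)
        tm = preprocess(P, R)
        J = np.concatenate([tm.P, tm.R], axis=1)
        d = np.linalg.matrix_rank(J)
        model = fit_joint(tm, d=d)
        model.R_raw = R.values
        for i in range(8):
            rec_r = decode_global(model.W[i], model, "rna")
            np.testing.assert_allclose(rec_r, R.values[i], atol=1e-8)
            rec_p = decode_global(model.W[i], model, "peptide")
            np.testing.assert_allclose(rec_p, P.values[i], atol=1e-8)


class TestEncoders:
    @pytest.mark.parametrize("block", ["peptide", "rna"])
    def test_matches_dense_lstsq_oracle(self, rng, block):
        P, R = random_matrices(rng, n=20, p=50, r=30)
        tm = preprocess(P, R)
        model = fit_joint(tm, d=8)
        for i in range(20):
            if block == "peptide":
                x = (P.values[i][tm.kept_P] - tm.mu_P[tm.kept_P]) / tm.norm_P
                w = embed_protein(P.values[i], model).w
                oracle = lstsq_oracle(model.Vp, x)
            else:
                x = (R.values[i][tm.kept_R] - tm.mu_R[tm.kept_R]) / tm.norm_R
                w = embed_rna(R.values[i], model).w
                oracle = lstsq_oracle(model.Vr, x)
            np.testing.assert_allclose(w, oracle, atol=1e-8)

    def test_zero_preprocessed_vector_maps_to_zero(self, rng):
        P, R = random_matrices(rng)
        tm = preprocess(P, R)
        model = fit_joint(tm, d=3)
        x = np.array(tm.mu_P)  # equals the column means -> centred to zero
        w = embed_protein(x, model).w
        np.testing.assert_allclose(w, 0, atol=1e-10)

    def test_unseen_templates_warn_and_empty_errors(self, small_model):
        with pytest.warns(UserWarning, match="outside the training"):
            embed_protein({"QQQQX": 1.0, small_model.col_ids_P[0]: 1.0},
                          small_model)
        with pytest.raises(ValueError, match="empty"):
            embed_protein({"QQQQX": 1.0}, small_model)

    def test_noisy_rna_copy_recovers_source_family(self, small_fixture, small_model):
        fx, _, P, R = small_fixture
        rng = np.random.default_rng(0)
        # a diverged member has a profile distinct from every other protein,
        # so its noisy copy must embed nearest to itself; high-band members
        # share their family's profile, so require only family-level retrieval
        for i, rid in enumerate(R.row_ids):
            noisy = R.values[i] + 0.1 * rng.normal(size=R.values.shape[1])
            w = embed_rna(noisy, small_model)
            dists = [e_dist(w, Embedding(wi, "joint")) for wi in small_model.W]
            nearest = small_model.row_ids[int(np.argmin(dists))]
            if fx.band_of[rid] <= 0.25:
                assert nearest == rid
            else:
                assert fx.family_of[nearest] == fx.family_of[rid]


class TestEDist:
    def test_closed_forms(self):
        a = Embedding(np.array([1.0, 0.0]), "protein")
        assert e_dist(a, Embedding(np.array([2.0, 0.0]), "protein")) == pytest.approx(0)
        assert e_dist(a, Embedding(np.array([0.0, 3.0]), "protein")) == pytest.approx(1)
        assert e_dist(a, Embedding(np.array([-1.0, 0.0]), "protein")) == pytest.approx(2)

    def test_zero_vector_neutral_with_warning(self):
        with pytest.warns(UserWarning, match="zero embedding"):
            d = e_dist(np.zeros(3), np.ones(3))
        assert d == 1.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            e_dist(np.ones(3), np.ones(4))


class TestDecoders:
    def test_zero_embedding_decodes_to_means(self, rng):
        P, R = random_matrices(rng)
        tm = preprocess(P, R)
        model = fit_joint(tm, d=3)
        np.testing.assert_allclose(
            decode_global(np.zeros(3), model, "rna"), tm.mu_R, atol=1e-12
        )

    def test_truncated_reconstruction_equals_svd_residual(self, rng):
        P, R = random_matrices(rng, n=8, p=12, r=10)
        tm = preprocess(P, R)
        d = 4
        model = fit_joint(tm, d=d)
        J = np.concatenate([tm.P, tm.R], axis=1)
        # rank-d approximation restricted to the selected components
        V = np.vstack([model.Vp, model.Vr])
        J_d = model.W @ V.T
        for i in range(8):
            rec = decode_global(model.W[i], model, "rna")
            expected = J_d[i, tm.P.shape[1]:] * tm.norm_R + tm.mu_R[tm.kept_R]
            np.testing.assert_allclose(rec[tm.kept_R], expected, atol=1e-8)

    def test_local_single_neighbor_identity(self, small_model):
        i = 3
        recon, nbh, edists, esims = decode_local(
            small_model.W[i] * 1.0, small_model
        )
        # force a single neighbor by shrinking the neighborhood threshold case:
        # self e-dist is ~0 so self is always included
        assert small_model.row_ids[i] in nbh
        assert esims[i] == pytest.approx(1.0, abs=1e-9)

    def test_local_equal_distance_unweighted_mean(self):
        model = core.JointModel(
            Vp=np.eye(2), Vr=np.eye(2), S=np.ones(2),
            W=np.array([[1.0, 0.0], [0.0, 1.0]]), d=2,
            scores=np.ones(2), gamma=25.0, nbh_threshold=0.01,
            conf_cutoff=0.127, row_ids=["a", "b"],
            col_ids_P=["p0", "p1"], col_ids_R=["k0", "k1"],
            kept_P=np.array([True, True]), kept_R=np.array([True, True]),
            mu_P=np.zeros(2), mu_R=np.zeros(2),
            norm_P=np.ones(2), norm_R=np.ones(2),
            R_raw=np.array([[2.0, 0.0], [0.0, 4.0]]),
        )
        recon, nbh, _, esims = decode_local(np.array([1.0, 1.0]), model)
        assert set(nbh) == {"a", "b"}
        np.testing.assert_allclose(recon, [1.0, 2.0])

    def test_rbf_closed_form(self):
        # e-sim at e-dist 0.2 with gamma 25 is exp(-1)
        assert math.exp(-25 * 0.2**2) == pytest.approx(math.exp(-1), abs=1e-12)
        # neighborhood boundary: e-sim >= 0.01 iff e-dist <= sqrt(ln(100)/25)
        boundary = math.sqrt(math.log(100) / 25)
        assert math.exp(-25 * boundary**2) == pytest.approx(0.01, abs=1e-12)

    def test_empty_neighborhood_zero_vector(self):
        model = core.JointModel(
            Vp=np.eye(2), Vr=np.eye(2), S=np.ones(2),
            W=np.array([[1.0, 0.0]]), d=2, scores=np.ones(2),
            gamma=25.0, nbh_threshold=0.01, conf_cutoff=0.127,
            row_ids=["a"], col_ids_P=["p0", "p1"], col_ids_R=["k0", "k1"],
            kept_P=np.array([True, True]), kept_R=np.array([True, True]),
            mu_P=np.zeros(2), mu_R=np.zeros(2),
            norm_P=np.ones(2), norm_R=np.ones(2),
            R_raw=np.array([[5.0, 5.0]]),
        )
        recon, nbh, _, _ = decode_local(np.array([-1.0, 0.0]), model)
        assert nbh == [] and np.all(recon == 0)

    def test_local_weights_convexity(self, small_model, small_fixture):
        """The local reconstruction lies in the convex hull of neighborhood
        profiles: each entry within [min, max] over the neighborhood."""
        _, _, P, R = small_fixture
        w = small_model.W[1] + 0.01
        recon, nbh, _, _ = decode_local(w, small_model)
        idx = [small_model.row_ids.index(i) for i in nbh]
        sub = small_model.R_raw[idx]
        assert np.all(recon <= sub.max(axis=0) + 1e-12)
        assert np.all(recon >= sub.min(axis=0) - 1e-12)


class TestQueries:
    def test_training_self_query_confident(self, small_fixture, small_model):
        fx, _, P, R = small_fixture
        rbr = fx.rbrs()[0]
        res = protein_query(peptide_profile(rbr), small_model)
        assert res.min_edist < 1e-2 and res.confident

    def test_random_sequence_not_confident(self, small_model):
        rng = np.random.default_rng(5)
        prot = ProteinRecord(
            "rnd", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 150))
        )
        rbr = build_rbr(prot, [DomainAnnotation("rnd", "RRM", 51, 100)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = protein_query(peptide_profile(rbr), small_model)
        assert not res.confident
        assert res.min_edist > small_model.conf_cutoff

    def test_global_local_consistency_in_dense_neighborhood(
        self, small_fixture, small_model
    ):
        fx, _, P, R = small_fixture
        rbr = fx.rbrs()[1]
        local = protein_query(peptide_profile(rbr), small_model, "local")
        glob = protein_query(peptide_profile(rbr), small_model, "global")
        pcc = np.corrcoef(local.reconstruction, glob.reconstruction)[0, 1]
        assert pcc > 0.8

    def test_rna_query_round_trip(self, rng):
        P, R = random_matrices(rng, n=8, p=12, r=10)
        tm = preprocess(P, R)
        d = np.linalg.matrix_rank(np.concatenate([tm.P, tm.R], axis=1))
        model = fit_joint(tm, d=d)
        res = rna_query(R.values[2], model)
        pcc = np.corrcoef(res.reconstruction, P.values[2])[0, 1]
        assert pcc > 0.9

    def test_rna_query_zero_profile_gives_mean_peptides(self, rng):
        P, R = random_matrices(rng)
        tm = preprocess(P, R)
        model = fit_joint(tm, d=3)
        res = rna_query(np.array(tm.mu_R), model)
        np.testing.assert_allclose(res.reconstruction, tm.mu_P, atol=1e-8)

    def test_planted_templates_recovered_by_rna_query(self):
        """Top reconstructed peptide templates come from the planted
        specificity block (windows overlapping it), for every intact
        protein of a noise-free cohort."""
        from jple import ris, synthetic

        fx = synthetic.gen_families(8, 4, seed=21)
        pm = synthetic.gen_planted_model(fx, noise_sd=0.0, seed=21)
        R = synthetic.gen_profiles(fx, pm)
        P = fx.peptide_matrix()
        recon = core.loocv_rna_queries(P, R)
        std = ris.standardize_reconstructions(ris.ReconstructionSet(recon))
        cols = std.matrix.col_ids
        b0, b1 = fx.block_span
        fractions = []
        for i, (rbr, row) in enumerate(zip(fx.rbrs(), std.matrix.values)):
            if fx.band_of[rbr.protein_id] < 0.8:
                continue
            fam = fx.family_of[rbr.protein_id]
            truth_n = sum(
                1 for j in np.flatnonzero(P.values[i] > 0)
                if pm.informative_templates.get(cols[j]) == fam
            )
            block_templates = set()
            for seg, start in rbr.segments:
                for o in range(len(seg) - 4):
                    if start + o + 5 >= b0 and start + o + 1 <= b1:
                        win = seg[o : o + 5]
                        for k in range(5):
                            block_templates.add(win[:k] + "X" + win[k + 1 :])
            present = np.flatnonzero(P.values[i] > 0)
            order = sorted(present, key=lambda j: -row[j])
            top = order[:truth_n]
            fractions.append(
                np.mean([cols[j] in block_templates for j in top])
            )
        assert min(fractions) >= 0.8


class TestAugmentation:
    def test_single_identical_homolog_equals_plain_profile(self):
        rbr = RBR("t", [("MKVLWAACDE", 0)], ["RRM"])
        plain = peptide_profile(rbr).as_dict()
        P_plus = build_augmented_profiles(
            [AugmentationEntry("t", [["MKVLWAACDE"]])]
        )
        aug = dict(zip(P_plus.col_ids, P_plus.values[0]))
        assert aug == plain

    def test_duplicate_homologs_do_not_inflate(self):
        block = ["MKVLWAACDE", "MKVLWAACDE"]
        once = build_augmented_profiles([AugmentationEntry("t", [block[:1]])])
        twice = build_augmented_profiles([AugmentationEntry("t", [block])])
        np.testing.assert_allclose(once.values, twice.values)

    def test_two_distinct_homologs_hand_computed(self):
        # two 5-aa homologs differing at the last residue: each position-0
        # window has 2 distinct peptides, weight 1/2 each
        P_plus = build_augmented_profiles(
            [AugmentationEntry("t", [["MKVLW", "MKVLA"]])]
        )
        aug = dict(zip(P_plus.col_ids, P_plus.values[0]))
        assert aug["XKVLW"] == pytest.approx(0.5)
        assert aug["XKVLA"] == pytest.approx(0.5)
        assert aug["MKVLX"] == pytest.approx(1.0)  # shared template, 0.5 + 0.5

    def test_gap_columns_break_windows(self):
        P_plus = build_augmented_profiles(
            [AugmentationEntry("t", [["MKV-LWACD"]])]
        )
        aug = dict(zip(P_plus.col_ids, P_plus.values[0]))
        # windows spanning the gap contribute nothing: only LWACD remains
        assert set(aug) == {
            "XWACD", "LXACD", "LWXCD", "LWAXD", "LWACX"
        }

    def test_no_homologs_falls_back_with_warning(self):
        rbr = RBR("t", [("MKVLWAACDE", 0)], ["RRM"])
        with pytest.warns(UserWarning, match="no homologs"):
            P_plus = build_augmented_profiles(
                [AugmentationEntry("t", [], rbr=rbr)]
            )
        aug = dict(zip(P_plus.col_ids, P_plus.values[0]))
        assert aug == peptide_profile(rbr).as_dict()
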
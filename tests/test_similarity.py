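"""Cosine similarity, cross-projection, and leave-one-out robustness."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import signsynergy as ss
from signsynergy.similarity import SimilarityError


def _orthonormal(rng, k, d):
    return ss.make_basis(d, k, rng)


class TestCosineSimilarity:
    def test_self_similarity_is_one(self, rng):
        pm = rng.normal(size=(100, 57))
        assert ss.pm_cosine_similarity(pm, pm) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_components_shared_weights_give_zero(self, rng):
        basis = _orthonormal(rng, 2, 57)
        w = rng.normal(size=300)
        a = ss.weighted_pm_matrix(w, basis[0])
        b = ss.weighted_pm_matrix(w, basis[1])
        assert ss.pm_cosine_similarity(a, b) == pytest.approx(0.0, abs=1e-10)

    def test_scale_invariance(self, rng):
        pm = rng.normal(size=(50, 12))
        assert ss.pm_cosine_similarity(pm, 3.0 * pm) == pytest.approx(1.0, abs=1e-12)

    def test_zero_pm_rejected(self, rng):
        with pytest.raises(SimilarityError):
            ss.pm_cosine_similarity(np.zeros((5, 3)), rng.normal(size=(5, 3)))

    def test_signed_mode_can_be_negative(self, rng):
        pm = rng.normal(size=(20, 6))
        assert ss.pm_cosine_similarity(pm, -pm, mode="signed") == pytest.approx(-1.0)
        assert ss.pm_cosine_similarity(pm, -pm) == pytest.approx(1.0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_factorization_identity_for_shared_weights(self, seed):
        """sim(outer(w, p_i), outer(w, p_j)) equals p_i . p_j exactly."""
        rng = np.random.default_rng(seed)
        basis = rng.normal(size=(2, 30))
        basis /= np.linalg.norm(basis, axis=1, keepdims=True)
        w = rng.normal(size=200)
        got = ss.pm_cosine_similarity(
            ss.weighted_pm_matrix(w, basis[0]),
            ss.weighted_pm_matrix(w, basis[1]),
            mode="signed",
        )
        assert got == pytest.approx(float(basis[0] @ basis[1]), abs=1e-10)

    def test_symmetry_and_bounds(self, rng):
        a, b = rng.normal(size=(2, 40, 8))
        s_ab = ss.pm_cosine_similarity(a, b, mode="signed")
        s_ba = ss.pm_cosine_similarity(b, a, mode="signed")
        assert s_ab == pytest.approx(s_ba, abs=1e-14)
        assert -1.0 <= s_ab <= 1.0


class TestIndividualVsCommon:
    @pytest.fixture()
    def signer_block(self, small_normalized):
        return small_normalized.signer_block("signer1")

    def test_same_data_gives_identity_like_matrix(self, signer_block):
        own = ss.fit_pca(signer_block, frame_rate=250.0)
        res = ss.individual_vs_common(
            signer_block, own, 6, 250.0, individual=own
        )
        np.testing.assert_allclose(np.diag(res.sim_matrix), 1.0, atol=1e-8)
        off = res.sim_matrix - np.diag(np.diag(res.sim_matrix))
        assert np.abs(off).max() < 1e-6

    def test_swapped_components_reported_as_permutation(self, signer_block):
        own = ss.fit_pca(signer_block, frame_rate=250.0)
        swapped_pcs = own.pcs.copy()
        swapped_pcs[[2, 3]] = swapped_pcs[[3, 2]]
        swapped = dataclasses.replace(own, pcs=swapped_pcs)
        res = ss.individual_vs_common(
            signer_block, own, 6, 250.0, individual=swapped
        )
        assert res.best_match[2] == 3 and res.best_match[3] == 2
        assert res.sim_matrix[2, 3] == pytest.approx(1.0, abs=1e-8)
        assert res.sim_matrix[3, 2] == pytest.approx(1.0, abs=1e-8)

    def test_equal_mix_with_shared_weights_gives_707_row(self, rng):
        """PM built on (PC1 + PC3)/sqrt(2) with a shared weight signal."""
        basis = _orthonormal(rng, 3, 57)
        w = rng.normal(size=400)
        mix = (basis[0] + basis[2]) / np.sqrt(2)
        pm_mix = ss.weighted_pm_matrix(w, mix)
        row = [
            ss.pm_cosine_similarity(pm_mix, ss.weighted_pm_matrix(w, basis[j]))
            for j in range(3)
        ]
        np.testing.assert_allclose(
            row, [1 / np.sqrt(2), 0.0, 1 / np.sqrt(2)], atol=1e-6
        )

    def test_mixed_component_flagged_as_combination(self, signer_block):
        """An individual PM mixing two common PMs matches neither singly.

        When the individual basis vector is (PC1 + PC2)/sqrt(2) but weights
        come from projecting the same data on each basis, the expected
        similarities follow from the eigenvalues:
        sim_j = sqrt(lam_j / (lam_1 + lam_2)) / sqrt(2).
        """
        own = ss.fit_pca(signer_block, frame_rate=250.0)
        mixed_pcs = own.pcs.copy()
        mixed_pcs[0] = (own.pcs[0] + own.pcs[1]) / np.sqrt(2)
        mixed = dataclasses.replace(own, pcs=mixed_pcs)
        res = ss.individual_vs_common(signer_block, own, 6, 250.0, individual=mixed)
        row = res.sim_matrix[0]
        lam = own.eigenvalues
        expected = np.sqrt(lam[:2] / (lam[0] + lam[1])) / np.sqrt(2)
        # filtering perturbs the raw-weight prediction slightly
        np.testing.assert_allclose(row[:2], expected, atol=0.02)
        np.testing.assert_allclose(row[2:], 0.0, atol=0.02)
        assert res.combination_flags[0]

    def test_threshold_masks_follow_matrix(self, signer_block):
        own = ss.fit_pca(signer_block, frame_rate=250.0)
        res = ss.individual_vs_common(signer_block, own, 4, 250.0, individual=own)
        np.testing.assert_array_equal(res.high_mask, res.sim_matrix > 0.7)
        np.testing.assert_array_equal(res.moderate_mask, res.sim_matrix > 0.5)


class TestCrossProjection:
    def test_own_basis_ratio_is_one(self, rng):
        X = rng.normal(size=(2000, 20))
        X -= X.mean(axis=0)
        d = ss.fit_pca(X)
        res = ss.cross_projection(X, d, X, d, 5)
        assert res.ratio == 1.0
        assert res.symmetric == 1.0

    def test_full_basis_ratio_is_one(self, rng):
        Xa = rng.normal(size=(500, 12))
        Xa -= Xa.mean(axis=0)
        Xb = rng.normal(size=(500, 12))
        Xb -= Xb.mean(axis=0)
        da, db = ss.fit_pca(Xa), ss.fit_pca(Xb)
        res = ss.cross_projection(Xa, da, Xb, db, 12)
        assert res.ratio == pytest.approx(1.0, abs=1e-10)
        assert res.symmetric == pytest.approx(1.0, abs=1e-10)

    def test_directed_ratio_never_exceeds_one(self):
        """PCA optimality: any other basis captures at most V1 for every N."""
        rng = np.random.default_rng(77)
        for _ in range(100):
            X = rng.normal(size=(300, 10)) @ rng.normal(size=(10, 10))
            X -= X.mean(axis=0)
            d_own = ss.fit_pca(X)
            other = ss.make_basis(10, 10, rng)
            d_other = dataclasses.replace(d_own, pcs=other)
            n = int(rng.integers(1, 11))
            res = ss.cross_projection(X, d_own, X, d_other, n)
            assert res.ratio <= 1.0 + 1e-10

    def test_shared_subspace_different_dynamics_similarity_one(self):
        cfg = ss.CohortConfig(
            n_signers=2, n_trials=2, trial_s=10.0, seed=31, snr_db=None,
            share_mode="identical",
        )
        trials, _ = ss.generate_cohort(cfg)
        cohort = ss.normalized_cohort_from_trials(trials)
        a = cohort.signer_block("signer1")
        b = cohort.signer_block("signer2")
        da = ss.fit_pca(a, frame_rate=250.0)
        db = ss.fit_pca(b, frame_rate=250.0)
        res = ss.cross_projection(a, da, b, db, 8)
        assert res.symmetric == pytest.approx(1.0, abs=0.01)

    def test_n_beyond_rank_rejected(self, rng):
        X = rng.normal(size=(100, 5))
        X -= X.mean(axis=0)
        d = ss.fit_pca(X)
        with pytest.raises(SimilarityError):
            ss.cross_projection(X, d, X, d, 6)


class TestLeaveOneOut:
    def test_duplicated_signer_changes_nothing(self, rng, markerset):
        frames = rng.normal(0, 40, size=(600, markerset.count, 3))
        t1 = ss.Trial("a", "a__t0", frames, 250.0)
        t2 = ss.Trial("b", "b__t0", frames.copy(), 250.0)
        pm = ss.build_posture_matrix([t1, t2], markerset)
        cohort = ss.normalize_cohort(pm)
        for res in ss.loo_robustness(cohort, 8):
            assert res.angles_deg.max() < 0.1
            assert res.robust_flags.all()

    def test_two_signer_angles_match_double_pca_oracle(self, small_normalized):
        """Angles equal a brute-force full-vs-reduced PCA comparison."""
        cohort = small_normalized
        signers = cohort.matrix.signer_ids()
        results = ss.loo_robustness(cohort, 5)
        full = ss.fit_pca(cohort)
        for res in results:
            keep_rows = np.concatenate(
                [
                    cohort.matrix.signer_row_indices(s)
                    for s in signers
                    if s != res.left_out
                ]
            )
            reduced = ss.fit_pca(cohort.matrix.rows[np.sort(keep_rows)])
            oracle = np.degrees(
                np.arccos(
                    np.clip(
                        np.abs(np.einsum("ij,ij->i", full.pcs[:5], reduced.pcs[:5])),
                        0,
                        1,
                    )
                )
            )
            np.testing.assert_allclose(res.angles_deg, oracle, atol=1e-8)

    def test_planted_rotation_detected_on_exactly_that_pair(self):
        trials, _cfg, rotated = ss.rotated_pair_scenario(seed=42)
        cohort = ss.normalized_cohort_from_trials(trials)
        results = {r.left_out: r for r in ss.loo_robustness(cohort, 8)}
        angles = results[rotated].angles_deg
        assert angles[4] > 15.0 and angles[5] > 15.0
        others = np.delete(angles, [4, 5])
        assert others.max() < 15.0
        assert not results[rotated].robust_flags[4]

    def test_single_signer_rejected(self, rng, markerset):
        frames = rng.normal(0, 40, size=(300, markerset.count, 3))
        pm = ss.build_posture_matrix([ss.Trial("a", "a__t0", frames, 250.0)], markerset)
        with pytest.raises(SimilarityError):
            ss.loo_robustness(ss.normalize_cohort(pm), 3)

    def test_angles_shrink_as_left_out_share_shrinks(self):
        """With structure fixed, more signers make each leave-out less disruptive."""
        max_angles = []
        for n_signers in (2, 6):
            cfg = ss.CohortConfig(
                n_signers=n_signers, n_trials=2, trial_s=4.0, seed=3,
                snr_db=25.0, share_mode="identical",
            )
            trials, _ = ss.generate_cohort(cfg)
            cohort = ss.normalized_cohort_from_trials(trials)
            results = ss.loo_robustness(cohort, 4)
            max_angles.append(max(r.angles_deg.max() for r in results))
        assert max_angles[1] < max_angles[0]
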
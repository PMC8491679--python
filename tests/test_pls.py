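"""Behavioral PLS: CORR, SVD, permutation, bootstrap, scores, thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from boldvar import pls
from boldvar.pls import (
    behavioral_pls,
    bootstrap_ratios,
    brain_scores,
    behavior_scores,
    correlation_matrix,
    latent_correlation,
    permutation_pvalues,
    pls_svd,
    threshold_map,
)


def planted_data(n=40, n_voxels=30, n_behav=4, strength=1.0, seed=0):
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n)
    brain = 0.3 * rng.standard_normal((n, n_voxels))
    brain[:, : n_voxels // 3] += strength * latent[:, None]
    behav = 0.3 * rng.standard_normal((n, n_behav))
    behav += strength * latent[:, None]
    return brain, behav


class TestCorrelationMatrix:
    def test_identical_columns_correlate_to_one(self, rng):
        x = rng.standard_normal(20)
        corr = correlation_matrix(x[:, None], x[:, None])
        assert corr.values[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_negated_column_correlates_to_minus_one(self, rng):
        x = rng.standard_normal(20)
        corr = correlation_matrix(x[:, None], -x[:, None])
        assert corr.values[0, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_pearson_oracle(self):
        # Textbook Pearson on a 5-subject instance, computed explicitly
        # from covariance and standard deviations.
        brain = np.array([[1.0], [2.0], [4.0], [5.0], [8.0]])
        behav = np.array([[2.0], [1.0], [5.0], [4.0], [9.0]])
        b = brain[:, 0] - brain[:, 0].mean()
        q = behav[:, 0] - behav[:, 0].mean()
        expected = (b * q).sum() / np.sqrt((b**2).sum() * (q**2).sum())
        corr = correlation_matrix(brain, behav)
        assert corr.values[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_column_named_in_error(self, rng):
        brain = rng.standard_normal((10, 3))
        brain[:, 1] = 5.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            correlation_matrix(brain, rng.standard_normal((10, 2)))

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            correlation_matrix(rng.standard_normal((10, 3)), rng.standard_normal((9, 2)))


class TestSVD:
    def test_diagonal_corr_gives_its_diagonal_as_singular_values(self):
        corr = pls.CorrMatrix(np.array([[1.0, 0.0], [0.0, 0.5]]), ["a", "b"], np.arange(2))
        model = pls_svd(corr)
        assert np.allclose(model.s, [1.0, 0.5])

    def test_rank_one_outer_product(self):
        u = np.array([0.6, 0.8])
        v = np.zeros(5)
        v[2] = 1.0
        corr = pls.CorrMatrix(0.8 * np.outer(u, v), ["a", "b"], np.arange(5))
        model = pls_svd(corr)
        assert model.s[0] == pytest.approx(0.8, abs=1e-12)
        assert np.allclose(model.s[1:], 0.0, atol=1e-12)

    def test_reconstruction_of_random_corr(self, rng):
        values = np.clip(rng.uniform(-1, 1, (6, 40)), -1, 1)
        corr = pls.CorrMatrix(values, [f"b{i}" for i in range(6)], np.arange(40))
        m = pls_svd(corr)
        recon = m.u @ np.diag(m.s) @ m.v.T
        assert np.max(np.abs(recon - values)) < 1e-10

    def test_energy_conservation(self, rng):
        values = np.clip(rng.uniform(-1, 1, (5, 25)), -1, 1)
        corr = pls.CorrMatrix(values, [f"b{i}" for i in range(5)], np.arange(25))
        m = pls_svd(corr)
        assert (m.s**2).sum() == pytest.approx(np.linalg.norm(values) ** 2, rel=1e-12)

    def test_sign_convention_largest_behavior_salience_positive(self, rng):
        values = np.clip(rng.uniform(-1, 1, (4, 10)), -1, 1)
        corr = pls.CorrMatrix(values, list("abcd"), np.arange(10))
        m = pls_svd(corr)
        for k in range(m.n_lv):
            j = np.argmax(np.abs(m.u[:, k]))
            assert m.u[j, k] > 0

    def test_unit_norm_columns(self, rng):
        values = np.clip(rng.uniform(-1, 1, (4, 12)), -1, 1)
        m = pls_svd(pls.CorrMatrix(values, list("abcd"), np.arange(12)))
        assert np.allclose(np.linalg.norm(m.u, axis=0), 1.0)
        assert np.allclose(np.linalg.norm(m.v, axis=0), 1.0)


class TestPermutation:
    def test_add_one_convention_floor(self):
        # Strongly planted signal: observed S1 beats every permutation.
        brain, behav = planted_data(n=60, strength=3.0, seed=1)
        p = permutation_pvalues(brain, behav, n_perm=100, seed=0)
        assert p[0] == pytest.approx(1.0 / 101.0, abs=1e-12)

    def test_pvalues_within_bounds(self):
        brain, behav = planted_data(n=20, strength=0.0, seed=2)
        p = permutation_pvalues(brain, behav, n_perm=100, seed=3)
        assert np.all(p >= 1.0 / 101.0) and np.all(p <= 1.0)

    def test_deterministic_given_seed(self):
        brain, behav = planted_data(n=25, strength=0.5, seed=4)
        a = permutation_pvalues(brain, behav, n_perm=120, seed=9)
        b = permutation_pvalues(brain, behav, n_perm=120, seed=9)
        assert np.array_equal(a, b)

    def test_small_n_perm_warns(self):
        brain, behav = planted_data(n=15, seed=5)
        with pytest.warns(UserWarning):
            permutation_pvalues(brain, behav, n_perm=50, seed=0)


class TestBootstrap:
    def test_procrustes_identity_when_resample_is_original(self):
        brain, behav = planted_data(n=30, seed=6)
        corr = correlation_matrix(brain, behav)
        u0, s0, vt0 = np.linalg.svd(corr.values, full_matrices=False)
        rot = pls._procrustes_rotation(u0, u0)
        assert np.allclose(rot, np.eye(rot.shape[0]), atol=1e-10)

    def test_effect_voxels_have_larger_bsr_than_null(self):
        brain, behav = planted_data(n=60, n_voxels=60, strength=1.5, seed=7)
        bsr, lo, hi, _ = bootstrap_ratios(brain, behav, n_boot=200, seed=8)
        effect = np.abs(bsr[:20, 0])
        null = np.abs(bsr[20:, 0])
        assert np.median(effect) > np.median(null)

    def test_stable_behavior_flag_matches_ci_definition(self):
        brain, behav = planted_data(n=60, strength=2.0, seed=9)
        model = behavioral_pls(brain, behav, n_perm=100, n_boot=100, seed=10)
        for i, label in enumerate(model.behavior_labels):
            excludes_zero = model.u_ci_low[i, 0] > 0 or model.u_ci_high[i, 0] < 0
            assert (label in model.stable_behaviors(0)) == excludes_zero

    def test_degenerate_identical_rows_error(self):
        brain = np.ones((10, 5))
        behav = np.ones((10, 3))
        with pytest.raises(ValueError):
            bootstrap_ratios(brain, behav, n_boot=100, seed=0)


class TestScores:
    def test_indicator_column_picks_out_voxel(self, rng):
        p = rng.standard_normal((12, 6))
        v = np.zeros((6, 2))
        v[3, 0] = 1.0
        sc = brain_scores(v, p)
        assert np.allclose(sc[:, 0], p[:, 3])

    def test_zero_data_gives_zero_scores(self):
        assert np.allclose(brain_scores(np.ones((4, 2)), np.zeros((7, 4))), 0.0)

    def test_matches_explicit_loop_oracle(self, rng):
        v = rng.standard_normal((8, 3))
        p = rng.standard_normal((10, 8))
        u = rng.standard_normal((5, 3))
        q = rng.standard_normal((10, 5))
        bs = brain_scores(v, p)
        qs = behavior_scores(u, q)
        for s in range(10):
            for k in range(3):
                assert bs[s, k] == pytest.approx(
                    sum(v[vv, k] * p[s, vv] for vv in range(8)), rel=1e-12
                )
                assert qs[s, k] == pytest.approx(
                    sum(u[b, k] * q[s, b] for b in range(5)), rel=1e-12
                )

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            brain_scores(rng.standard_normal((5, 2)), rng.standard_normal((7, 4)))


class TestLatentCorrelation:
    def test_identical_vectors(self, rng):
        x = rng.standard_normal(15)
        r_p, r_s = latent_correlation(x, x)
        assert r_p == pytest.approx(1.0)
        assert r_s == pytest.approx(1.0)

    def test_sign_flip(self, rng):
        x = rng.standard_normal(15)
        r_p, r_s = latent_correlation(x, -x)
        assert r_p == pytest.approx(-1.0)
        assert r_s == pytest.approx(-1.0)

    def test_constant_vector_rejected(self, rng):
        with pytest.raises(ValueError):
            latent_correlation(np.ones(10), rng.standard_normal(10))


class TestThresholdMap:
    def test_all_subthreshold_gives_empty_sets(self):
        pos, neg = threshold_map(np.array([1.0, -2.0, 0.5]), np.arange(3))
        assert pos.size == 0 and neg.size == 0

    def test_boundary_value_included(self):
        pos, neg = threshold_map(np.array([3.0, -3.0, 2.999]), np.arange(3))
        assert pos.tolist() == [0]
        assert neg.tolist() == [1]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_map(np.array([1.0]), np.arange(1), threshold=0.0)


@pytest.fixture()
def instance():
    """Full-rank 4 behaviors x 6 voxels x 12 subjects oracle instance."""
    rng = np.random.default_rng(2024)
    brain = rng.standard_normal((12, 6))
    behav = rng.standard_normal((12, 4))
    return brain, behav


class TestFullModelSmallInstance:

    def test_reconstruction_and_energy(self, instance):
        brain, behav = instance
        corr = correlation_matrix(brain, behav)
        m = pls_svd(corr)
        recon = m.u @ np.diag(m.s) @ m.v.T
        assert np.max(np.abs(recon - corr.values)) < 1e-10
        assert (m.s**2).sum() == pytest.approx(
            np.linalg.norm(corr.values) ** 2, rel=1e-10
        )
        assert np.all(np.diff(m.s) <= 1e-12)

    def test_scores_match_brute_force(self, instance):
        brain, behav = instance
        model = behavioral_pls(brain, behav, n_perm=100, n_boot=100, seed=1)
        zb = (behav - behav.mean(0)) / behav.std(0)
        zv = (brain - brain.mean(0)) / brain.std(0)
        for s in range(12):
            for k in range(4):
                assert model.brain_scores[s, k] == pytest.approx(
                    sum(model.v[vv, k] * zv[s, vv] for vv in range(6)), rel=1e-9
                )
                assert model.behavior_scores[s, k] == pytest.approx(
                    sum(model.u[b, k] * zb[s, b] for b in range(4)), rel=1e-9
                )


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_energy_conservation_property(seed):
    """Sum of squared singular values equals squared Frobenius norm of CORR."""
    rng = np.random.default_rng(seed)
    n = rng.integers(5, 20)
    brain = rng.standard_normal((n, int(rng.integers(2, 15))))
    behav = rng.standard_normal((n, int(rng.integers(2, 6))))
    corr = correlation_matrix(brain, behav)
    m = pls_svd(corr)
    assert (m.s**2).sum() == pytest.approx(np.linalg.norm(corr.values) ** 2, rel=1e-8)


class TestConfigSwitches:
    def test_procrustes_corrected_permutation_variant(self):
        brain, behav = planted_data(n=40, strength=2.0, seed=11)
        p = permutation_pvalues(brain, behav, n_perm=100, seed=2, procrustes=True)
        assert np.all((p >= 1 / 101) & (p <= 1.0))
        assert p[0] == pytest.approx(1 / 101, abs=1e-12)  # strong planted LV1

    def test_bootstrap_mean_numerator_switch(self):
        brain, behav = planted_data(n=50, strength=1.5, seed=12)
        a, *_ = bootstrap_ratios(brain, behav, n_boot=150, seed=3)
        b, *_ = bootstrap_ratios(brain, behav, n_boot=150, seed=3, numerator="mean")
        assert np.all(np.isfinite(b))
        # Same resamples, same SEs: ratios agree in sign pattern on the
        # strongly planted voxels.
        assert np.array_equal(np.sign(a[:10, 0]), np.sign(b[:10, 0]))
        with pytest.raises(ValueError):
            bootstrap_ratios(brain, behav, n_boot=100, seed=0, numerator="median")
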
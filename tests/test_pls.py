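"""PLS correlation: crossblock stack, SVD, permutation, bootstrap, clusters."""

import numpy as np
import pytest

from qmripls import phantom, pls


def _random_blocks(rng, n=40, p=60, q=16, conditions=("NDI", "ODI", "FW")):
    behavior = rng.normal(size=(n, q))
    brain = {c: rng.normal(size=(n, p)) for c in conditions}
    return behavior, brain


class TestStandardize:
    def test_simple_column(self):
        z = pls.standardize_columns(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z.ravel(), [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        x = rng.normal(size=(20, 4))
        z = pls.standardize_columns(x)
        np.testing.assert_allclose(pls.standardize_columns(z), z, atol=1e-12)

    def test_constant_column_named(self):
        x = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="1"):
            pls.standardize_columns(x)


class TestCrossblock:
    def test_identical_column_gives_unit_correlation(self, rng):
        behavior, brain = _random_blocks(rng, n=30, p=5)
        brain["NDI"][:, 2] = behavior[:, 0]
        r, labels = pls.stack_crossblock(behavior, brain)
        i = labels.index((None, "NDI", 0))
        assert r[i, 2] == pytest.approx(1.0, abs=1e-12)

    def test_independent_blocks_bounded_by_fisher(self, rng):
        behavior, brain = _random_blocks(rng, n=1000, p=100,
                                         conditions=("NDI",))
        r, _ = pls.stack_crossblock(behavior, brain)
        assert np.mean(np.abs(r) >= 0.11) < 0.005

    def test_two_identical_groups_give_equal_blocks(self, rng):
        behavior, brain = _random_blocks(rng, n=30, p=8, conditions=("NDI",))
        behavior2 = np.vstack([behavior, behavior])
        brain2 = {"NDI": np.vstack([brain["NDI"], brain["NDI"]])}
        groups = np.repeat([0, 1], 30)
        r, labels = pls.stack_crossblock(behavior2, brain2, groups)
        assert r.shape == (32, 8)
        np.testing.assert_allclose(r[:16], r[16:], atol=1e-12)


class TestDecompose:
    def test_zero_matrix(self):
        s, _u, _v = pls.decompose(np.zeros((8, 10)))
        np.testing.assert_allclose(s, 0.0)

    def test_rank_one(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=9)
        s, u, v = pls.decompose(np.outer(a, b))
        assert s[0] == pytest.approx(np.linalg.norm(a) * np.linalg.norm(b))
        assert np.allclose(s[1:], 0.0, atol=1e-10)
        assert abs(abs(u[:, 0] @ (a / np.linalg.norm(a)))) == pytest.approx(1.0)
        assert abs(abs(v[:, 0] @ (b / np.linalg.norm(b)))) == pytest.approx(1.0)

    def test_sign_convention(self, rng):
        r = rng.normal(size=(10, 20))
        _s, _u, v = pls.decompose(r)
        for l in range(v.shape[1]):
            assert v[np.argmax(np.abs(v[:, l])), l] > 0

    def test_matches_gram_eigendecomposition(self, rng):
        r = rng.normal(size=(12, 40))
        s, _u, v = pls.decompose(r)
        evals, evecs = np.linalg.eigh(r.T @ r)
        s_oracle = np.sqrt(np.maximum(evals[::-1], 0))[:12]
        np.testing.assert_allclose(s, s_oracle, atol=1e-8)
        for l in range(3):
            assert abs(v[:, l] @ evecs[:, -1 - l]) == pytest.approx(1.0, abs=1e-8)

    def test_frobenius_identity(self, rng):
        r = rng.normal(size=(10, 30))
        s, _u, _v = pls.decompose(r)
        assert np.sum(s ** 2) == pytest.approx(np.sum(r ** 2), rel=1e-10)


class TestCovFraction:
    def test_examples(self):
        np.testing.assert_allclose(pls.covariance_fraction(np.array([2.0, 1, 1])),
                                   [400 / 6, 100 / 6, 100 / 6])
        np.testing.assert_allclose(pls.covariance_fraction(np.array([3.0, 0])),
                                   [100.0, 0.0])
        assert pls.covariance_fraction(np.array([1.0, 2, 3])).sum() == \
            pytest.approx(100.0, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            pls.covariance_fraction(np.zeros(3))


class TestBrainScores:
    def test_one_hot_salience_returns_voxel_column(self, rng):
        x = pls.standardize_columns(rng.normal(size=(20, 6)))
        v = np.zeros((6, 1))
        v[3, 0] = 1.0
        np.testing.assert_allclose(pls.compute_brain_scores(x, v)[:, 0], x[:, 3])

    def test_hand_worked_product(self):
        x = np.array([[1.0, 2.0], [0.0, -1.0], [3.0, 1.0]])
        v = np.array([[0.6], [0.8]])
        np.testing.assert_allclose(pls.compute_brain_scores(x, v).ravel(),
                                   [2.2, -0.8, 2.6])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            pls.compute_brain_scores(np.zeros((4, 3)), np.zeros((5, 1)))


class TestContributions:
    def test_concentrated_and_uniform(self):
        labels = [(None, c, m) for c in ("NDI", "ODI", "FW") for m in range(16)]
        u = np.zeros(48)
        u[:16] = 0.25
        out = pls.condition_contributions(u, labels)
        assert out["NDI"] == pytest.approx(100.0)
        uniform = pls.condition_contributions(np.ones(48), labels)
        for c in ("NDI", "ODI", "FW"):
            assert uniform[c] == pytest.approx(100.0 / 3.0)


class TestPermutation:
    def test_add_one_counting_rule_and_determinism(self):
        # a planted deterministic association beats every permutation
        rng = np.random.default_rng(0)
        n, p = 40, 30
        z = rng.normal(size=n)
        behavior = np.tile(z[:, None], (1, 16)) + 0.01 * rng.normal(size=(n, 16))
        brain = {"NDI": np.outer(z, rng.normal(size=p))
                 + 0.01 * rng.normal(size=(n, p))}
        p1 = pls.permutation_test(behavior, brain, n_perm=100, seed=7)
        assert p1[0] == pytest.approx(1.0 / 101.0)
        p2 = pls.permutation_test(behavior, brain, n_perm=100, seed=7)
        np.testing.assert_array_equal(p1, p2)

    def test_subject_order_invariance(self, rng):
        behavior, brain = _random_blocks(rng, n=30, p=20)
        perm = rng.permutation(30)
        r1, _ = pls.stack_crossblock(behavior, brain)
        r2, _ = pls.stack_crossblock(behavior[perm],
                                     {c: x[perm] for c, x in brain.items()})
        s1, *_ = pls.decompose(r1)
        s2, *_ = pls.decompose(r2)
        np.testing.assert_allclose(s1, s2, atol=1e-10)


class TestBootstrap:
    def test_degenerate_voxel_has_large_bsr(self, rng):
        n = 60
        z = rng.normal(size=n)
        behavior = rng.normal(size=(n, 16))
        behavior[:, 0] = z
        brain = {"NDI": np.column_stack([z, rng.normal(size=(n, 4))])}
        out = pls.bootstrap(behavior, brain, n_boot=100, seed=1, n_keep=1)
        assert abs(out.bsr[0, 0]) > 10.0

    def test_deterministic_pair_ci_excludes_zero(self, rng):
        n = 50
        z = rng.normal(size=n)
        behavior = np.column_stack([z] + [rng.normal(size=n) for _ in range(15)])
        brain = {"NDI": np.column_stack([z + 0.05 * rng.normal(size=n),
                                         rng.normal(size=(n, 3))])}
        out = pls.bootstrap(behavior, brain, n_boot=150, seed=2, n_keep=1)
        # row 0 is (metric 0, NDI); its correlation with the brain score is
        # driven by the planted pair
        assert out.corr_ci_low[0, 0] > 0.0

    def test_procrustes_reduces_salience_variance_with_close_lvs(self):
        # two planted latents of similar strength: without alignment,
        # axis swapping inflates the bootstrap SD of the saliences
        spec = phantom.PhantomSpec(
            n_subjects=80, grid_shape=(8, 8, 8), seed=4,
            latent_strength=np.array([[8.0, 7.0], [7.0, 8.0], [0.5, 0.5]]))
        t = phantom.make_phantom(spec)
        brain = {c: t.noddi_maps[c].reshape(80, -1) for c in phantom.CONDITIONS}
        behavior = t.behavior.to_numpy()
        aligned = pls.bootstrap(behavior, brain, n_boot=100, seed=3, n_keep=2)

        # unaligned rerun: force identity rotation by aligning to itself
        rng = np.random.default_rng(3)
        r_obs, _ = pls.stack_crossblock(behavior, brain)
        _s, _u, v_obs = pls.decompose(r_obs)
        sds = []
        vs = []
        for _ in range(100):
            draw = rng.choice(80, size=80, replace=True)
            b = pls.standardize_columns(behavior[draw])
            xs = {c: pls.standardize_columns(x[draw]) for c, x in brain.items()}
            rows = [b.T @ x / (79) for x in xs.values()]
            _sb, _ub, vb = pls.decompose(np.vstack(rows))
            vs.append(vb[:, :2])
        sd_raw = np.std(np.array(vs), axis=0)
        assert np.median(sd_raw) > np.median(aligned.v_boot_sd)

    def test_bootstrap_reproducible(self, rng):
        behavior, brain = _random_blocks(rng, n=25, p=15, conditions=("NDI",))
        a = pls.bootstrap(behavior, brain, n_boot=100, seed=9, n_keep=2)
        b = pls.bootstrap(behavior, brain, n_boot=100, seed=9, n_keep=2)
        np.testing.assert_array_equal(a.bsr, b.bsr)


class TestClusters:
    def test_32_voxel_floor(self):
        vol = np.zeros((10, 10, 10))
        vol[0, 0:4, 0:8] = 5.0  # 32-voxel slab -> kept
        keep = pls.bsr_threshold_clusters(vol)
        assert keep.sum() == 32
        vol[0, 3, 7] = 0.0  # now 31 voxels -> removed
        assert pls.bsr_threshold_clusters(vol).sum() == 0

    def test_subthreshold_everywhere_is_empty(self):
        assert not pls.bsr_threshold_clusters(np.full((5, 5, 5), 1.9)).any()

    def test_opposite_sign_touching_blobs_are_separate(self):
        vol = np.zeros((10, 10, 4))
        vol[0:4, 0:4, 0:2] = 5.0    # 32 voxels positive
        vol[4:8, 0:4, 0:2] = -5.0   # 32 voxels negative, touching
        keep = pls.bsr_threshold_clusters(vol, min_cluster=32)
        assert keep.sum() == 64
        # shrink the negative blob below the floor: only positive survives
        vol[7, :, :] = 0.0
        keep = pls.bsr_threshold_clusters(vol, min_cluster=32)
        assert keep.sum() == 32


class TestRunPls:
    def test_end_to_end_structure_and_matched_pair_dominance(self):
        t = phantom.make_phantom(phantom.PhantomSpec(
            n_subjects=60, grid_shape=(10, 10, 6), seed=8))
        brain = {c: t.noddi_maps[c].reshape(60, -1) for c in phantom.CONDITIONS}
        res = pls.run_pls(t.behavior.to_numpy(), brain, n_perm=100,
                          n_boot=100, seed=1, n_keep=2)
        assert res.cov_fraction.sum() == pytest.approx(100.0, abs=1e-9)
        assert res.perm_p[0] < 0.05
        # the LV-1 brain score correlates best with its own latent
        score = res.brain_scores["NDI"][:, 0]
        r_own = abs(np.corrcoef(score, t.latent_scores[:, 0])[0, 1])
        r_other = abs(np.corrcoef(score, t.latent_scores[:, 1])[0, 1])
        assert r_own > r_other

    def test_grouped_model_shapes(self, rng):
        behavior, brain = _random_blocks(rng, n=40, p=25)
        groups = np.repeat([0, 1], 20)
        res = pls.run_pls(behavior, brain, groups=groups, n_perm=0, n_boot=0)
        assert res.u.shape[0] == 2 * 3 * 16
        assert len(res.row_labels) == 96
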
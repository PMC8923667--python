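"""FC matrices, sparsification, cosine affinity and diffusion embedding."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import pearsonr

import inttopo as it
from inttopo.containers import VoxelTimeSeries

from .oracles import cosine_affinity_oracle, dense_diffusion_oracle, match_up_to_sign


def _vts(values, tr=1.1):
    return VoxelTimeSeries(np.asarray(values, float), tr)


class TestFcMatrix:
    def test_self_and_negation(self, rng):
        x = rng.standard_normal(100)
        fc = it.fc_matrix(_vts(np.stack([x, -x])))
        assert fc.values[0, 0] == pytest.approx(1.0)
        assert fc.values[0, 1] == pytest.approx(-1.0)
        assert fc.symmetric

    def test_matches_numpy_corrcoef(self, rng):
        x = rng.standard_normal((7, 90))
        fc = it.fc_matrix(_vts(x))
        np.testing.assert_allclose(fc.values, np.corrcoef(x), atol=1e-12)

    def test_independent_white_noise_is_near_zero(self):
        hits = 0
        for seed in range(200):
            x = np.random.default_rng(seed).standard_normal((2, 700))
            if abs(it.fc_matrix(_vts(x)).values[0, 1]) < 3 / np.sqrt(700):
                hits += 1
        assert hits >= 195  # ~99% of draws

    def test_zero_variance_voxel_flagged_not_dropped(self, rng):
        x = rng.standard_normal((3, 50))
        x[1] = 2.0
        fc = it.fc_matrix(_vts(x))
        assert list(fc.bad_sources) == [1]
        assert np.isnan(fc.values[1]).all() and np.isnan(fc.values[:, 1]).all()
        assert fc.values[0, 0] == pytest.approx(1.0)

    def test_cross_structure_matrix_is_rectangular(self, rng):
        a, b = rng.standard_normal((4, 80)), rng.standard_normal((6, 80))
        fc = it.fc_matrix(_vts(a), _vts(b))
        assert fc.shape == (4, 6) and not fc.symmetric


class TestGroupFc:
    def test_identical_matrices_unchanged(self, rng):
        x = rng.standard_normal((5, 60))
        fc = it.fc_matrix(_vts(x))
        merged = it.group_fc([fc, fc, fc])
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(merged.values[off], fc.values[off], atol=1e-12)

    def test_fisher_mean_closed_form(self):
        m1 = it.FcMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]), symmetric=True)
        m2 = it.FcMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), symmetric=True)
        merged = it.group_fc([m1, m2])
        assert merged.values[0, 1] == pytest.approx(np.tanh(np.arctanh(0.5) / 2), abs=1e-12)
        assert merged.values[0, 0] >= 1 - 2e-7  # clipped diagonal survives

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            it.group_fc([it.FcMatrix(np.eye(2)), it.FcMatrix(np.eye(3))])


class TestSparsify:
    def test_top_entry_survives_at_ten_percent(self, rng):
        row = rng.permutation(10).astype(float)[None, :]
        out = it.sparsify(it.FcMatrix(row / 10), density=0.1)
        assert np.count_nonzero(out.values) == 1
        assert out.values[0, row.argmax()] == row.max() / 10

    def test_tie_at_cutoff_keeps_lower_column(self):
        row = np.array([[0.5, 0.5, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]])
        out = it.sparsify(it.FcMatrix(row), density=0.1)
        assert out.values[0, 0] == 0.5 and out.values[0, 1] == 0.0

    def test_density_one_is_identity(self, rng):
        fc = it.fc_matrix(_vts(rng.standard_normal((6, 40))))
        np.testing.assert_array_equal(it.sparsify(fc, 1.0).values, fc.values)

    @pytest.mark.parametrize("density", [0.0, -0.2, 1.5])
    def test_bad_density_rejected(self, density):
        with pytest.raises(ValueError):
            it.sparsify(it.FcMatrix(np.eye(3)), density)

    @given(st.integers(0, 10_000), st.floats(0.05, 0.95))
    def test_keep_count_is_ceil_density_times_cols(self, seed, density):
        v = np.clip(np.random.default_rng(seed).standard_normal((4, 30)), -1, 1)
        out = it.sparsify(it.FcMatrix(v), density)
        expected = int(np.ceil(density * 30))
        # kept entries are the largest by signed value, per row
        assert (np.count_nonzero(out.values, axis=1) <= expected).all()
        for r in range(4):
            kept = out.values[r][out.values[r] != 0]
            dropped_max = np.sort(v[r])[:-expected].max()
            assert kept.min() >= dropped_max - 1e-12


class TestCosineAffinity:
    def test_identical_and_disjoint_rows(self):
        x = it.FcMatrix(np.array([[1.0, 1.0, 0.0, 0.0],
                                  [1.0, 1.0, 0.0, 0.0],
                                  [0.0, 0.0, 0.5, 0.5]]) / 2)
        a = it.cosine_affinity(x)
        assert a.values[0, 1] == pytest.approx(1.0)
        assert a.values[0, 2] == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self, rng):
        x = rng.standard_normal((8, 20))
        x[np.abs(x) < 0.8] = 0.0
        x = np.clip(x, -1, 1)
        a = it.cosine_affinity(it.FcMatrix(x))
        np.testing.assert_allclose(a.values, cosine_affinity_oracle(x), atol=1e-12)

    def test_all_zero_row_raises_with_indices(self):
        x = np.array([[0.5, 0.5], [0.0, 0.0]])
        with pytest.raises(ValueError, match=r"\[1\]"):
            it.cosine_affinity(it.FcMatrix(x))

    def test_symmetry_to_1e12(self, rng):
        x = rng.standard_normal((12, 25))
        a = it.cosine_affinity(it.FcMatrix(np.clip(x, -1, 1)))
        assert np.abs(a.values - a.values.T).max() <= 1e-12


def _random_affinity(rng, n):
    x = rng.random((n, n))
    w = (x + x.T) / 2
    np.fill_diagonal(w, 1.0)
    return w


class TestDiffusionEmbedding:
    def test_matches_dense_oracle_up_to_sign(self, rng):
        for _ in range(5):
            w = _random_affinity(rng, 50)
            g = it.diffusion_embedding(it.AffinityMatrix(w), 5)
            comps, lam = dense_diffusion_oracle(w, 5)
            assert match_up_to_sign(g.components, comps, 1e-8)
            np.testing.assert_allclose(g.eigenvalues, lam, atol=1e-10)

    def test_two_bridged_blocks_separate_on_first_component(self):
        w = np.full((6, 6), 1e-6)
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        w = (w + w.T) / 2
        g = it.diffusion_embedding(it.AffinityMatrix(w), 2)
        c1 = g.component(1)
        assert np.ptp(np.sign(c1[:3])) == 0 and np.ptp(np.sign(c1[3:])) == 0
        assert np.sign(c1[0]) == -np.sign(c1[3])
        assert np.abs(c1[:3] - c1[:3].mean()).max() < 1e-3 * np.abs(c1).max()

    def test_uniform_affinity_has_vanishing_spectrum(self):
        g = it.diffusion_embedding(it.AffinityMatrix(np.full((20, 20), 0.5)), 3)
        assert np.abs(g.eigenvalues).max() < 1e-10

    def test_disconnected_affinity_raises(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            it.diffusion_embedding(it.AffinityMatrix(w), 2)

    def test_permutation_equivariance_up_to_sign(self, rng):
        w = _random_affinity(rng, 30)
        perm = rng.permutation(30)
        g = it.diffusion_embedding(it.AffinityMatrix(w), 3)
        gp = it.diffusion_embedding(it.AffinityMatrix(w[np.ix_(perm, perm)]), 3)
        assert match_up_to_sign(gp.components, g.components[:, perm], 1e-8)

    def test_eigenvalues_descending_in_unit_interval(self, rng):
        g = it.diffusion_embedding(it.AffinityMatrix(_random_affinity(rng, 40)), 8)
        assert (np.diff(g.eigenvalues) <= 1e-12).all()
        assert g.eigenvalues.min() >= -1e-9 and g.eigenvalues.max() <= 1.0


class TestTopographyRecovery:
    def test_first_gradient_recovers_planted_axis(self):
        """Graded-mixing synthetic data: |r|(G1, planted axis) >= 0.9 (median, 20 seeds)."""
        rs = []
        for seed in range(20):
            cfg = it.SyntheticConfig(n_subjects=1, n_runs=5, seed=seed)
            ds = it.generate_dataset(cfg)
            fc = it.group_fc([it.fc_matrix(r) for r in ds.runs_for("sub-01")])
            grads = it.diffusion_embedding(it.cosine_affinity(it.sparsify(fc)), 5)
            rs.append(abs(pearsonr(grads.component(1), ds.ground_truth.gradient_axis).statistic))
        assert np.median(rs) >= 0.9
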
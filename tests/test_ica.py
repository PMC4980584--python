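"""Spatial ICA decomposition, z-maps, voxel selection and the weighted AIF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icaperf import ica as I
from icaperf.concentration import ConversionParams
from icaperf.phantom import PhantomSpec, build_phantom


class TestChooseComponents:
    def test_cumulative_eigenvalue_rule(self):
        # cumulative sums 0.90, 0.98, 0.995 -> three components reach 0.99
        assert I.choose_n_components([0.90, 0.08, 0.015, 0.005], 0.99) == 3

    def test_full_spectrum_needed(self):
        assert I.choose_n_components([0.5, 0.3, 0.2], 1.0) == 3


class TestDecompose:
    def test_recovers_disjoint_sources(self):
        # two spatially disjoint, strongly non-Gaussian maps under a random
        # 2x2 mixing; best-matched component maps correlate >= 0.99
        rng = np.random.default_rng(0)
        v, p = 400, 30
        m1 = np.zeros(v); m1[:50] = 1.0
        m2 = np.zeros(v); m2[200:250] = 1.0
        tc = rng.normal(size=(p, 2))
        A = rng.normal(size=(2, 2))
        X = (tc @ A) @ np.vstack([m1, m2]) + rng.normal(0, 0.01, (p, v))
        ic = I.decompose(X, n_components=2, seed=1)
        for target in (m1, m2):
            r = max(abs(np.corrcoef(target, comp)[0, 1]) for comp in ic.component_maps)
            assert r >= 0.99

    def test_too_many_components_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 50))
        with pytest.raises(ValueError):
            I.decompose(X, n_components=11, seed=0)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            I.decompose(np.ones((10, 50)), n_components=2, seed=0)

    def test_exactly_one_dimension_argument(self):
        X = np.random.default_rng(0).normal(size=(10, 50))
        with pytest.raises(ValueError):
            I.decompose(X, seed=0)
        with pytest.raises(ValueError):
            I.decompose(X, n_components=2, variance_fraction=0.9, seed=0)

    def test_deterministic_given_seed(self, noisy_phantom):
        _, series, _ = noisy_phantom
        a = I.decompose(series, n_components=5, seed=3)
        b = I.decompose(series, n_components=5, seed=3)
        np.testing.assert_array_equal(a.component_maps, b.component_maps)
        np.testing.assert_array_equal(a.time_courses, b.time_courses)

    def test_reconstruction_error_bounded(self, noisy_phantom):
        # retained components explain at least the requested eigenvalue mass
        _, series, _ = noisy_phantom
        vf = 0.99
        ic = I.decompose(series, variance_fraction=vf, seed=0)
        X = series.as_matrix()
        resid = ic.reconstruct() - X
        Xc = X - X.mean(axis=1, keepdims=True)
        rel = (resid ** 2).sum() / (Xc ** 2).sum()
        assert rel <= 1 - vf + 0.02


class TestZMap:
    def test_population_convention(self):
        z = I.zscore_map(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z.values, [-1.22474487, 0.0, 1.22474487])
        assert z.values.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.values.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_mean_voxel_maps_to_zero(self):
        z = I.zscore_map(np.array([1.0, 3.0, 2.0, 2.0]))
        assert z.values[np.array([1.0, 3.0, 2.0, 2.0]) == 2.0] == pytest.approx(0.0)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            I.zscore_map(np.full(10, 3.3))


class TestTopK:
    def test_distinct_values(self):
        rng = np.random.default_rng(2)
        vals = rng.permutation(81).astype(float)
        z = I.zscore_map(vals)
        top = I.top_k_voxels(z, 50)
        assert set(top.tolist()) == set(np.argsort(vals)[-50:].tolist())

    def test_single_larger_value(self):
        vals = np.zeros(20); vals[13] = 1.0
        top = I.top_k_voxels(I.zscore_map(vals), 1)
        assert top.tolist() == [13]

    def test_tie_break_lowest_index(self):
        # ties straddling the cut: lowest-index tied voxels enter
        vals = np.array([5.0, 1.0, 3.0, 3.0, 3.0, 0.0])
        top = I.top_k_voxels(I.zscore_map(vals), 3)
        assert sorted(top.tolist()) == [0, 2, 3]

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            I.top_k_voxels(I.zscore_map(np.arange(5.0)), 6)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(min_value=-3, max_value=3), min_size=5, max_size=40),
           st.integers(min_value=1, max_value=5))
    def test_matches_full_sort_oracle(self, vals, k):
        vals = np.asarray(vals, dtype=float)
        if np.unique(vals).size < 2 or k > vals.size:
            return
        top = I.top_k_voxels(I.zscore_map(vals), k)
        oracle = sorted(range(vals.size), key=lambda i: (-vals[i], i))[:k]
        assert sorted(top.tolist()) == sorted(oracle)


class TestWeightedAIF:
    def test_uniform_z_reduces_to_plain_mean(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 6))
        z = I.ZMap(values=np.full(6, 2.0), mean_ic=0, std_ic=1,
                   voxel_ids=np.arange(6))
        aif = I.weighted_aif(X, np.arange(6), z)
        np.testing.assert_allclose(aif.curve, X.mean(axis=1), rtol=1e-12)

    def test_single_voxel(self):
        X = np.random.default_rng(1).random((30, 4))
        z = I.ZMap(values=np.array([1.0, 2.0, 3.0, 4.0]), mean_ic=0, std_ic=1,
                   voxel_ids=np.arange(4))
        aif = I.weighted_aif(X, np.array([2]), z)
        np.testing.assert_allclose(aif.curve, X[:, 2])

    def test_two_voxel_hand_computation(self):
        # z = [3, 1] -> weights [1.5, 0.5] -> (1.5 S1 + 0.5 S2) / 2
        X = np.random.default_rng(2).random((30, 2))
        z = I.ZMap(values=np.array([3.0, 1.0]), mean_ic=0, std_ic=1,
                   voxel_ids=np.array([0, 1]))
        aif = I.weighted_aif(X, np.array([0, 1]), z)
        np.testing.assert_allclose(aif.curve, (1.5 * X[:, 0] + 0.5 * X[:, 1]) / 2,
                                   rtol=1e-12)

    def test_nonpositive_z_excluded(self):
        X = np.random.default_rng(3).random((30, 3))
        z = I.ZMap(values=np.array([2.0, -1.0, 1.0]), mean_ic=0, std_ic=1,
                   voxel_ids=np.arange(3))
        aif = I.weighted_aif(X, np.arange(3), z)
        assert 1 not in aif.voxel_ids.tolist()


class TestRankingAndSelection:
    @pytest.mark.parametrize("seed", [2, 4])
    def test_artery_pole_ranks_first_on_phantom(self, seed):
        from icaperf.evaluation import segment_phantom

        res = segment_phantom(PhantomSpec(cnr=70.0, seed=seed), n_restarts=4)
        assert res["artery_score"][True].true_rate >= 0.9

    def test_equal_scores_stable_order(self):
        a = I.ComponentScore(component=1, score=1.0, fit=None, sign=1)
        b = I.ComponentScore(component=0, score=1.0, fit=None, sign=-1)
        c = I.ComponentScore(component=0, score=1.0, fit=None, sign=1)
        ordered = sorted([a, b, c], key=lambda s: (-s.score, s.component, -s.sign))
        assert [(s.component, s.sign) for s in ordered] == [(0, 1), (0, -1), (1, 1)]

    def test_selection_invariant_to_restart_order(self, noisy_phantom):
        spec, series, _ = noisy_phantom
        conv = ConversionParams(baseline_window=(1, 6))
        runs = I.decompose_ensemble(series, n_components=10, seed=1,
                                    n_restarts=3, conv=conv, dt=spec.dt)
        a1, s1 = I.select_artery_surround(runs)
        a2, s2 = I.select_artery_surround(list(reversed(runs)))
        assert set(a1.voxels.tolist()) == set(a2.voxels.tolist())
        if s1 is not None and s2 is not None:
            assert set(s1.voxels.tolist()) == set(s2.voxels.tolist())

    def test_weighted_close_to_unweighted(self, noisy_phantom):
        # the z-weighted and plain-average AIFs from one voxel set differ by
        # far less than AIFs from different sources do
        spec, series, truth = noisy_phantom
        ic = I.decompose(series, n_components=10, seed=7)
        conv = ConversionParams(baseline_window=(1, 6))
        ranking = I.rank_components(ic, conv, spec.dt)
        best = ranking[0]
        z = I.component_zmap(ic, best.component, best.sign)
        vox = I.top_k_voxels(z, 50)
        X = series.as_matrix()
        weighted = I.weighted_aif(X, vox, z).curve
        plain = X[:, vox].mean(axis=1)
        between = np.abs(truth.pure_signals["artery"] - truth.pure_signals["surround"]).max()
        assert np.abs(weighted - plain).max() < between


class TestCompactness:
    def test_contiguous_beats_scattered(self):
        shape = (9, 21)
        block = np.arange(27)  # contiguous rows 0-1ish of the grid
        scattered = np.arange(0, 27 * 7, 7)
        assert I.compactness(block, shape) > I.compactness(scattered, shape)
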
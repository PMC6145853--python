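"""PCA denoising, FastICA runs, robustness clustering, model order."""

import numpy as np
import pytest

from hconnica import (
    DecompositionConfig,
    DecompositionError,
    InsufficientSubjectsError,
    RunResult,
    SyntheticSpec,
    cluster_robust_traits,
    decompose,
    generate_hybrid_population,
    pca_denoise,
    run_ica,
    sample_run_cohort,
    select_model_order,
)


class TestPcaDenoise:
    def test_exact_rank_two_matrix_retains_two_components(self, rng):
        X = rng.normal(size=(10, 2)) @ rng.normal(size=(2, 50))
        recon, k, cum = pca_denoise(X, 0.90)
        assert k == 2
        assert np.abs(recon - X).max() <= 1e-10

    def test_fraction_one_reconstructs_input(self, rng):
        X = rng.normal(size=(8, 30))
        recon, k, _ = pca_denoise(X, 1.0)
        np.testing.assert_allclose(recon, X, atol=1e-10)

    def test_fraction_above_one_rejected(self, rng):
        with pytest.raises(DecompositionError):
            pca_denoise(rng.normal(size=(5, 5)), 1.1)

    def test_planted_five_traits_bracket_retained_rank(self):
        hy, _ = generate_hybrid_population(SyntheticSpec(n_nodes=32), seed=0)
        _, k, _ = pca_denoise(hy.data, 0.90)
        assert 5 <= k <= hy.n_profiles - 1


class TestSampleRunCohort:
    def test_hundred_subjects_eight_conditions(self, rng):
        subs = [f"S{i}" for i in range(100) for _ in range(8)]
        conds = [f"C{c}" for _ in range(100) for c in range(8)]
        rows = sample_run_cohort(subs, conds, 10, rng)
        chosen_subs = [subs[r] for r in rows]
        chosen_conds = [conds[r] for r in rows]
        assert len(rows) == 80
        assert len(set(chosen_subs)) == 80
        assert all(chosen_conds.count(f"C{c}") == 10 for c in range(8))

    def test_exact_matching_returned_when_it_exists(self, rng):
        subs = [f"S{i}" for i in range(8)]
        conds = [f"C{i}" for i in range(8)]
        rows = sample_run_cohort(subs, conds, 1, rng)
        assert sorted(rows.tolist()) == list(range(8))

    def test_insufficient_subjects_rejected(self, rng):
        subs = ["A", "B", "C", "A", "B", "C", "A"]
        conds = ["C1", "C1", "C1", "C2", "C2", "C2", "C3"]
        with pytest.raises(InsufficientSubjectsError):
            sample_run_cohort(subs, conds, 2, rng)

    def test_deterministic_given_seed(self):
        subs = [f"S{i}" for i in range(40) for _ in range(4)]
        conds = [f"C{c}" for _ in range(40) for c in range(4)]
        a = sample_run_cohort(subs, conds, 5, np.random.default_rng(7))
        b = sample_run_cohort(subs, conds, 5, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


def planted_mixture(rng, P=40, L=1500, K=3):
    """Noise-free mixture of sparse leptokurtic sources."""
    S = rng.laplace(size=(K, L)) * (rng.random((K, L)) < 0.2)
    S /= np.linalg.norm(S, axis=1, keepdims=True)
    A = rng.normal(size=(P, K))
    return A @ S, A, S


class TestRunIca:
    def test_recovers_planted_sparse_sources(self, rng):
        X, A, S = planted_mixture(rng)
        res = run_ica(X, 3, seed=0)
        cross = np.abs(np.corrcoef(np.vstack([S, res.components]))[:3, 3:])
        # every planted source matched by some component up to sign/permutation
        assert (cross.max(axis=1) > 0.99).all()

    def test_same_seed_bit_identical(self, rng):
        X, _, _ = planted_mixture(rng)
        a = run_ica(X, 3, seed=11)
        b = run_ica(X, 3, seed=11)
        np.testing.assert_array_equal(a.components, b.components)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_components_unit_norm_and_reconstruction(self, rng):
        X, _, _ = planted_mixture(rng)
        res = run_ica(X, 3, seed=2)
        np.testing.assert_allclose(
            np.linalg.norm(res.components, axis=1), 1.0, atol=1e-9)
        recon = res.weights @ res.components
        # mixture is mean-free per profile up to centering; compare centered
        Xc = X - X.mean(axis=1, keepdims=True)
        rc = recon - recon.mean(axis=1, keepdims=True)
        assert np.abs(Xc - rc).max() < 1e-6 * np.abs(Xc).max() + 1e-8

    def test_m_above_rank_rejected(self, rng):
        X = rng.normal(size=(4, 2)) @ rng.normal(size=(2, 100))
        with pytest.raises(DecompositionError, match="rank"):
            run_ica(X, 3, seed=0)

    def test_column_shuffle_equivariance(self, rng):
        X, _, _ = planted_mixture(rng)
        perm = rng.permutation(X.shape[1])
        a = run_ica(X, 3, seed=5)
        b = run_ica(X[:, perm], 3, seed=5)
        unshuffled = np.empty_like(b.components)
        unshuffled[:, perm] = b.components
        cross = np.abs(np.corrcoef(
            np.vstack([a.components, unshuffled]))[:3, 3:])
        assert (cross.max(axis=1) > 0.999).all()


def synthetic_runs(rng, n_runs=10, M=4, L=600, common=None):
    """RunResults sharing one planted component plus M-1 random ones."""
    if common is None:
        common = rng.normal(size=L)
    common = common / np.linalg.norm(common)
    runs = []
    for r in range(n_runs):
        comps = rng.normal(size=(M, L))
        comps[0] = common * (1 if r % 2 == 0 else -1)  # sign flips across runs
        comps /= np.linalg.norm(comps, axis=1, keepdims=True)
        runs.append(RunResult(
            run_id=r, profile_indices=np.arange(20),
            components=comps, weights=rng.normal(size=(20, M)),
            converged=True, seed=r,
        ))
    return runs


class TestClusterRobustTraits:
    def test_identical_runs_all_components_frequency_one(self, rng):
        comps = rng.normal(size=(4, 500))
        comps /= np.linalg.norm(comps, axis=1, keepdims=True)
        runs = [RunResult(run_id=r, profile_indices=np.arange(10),
                          components=comps.copy(),
                          weights=rng.normal(size=(10, 4)),
                          converged=True, seed=r) for r in range(5)]
        traits = cluster_robust_traits(runs, 0.5, 0.5)
        assert len(traits) == 4
        assert all(t.frequency == 1.0 for t in traits)

    def test_single_common_component_yields_one_robust_trait(self, rng):
        runs = synthetic_runs(rng)
        traits = cluster_robust_traits(runs, 0.5, 0.5)
        assert len(traits) == 1
        assert traits[0].frequency == 1.0

    def test_sign_aligned_mean_invariant(self, rng):
        runs = synthetic_runs(rng)
        traits = cluster_robust_traits(runs, 0.5, 0.5)
        t = traits[0]
        stacked = []
        for run_id, comp_id, _, sign in t.members:
            stacked.append(sign * runs[run_id].components[comp_id])
        np.testing.assert_allclose(t.vector, np.mean(stacked, axis=0),
                                   atol=1e-12)

    def test_frequency_monotone_in_r_threshold(self, rng):
        runs = synthetic_runs(rng, n_runs=12)
        freqs = []
        for r_thresh in (0.3, 0.5, 0.7, 0.9):
            traits = cluster_robust_traits(runs, r_thresh, 0.1)
            freqs.append(max((t.frequency for t in traits), default=0.0))
        assert all(a >= b for a, b in zip(freqs, freqs[1:]))

    def test_single_run_returns_empty_with_warning(self, rng):
        runs = synthetic_runs(rng, n_runs=1)
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert cluster_robust_traits(runs, 0.5, 0.5) == []

    def test_weights_averaged_only_over_sampling_runs(self, rng):
        # two runs on disjoint cohorts: each profile's weight comes from
        # exactly one run, never-sampled profiles are NaN
        common = rng.normal(size=300)
        runs = []
        for r, rows in enumerate((np.arange(0, 10), np.arange(10, 20))):
            comps = np.vstack([common, rng.normal(size=300)])
            comps /= np.linalg.norm(comps, axis=1, keepdims=True)
            runs.append(RunResult(
                run_id=r, profile_indices=rows, components=comps,
                weights=rng.normal(size=(10, 2)), converged=True, seed=r))
        traits = cluster_robust_traits(runs, 0.5, 0.5, n_profiles=25)
        t = traits[0]
        assert np.isfinite(t.weights[:20]).all()
        assert np.isnan(t.weights[20:]).all()
        assert t.counts[:20].max() == 1


class TestDecomposeAndModelOrder:
    def test_decompose_deterministic(self):
        hy, _ = generate_hybrid_population(SyntheticSpec(n_nodes=24), seed=3)
        cfg = DecompositionConfig(n_components=6, n_runs=3, seed=9)
        t1, d1 = decompose(hy, cfg)
        t2, d2 = decompose(hy, cfg)
        assert len(t1) == len(t2)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.vector, b.vector)

    def test_model_order_scan_finds_task_sensitive_traits(self):
        spec = SyntheticSpec(n_nodes=24, n_traits=3, n_task_sensitive=2)
        hy, _ = generate_hybrid_population(spec, seed=4)
        cfg = DecompositionConfig(n_components=4, n_runs=3, seed=4)
        best, table = select_model_order(hy, range(2, 7), cfg,
                                         icc_threshold=0.5)
        assert table.loc[table.M == best, "n_task_sensitive"].iloc[0] == 2
        assert table.n_task_sensitive.max() == 2

    def test_single_m_returned_with_diagnostics(self):
        hy, _ = generate_hybrid_population(SyntheticSpec(n_nodes=24), seed=5)
        cfg = DecompositionConfig(n_components=4, n_runs=3, seed=5)
        best, table = select_model_order(hy, [4], cfg)
        assert best == 4 and len(table) == 1

    def test_pure_noise_returns_smallest_m_with_warning(self, rng):
        from hconnica import EdgeIndex, EdgeMask, HybridDataset
        n = 12
        ind = np.zeros(n * (n - 1) // 2, dtype=bool)
        ind[:5] = True
        idx = EdgeIndex.from_mask(EdgeMask(n_nodes=n, indicator=ind))
        data = rng.normal(size=(24, idx.length)) * 0.1
        hy = HybridDataset(
            data=np.clip(data, -1, 1),
            subjects=[f"S{i}" for i in range(24)],
            conditions=[f"C{i % 4}" for i in range(24)],
            edge_index=idx,
        )
        cfg = DecompositionConfig(n_components=3, n_runs=3,
                                  n_per_condition=6, seed=0)
        with pytest.warns(UserWarning, match="smallest"):
            best, table = select_model_order(hy, [2, 3], cfg,
                                             icc_threshold=0.99)
        assert best == 2
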
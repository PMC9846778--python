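import itertools

import numpy as np
import pytest
from sklearn.decomposition import NMF as SkNMF
from sklearn.metrics import silhouette_samples as sk_silhouette

from sigarch.catalogue_io import MutationalCatalogue, SignatureMatrix
from sigarch.contexts import N_CONTEXTS
from sigarch.extraction import (
    NMFRunSet,
    SignatureExtractor,
    catalogue_mse,
    collect_nmf_runs,
    consensus_partition,
    evaluate_scenario,
    match_to_truth,
    refit_exposures,
    run_nmf_once,
    select_rank,
    silhouette_samples_cosine,
    success_frequency,
)
from sigarch.nmf import kl_divergence, multiplicative_nmf
from sigarch.synthetic import ScenarioConfig, generate_scenario


def _orthogonal_catalogue(k, n_samples, rng, mutations=2000):
    """Noiseless catalogue from k disjoint-support block signatures."""
    rows = np.zeros((k, N_CONTEXTS))
    block = N_CONTEXTS // k
    for i in range(k):
        rows[i, i * block : (i + 1) * block] = rng.uniform(0.5, 1.5, block)
    sig = SignatureMatrix.from_profiles([f"T{i}" for i in range(k)], rows)
    expo = rng.dirichlet(np.ones(k), size=n_samples).T
    counts = np.rint(mutations * (sig.values.T @ expo)).astype(int)
    cat = MutationalCatalogue([f"S{j}" for j in range(n_samples)], counts)
    return sig, cat


class TestMultiplicativeNMF:
    def test_kl_objective_non_increasing_every_iteration(self, rng):
        x = rng.poisson(20.0, size=(N_CONTEXTS, 30)).astype(float)
        res = multiplicative_nmf(x, 3, rng, max_iter=200)
        assert np.all(np.diff(res.objective_path) <= 1e-8)

    def test_frobenius_objective_non_increasing(self, rng):
        x = rng.poisson(20.0, size=(N_CONTEXTS, 30)).astype(float)
        res = multiplicative_nmf(x, 3, rng, loss="frobenius", max_iter=200)
        assert np.all(np.diff(res.objective_path) <= 1e-8)

    def test_reaches_sklearn_kl_objective(self, rng):
        """Independent cross-check: converged KL loss comparable to sklearn's
        multiplicative-update KL-NMF on the same matrix."""
        x = rng.poisson(15.0, size=(N_CONTEXTS, 40)).astype(float)
        ours = multiplicative_nmf(x, 3, np.random.default_rng(0), max_iter=3000)
        sk = SkNMF(
            3, beta_loss="kullback-leibler", solver="mu", init="random",
            random_state=0, max_iter=3000, tol=1e-8,
        ).fit(x)
        sk_obj = kl_divergence(x, sk.transform(x) @ sk.components_)
        assert ours.objective <= sk_obj * 1.05

    def test_fixed_seed_is_bit_deterministic(self, rng):
        x = rng.poisson(10.0, size=(N_CONTEXTS, 20)).astype(float)
        cat = MutationalCatalogue([f"S{i}" for i in range(20)], x.astype(int))
        s1, e1 = run_nmf_once(cat, 2, np.random.default_rng(42))
        s2, e2 = run_nmf_once(cat, 2, np.random.default_rng(42))
        assert np.array_equal(s1, s2) and np.array_equal(e1, e2)

    def test_rank_one_recovers_row_sum_profile(self, rng):
        _, cat = _orthogonal_catalogue(2, 30, rng)
        sig, _ = run_nmf_once(cat, 1, np.random.default_rng(1), max_iter=2000)
        profile = cat.counts.sum(axis=1) / cat.counts.sum()
        np.testing.assert_allclose(sig[0], profile, atol=1e-6)

    def test_exact_factorisation_recovery(self, rng):
        truth, cat = _orthogonal_catalogue(2, 50, rng)
        sig, _ = run_nmf_once(cat, 2, np.random.default_rng(3), max_iter=2000)
        match = match_to_truth(
            SignatureMatrix.from_profiles(["a", "b"], sig), truth, threshold=0.99
        )
        assert match.success

    def test_poisson_resampling_perturbs_input(self, rng):
        _, cat = _orthogonal_catalogue(2, 30, rng)
        s_plain, _ = run_nmf_once(cat, 2, np.random.default_rng(5), resample=False)
        s_boot, _ = run_nmf_once(cat, 2, np.random.default_rng(5), resample=True)
        assert not np.allclose(s_plain, s_boot)


class TestSilhouettes:
    def test_hand_computed_four_point_example(self):
        """Silhouettes equal the (b-a)/max(a,b) arithmetic done by hand."""
        pts = np.zeros((4, N_CONTEXTS))
        pts[0, 0], pts[0, 1] = 1.0, 0.1
        pts[1, 0], pts[1, 1] = 1.0, 0.2
        pts[2, 50], pts[2, 51] = 1.0, 0.1
        pts[3, 50], pts[3, 51] = 1.0, 0.3
        labels = np.array([0, 0, 1, 1])

        def cosd(u, v):
            return 1 - u @ v / (np.linalg.norm(u) * np.linalg.norm(v))

        expected = []
        for i in range(4):
            mate = {0: 1, 1: 0, 2: 3, 3: 2}[i]
            a = cosd(pts[i], pts[mate])
            others = [j for j in range(4) if labels[j] != labels[i]]
            b = np.mean([cosd(pts[i], pts[j]) for j in others])
            expected.append((b - a) / max(a, b))
        np.testing.assert_allclose(
            silhouette_samples_cosine(pts, labels), expected, atol=1e-12
        )

    def test_agrees_with_sklearn_on_random_clusters(self, rng):
        pts = np.abs(rng.normal(size=(12, N_CONTEXTS)))
        labels = np.repeat([0, 1, 2], 4)
        ours = silhouette_samples_cosine(pts, labels)
        dist = np.zeros((12, 12))
        for i in range(12):
            for j in range(12):
                if i != j:
                    dist[i, j] = 1 - pts[i] @ pts[j] / (
                        np.linalg.norm(pts[i]) * np.linalg.norm(pts[j])
                    )
        theirs = sk_silhouette(dist, labels, metric="precomputed")
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_identical_points_score_zero(self):
        pts = np.tile(np.linspace(1, 2, N_CONTEXTS), (4, 1))
        np.testing.assert_array_equal(
            silhouette_samples_cosine(pts, np.array([0, 0, 1, 1])), 0.0
        )


class TestConsensusPartition:
    def _runs_from(self, sigs, n_runs, rng, noise=0.0):
        runs = []
        for _ in range(n_runs):
            s = sigs + noise * np.abs(rng.normal(size=sigs.shape))
            s = s / s.sum(axis=1, keepdims=True)
            runs.append(s[rng.permutation(sigs.shape[0])])
        return NMFRunSet(sigs.shape[0], runs, [np.zeros((sigs.shape[0], 1))] * n_runs)

    def test_identical_well_separated_runs_give_stability_one(self, rng):
        sigs = np.zeros((3, N_CONTEXTS))
        sigs[0, :5] = sigs[1, 40:45] = sigs[2, 90:95] = 0.2
        res = consensus_partition(self._runs_from(sigs, 5, rng))
        assert res.c_mean == pytest.approx(1.0, abs=1e-9)
        assert res.c_min == pytest.approx(1.0, abs=1e-9)
        match = match_to_truth(
            SignatureMatrix.from_profiles(["a", "b", "c"], res.consensus_signatures),
            SignatureMatrix.from_profiles(["x", "y", "z"], sigs),
            threshold=0.999,
        )
        assert match.success

    def test_every_cluster_has_one_member_per_run(self, rng):
        sigs = np.abs(rng.normal(size=(4, N_CONTEXTS))) + 0.01
        sigs /= sigs.sum(axis=1, keepdims=True)
        res = consensus_partition(self._runs_from(sigs, 6, rng, noise=0.001))
        labels = res.labels.reshape(6, 4)
        for row in labels:
            assert sorted(row) == [0, 1, 2, 3]

    def test_unstable_signature_cluster_scores_lowest(self, rng):
        n_runs = 8
        stable = np.zeros((2, N_CONTEXTS))
        stable[0, :10] = stable[1, 50:60] = 0.1
        runs = []
        for _ in range(n_runs):
            wild = np.abs(rng.normal(size=N_CONTEXTS)) + 1e-3
            s = np.vstack([stable, wild / wild.sum()])
            runs.append(s)
        res = consensus_partition(
            NMFRunSet(3, runs, [np.zeros((3, 1))] * n_runs)
        )
        order = np.argsort(res.cluster_stability)
        # the wandering third signature forms the least stable cluster
        wild_cluster = res.labels.reshape(n_runs, 3)[0, 2]
        assert order[0] == wild_cluster
        assert res.c_min <= res.c_mean

    def test_rank_one_consensus_is_trivially_stable(self, rng):
        sigs = np.abs(rng.normal(size=(1, N_CONTEXTS))) + 0.01
        sigs /= sigs.sum()
        runs = NMFRunSet(1, [sigs.copy() for _ in range(4)], [np.zeros((1, 1))] * 4)
        res = consensus_partition(runs)
        assert res.c_mean == 1.0


class TestRankSelection:
    def test_recovers_two_orthogonal_signatures(self, rng):
        _, cat = _orthogonal_catalogue(2, 60, rng)
        chosen, per_k, stable = select_rank(
            cat, range(1, 5), np.random.default_rng(0),
            n_runs=4, resample=False, max_iter=600, tol=1e-5,
        )
        assert chosen == 2 and stable

    def test_singleton_range_returns_that_rank(self, rng):
        _, cat = _orthogonal_catalogue(2, 30, rng)
        chosen, per_k, _ = select_rank(
            cat, [3], np.random.default_rng(0), n_runs=3, resample=False,
            max_iter=300, tol=1e-4,
        )
        assert chosen == 3 and set(per_k) == {3}

    def test_estimator_api_fit_and_transform(self, rng):
        truth, cat = _orthogonal_catalogue(3, 50, rng)
        est = SignatureExtractor(
            k_range=(2, 3, 4), n_runs=4, resample=False, random_state=0,
            max_iter=600, tol=1e-5,
        ).fit(cat.counts.T)
        assert est.rank_ == 3
        assert est.signatures_.shape == (3, N_CONTEXTS)
        np.testing.assert_allclose(est.signatures_.sum(axis=1), 1.0, atol=1e-9)
        expo = est.transform(cat.counts.T)
        assert expo.shape == (50, 3)
        assert est.stability_["c_min"] <= est.stability_["c_mean"]
        params = est.get_params()
        assert params["n_runs"] == 4  # sklearn param round-trip
        assert sorted(est.diagnostics_) == [2, 3, 4]


class TestMatching:
    def test_truth_vs_itself(self, random_signatures):
        m = match_to_truth(random_signatures, random_signatures)
        assert m.success
        assert all(c == pytest.approx(1.0, abs=1e-12) for _, _, c in m.pairs)

    def test_row_permutation_recovered(self, random_signatures):
        perm = [3, 1, 4, 0, 2]
        permuted = SignatureMatrix(
            [random_signatures.names[i] for i in perm],
            random_signatures.values[perm],
        )
        m = match_to_truth(permuted, random_signatures)
        assert m.success
        assert all(t == e for t, e, _ in m.pairs)

    def test_noise_replacement_fails(self, random_signatures, rng):
        values = random_signatures.values.copy()
        noise = np.zeros(N_CONTEXTS)
        noise[rng.integers(N_CONTEXTS)] = 1.0
        values[0] = noise
        broken = SignatureMatrix.from_profiles(random_signatures.names, values)
        assert not match_to_truth(broken, random_signatures, threshold=0.95).success

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_equals_exhaustive_permutation_search(self, rng, k):
        truth = SignatureMatrix.from_profiles(
            [f"t{i}" for i in range(k)], rng.uniform(size=(k, N_CONTEXTS))
        )
        ext = SignatureMatrix.from_profiles(
            [f"e{i}" for i in range(k)], rng.uniform(size=(k, N_CONTEXTS))
        )
        m = match_to_truth(ext, truth)
        cos = np.array(
            [
                [
                    truth.values[i] @ ext.values[j]
                    / (np.linalg.norm(truth.values[i]) * np.linalg.norm(ext.values[j]))
                    for j in range(k)
                ]
                for i in range(k)
            ]
        )
        best = max(
            sum(cos[i, p[i]] for i in range(k))
            for p in itertools.permutations(range(k))
        )
        assert sum(c for _, _, c in m.pairs) == pytest.approx(best, abs=1e-12)


class TestEvaluationMetrics:
    def test_success_frequency_arithmetic(self):
        assert success_frequency([True] * 9 + [False]) == pytest.approx(0.9)
        assert success_frequency([False, False]) == 0.0
        with pytest.raises(ValueError):
            success_frequency([])

    def test_mse_matches_four_term_hand_computation(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        xhat = np.array([[1.0, 0.0], [0.0, 4.0]])
        by_hand = (0**2 + 2**2 + 3**2 + 0**2) / 4
        assert catalogue_mse(x, xhat) == pytest.approx(by_hand, abs=1e-15)

    def test_mse_brute_force_on_random_matrices(self, rng):
        x = rng.uniform(size=(6, 7))
        y = rng.uniform(size=(6, 7))
        brute = sum(
            (x[i, j] - y[i, j]) ** 2 for i in range(6) for j in range(7)
        ) / 42
        assert catalogue_mse(x, y) == pytest.approx(brute, abs=1e-13)

    def test_evaluate_scenario_on_separable_truth(self, rng):
        rows = np.zeros((3, N_CONTEXTS))
        rows[0, :6] = rows[1, 40:46] = rows[2, 90:96] = np.arange(1, 7)
        truth = SignatureMatrix.from_profiles(["a", "b", "c"], rows)
        reps = generate_scenario(
            truth, ScenarioConfig(n_samples=50, mutations_per_sample=3000,
                                  n_replicates=2, seed=9)
        )
        ev = evaluate_scenario(
            reps, np.random.default_rng(0), k_range=(2, 3, 4),
            n_runs=4, resample=False, max_iter=600, tol=1e-5,
        )
        assert ev.f_success == 1.0
        assert ev.mse_iqr[0] <= ev.mse_median <= ev.mse_iqr[1]
        assert all(r["chosen_k"] == 3 for r in ev.per_replicate)


class TestRefitting:
    def test_exact_recovery_on_noiseless_catalogue(self, rng):
        truth, _ = _orthogonal_catalogue(3, 1, rng)
        expo = rng.uniform(1000, 3000, size=(3, 20))
        noiseless = truth.values.T @ expo
        res = refit_exposures(noiseless, truth)
        np.testing.assert_allclose(res.exposures, expo, rtol=1e-6)
        assert res.mean_cosine == pytest.approx(1.0, abs=1e-12)
        assert res.mean_mae == pytest.approx(0.0, abs=1e-8)
        # integer rounding of the counts shifts exposures only marginally
        cat = MutationalCatalogue(
            [f"S{j}" for j in range(20)], np.rint(noiseless).astype(int)
        )
        res_int = refit_exposures(cat, truth)
        np.testing.assert_allclose(res_int.exposures, expo, rtol=1e-2)
        assert res_int.mean_cosine > 0.9999
        assert res_int.mean_mae < 0.5

    def test_single_signature_refit_matches_grid_search(self, rng):
        sig = SignatureMatrix.from_profiles(
            ["only"], rng.uniform(size=(1, N_CONTEXTS))
        )
        counts = rng.poisson(50, size=(N_CONTEXTS, 1))
        cat = MutationalCatalogue(["S1"], counts)
        res = refit_exposures(cat, sig)
        a = sig.values[0]
        grid = np.linspace(0, 2 * counts.sum(), 50001)
        losses = ((counts[:, 0][None, :] - grid[:, None] * a[None, :]) ** 2).sum(axis=1)
        best = grid[np.argmin(losses)]
        assert res.exposures[0, 0] == pytest.approx(best, rel=1e-3)
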
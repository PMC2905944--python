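"""PCA whitening, model-order selection, fixed-point ICA and group models."""

import numpy as np
import pytest

from icaseed import (
    StatMap,
    back_reconstruct,
    estimate_dim,
    fastica_spatial,
    group_ica,
    match_component,
    pca_reduce,
    rank_by_variance,
)

from conftest import make_run


def _sparse_sources(n_sources, v, rng, density=0.05):
    """Sparse, positively skewed spatial sources (strongly non-Gaussian)."""
    S = np.zeros((n_sources, v))
    for i in range(n_sources):
        idx = rng.choice(v, int(density * v), replace=False)
        S[i, idx] = rng.exponential(1.0, len(idx)) + 1.0
    return S


def _mixture_run(n_sources, t, v, seed, noise_sd=0.0):
    rng = np.random.default_rng(seed)
    S = _sparse_sources(n_sources, v, rng)
    M = rng.standard_normal((t, n_sources))
    X = M @ S
    if noise_sd:
        X = X + noise_sd * rng.standard_normal((t, v))
    return make_run(X), S, M


def _best_match_r(zmaps, true_sources):
    """Mean |r| of each true source with its best-matching estimated map."""
    rs = []
    for s in true_sources:
        sc = (s - s.mean()) / s.std()
        cand = [abs(np.corrcoef(sc, z)[0, 1]) for z in zmaps]
        rs.append(max(cand))
    return float(np.mean(rs))


class TestPCAReduce:
    def test_exact_rank_two(self):
        run, _, _ = _mixture_run(2, 20, 500, seed=0)
        white = pca_reduce(run, 2)
        assert white.residual_variance_fraction < 1e-10
        cov = white.scores @ white.scores.T / run.v
        np.testing.assert_allclose(cov, np.eye(2), atol=1e-6)

    def test_reconstruction_error_matches_discarded_eigenvalues(self):
        rng = np.random.default_rng(1)
        run = make_run(rng.standard_normal((50, 500)))
        white = pca_reduce(run, 10)
        X = run.data - run.data.mean(axis=0, keepdims=True)
        recon = white.dewhitening @ white.whitening @ X
        err = np.sum((X - recon) ** 2) / run.v
        evals = np.linalg.eigvalsh(X @ X.T / run.v)[::-1]
        assert abs(err - evals[10:].sum()) < 1e-8 * evals.sum()

    def test_n1_top_eigenvalue_share(self):
        rng = np.random.default_rng(2)
        run = make_run(rng.standard_normal((30, 400)))
        white = pca_reduce(run, 1)
        X = run.data - run.data.mean(axis=0, keepdims=True)
        evals = np.linalg.eigvalsh(X @ X.T / run.v)[::-1]
        np.testing.assert_allclose(
            white.explained_variance, [evals[0] / evals.sum()], rtol=1e-10
        )

    def test_out_of_range_order_rejected(self, small_run):
        with pytest.raises(ValueError):
            pca_reduce(small_run, 0)
        with pytest.raises(ValueError):
            pca_reduce(small_run, small_run.t)


class TestEstimateDim:
    def test_strong_signals_detected(self):
        rng = np.random.default_rng(3)
        t, v = 60, 2000
        M = np.linalg.qr(rng.standard_normal((t, 3)))[0] * 10
        S = rng.standard_normal((3, v))
        run = make_run(M @ S + 1e-3 * rng.standard_normal((t, v)))
        for method in ("AIC", "BIC", "MDL"):
            assert estimate_dim(run, method) >= 3

    def test_pure_noise_small_order(self):
        # consistent criteria should not hallucinate structure in iid noise
        hits = {"BIC": 0, "MDL": 0}
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            run = make_run(rng.standard_normal((60, 2000)))
            for method in hits:
                if estimate_dim(run, method) <= 3:
                    hits[method] += 1
        assert hits["BIC"] > 10 and hits["MDL"] > 10

    def test_deterministic_and_validates(self, small_run):
        assert estimate_dim(small_run, "AIC") == estimate_dim(small_run, "AIC")
        with pytest.raises(ValueError, match="unknown"):
            estimate_dim(small_run, "laplace")


class TestFastICA:
    def test_recovers_sparse_sources_noise_free(self):
        run, S, _ = _mixture_run(2, 40, 2000, seed=4)
        comps = fastica_spatial(pca_reduce(run, 2), rng_seed=0)
        assert _best_match_r(comps.zmaps, S) > 0.95

    def test_seeded_determinism(self):
        run, _, _ = _mixture_run(3, 40, 1000, seed=5)
        white = pca_reduce(run, 3)
        a = fastica_spatial(white, rng_seed=42)
        b = fastica_spatial(white, rng_seed=42)
        np.testing.assert_array_equal(a.timecourses, b.timecourses)
        np.testing.assert_array_equal(a.zmaps, b.zmaps)

    def test_zmaps_standardized_and_order_by_variance(self):
        run, _, _ = _mixture_run(3, 40, 1000, seed=6, noise_sd=0.1)
        comps = fastica_spatial(pca_reduce(run, 3), rng_seed=1)
        np.testing.assert_allclose(comps.zmaps.mean(axis=1), 0, atol=1e-8)
        np.testing.assert_allclose(comps.zmaps.var(axis=1), 1, atol=1e-8)
        assert np.all(np.diff(comps.variance_fraction) <= 1e-12)

    def test_reconstruction_matches_pca_rank_n(self):
        run, _, _ = _mixture_run(3, 40, 1000, seed=7, noise_sd=0.5)
        white = pca_reduce(run, 3)
        comps = fastica_spatial(white, rng_seed=2)
        X = run.data - run.data.mean(axis=0, keepdims=True)
        pca_recon = white.dewhitening @ white.whitening @ X
        ica_recon = comps.timecourses @ comps.maps
        assert np.var(ica_recon - pca_recon) < 1e-6 * np.var(pca_recon)

    def test_matches_sklearn_oracle(self):
        # independent implementation as the cross-check, on the same whitening
        from sklearn.decomposition import FastICA

        run, S, _ = _mixture_run(3, 50, 2000, seed=8)
        white = pca_reduce(run, 3)
        ours = fastica_spatial(white, rng_seed=3)
        sk = FastICA(
            whiten=False, fun="logcosh", tol=1e-8, max_iter=500, random_state=0
        )
        theirs = sk.fit_transform(white.scores.T).T
        theirs = (theirs - theirs.mean(axis=1, keepdims=True)) / theirs.std(
            axis=1, keepdims=True
        )
        assert _best_match_r(ours.zmaps, theirs) > 0.999

    def test_mean_recovery_over_seeds(self):
        rs = []
        for seed in range(10):
            run, S, _ = _mixture_run(4, 60, 2000, seed=200 + seed)
            comps = fastica_spatial(pca_reduce(run, 4), rng_seed=seed)
            rs.append(_best_match_r(comps.zmaps, S))
        assert np.mean(rs) > 0.95


class TestRankByVariance:
    def test_sorts_descending_with_stable_ties(self):
        run, _, _ = _mixture_run(3, 40, 800, seed=9, noise_sd=0.2)
        comps = fastica_spatial(pca_reduce(run, 3), rng_seed=0)
        shuffled = rank_by_variance(comps)
        assert np.all(np.diff(shuffled.variance_fraction) <= 1e-12)

    def test_noise_free_fractions_sum_to_one(self):
        run, _, _ = _mixture_run(3, 40, 800, seed=10)
        comps = fastica_spatial(pca_reduce(run, 3), rng_seed=0)
        assert abs(comps.variance_fraction.sum() - 1.0) < 1e-6


class TestGroupICA:
    def test_single_subject_equals_single_run_ica(self, small_run):
        run, _, _ = _mixture_run(2, 40, 800, seed=11, noise_sd=0.1)
        model = group_ica([run], 2, rng_seed=5)
        single = fastica_spatial(pca_reduce(run, 2), rng_seed=5)
        np.testing.assert_allclose(
            model.group_components.zmaps, single.zmaps, atol=1e-8
        )

    def test_subject_ranges(self):
        r1, _, _ = _mixture_run(2, 30, 800, seed=12, noise_sd=0.1)
        r2 = r1.with_data(r1.data[:20], "short")
        model = group_ica([r1, r2], 2, rng_seed=0)
        assert model.subject_ranges == [(0, 30), (30, 50)]


class TestBackReconstruct:
    def test_one_subject_group_reproduces_single_run_maps(self):
        run, _, _ = _mixture_run(3, 50, 1000, seed=13)
        model = group_ica([run], 3, rng_seed=7)
        subj = back_reconstruct(model, [run], 0)
        grp = model.group_components
        for k in range(3):
            r = np.corrcoef(subj.maps[k], grp.maps[k])[0, 1]
            assert abs(abs(r) - 1.0) < 1e-8

    def test_zero_amplitude_subject_has_suppressed_map(self):
        # subject 2 lacks source 2: inside source 2's true region the
        # subject-2 reconstructed z map stays far below the group z map
        rng = np.random.default_rng(14)
        v, t = 2000, 60
        S = np.zeros((2, v))
        S[0, 100:150] = rng.exponential(1.0, 50) + 1.0  # disjoint supports
        S[1, 300:350] = rng.exponential(1.0, 50) + 1.0
        M1 = rng.standard_normal((t, 2))
        M2 = rng.standard_normal((t, 2))
        noise = 0.02
        runs = [
            make_run(M1 @ S + noise * rng.standard_normal((t, v))),
            make_run(np.outer(M2[:, 0], S[0]) + noise * rng.standard_normal((t, v))),
        ]
        model = group_ica(runs, 2, rng_seed=3)
        grp = model.group_components
        k2 = int(np.argmax([abs(np.corrcoef(z, S[1])[0, 1]) for z in grp.zmaps]))
        on_mask = S[1] > 0
        subj2 = back_reconstruct(model, runs, 1)
        group_peak = np.max(np.abs(grp.zmaps[k2][on_mask]))
        subj2_peak = np.max(np.abs(subj2.zmaps[k2][on_mask]))
        assert subj2_peak < 0.5 * group_peak

    def test_variance_accounting(self):
        run, _, _ = _mixture_run(2, 50, 1500, seed=15, noise_sd=0.3)
        model = group_ica([run], 2, rng_seed=1)
        subj = back_reconstruct(model, [run], 0)
        X = run.data - run.data.mean(axis=0, keepdims=True)
        resid = X - subj.timecourses @ subj.maps
        white = pca_reduce(run, 2)
        noise_var = 0.3**2 * run.v * run.t  # injected noise energy
        discarded = white.residual_variance_fraction * np.sum(X**2)
        assert np.sum(resid**2) <= 1.1 * (noise_var + discarded)

    def test_unknown_subject_rejected(self):
        run, _, _ = _mixture_run(2, 30, 500, seed=16, noise_sd=0.1)
        model = group_ica([run], 2, rng_seed=0)
        with pytest.raises(KeyError):
            back_reconstruct(model, [run], 5)


class TestMatchComponent:
    def test_exact_and_flipped_reference(self):
        run, _, _ = _mixture_run(4, 40, 1500, seed=17, noise_sd=0.1)
        comps = fastica_spatial(pca_reduce(run, 4), rng_seed=0)
        ref = StatMap(comps.zmaps[2].copy(), "z", comps.mask)
        idx, r, _ = match_component(comps, ref)
        assert (idx, round(r, 6)) == (2, 1.0)
        neg = StatMap(-comps.zmaps[2], "z", comps.mask)
        idx, r, flipped = match_component(comps, neg)
        assert idx == 2 and abs(r - 1.0) < 1e-12
        # the returned set is sign-aligned with the reference
        assert np.corrcoef(flipped.zmaps[2], neg.values)[0, 1] > 0.999

    def test_orthogonal_reference_is_weak(self):
        rng = np.random.default_rng(18)
        run, _, _ = _mixture_run(3, 40, 5000, seed=18, noise_sd=0.1)
        comps = fastica_spatial(pca_reduce(run, 3), rng_seed=0)
        ref = StatMap(rng.standard_normal(run.v), "z", comps.mask)
        with pytest.warns(UserWarning, match="weak"):
            _, r, _ = match_component(comps, ref)
        assert abs(r) < 0.2

    def test_constant_reference_rejected(self):
        run, _, _ = _mixture_run(2, 30, 500, seed=19, noise_sd=0.1)
        comps = fastica_spatial(pca_reduce(run, 2), rng_seed=0)
        with pytest.raises(ValueError, match="constant"):
            match_component(comps, StatMap(np.ones(run.v), "z", comps.mask))
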
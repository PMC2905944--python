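"""Task regressors, voxelwise OLS with Gaussianised z maps, thresholding."""

import numpy as np
import pytest
from scipy import stats

from icaseed import (
    DesignMatrix,
    SeedSpec,
    StatMap,
    TimeCourse,
    build_task_regressor,
    glm_fit,
    seed_fc,
    threshold_map,
)
from icaseed.glm import Z_CAP
from icaseed.seeding import peak_voxel

from conftest import make_run


class TestBuildTaskRegressor:
    def test_impulse_peaks_near_lag(self):
        tr = 1.0
        reg = build_task_regressor([0.0], [1.0], t=40, tr=tr, peak_lag=5.0)
        assert np.argmax(reg.values) == 5  # sample nearest 5 s

    def test_block_design_period_and_lag(self):
        # 12 s off / 12 s on blocks at tr 4 s: regressor period is 6 samples
        tr, t = 4.0, 60
        onsets = np.arange(12, t * tr, 24.0)
        reg = build_task_regressor(onsets, [12.0], t=t, tr=tr)
        # oracle: direct convolution of the boxcar with the sampled kernel
        times = np.arange(t) * tr
        box = np.zeros(t)
        for o in onsets:
            box[(times >= o) & (times < o + 12.0)] = 1.0
        half = int(np.ceil((5 + 4 * 2.8) / tr))
        tau = np.arange(-half, half + 1) * tr
        tau = tau[np.abs(tau - 5.0) <= 4 * 2.8]
        kern = np.exp(-((tau - 5.0) ** 2) / (2 * 2.8**2))
        kern /= kern.sum()
        oracle = np.convolve(box, kern, mode="full")[np.sum(tau < 0) :][:t]
        oracle = (oracle - oracle.mean()) / oracle.std(ddof=1)
        np.testing.assert_allclose(reg.values, oracle, atol=1e-12)
        # periodicity of 6 samples away from the edges
        np.testing.assert_allclose(reg.values[12:48], reg.values[6:42], atol=1e-6)
        # response peaks about one sample after each mid-block (lag ~5 s > tr)
        assert np.argmax(reg.values[3:9]) >= 2

    def test_empty_and_degenerate_blocks_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_task_regressor([], [], t=50, tr=2.0)
        with pytest.raises(ValueError):
            build_task_regressor([500.0], [10.0], t=50, tr=2.0)  # outside run

    def test_normalized_output(self):
        reg = build_task_regressor([0, 40, 80], [20.0], t=60, tr=2.0)
        assert abs(reg.values.mean()) < 1e-12
        assert abs(reg.values.std(ddof=1) - 1) < 1e-12


class TestGLMFit:
    def test_exact_fit_hits_cap(self):
        rng = np.random.default_rng(0)
        g = rng.standard_normal(30)
        run = make_run(np.outer(g, [2.0, -1.0]))
        design = DesignMatrix([TimeCourse(g, "g")])
        res = glm_fit(run, design)
        np.testing.assert_allclose(res.betas[0].values, [2.0, -1.0], atol=1e-10)
        assert res.zmaps[0].values[0] == Z_CAP
        assert res.zmaps[0].values[1] == -Z_CAP
        assert res.dof == 29

    def test_orthogonal_columns_match_univariate_slopes(self):
        rng = np.random.default_rng(1)
        g1 = rng.standard_normal(50)
        g1 -= g1.mean()
        g2 = rng.standard_normal(50)
        g2 -= g2.mean()
        g2 -= g1 * (g1 @ g2) / (g1 @ g1)
        run = make_run(rng.standard_normal((50, 20)))
        res = glm_fit(run, DesignMatrix([TimeCourse(g1, "a"), TimeCourse(g2, "b")]))
        for g, beta in [(g1, res.betas[0]), (g2, res.betas[1])]:
            uni = run.data.T @ g / (g @ g)
            np.testing.assert_allclose(beta.values, uni, atol=1e-10)

    def test_null_type_one_error_calibrated(self):
        # Monte Carlo: two-sided alpha=0.05 on the Gaussianised z values
        rates = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            run = make_run(rng.standard_normal((40, 2000)))
            g = rng.standard_normal(40)
            res = glm_fit(run, DesignMatrix([TimeCourse(g, "g")]))
            z = res.zmaps[0].values
            rates.append(np.mean(np.abs(z) > stats.norm.isf(0.025)))
        assert abs(np.mean(rates) - 0.05) < 0.01

    def test_z_monotone_in_correlation(self):
        # with demeaned data and regressor (the pipeline convention), z is a
        # monotone function of the voxel-regressor Pearson correlation
        rng = np.random.default_rng(2)
        run = make_run(rng.standard_normal((60, 300)))
        run = run.with_data(run.data - run.data.mean(axis=0), "demeaned")
        g = rng.standard_normal(60)
        g -= g.mean()
        res = glm_fit(run, DesignMatrix([TimeCourse(g, "g")]))
        corr = run.data.T @ g
        corr /= np.linalg.norm(run.data, axis=0) * np.linalg.norm(g)
        order = np.argsort(corr)
        z_sorted = res.zmaps[0].values[order]
        assert np.all(np.diff(z_sorted) > -1e-10)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(3)
        run = make_run(rng.standard_normal((30, 10)))
        g = rng.standard_normal(30)
        design = DesignMatrix([TimeCourse(g, "a"), TimeCourse(2 * g, "b")])
        with pytest.raises(ValueError, match="rank"):
            glm_fit(run, design)

    def test_ar1_prewhitening_calibration(self):
        # AR(1) noise inflates OLS false positives; prewhitening restores them
        rng = np.random.default_rng(4)
        t, v, phi = 80, 2000, 0.5
        eps = rng.standard_normal((t, v))
        for i in range(1, t):
            eps[i] = phi * eps[i - 1] + np.sqrt(1 - phi**2) * eps[i]
        run = make_run(eps)
        g = np.sin(np.arange(t) / 3)  # smooth regressor: sensitive to autocorr
        design = DesignMatrix([TimeCourse(g, "g")])
        z_ols = glm_fit(run, design).zmaps[0].values
        z_pw = glm_fit(run, design, prewhiten=True).zmaps[0].values
        crit = stats.norm.isf(0.025)
        assert np.mean(np.abs(z_pw) > crit) < np.mean(np.abs(z_ols) > crit)


class TestThresholdMap:
    def _zmap(self, values):
        return StatMap(np.asarray(values, float), "z", make_run(np.zeros((2, len(values)))).mask)

    def test_fixed_z(self):
        out = threshold_map(self._zmap([2.0, 3.2, 4.0]), "fixed_z", 3.1)
        assert out.include.tolist() == [False, True, True]

    def test_bonferroni_cutoff_matches_normal_quantile(self):
        rng = np.random.default_rng(5)
        v = 90295
        zm = StatMap(rng.standard_normal(v), "z", make_run(np.zeros((2, v))).mask)
        out = threshold_map(zm, "bonferroni", 0.05)
        expect = stats.norm.isf(0.05 / v)
        assert abs(out.threshold_used - expect) < 1e-10
        assert abs(expect - 4.8715) < 0.001  # one-tailed quantile at 5.54e-7

    def test_bonferroni_controls_familywise_rate(self):
        fams = 0
        for seed in range(200):
            rng = np.random.default_rng(2000 + seed)
            zm = self._zmap(rng.standard_normal(2000))
            if threshold_map(zm, "bonferroni", 0.05).n_included > 0:
                fams += 1
        assert fams / 200 <= 0.05 + 0.03  # binomial slack at n=200

    def test_fdr_keeps_strong_signals(self):
        rng = np.random.default_rng(6)
        values = rng.standard_normal(1000)
        values[:20] += 6.0
        out = threshold_map(self._zmap(values), "fdr", 0.05)
        assert np.sum(out.include[:20]) >= 18

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            threshold_map(self._zmap([1.0, 2.0]), "bonferroni", 1.5)
        with pytest.raises(ValueError, match="unknown"):
            threshold_map(self._zmap([1.0, 2.0]), "grf", 0.05)


class TestSeedFC:
    def test_sv_equals_direct_regression_on_peak_series(self):
        rng = np.random.default_rng(7)
        run = make_run(rng.standard_normal((50, 40)))
        zvals = np.zeros(40)
        zvals[11] = 7.0
        seed = peak_voxel(StatMap(zvals, "z", run.mask))
        fc = seed_fc(run, seed)
        series = run.data[:, 11]
        series = (series - series.mean()) / series.std(ddof=1)
        oracle = glm_fit(run, DesignMatrix([TimeCourse(series, "peak")]))
        np.testing.assert_allclose(fc.values, oracle.zmaps[0].values, atol=1e-10)

    def test_dra_single_component_equals_drs(self):
        rng = np.random.default_rng(8)
        v, t = 500, 60
        c = rng.standard_normal(v)
        m = rng.standard_normal(t)
        run = make_run(np.outer(m, c) + 0.3 * rng.standard_normal((t, v)))
        from icaseed import fastica_spatial, pca_reduce

        comps = fastica_spatial(pca_reduce(run, 1), rng_seed=0)
        drs = seed_fc(run, SeedSpec(method="DRS", source_map=comps.zmap(0)))
        dra = seed_fc(run, SeedSpec(method="DRA", source_set=comps, interest_index=0))
        np.testing.assert_allclose(drs.values, dra.values, atol=1e-8)

    def test_deterministic_reruns(self):
        rng = np.random.default_rng(9)
        run = make_run(rng.standard_normal((40, 100)))
        c = rng.standard_normal(100)
        spec = SeedSpec(method="DRS", source_map=StatMap(c, "raw", run.mask))
        a = seed_fc(run, spec)
        b = seed_fc(run, spec)
        np.testing.assert_array_equal(a.values, b.values)

    def test_null_bonferroni_survivors_bounded(self):
        # pure-noise runs with arbitrary seeds rarely yield corrected hits
        total_maps, maps_with_hits = 100, 0
        for seed in range(total_maps):
            rng = np.random.default_rng(3000 + seed)
            run = make_run(rng.standard_normal((30, 500)))
            zvals = np.zeros(500)
            zvals[seed % 500] = 5.0
            fc = seed_fc(run, peak_voxel(StatMap(zvals, "z", run.mask)))
            # exclude the seed voxel itself (self-correlation is structural)
            keep = np.ones(500, dtype=bool)
            keep[seed % 500] = False
            out = threshold_map(fc, "bonferroni", 0.05)
            if np.any(out.include & keep):
                maps_with_hits += 1
        assert maps_with_hits / total_maps <= 0.05 + 0.03
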
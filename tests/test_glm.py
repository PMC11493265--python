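"""Design coding, first-level fits, paired t, bootstrap F-max, moderation,
power calculation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dpxdyn.glm import (
    build_condition_design,
    build_design,
    cluster_summary,
    covariate_moderation,
    fit_first_level,
    fmax_bootstrap_threshold,
    group_contrast,
    paired_t_power,
    paired_t_sample_size,
    paired_t_second_level,
    significance_mask,
    solve_paired_t_n,
)


def _trials(pairs):
    return pd.DataFrame(
        dict(
            trial_id=range(len(pairs)), block=0, cue=[p[0] for p in pairs],
            probe=[p[1] for p in pairs], pair=pairs,
            response="target", correct=pd.array([True] * len(pairs), dtype="boolean"),
            rt=0.3,
        )
    )


class TestBuildDesign:
    def test_effect_codes_for_cue(self):
        d = build_design(_trials(["AX", "BX", "AX"]), ["cue"], add_intercept=False)
        assert np.array_equal(d.X[:, 0], [-1.0, 1.0, -1.0])

    def test_intercept_only(self):
        d = build_design(_trials(["AX", "BX"]), [], add_intercept=True)
        assert d.X.shape == (2, 1)
        assert (d.X == 1.0).all()

    def test_interaction_matches_truth_table(self):
        pairs = ["AX", "AY", "BX", "BY"]
        d = build_design(_trials(pairs), ["cue", "probe", "cue:probe"], add_intercept=True)
        codes = {"A": -1.0, "B": 1.0, "X": -1.0, "Y": 1.0}
        for i, p in enumerate(pairs):
            assert d.X[i, 3] == codes[p[0]] * codes[p[1]]

    def test_single_level_factor_warns_on_design(self):
        d = build_design(_trials(["AX", "AX"]), ["cue"])
        assert d.rank_warnings


class TestFirstLevel:
    def test_intercept_only_returns_feature_means(self):
        Y = np.array([[1.0, 2.0], [3.0, 6.0], [5.0, 10.0]])
        X = build_design(_trials(["AX", "AX", "AX"]), [], add_intercept=True)
        bm = fit_first_level(Y, X, n_channels=1, n_times=2)
        assert np.allclose(bm.beta[0, 0], [3.0, 6.0])

    def test_balanced_effect_coding_identity(self):
        # y = [1, 3, 5, 7] on codes [-1, -1, +1, +1]: mean 4, half-difference 2
        y = np.array([[1.0], [3.0], [5.0], [7.0]])
        X = build_design(_trials(["AX", "AX", "BX", "BX"]), ["cue"], add_intercept=True)
        bm = fit_first_level(y, X, n_channels=1, n_times=1)
        assert bm.beta[0, 0, 0] == pytest.approx(4.0)
        assert bm.beta[1, 0, 0] == pytest.approx(2.0)

    def test_pinv_equals_ols_for_full_rank(self):
        rng = np.random.default_rng(0)
        trials = _trials(["AX", "AY", "BX", "BY"] * 10)
        X = build_design(trials, ["cue", "probe"], add_intercept=True)
        Y = rng.normal(size=(40, 12))
        bm = fit_first_level(Y, X, n_channels=3, n_times=4)
        ols, *_ = np.linalg.lstsq(X.X, Y, rcond=None)
        assert np.allclose(bm.beta.reshape(3, 12), ols, rtol=1e-8, atol=1e-10)

    def test_duplicated_column_gives_same_fitted_values(self):
        rng = np.random.default_rng(1)
        trials = _trials(["AX", "AX", "BX", "BX"] * 5)
        full = build_design(trials, ["cue"], add_intercept=True)
        dup = build_design(trials, ["cue", "cue"], add_intercept=True)
        Y = rng.normal(size=(20, 4))
        b_full = fit_first_level(Y, full, n_channels=2, n_times=2)
        b_dup = fit_first_level(Y, dup, n_channels=2, n_times=2)
        fit_full = full.X @ b_full.beta.reshape(2, 4)
        fit_dup = dup.X @ b_dup.beta.reshape(3, 4)
        assert np.allclose(fit_full, fit_dup, atol=1e-10)
        assert b_dup.design_rank == 2

    def test_condition_design_recovers_condition_means(self):
        trials = _trials(["AX", "BX", "AX", "BX"])
        X = build_condition_design(trials, by="cue")
        Y = np.array([[1.0], [10.0], [3.0], [20.0]])
        bm = fit_first_level(Y, X, n_channels=1, n_times=1)
        by_name = dict(zip(bm.names, bm.beta[:, 0, 0]))
        assert by_name["A"] == pytest.approx(2.0)
        assert by_name["B"] == pytest.approx(15.0)


class TestPairedT:
    def test_identical_conditions_give_zero(self):
        a = np.random.default_rng(0).normal(size=(5, 2, 3))
        res = paired_t_second_level(a, a.copy())
        assert np.allclose(res.t_map, 0.0)

    def test_textbook_example(self):
        a = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        b = np.zeros((3, 1, 1))
        res = paired_t_second_level(a, b)
        assert res.t_map[0, 0] == pytest.approx(3.464, abs=1e-3)
        assert res.f_map[0, 0] == pytest.approx(12.0, abs=1e-2)
        assert res.df == 2

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 6, 2, 2))
        r1 = paired_t_second_level(a, b)
        r2 = paired_t_second_level(b, a)
        assert np.allclose(r1.t_map, -r2.t_map)
        assert np.allclose(r1.f_map, r2.f_map)


class TestFmaxBootstrap:
    def test_definitional_properties(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 8, 2, 5))
        f_crit, dist = fmax_bootstrap_threshold(a, b, alpha=0.01, B=250, seed=0)
        assert dist.shape == (250,)
        assert f_crit == pytest.approx(np.quantile(dist, 0.99))

    def test_alpha_monotonicity_on_identical_resamples(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(2, 8, 2, 5))
        f05, _ = fmax_bootstrap_threshold(a, b, alpha=0.05, B=300, seed=9)
        f01, _ = fmax_bootstrap_threshold(a, b, alpha=0.01, B=300, seed=9)
        assert f05 <= f01

    def test_small_B_refused(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(2, 8, 1, 1))
        with pytest.raises(ValueError):
            fmax_bootstrap_threshold(a, b, B=50, seed=0)


class TestSignificanceMask:
    def test_null_map_empty(self):
        res = paired_t_second_level(np.zeros((4, 1, 3)), np.zeros((4, 1, 3)))
        res.f_crit = 1.0
        assert not significance_mask(res).any()

    def test_exact_tie_is_not_significant(self):
        a = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        res = paired_t_second_level(a, np.zeros((3, 1, 1)))
        res.f_crit = float(res.f_map[0, 0])
        assert not significance_mask(res).any()

    def test_cardinality_matches_exhaustive_count(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=(2, 10, 4, 6))
        res = group_contrast(a, b, alpha=0.05, B=200, seed=1)
        brute = sum(
            1
            for c in range(4)
            for t in range(6)
            if res.f_map[c, t] > res.f_crit
        )
        assert int(res.mask.sum()) == brute


class TestModeration:
    def test_exact_linear_relation_recovered(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        maps = 3.5 * x[:, None, None] * np.ones((1, 2, 2))
        res = covariate_moderation(maps, x, B=150, seed=0)
        assert np.allclose(res.b_map, 3.5)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=8)
        maps = rng.normal(size=(8, 2, 3))
        r1 = covariate_moderation(maps, x, B=120, seed=3)
        r2 = covariate_moderation(maps, 2.0 * x, B=120, seed=3)
        assert np.allclose(r2.b_map, r1.b_map / 2.0)
        assert np.allclose(r2.t_map, r1.t_map)

    def test_null_calibration_uncorrected_rate(self):
        # covariate independent of the maps: pointwise |t| exceeds the
        # central-t alpha quantile at about the nominal rate
        rng = np.random.default_rng(8)
        alpha, hits, total = 0.05, 0, 0
        for _ in range(30):
            x = rng.normal(size=12)
            maps = rng.normal(size=(12, 3, 10))
            res = covariate_moderation(maps, x, B=100, seed=int(rng.integers(2**31)))
            tcrit = stats.t.ppf(1 - alpha / 2, df=10)
            hits += int((np.abs(res.t_map) > tcrit).sum())
            total += res.t_map.size
        rate = hits / total
        mc_err = np.sqrt(alpha * (1 - alpha) / total)
        assert rate <= alpha + 5 * mc_err  # correlated points: generous band

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            covariate_moderation(np.random.default_rng(0).normal(size=(6, 1, 1)),
                                 np.ones(6), B=100, seed=0)


class TestPower:
    def test_sample_size_monotone_in_effect(self):
        sizes = [paired_t_sample_size(d, 0.8, 0.01) for d in (0.3, 0.5, 0.8)]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_sample_size_matches_brute_force_power_scan(self):
        target = paired_t_sample_size(0.8, 0.80, 0.05)
        # independent scan straight from the noncentral-t power definition
        def power(n):
            df = n - 1
            tc = stats.t.ppf(0.975, df)
            nc = 0.8 * np.sqrt(n)
            return 1 - stats.nct.cdf(tc, df, nc) + stats.nct.cdf(-tc, df, nc)

        brute = next(n for n in range(2, 500) if power(n) >= 0.80)
        assert target == brute

    def test_continuous_root_bounds_integer_answer(self):
        n_int = paired_t_sample_size(0.5, 0.80, 0.01)
        n_cont = solve_paired_t_n(0.5, 0.80, 0.01)
        assert n_int == int(np.ceil(n_cont))
        assert paired_t_power(n_int, 0.5, 0.01) >= 0.80
        assert paired_t_power(n_int - 1, 0.5, 0.01) < 0.80


def test_cluster_summary_contiguous_runs():
    from dpxdyn.glm import GroupTestResult

    t_map = np.array([[0.0, 5.0, 6.0, 0.0, 7.0]])
    res = GroupTestResult(t_map=t_map, f_map=t_map ** 2, df=2, f_crit=10.0)
    res.mask = significance_mask(res)
    out = cluster_summary(res, ["Cz"], np.arange(5) / 10.0)
    assert len(out) == 2
    assert out.iloc[0]["tmin"] == pytest.approx(0.1)
    assert out.iloc[0]["tmax"] == pytest.approx(0.2)
    assert out.iloc[0]["peak_t"] == pytest.approx(6.0)
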
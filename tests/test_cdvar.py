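"""Condition-driven VAR: design construction, OLS fit, Wald inference."""

import warnings

import numpy as np
import pytest

from nirsconn import (
    ClusterAssignment,
    ConditionCoding,
    DataError,
    ProjectedSeries,
    SingularDesignError,
    build_design,
    companion_spectral_radius,
    fit_ols,
    make_ground_truth,
    significant_edges,
    simulate_condition_run,
    trial_average,
    wald_pvalues,
)


def series(g, fs=10.2, cond=None):
    M = g.shape[0]
    asg = ClusterAssignment(np.arange(M), M, np.zeros((M, 3)))
    return ProjectedSeries(g=g, fs=fs, assignment=asg, run_condition=cond)


class TestTrialAverage:
    def test_single_epoch_identity(self, rng):
        e = series(rng.standard_normal((3, 20)))
        assert np.array_equal(trial_average([e]).g, e.g)

    def test_opposite_epochs_cancel(self, rng):
        g = rng.standard_normal((2, 15))
        assert np.allclose(trial_average([series(g), series(-g)]).g, 0.0)

    def test_matches_elementwise_mean(self, rng):
        gs = [rng.standard_normal((2, 10)) for _ in range(4)]
        avg = trial_average([series(g) for g in gs]).g
        assert np.array_equal(avg, np.mean(gs, axis=0))

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(DataError):
            trial_average(
                [series(rng.standard_normal((2, 10))),
                 series(rng.standard_normal((2, 11)))]
            )


class TestBuildDesign:
    def test_baseline_only_reduces_to_plain_var(self, rng):
        d = build_design(
            {"barefoot": series(rng.standard_normal((2, 30)))},
            ConditionCoding(("barefoot",)),
            p=1,
        )
        assert d.X.shape[1] == 2          # no delta columns when K=0
        assert d.Y.shape == (29, 2)

    def test_five_condition_width(self, rng):
        conds = ConditionCoding()
        data = {
            c: series(rng.standard_normal((6, 40)), cond=c)
            for c in conds.condition_names
        }
        d = build_design(data, conds, p=1)
        assert d.X.shape[1] == 6 * (1 + 4)  # 30 predictors
        assert d.Y.shape[1] == 6

    def test_delta_columns_zero_outside_condition(self, rng):
        conds = ConditionCoding(("base", "c1"))
        data = {
            "base": series(rng.standard_normal((2, 20))),
            "c1": series(rng.standard_normal((2, 20))),
        }
        d = build_design(data, conds, p=1)
        # baseline rows come first; their delta block must be all zero
        assert np.all(d.X[:19, 2:] == 0)
        assert np.array_equal(d.X[19:, 2:], d.X[19:, :2])

    def test_no_lag_leaks_across_runs(self):
        """Sentinels at run edges never show up as predictors."""
        sentinel = 1e9
        runs = []
        for _ in range(3):
            g = np.random.default_rng(len(runs)).standard_normal((2, 12))
            g[:, -1] = sentinel  # final sample: never a lag-1 predictor
            runs.append(series(g))
        d = build_design({"base": runs}, ConditionCoding(("base",)), p=1)
        assert not np.any(np.abs(d.X) >= sentinel)
        assert np.sum(np.abs(d.Y) >= sentinel) == 2 * 3  # responses only

    def test_too_few_samples_names_condition(self, rng):
        with pytest.raises(DataError, match="shortrun"):
            build_design(
                {"shortrun": series(rng.standard_normal((2, 1)))},
                ConditionCoding(("shortrun",)),
                p=1,
            )


def exact_recovery_data(M=2, K=2, T=14, seed=0):
    """Innovation-free recursions from random starts: data that satisfy the
    condition-driven VAR exactly."""
    rng = np.random.default_rng(seed)
    truth = make_ground_truth(M=M, K=K, p=1, sparsity=0.5, effect_size=0.3,
                              seed=seed)
    names = tuple(f"c{k}" for k in range(K + 1))
    data = {}
    for k, name in enumerate(names):
        phi = truth.phi_total(k)[0]
        g = np.zeros((M, T))
        g[:, 0] = rng.standard_normal(M)
        for t in range(1, T):
            g[:, t] = phi @ g[:, t - 1]
        data[name] = series(g, cond=name)
    return truth, ConditionCoding(names), data


class TestFitOls:
    def test_exact_recovery_noise_free(self):
        truth, coding, data = exact_recovery_data()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # short runs by construction
            fit = fit_ols(build_design(data, coding, p=1))
        assert np.max(np.abs(fit.phi[0, 0] - truth.phi0[0])) < 1e-8
        for k in range(truth.K):
            assert np.max(np.abs(fit.phi[k + 1, 0] - truth.deltas[k, 0])) < 1e-8

    def test_matches_pseudoinverse_oracle(self, rng):
        # independent stacked solve, built with explicit loops
        g0 = rng.standard_normal((2, 25))
        g1 = rng.standard_normal((2, 25))
        coding = ConditionCoding(("a", "b"))
        d = build_design({"a": series(g0), "b": series(g1)}, coding, p=1)
        fit = fit_ols(d)

        rows_X, rows_Y = [], []
        for g, is_b in [(g0, 0), (g1, 1)]:
            for t in range(1, 25):
                rows_Y.append(g[:, t])
                rows_X.append(
                    np.concatenate([g[:, t - 1], is_b * g[:, t - 1]])
                )
        B = np.linalg.pinv(np.array(rows_X)) @ np.array(rows_Y)
        phi0 = B[:2].T
        delta = B[2:].T
        assert np.max(np.abs(fit.phi[0, 0] - phi0)) < 1e-8
        assert np.max(np.abs(fit.phi[1, 0] - delta)) < 1e-8

    def test_reduction_matches_statsmodels_var(self, rng):
        """K=0 fit coincides with an ordinary VAR(1) fit (external oracle)."""
        VAR = pytest.importorskip("statsmodels.tsa.api").VAR
        truth = make_ground_truth(M=3, K=0, seed=4)
        g = simulate_condition_run(truth, 0, 400, seed=5)
        fit = fit_ols(build_design({"b": series(g)}, ConditionCoding(("b",)), p=1))
        res = VAR(g.T).fit(maxlags=1, trend="n")
        assert np.max(np.abs(fit.phi[0, 0] - res.coefs[0])) < 1e-8

    def test_joint_baseline_equals_baseline_only_fit(self, rng):
        """The dummy design is saturated, so the joint OLS baseline block
        equals a VAR fit on the baseline run alone, exactly."""
        truth = make_ground_truth(M=3, K=2, seed=9)
        data = {}
        names = ("c0", "c1", "c2")
        for k, n in enumerate(names):
            data[n] = series(simulate_condition_run(truth, k, 300, seed=10 + k))
        joint = fit_ols(build_design(data, ConditionCoding(names), p=1))
        solo = fit_ols(
            build_design({"c0": data["c0"]}, ConditionCoding(("c0",)), p=1)
        )
        assert np.max(np.abs(joint.phi[0] - solo.phi[0])) < 1e-10

    def test_missing_condition_raises_singular(self, rng):
        coding = ConditionCoding(("a", "b"))
        d = build_design({"a": series(rng.standard_normal((2, 30)))}, coding, p=1)
        with pytest.raises(SingularDesignError):
            fit_ols(d)

    def test_small_sample_warning(self, rng):
        d = build_design(
            {"a": series(rng.standard_normal((2, 12)))},
            ConditionCoding(("a",)), p=1,
        )
        with pytest.warns(UserWarning, match="small sample"):
            fit_ols(d)


class TestWald:
    def _fit(self, rng, T=300):
        truth = make_ground_truth(M=2, K=0, seed=2)
        g = simulate_condition_run(truth, 0, T, seed=3)
        return fit_ols(build_design({"b": series(g)}, ConditionCoding(("b",)), p=1))

    def test_zero_coefficient_gives_p_one(self, rng):
        fit = self._fit(rng)
        fit.phi[:] = 0.0
        p = wald_pvalues(fit)
        assert np.allclose(p, 1.0)

    def test_z_196_gives_p_05(self, rng):
        fit = self._fit(rng)
        fit.phi = 1.96 * fit.se
        p = wald_pvalues(fit)
        assert np.allclose(p, 0.05, atol=5e-4)

    def test_zero_se_flagged_not_silent(self, rng):
        fit = self._fit(rng)
        fit.se[0, 0, 0, 0] = 0.0
        with pytest.warns(UserWarning, match="zero standard error"):
            p = wald_pvalues(fit)
        assert np.isnan(p[0, 0, 0, 0])

    def test_white_noise_estimates_near_zero(self):
        """With no dynamics, nearly all coefficients land within 3 SEs of 0."""
        hits = total = 0
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)
            g = rng.standard_normal((2, 300))
            fit = fit_ols(
                build_design({"b": series(g)}, ConditionCoding(("b",)), p=1)
            )
            wald_pvalues(fit)
            hits += np.sum(np.abs(fit.zvalues) <= 3.0)
            total += fit.zvalues.size
        assert hits / total >= 0.99


class TestSignificantEdges:
    def test_all_p_one_empty(self):
        assert significant_edges(np.ones((2, 1, 3, 3))).sum() == 0

    def test_counts_below_alpha(self, rng):
        p = np.ones(20)
        p[[3, 7, 11]] = 0.01
        assert significant_edges(p, 0.05).sum() == 3

    def test_bh_matches_independent_step_up(self, rng):
        pv = rng.uniform(0, 0.2, size=40)
        ours = significant_edges(pv, 0.05, correction="bh")
        # independent step-up implementation
        m = len(pv)
        srt = np.sort(pv)
        ks = [i for i in range(m) if srt[i] <= 0.05 * (i + 1) / m]
        cut = srt[max(ks)] if ks else -1.0
        expected = pv <= cut
        assert np.array_equal(ours, expected)

    def test_bad_alpha(self):
        with pytest.raises(Exception):
            significant_edges(np.ones(3), alpha=1.5)


class TestCompanionRadius:
    def test_zero_matrix(self):
        assert companion_spectral_radius(np.zeros((1, 3, 3))) == 0.0

    def test_diagonal(self):
        assert companion_spectral_radius(0.9 * np.eye(6)) == pytest.approx(0.9)

    def test_matches_explicit_companion_eig(self, rng):
        phi = rng.standard_normal((2, 6, 6)) * 0.2
        ours = companion_spectral_radius(phi)
        comp = np.zeros((12, 12))
        comp[:6, :6] = phi[0]
        comp[:6, 6:] = phi[1]
        comp[6:, :6] = np.eye(6)
        expected = np.max(np.abs(np.linalg.eigvals(comp)))
        assert abs(ours - expected) < 1e-10
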
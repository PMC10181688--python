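"""Ground-truth generation, VAR simulation, channel expansion, and
full-experiment synthesis."""

import hashlib

import numpy as np
import pytest

from nirsconn import (
    ConditionCoding,
    NumericalError,
    ParadigmSpec,
    ValidationError,
    apply_filter,
    block_envelope,
    build_design,
    cluster_channels,
    companion_spectral_radius,
    design_fir_bandpass,
    expand_to_channels,
    extract_task_epochs,
    fit_ols,
    make_ground_truth,
    match_clusters,
    project_mean,
    project_median,
    simulate_condition_run,
    simulate_experiment,
    wald_pvalues,
    write_snirf,
    FilterSpec,
)


class TestGroundTruth:
    def test_zero_sparsity_is_diagonal_only(self):
        t = make_ground_truth(M=4, K=2, sparsity=0.0, seed=0)
        assert np.all(t.phi0[0][~np.eye(4, dtype=bool)] == 0)
        assert np.all(t.deltas == 0)

    def test_deterministic_from_seed(self):
        a = make_ground_truth(M=5, K=3, seed=42)
        b = make_ground_truth(M=5, K=3, seed=42)
        assert np.array_equal(a.phi0, b.phi0)
        assert np.array_equal(a.deltas, b.deltas)

    @pytest.mark.parametrize("seed", range(5))
    def test_stability_margin_enforced(self, seed):
        t = make_ground_truth(M=6, K=4, sparsity=0.4, effect_size=0.6, seed=seed)
        for k in range(t.K + 1):
            assert companion_spectral_radius(t.phi_total(k)) < 0.95


class TestSimulateRun:
    def test_zero_coefficients_give_white_noise(self):
        t = make_ground_truth(M=3, K=0, sparsity=0.0, diag=0.0, seed=0)
        x = simulate_condition_run(t, 0, 20000, seed=1)
        sample_cov = np.cov(x)
        assert np.all(np.abs(sample_cov - t.resid_cov) < 0.1)  # within 10%

    def test_ar1_autocorrelation_closed_form(self):
        t = make_ground_truth(M=1, K=0, sparsity=0.0, diag=0.9, seed=0)
        x = simulate_condition_run(t, 0, 10000, seed=2)[0]
        rho = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert rho == pytest.approx(0.9, abs=0.05)

    def test_deterministic_from_seed(self):
        t = make_ground_truth(M=3, K=1, seed=0)
        a = simulate_condition_run(t, 1, 100, seed=5)
        b = simulate_condition_run(t, 1, 100, seed=5)
        assert np.array_equal(a, b)

    def test_unstable_truth_refused(self):
        t = make_ground_truth(M=2, K=0, sparsity=0.0, seed=0)
        t.phi0[0] = np.eye(2) * 1.1  # force instability post hoc
        with pytest.raises(NumericalError, match="unstable"):
            simulate_condition_run(t, 0, 100, seed=0)

    def test_student_t_innovations_unit_variance(self):
        t = make_ground_truth(M=2, K=0, sparsity=0.0, diag=0.0, seed=0)
        x = simulate_condition_run(t, 0, 20000, seed=3,
                                   innovation="student_t", df=5)
        assert np.allclose(np.var(x, axis=1), 1.0, atol=0.15)


class TestExpandToChannels:
    def test_noiseless_median_projection_is_identity(self, rng):
        x = rng.standard_normal((4, 50))
        hb, geom, asg = expand_to_channels(
            x, channels_per_cluster=3, channel_noise_sd=0.0, seed=0
        )
        proj = project_median(hb, asg)
        assert np.allclose(proj.g, x, atol=1e-12)

    def test_outlier_biases_mean_not_median(self, rng):
        x = rng.standard_normal((4, 100))
        common = dict(channels_per_cluster=5, channel_noise_sd=0.0, seed=0)
        hb, _, asg = expand_to_channels(x, **common)
        hb_out, _, _ = expand_to_channels(
            x, outlier_channels=4, outlier_offset=100.0, **common
        )
        med = project_median(hb_out, asg).g
        mean = project_mean(hb_out, asg).g
        assert np.allclose(med, project_median(hb, asg).g, atol=1e-12)
        assert np.allclose(mean - project_mean(hb, asg).g, 100.0 / 5, atol=1e-9)

    def test_clustering_recovers_spawning_partition(self, rng):
        x = rng.standard_normal((6, 20))
        hb, geom, true_asg = expand_to_channels(
            x, channels_per_cluster=5, channel_noise_sd=0.1, seed=1
        )
        est = cluster_channels(hb.channel_coords, 6, seed=2)
        perm = match_clusters(est, true_asg.centroids)
        assert np.array_equal(perm[est.labels], true_asg.labels)

    def test_channel_coords_midpoints_consistent(self, rng):
        x = rng.standard_normal((3, 10))
        hb, geom, _ = expand_to_channels(x, channels_per_cluster=2, seed=0)
        # HbSeries rows are per pair; geometry has 2 wavelength rows per pair
        assert geom.n_channels == 2 * hb.n_channels
        assert np.allclose(geom.channel_coords[::2], hb.channel_coords)

    def test_majority_outliers_warn(self, rng):
        x = rng.standard_normal((2, 10))
        with pytest.warns(UserWarning, match="half"):
            expand_to_channels(
                x, channels_per_cluster=3, outlier_channels=4,
                outlier_offset=10.0, seed=0,
            )


class TestParadigm:
    def test_run_length_matches_block_arithmetic(self):
        p = ParadigmSpec()
        # 17 + 4*22 + 3*10 + 17 = 152 s -> 1550 samples at 10.2 Hz
        assert p.total_s == pytest.approx(152.0)
        assert p.n_samples == 1550

    def test_envelope_boxcar_covers_task_blocks(self):
        p = ParadigmSpec()
        env = block_envelope(p, "boxcar")
        assert env.sum() == pytest.approx(4 * 22 * 10.2, rel=0.01)
        assert env[0] == 0 and env[-1] == 0

    def test_envelope_hrf_is_delayed_and_normalised(self):
        p = ParadigmSpec()
        env = block_envelope(p, "hrf")
        assert env.max() == pytest.approx(1.0)
        box = block_envelope(p, "boxcar")
        assert np.argmax(env > 0.5) > np.argmax(box > 0.5)  # hemodynamic lag


class TestSimulateExperiment:
    def test_one_run_per_condition_distinct_labels(self):
        t = make_ground_truth(M=3, K=4, seed=0)
        exp = simulate_experiment(t, seed=1, channels_per_cluster=2)
        assert len(exp.runs) == 5
        assert len({r.condition for r in exp.runs}) == 5

    def test_snirf_output_byte_identical_across_reruns(self, tmp_path):
        t = make_ground_truth(M=2, K=1, seed=3)
        digests = []
        for attempt in range(2):
            exp = simulate_experiment(t, seed=7, channels_per_cluster=2)
            f = tmp_path / f"run{attempt}.snirf"
            write_snirf(exp.geometry, exp.runs[0].recording, f)
            digests.append(hashlib.sha256(f.read_bytes()).hexdigest())
        assert digests[0] == digests[1]

    def test_condition_count_mismatch_rejected(self):
        t = make_ground_truth(M=2, K=1, seed=0)
        with pytest.raises(ValidationError):
            simulate_experiment(t, conditions=["a", "b", "c"], seed=0)


def _pipeline_fit(filter_on, seed=1, trials=20):
    """simulate -> (filter) -> median-project -> per-trial stacked fit,
    coefficients mapped back to generator order."""
    truth = make_ground_truth(M=4, K=2, p=1, sparsity=0.2, effect_size=0.4,
                              seed=seed)
    conds = ["c0", "c1", "c2"]
    exp = simulate_experiment(
        truth, ParadigmSpec(trials=trials), conditions=conds, seed=seed + 1,
        channels_per_cluster=5, channel_noise_sd=0.1,
    )
    taps = design_fir_bandpass(FilterSpec(fs=exp.paradigm.fs))
    asg = cluster_channels(exp.runs[0].hb.channel_coords, truth.M, seed=seed)
    perm = match_clusters(asg, exp.anchors)
    inv = np.argsort(perm)
    data = {}
    for run in exp.runs:
        hb = apply_filter(run.hb, taps) if filter_on else run.hb
        data[run.condition] = extract_task_epochs(project_median(hb, asg))
    fit = fit_ols(build_design(data, ConditionCoding(tuple(conds)), p=1))
    pv = wald_pvalues(fit)
    phi = fit.phi[:, :, inv][:, :, :, inv]
    pv = pv[:, :, inv][:, :, :, inv]
    truth_all = np.concatenate([truth.phi0[None], truth.deltas])
    return phi, pv, truth_all, truth


class TestFullPipelineRecovery:
    def test_unfiltered_pipeline_recovers_truth(self):
        """End-to-end (no band-pass): nonzero coefficients keep their signs
        and true-zero deltas reject near the nominal rate."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            phi, pv, truth_all, truth = _pipeline_fit(filter_on=False)
        nz = truth_all != 0
        assert np.mean(np.sign(phi[nz]) == np.sign(truth_all[nz])) >= 0.95
        zero_deltas = np.concatenate(
            [np.zeros_like(truth.phi0[None], dtype=bool), truth.deltas == 0]
        )
        assert np.mean(pv[zero_deltas] <= 0.05) <= 0.15
        assert np.sqrt(np.mean((phi - truth_all) ** 2)) < 0.05

    def test_bandpass_inflates_false_positives(self):
        """The 0.01-0.4 Hz zero-phase band-pass colors the residuals so
        heavily that lag-1 Wald inference loses calibration -- a documented
        property of the method, asserted here so it stays visible."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            phi, pv, truth_all, truth = _pipeline_fit(filter_on=True)
        zero_deltas = np.concatenate(
            [np.zeros_like(truth.phi0[None], dtype=bool), truth.deltas == 0]
        )
        assert np.mean(pv[zero_deltas] <= 0.05) > 0.3
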
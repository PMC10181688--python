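"""End-to-end pipeline: (simulate | read) -> preprocess -> project -> fit ->
maps, with a deterministic artifact directory and a provenance log.

Given one seed and one config, every output file is byte-identical across
reruns.  Stage failures leave partial outputs in place together with a
FAILED marker naming the stage.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cdvar import (
    ConditionCoding,
    build_design,
    extract_task_epochs,
    fit_ols,
    significant_edges,
    trial_average,
    wald_pvalues,
)
from .config import RunConfig
from .errors import DataError, NirsconnError
from .io import read_snirf, write_snirf
from .maps import build_maps, export_map, interhemispheric_summary
from .preprocess import (
    DEFAULT_EXTINCTION,
    FilterSpec,
    apply_filter,
    design_fir_bandpass,
    mbll,
    optical_density,
)
from .projection import cluster_channels, project_mean, project_median
from .synthetic import GroundTruth, ParadigmSpec, make_ground_truth, simulate_experiment

__all__ = ["run_pipeline"]


def _log(lines: list[str], msg: str) -> None:
    lines.append(msg)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis chain; returns the artifact directory.

    Layout: ``sim/`` (when simulating), ``hb/``, ``projected/``, ``fit/``,
    ``maps/`` and ``log.txt``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    _log(log, f"nirsconn {__version__}")
    _log(log, f"python {sys.version.split()[0]}  numpy {np.__version__}")
    _log(log, f"config: {config.model_dump_json()}")
    stage = "setup"
    try:
        # ---------------- inputs ----------------
        stage = "simulate" if config.simulate else "read"
        runs = []  # list of (geometry, recording)
        if config.simulate:
            s = config.sim
            truth = make_ground_truth(
                M=config.clusters,
                K=len(config.conditions) - 1,
                p=config.order,
                sparsity=s.sparsity,
                effect_size=s.effect_size,
                seed=config.seed,
            )
            paradigm = ParadigmSpec(
                initial_rest_s=s.initial_rest_s,
                task_s=s.task_s,
                inter_rest_s=s.inter_rest_s,
                trials=s.trials,
                fs=s.fs,
            )
            experiment = simulate_experiment(
                truth,
                paradigm,
                conditions=config.conditions,
                seed=config.seed,
                channels_per_cluster=s.channels_per_cluster,
                channel_noise_sd=s.channel_noise_sd,
                outlier_channels=s.outlier_channels,
                outlier_offset=s.outlier_offset,
                envelope=s.envelope,
            )
            sim_dir = out / "sim"
            sim_dir.mkdir(exist_ok=True)
            for run in experiment.runs:
                fname = sim_dir / f"{run.condition.replace(' ', '_')}.snirf"
                write_snirf(experiment.geometry, run.recording, fname)
                runs.append((experiment.geometry, run.recording))
            _write_truth(sim_dir / "truth.json", truth)
            _log(log, f"simulated {len(runs)} runs -> {sim_dir}")
        else:
            if not config.inputs:
                raise DataError("no input files given and simulate=False")
            for p in config.inputs:
                runs.append(read_snirf(p))
            _log(log, f"read {len(runs)} SNIRF runs")

        # ---------------- preprocess ----------------
        stage = "preprocess"
        ext = config.mbll.extinction_table or DEFAULT_EXTINCTION
        _log(log, f"MBLL: dpf={config.mbll.dpf} extinction={ext}")
        fs = runs[0][1].fs
        spec = FilterSpec(
            order=config.filter.order, band=tuple(config.filter.band_hz), fs=fs
        )
        taps = design_fir_bandpass(spec)
        _log(
            log,
            f"FIR band-pass: order={spec.order} band={spec.band} Hz "
            f"fs={fs} zero_phase={config.filter.zero_phase} "
            f"domain={config.filter_domain}",
        )
        hb_dir = out / "hb"
        hb_dir.mkdir(exist_ok=True)
        hb_runs = []
        for geometry, rec in runs:
            od = optical_density(rec)
            if config.filter_domain == "od":
                from .preprocess import _filter_matrix

                od = _filter_matrix(od, taps, config.filter.zero_phase)
            hb = mbll(
                od,
                geometry,
                fs=rec.fs,
                dpf=config.mbll.dpf,
                extinction=ext,
                run_condition=rec.run_condition,
                event_markers=rec.event_markers,
            )
            if config.filter_domain == "hb":
                hb = apply_filter(hb, taps, config.filter.zero_phase)
            hb_runs.append(hb)
            _save_matrix_csv(
                hb_dir / f"{_slug(rec.run_condition)}_hbo.csv", hb.hbo, hb.fs
            )
        _log(log, f"preprocessed {len(hb_runs)} runs -> {hb_dir}")

        # ---------------- projection ----------------
        stage = "project"
        assignment = cluster_channels(
            hb_runs[0].channel_coords, config.clusters, seed=config.seed
        )
        project = project_median if config.projection == "median" else project_mean
        projected = [project(hb, assignment) for hb in hb_runs]
        proj_dir = out / "projected"
        proj_dir.mkdir(exist_ok=True)
        pd.DataFrame(
            {
                "channel": np.arange(assignment.n_channels),
                "label": assignment.labels,
                "roi_name": [
                    assignment.cluster_name(l) for l in assignment.labels
                ],
            }
        ).to_csv(proj_dir / "assignment.csv", index=False)
        for ps in projected:
            _save_matrix_csv(
                proj_dir / f"{_slug(ps.run_condition)}_projected.csv", ps.g, ps.fs
            )
        _log(
            log,
            f"projected to M={config.clusters} clusters "
            f"({config.projection}) -> {proj_dir}",
        )

        # ---------------- fit ----------------
        stage = "fit"
        coding = ConditionCoding(tuple(config.conditions))
        series_by_condition = {}
        for ps in projected:
            epochs = extract_task_epochs(ps, include_rest=config.include_rest)
            series_by_condition[ps.run_condition] = (
                epochs if config.per_trial else trial_average(epochs)
            )
            _log(
                log,
                f"condition {ps.run_condition!r}: {len(epochs)} epochs, "
                f"mode={'per-trial' if config.per_trial else 'trial-averaged'}",
            )
        design = build_design(series_by_condition, coding, p=config.order)
        fit = fit_ols(design)
        pvals = wald_pvalues(fit)
        fit_dir = out / "fit"
        fit_dir.mkdir(exist_ok=True)
        _write_coefficients(fit_dir / "coefficients.csv", fit)
        summary = {
            "n_obs": fit.n_obs,
            "n_obs_per_condition": fit.n_obs_per_condition,
            "n_coefficients_per_equation": design.n_coef,
            "companion_spectral_radii": fit.companion_radii(),
            "alpha": config.alpha,
            "correction": config.correction,
            "significant_edges_per_condition": {
                name: int(
                    significant_edges(
                        pvals[k],
                        config.alpha,
                        None if config.correction == "none" else config.correction,
                    ).sum()
                )
                for k, name in enumerate(fit.condition_names)
            },
        }
        (fit_dir / "summary.json").write_text(json.dumps(summary, indent=2))
        _log(log, f"fit: n={fit.n_obs}, q={design.n_coef} -> {fit_dir}")

        # ---------------- maps ----------------
        stage = "maps"
        maps = build_maps(
            fit,
            assignment,
            alpha=config.alpha,
            correction=None if config.correction == "none" else config.correction,
        )
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        hemi_rows = []
        for cmap in maps:
            base = maps_dir / _slug(cmap.condition)
            export_map(cmap, "csv", base.with_suffix(".csv"))
            export_map(cmap, "json", base.with_suffix(".json"))
            export_map(cmap, "graphml", base.with_suffix(".graphml"))
            hemi_rows.append(
                dict(condition=cmap.condition, **interhemispheric_summary(cmap))
            )
        pd.DataFrame(hemi_rows).to_csv(
            maps_dir / "hemisphere_summary.csv", index=False
        )
        _log(log, f"maps for {len(maps)} conditions -> {maps_dir}")

    except NirsconnError:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        _log(log, f"FAILED at stage {stage}")
        (out / "log.txt").write_text("\n".join(log) + "\n")
        raise
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return out


def _slug(name: str | None) -> str:
    return (name or "run").replace(" ", "_").replace("/", "_")


def _save_matrix_csv(path: Path, matrix: np.ndarray, fs: float) -> None:
    t = np.arange(matrix.shape[1]) / fs
    df = pd.DataFrame(matrix.T, columns=[f"s{i}" for i in range(matrix.shape[0])])
    df.insert(0, "time", t)
    df.to_csv(path, index=False)


def _write_truth(path: Path, truth: GroundTruth) -> None:
    path.write_text(
        json.dumps(
            {
                "M": truth.M,
                "K": truth.K,
                "p": truth.p,
                "seed": truth.seed,
                "sparsity": truth.sparsity,
                "effect_size": truth.effect_size,
                "phi0": truth.phi0.tolist(),
                "deltas": truth.deltas.tolist(),
                "resid_cov": truth.resid_cov.tolist(),
            },
            indent=2,
        )
    )


def _write_coefficients(path: Path, fit) -> None:
    rows = []
    for k, cond in enumerate(fit.condition_names):
        for l in range(fit.p):
            for i in range(fit.M):
                for j in range(fit.M):
                    rows.append(
                        dict(
                            condition=cond,
                            lag=l + 1,
                            from_cluster=j,
                            to_cluster=i,
                            estimate=fit.phi[k, l, i, j],
                            se=fit.se[k, l, i, j],
                            z=fit.zvalues[k, l, i, j],
                            p=fit.pvalues[k, l, i, j],
                        )
                    )
    pd.DataFrame(rows).to_csv(path, index=False)
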
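"""End-to-end pipeline: simulate -> screen -> fit -> metrics -> decompose ->
associate -> project/null.

The configuration defaults are the analysis' printed settings: a 7-state
solution fitted with 10 restarts, 300 permutations for the gradient-space
null, the 2.5 sigma dwell-time outlier rule, mean-FD > 0.3 mm and >15%
flagged-volume exclusion rules, and eigenvalue > 1 component retention.
Every run writes a manifest recording package versions, seeds and every
threshold used, sufficient to re-run the pipeline bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import build_design_matrix, fit_mancova
from .behaviour import back_project_betas, pca_varimax
from .gradients import (exceedance_test, load_gradient_basis, permutation_null,
                        project_states)
from .hmm import (compute_state_metrics, decode_states, fit_group_hmm,
                  standardise_dwell_times)
from .ingest import (ExclusionThresholds, apply_exclusion, load_motion_csv,
                     load_timeseries_dir, save_group_matrix,
                     standardise_and_concatenate)
from .synth import SimulationConfig, write_dataset

log = logging.getLogger("neurostates")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings for a full pipeline run (defaults = the study's settings)."""

    data_dir: str | None = None  # existing dataset; None -> simulate
    out_dir: str = "neurostates_out"
    n_states: int = 7
    n_runs: int = 10
    n_permutations: int = 300
    seed: int = 0
    fd_mean_max_mm: float = 0.3
    fd_scrub_mm: float = 0.5
    bad_fraction_max: float = 0.15
    outlier_sigma: float = 2.5
    use_abs_max: bool = False
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        defaults = cls()
        for f in dataclasses.fields(cls):
            if f.name in data and getattr(cfg, f.name) != getattr(defaults, f.name):
                log.info("config override: %s = %r", f.name, getattr(cfg, f.name))
        return cfg


def _simulation_config(config: PipelineConfig) -> SimulationConfig:
    overrides = dict(config.simulation)
    overrides.setdefault("seed", config.seed)
    overrides.setdefault("n_states", config.n_states)
    return SimulationConfig(**overrides)


def _stage(name):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the results bundle.

    The bundle holds the exclusion report, the fitted model, state metrics,
    the component models, the per-state MANCOVA results for experience (and
    well-being when present), and the gradient projection with its
    permutation null. All artefacts are also written under ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = _stage("simulate/load")
    if config.data_dir is None:
        sim = _simulation_config(config)
        data_dir = write_dataset(sim, out / "data")
    else:
        data_dir = Path(config.data_dir)
    timings["simulate"] = time.perf_counter() - t0

    t0 = _stage("ingest")
    subjects = load_timeseries_dir(data_dir / "timeseries")
    motion = load_motion_csv(data_dir / "motion.csv",
                             scrub_threshold_mm=config.fd_scrub_mm)
    pairs = []
    for ts in subjects:
        if ts.subject_id not in motion:
            raise ValueError(f"missing motion trace for subject {ts.subject_id}")
        pairs.append((ts, motion[ts.subject_id]))
    thresholds = ExclusionThresholds(fd_mean_max_mm=config.fd_mean_max_mm,
                                     scrub_threshold_mm=config.fd_scrub_mm,
                                     bad_fraction_max=config.bad_fraction_max)
    retained, exclusion_report = apply_exclusion(pairs, thresholds)
    group = standardise_and_concatenate(retained)
    save_group_matrix(group, out / "group")
    (out / "exclusion_report.json").write_text(json.dumps(exclusion_report, indent=1))
    timings["ingest"] = time.perf_counter() - t0

    t0 = _stage("fit")
    params, best_run, objectives = fit_group_hmm(
        group, n_states=config.n_states, n_runs=config.n_runs, seed=config.seed)
    _save_model(params, best_run, objectives, out / "model.json")
    timings["fit"] = time.perf_counter() - t0

    t0 = _stage("metrics")
    sequences = decode_states(params, group)
    metrics = compute_state_metrics([s.viterbi_path for s in sequences],
                                    config.n_states, group.retained_ids)
    dwell_std = standardise_dwell_times(metrics.mean_dwell_time,
                                        sigma=config.outlier_sigma)
    _save_metrics(metrics, out / "state_metrics.csv")
    timings["metrics"] = time.perf_counter() - t0

    t0 = _stage("decompose/associate")
    retained_ids = group.retained_ids
    mean_fd = np.array([motion[sid].mean_fd for sid in retained_ids])
    covariates = pd.read_csv(data_dir / "covariates.csv").set_index("subject_id")
    age = covariates.loc[retained_ids, "age"].to_numpy()
    gender = covariates.loc[retained_ids, "gender"].to_numpy()
    design = build_design_matrix(dwell_std, mean_fd, age, gender)

    reports = pd.read_csv(data_dir / "reports.csv", index_col="subject_id")
    missing = [i for i in retained_ids if i not in reports.index]
    if missing:
        raise ValueError(f"missing reports for subjects: {missing[:5]}")
    reports = reports.loc[retained_ids]
    experience_model = pca_varimax(reports)
    experience_results = fit_mancova(experience_model.scores, design)
    beta_rows = np.stack([r.betas for r in experience_results])
    item_betas = back_project_betas(beta_rows, experience_model)
    for r, ib in zip(experience_results, item_betas):
        r.item_space_betas = ib
    _save_mancova(experience_results, experience_model.item_labels,
                  out / "experience_mancova.json")

    wellbeing_results = None
    wellbeing_model = None
    wb_path = data_dir / "wellbeing.csv"
    if wb_path.exists():
        wb = pd.read_csv(wb_path, index_col="subject_id")
        wb_ids = [i for i in retained_ids if i in wb.index]
        wb = wb.loc[wb_ids]
        wellbeing_model = pca_varimax(wb)
        rows = [retained_ids.index(i) for i in wb_ids]
        wb_design = build_design_matrix(dwell_std[rows], mean_fd[rows],
                                        age[rows], gender[rows])
        wellbeing_results = fit_mancova(wellbeing_model.scores, wb_design)
        wb_betas = np.stack([r.betas for r in wellbeing_results])
        for r, ib in zip(wellbeing_results,
                         back_project_betas(wb_betas, wellbeing_model)):
            r.item_space_betas = ib
        _save_mancova(wellbeing_results, wellbeing_model.item_labels,
                      out / "wellbeing_mancova.json")
    timings["associate"] = time.perf_counter() - t0

    t0 = _stage("project/null")
    basis = load_gradient_basis(data_dir / "gradients.tsv")
    projection = project_states(params.means, basis,
                                use_abs_max=config.use_abs_max)
    null = permutation_null(params.means, basis,
                            n_permutations=config.n_permutations,
                            seed=config.seed, use_abs_max=config.use_abs_max)
    p_exceed, verdict = exceedance_test(projection.weighted_sum, null)
    _save_projection(projection, null, p_exceed, verdict, out)
    timings["project"] = time.perf_counter() - t0

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "n_subjects_input": len(subjects),
        "n_subjects_retained": len(retained),
        "best_run": int(best_run),
        "run_objectives": objectives.tolist(),
        "timings_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return {
        "exclusion_report": exclusion_report,
        "group": group,
        "params": params,
        "best_run": best_run,
        "run_objectives": objectives,
        "metrics": metrics,
        "dwell_std": dwell_std,
        "experience_model": experience_model,
        "experience_results": experience_results,
        "wellbeing_model": wellbeing_model,
        "wellbeing_results": wellbeing_results,
        "projection": projection,
        "null": null,
        "exceedance_p": p_exceed,
        "verdict": verdict,
        "manifest": manifest,
    }


def _save_model(params, best_run, objectives, path: Path) -> None:
    path.write_text(json.dumps({
        "n_states": params.n_states,
        "means": params.means.tolist(),
        "covariances": params.covariances.tolist(),
        "transition_matrix": params.transition_matrix.tolist(),
        "initial_probs": params.initial_probs.tolist(),
        "objective_trace": params.objective_trace.tolist(),
        "converged": params.converged,
        "cov_regularised": params.cov_regularised,
        "best_run": int(best_run),
        "run_objectives": np.asarray(objectives).tolist(),
    }))


def _save_metrics(metrics, path: Path) -> None:
    K = metrics.mean_dwell_time.shape[1]
    df = pd.DataFrame({"subject_id": metrics.subject_ids})
    for s in range(K):
        df[f"dwell_state_{s + 1}"] = metrics.mean_dwell_time[:, s]
        df[f"occupancy_state_{s + 1}"] = metrics.fractional_occupancy[:, s]
    df["switching_rate"] = metrics.switching_rate
    df.to_csv(path, index=False, float_format="%.6f")


def _save_mancova(results, item_labels, path: Path) -> None:
    path.write_text(json.dumps([{
        "predictor": r.predictor,
        "wilks_lambda": r.wilks_lambda,
        "f_stat": r.f_stat,
        "df1": r.df1,
        "df2": r.df2,
        "p_value": r.p_value,
        "partial_eta_sq": r.partial_eta_sq,
        "betas": r.betas.tolist(),
        "n_tests_in_family": r.n_tests_in_family,
        "item_space_betas": dict(zip(item_labels, r.item_space_betas.tolist()))
        if r.item_space_betas is not None else None,
    } for r in results], indent=1))


def _save_projection(projection, null, p_exceed, verdict, out: Path) -> None:
    K = projection.coords.shape[0]
    pd.DataFrame(projection.coords, columns=["G1", "G2", "G3"],
                 index=[f"state_{s + 1}" for s in range(K)]).to_csv(
        out / "state_coordinates.csv")
    pd.DataFrame(null.synthetic_state_coords,
                 columns=["G1", "G2", "G3"]).to_csv(
        out / "null_coordinates.csv", index=False, float_format="%.6f")
    (out / "gradient_summary.json").write_text(json.dumps({
        "weighted_distance_sum": projection.weighted_sum,
        "n_permutations": null.n_permutations,
        "n_synthetic_states": int(null.synthetic_state_coords.shape[0]),
        "null_sums": null.null_sums.tolist(),
        "band_95": null.band_95.tolist(),
        "exceedance_p": p_exceed,
        "verdict": verdict,
    }))
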
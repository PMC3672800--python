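"""End-to-end orchestration: simulate -> track -> network -> predict.

A :class:`PipelineConfig` fully determines a run: one global seed fans out
to per-stage seeds through a fixed counter scheme, every stage writes plain
text artifacts into the run directory, and a manifest records the config
hash and a checksum for each output so a rerun with the same config is
byte-identical and attributable.  A completed run (matching config hash in
the manifest) is not recomputed unless ``force`` is set.

The simulated cohort links its two arms the way the motivating study found
them linked: clinical rigidity scores are a sparse linear function of
connection strengths, and each subject's tracking damping ratio drifts
upward with their score (more rigid subjects overshoot less).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rigidnet import io
from rigidnet import network as net_mod
from rigidnet import preprocess, regression, simulate, tracking

logger = logging.getLogger("rigidnet")

STAGES = ("simulate", "track", "network", "predict")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run depends on; round-trips through YAML."""

    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    force: bool = False

    # --- simulate: cohort and networks ---
    n_subjects_pd: int = 10
    n_subjects_control: int = 10
    n_rois: int = 52
    n_connections: int = 227
    n_true_edges: int = 9
    base_coeff: float = 0.25
    beta_scale: float = 5.0
    score_noise_sd: float = 1.0
    roi_timepoints: int = 270
    tr: float = 1.985
    innovation_sd: float = 1.0

    # --- simulate: tracking trials ---
    runs_per_subject: int = 3
    noise_levels: tuple[float, ...] = (0.0, 25.0, 50.0)
    tracking_noise_sd: float = 0.1
    zeta_base: float = 0.8
    zeta_gain: float = 0.15
    zeta_jitter_sd: float = 0.05
    omega_low: float = 2.0
    omega_high: float = 5.0
    trial_duration: float = 90.0
    sample_rate: float = 50.0

    # --- track ---
    aggregator: str = "mean"

    # --- network ---
    fdr_level: float = 0.05
    max_cond_size: int = 3
    apply_dct: bool = True
    dct_cutoff: float = 128.0

    # --- predict ---
    n_folds: int = 10
    lasso_rule: str = "min"

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        object.__setattr__(self, "noise_levels", tuple(self.noise_levels))
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["noise_levels"] = list(d["noise_levels"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "noise_levels" in d:
            d["noise_levels"] = tuple(d["noise_levels"])
        return cls(**d)

    def config_hash(self) -> str:
        # force is an execution flag, not an identity of the outputs
        d = dataclasses.asdict(self)
        d.pop("force")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed: the global seed expanded by a fixed counter."""
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(paths: dict[str, str | Path]) -> list[dict]:
    """Schema/finiteness/alignment checks; returns a machine-readable issue list.

    Recognized keys: ``strengths`` (CSV, subject_id index), ``clinical``
    (CSV with subject_id, score), ``trials_dir`` (directory of trial CSVs).
    """
    issues: list[dict] = []

    def numeric_issues(df: pd.DataFrame, fname: str, cols=None) -> None:
        for col in df.columns if cols is None else [c for c in cols if c in df.columns]:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            for row in bad:
                issues.append(
                    {
                        "file": fname,
                        "row": str(row),
                        "column": str(col),
                        "issue": f"non-numeric value {df.loc[row, col]!r}",
                    }
                )

    strengths = clinical = None
    if "strengths" in paths:
        f = Path(paths["strengths"])
        if not f.exists():
            issues.append({"file": str(f), "issue": "missing file"})
        else:
            strengths = pd.read_csv(f, index_col="subject_id", dtype=str)
            numeric_issues(strengths, str(f))
    if "clinical" in paths:
        f = Path(paths["clinical"])
        if not f.exists():
            issues.append({"file": str(f), "issue": "missing file"})
        else:
            clinical = pd.read_csv(f, dtype=str)
            if "subject_id" not in clinical.columns:
                issues.append({"file": str(f), "issue": "missing subject_id column"})
                clinical = None
            else:
                clinical = clinical.set_index("subject_id")
                score_cols = [c for c in clinical.columns if c != "group"]
                numeric_issues(clinical, str(f), cols=score_cols)
    if strengths is not None and clinical is not None:
        only_clin = sorted(set(clinical.index) - set(strengths.index))
        for sid in only_clin:
            issues.append(
                {
                    "subject_id": sid,
                    "files": [str(paths["clinical"]), str(paths["strengths"])],
                    "issue": "subject in clinical data but absent from strengths",
                }
            )
    if "trials_dir" in paths:
        d = Path(paths["trials_dir"])
        if not d.is_dir():
            issues.append({"file": str(d), "issue": "missing trials directory"})
        else:
            for f in sorted(d.glob("*.csv")):
                df = pd.read_csv(f, dtype=str)
                missing = {"time_s", "u", "y"} - set(df.columns)
                if missing:
                    issues.append(
                        {"file": str(f), "issue": f"missing columns {sorted(missing)}"}
                    )
                else:
                    numeric_issues(df, str(f))
    return issues


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_simulate(cfg: PipelineConfig, run_dir: Path) -> list[Path]:
    seed = cfg.stage_seed("simulate")
    rng = np.random.default_rng(seed)
    n_total = cfg.n_subjects_pd + cfg.n_subjects_control
    density = cfg.n_connections / net_mod.edge_universe_size(cfg.n_rois)
    W = simulate.sparse_var_matrix(
        cfg.n_rois, density, cfg.base_coeff, seed=seed, signed=True
    )
    # sparse_var_matrix rounds the edge count; regenerate deterministically
    # until the support size matches the requested connection count
    attempt = 0
    while int(np.count_nonzero(W)) != cfg.n_connections:
        attempt += 1
        W = simulate.sparse_var_matrix(
            cfg.n_rois, density, cfg.base_coeff, seed=seed + 7919 * attempt, signed=True
        )
        if attempt > 100:
            raise RuntimeError("could not hit the requested connection count")
    base_net = simulate.NetworkSimSpec(
        n_rois=cfg.n_rois,
        coeff_matrix=W,
        innovation_sd=cfg.innovation_sd,
        n_timepoints=cfg.roi_timepoints,
        tr=cfg.tr,
        seed=seed,
    )
    support = tuple(
        int(k) for k in rng.choice(cfg.n_connections, cfg.n_true_edges, replace=False)
    )
    beta = tuple(
        float(b)
        for b in rng.choice([-1.0, 1.0], cfg.n_true_edges) * cfg.beta_scale
    )
    cohort_spec = simulate.CohortSimSpec(
        n_subjects=n_total,
        n_connections=cfg.n_connections,
        true_support=support,
        beta_values=beta,
        score_noise_sd=cfg.score_noise_sd,
        seed=seed,
    )
    cohort = simulate.simulate_cohort(cohort_spec, base_net, slot_rule="support")

    groups = ["PD"] * cfg.n_subjects_pd + ["CTL"] * cfg.n_subjects_control
    # rigidity scores only make clinical sense for the patient group; shift
    # them into the ordinal range so the PD spread is usable downstream
    scores = cohort.Y - cohort.Y.min()

    roi_dir = run_dir / "roi"
    trials_dir = run_dir / "trials"
    roi_dir.mkdir(parents=True, exist_ok=True)
    trials_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    roi_names = tuple(f"roi{j:03d}" for j in range(cfg.n_rois))
    score_sd = scores.std() or 1.0
    score_mean = scores.mean()
    manifest_rows = []
    for k, sid in enumerate(cohort.subject_ids):
        series = preprocess.ROITimeSeries(
            data=cohort.roi_series[sid],
            tr=cfg.tr,
            roi_names=roi_names,
            subject_id=sid,
            group=groups[k],
        )
        f = roi_dir / f"{sid}.tsv"
        io.write_roi_series(f, series)
        outputs.append(f)
        # damping ratio drifts up with rigidity: less overshoot when rigid
        zeta_k = float(
            np.clip(
                cfg.zeta_base
                + cfg.zeta_gain * (scores[k] - score_mean) / score_sd
                + rng.normal(0.0, cfg.zeta_jitter_sd),
                0.15,
                2.5,
            )
        )
        omega_k = float(rng.uniform(cfg.omega_low, cfg.omega_high))
        for r, level in enumerate(cfg.noise_levels[: cfg.runs_per_subject]):
            spec = simulate.TrackingSimSpec(
                zeta=zeta_k,
                omega_n=omega_k,
                duration=cfg.trial_duration,
                sample_rate=cfg.sample_rate,
                noise_sd=cfg.tracking_noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            trial = simulate.simulate_tracking_trial(spec)
            f = trials_dir / f"{sid}_run-{r + 1:02d}.csv"
            io.write_trial(
                f,
                trial,
                meta={
                    "subject_id": sid,
                    "run": r + 1,
                    "visual_noise_pct": level,
                    "zeta": zeta_k,
                    "omega_n": omega_k,
                    "noise_sd": cfg.tracking_noise_sd,
                    "seed": spec.seed,
                },
            )
            outputs.append(f)
        manifest_rows.append(
            {"subject_id": sid, "group": groups[k], "score": scores[k]}
        )
    mf = run_dir / "subjects.csv"
    io.write_manifest_csv(mf, manifest_rows)
    outputs.append(mf)
    gt = run_dir / "ground_truth.json"
    truth = dataclasses.replace(
        cohort.truth,
        tracking={
            row["subject_id"]: {"score": float(row["score"])}
            for row in manifest_rows
        },
    )
    gt.write_text(truth.to_json())
    outputs.append(gt)
    edges_f = run_dir / "true_edges.json"
    edges_f.write_text(
        json.dumps(
            {
                "edge_slots": [[int(i), int(j)] for i, j in cohort.edge_slots],
                "true_support": [int(k) for k in support],
                "beta": list(beta),
            },
            indent=2,
        )
    )
    outputs.append(edges_f)
    logger.info(
        "simulate: %d subjects, %d ROIs, %d connections",
        n_total, cfg.n_rois, cfg.n_connections,
    )
    return outputs


def _stage_track(cfg: PipelineConfig, run_dir: Path) -> list[Path]:
    trials_dir = run_dir / "trials"
    rows = []
    for f in sorted(trials_dir.glob("*.csv")):
        meta = json.loads(f.with_suffix(".json").read_text())
        trial = io.read_trial(f)
        m = tracking.trial_metrics(trial)
        rows.append(
            {
                "subject_id": meta["subject_id"],
                "run_id": meta["run"],
                "visual_noise_pct": meta["visual_noise_pct"],
                "rms": tracking.rms_error(trial),
                "zeta": m.zeta,
                "omega_n": m.omega_n,
                "rise_time": m.rise_time,
                "peak_time": m.peak_time if m.peak_time is not None else np.nan,
                "settling_time": m.settling_time,
                "classification": m.classification,
            }
        )
    runs_df = pd.DataFrame(rows)
    f_runs = run_dir / "metrics_runs.csv"
    runs_df.to_csv(f_runs, index=False, float_format=io.FLOAT_FMT)

    sub_rows = []
    for sid, grp in runs_df.groupby("subject_id"):
        ok = grp[grp["classification"] != "degenerate"]
        agg = np.mean if cfg.aggregator == "mean" else np.median
        sub_rows.append(
            {
                "subject_id": sid,
                "n_runs": len(grp),
                "n_valid": len(ok),
                "rms_mean": float(grp["rms"].mean()),
                "zeta": float(agg(ok["zeta"])),
                "omega_n": float(agg(ok["omega_n"])),
            }
        )
    f_subs = run_dir / "metrics_subjects.csv"
    pd.DataFrame(sub_rows).to_csv(f_subs, index=False, float_format=io.FLOAT_FMT)

    fstat, pval = tracking.compare_rms_groups(
        runs_df["rms"].to_numpy(), runs_df["visual_noise_pct"].to_numpy()
    )
    f_sum = run_dir / "track_summary.json"
    f_sum.write_text(
        json.dumps(
            {"rms_anova_F": fstat, "rms_anova_p": pval, "n_runs": len(runs_df)},
            indent=2,
        )
    )
    logger.info("track: %d runs, RMS ANOVA F=%.3f p=%.3f", len(runs_df), fstat, pval)
    return [f_runs, f_subs, f_sum]


def _stage_network(cfg: PipelineConfig, run_dir: Path) -> list[Path]:
    subjects = pd.read_csv(run_dir / "subjects.csv")
    series_list = []
    for sid in subjects["subject_id"]:
        s = io.read_roi_series(run_dir / "roi" / f"{sid}.tsv", tr=cfg.tr, subject_id=sid)
        if cfg.apply_dct:
            s = preprocess.dct_highpass(s, cfg.dct_cutoff)
        s = preprocess.standardize(s)
        series_list.append(s)
    net = net_mod.pcfdr_learn(
        series_list, q=cfg.fdr_level, max_cond_size=cfg.max_cond_size
    )
    f_net = run_dir / "network.json"
    f_net.write_text(net.to_json())
    strengths = {}
    for s in series_list:
        sv = net_mod.dbn_strengths(s, net)
        strengths[sv.subject_id] = sv.values
    df = pd.DataFrame.from_dict(
        strengths, orient="index", columns=list(net.edge_labels)
    )
    df.index.name = "subject_id"
    f_str = run_dir / "strengths.csv"
    df.to_csv(f_str, float_format=io.FLOAT_FMT)
    logger.info("network: %d edges at FDR %.2f", len(net.edges), cfg.fdr_level)
    return [f_net, f_str]


def _stage_predict(cfg: PipelineConfig, run_dir: Path) -> list[Path]:
    issues = validate_inputs(
        {"strengths": run_dir / "strengths.csv", "clinical": run_dir / "subjects.csv"}
    )
    if issues:
        raise ValueError(f"invalid inputs: {issues}")
    strengths = io.read_strengths(run_dir / "strengths.csv")
    subjects = pd.read_csv(run_dir / "subjects.csv").set_index("subject_id")
    pd_ids = subjects.index[subjects["group"] == "PD"]
    X = strengths.loc[pd_ids]
    design = regression.CohortDesign(
        X=X.to_numpy(float),
        Y=subjects.loc[pd_ids, "score"].to_numpy(float),
        edge_labels=tuple(X.columns),
        subject_ids=tuple(pd_ids),
    )
    n_folds = min(cfg.n_folds, design.n_subjects)
    sel = regression.lasso_cv_select(
        design, n_folds=n_folds, seed=cfg.stage_seed("predict"), rule=cfg.lasso_rule
    )
    f_sel = run_dir / "selection.json"
    f_sel.write_text(
        json.dumps(
            {
                "lambdas": sel.lambdas.tolist(),
                "cv_errors": sel.cv_errors.tolist(),
                "chosen_lambda": sel.chosen_lambda,
                "selected_edges": [design.edge_labels[k] for k in sel.selected],
                "fold_ids": sel.fold_ids.tolist(),
            },
            indent=2,
        )
    )
    outputs = [f_sel]

    selected = list(sel.selected)
    if selected and len(selected) >= design.n_subjects - 1:
        # robust refit needs residual degrees of freedom; keep the strongest
        order = np.argsort(-np.abs(sel.coef_std[selected]))
        selected = sorted(selected[i] for i in order[: design.n_subjects - 2])
        logger.warning(
            "predict: truncated selection to %d strongest edges for the refit",
            len(selected),
        )
    rows = []
    if selected:
        fit = regression.robust_regress(design, selected)
        for j, k in enumerate(fit.edge_indices):
            rows.append(
                {
                    "edge": design.edge_labels[k],
                    "sign": "+" if fit.coefficients[j] >= 0 else "-",
                    "coefficient": fit.coefficients[j],
                    "std_error": fit.std_errors[j],
                    "p_value": fit.p_values[j],
                }
            )
    f_res = run_dir / "results.csv"
    pd.DataFrame(
        rows, columns=["edge", "sign", "coefficient", "std_error", "p_value"]
    ).to_csv(f_res, index=False, float_format=io.FLOAT_FMT)
    outputs.append(f_res)

    grp_rows = []
    labels = subjects.loc[strengths.index, "group"].to_numpy()
    for k in selected:
        col = design.edge_labels[k]
        stat, p = regression.compare_strengths_groups(
            strengths[col].to_numpy(float), labels
        )
        grp_rows.append({"edge": col, "t_stat": stat, "p_value": p})
    f_grp = run_dir / "group_comparison.csv"
    pd.DataFrame(grp_rows, columns=["edge", "t_stat", "p_value"]).to_csv(
        f_grp, index=False, float_format=io.FLOAT_FMT
    )
    outputs.append(f_grp)

    # behavioral arm: damping ratio vs rigidity score in the patient group
    metrics = pd.read_csv(run_dir / "metrics_subjects.csv").set_index("subject_id")
    zeta = metrics.loc[pd_ids, "zeta"].to_numpy(float)
    zdesign = regression.CohortDesign(
        X=zeta[:, None],
        Y=design.Y,
        edge_labels=("zeta",),
        subject_ids=tuple(pd_ids),
    )
    zfit = regression.robust_regress(zdesign)
    f_z = run_dir / "predict_summary.json"
    f_z.write_text(
        json.dumps(
            {
                "n_selected_edges": len(selected),
                "zeta_score_slope": float(zfit.coefficients[0]),
                "zeta_score_p": float(zfit.p_values[0]),
            },
            indent=2,
        )
    )
    outputs.append(f_z)
    logger.info("predict: %d edges selected", len(selected))
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "track": _stage_track,
    "network": _stage_network,
    "predict": _stage_predict,
}


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Writes ``manifest.json`` (config hash, package version, per-stage seeds
    and output checksums).  If the directory already holds a manifest with
    the same config hash, the run is considered complete and skipped unless
    ``config.force`` is set.
    """
    from rigidnet import __version__

    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists() and not config.force:
        try:
            prev = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            prev = {}
        if prev.get("config_hash") == config.config_hash():
            logger.info("run already complete (config hash match); skipping")
            return run_dir
    (run_dir / "config.yaml").write_text(config.to_yaml())
    manifest: dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "stage_seeds": {s: config.stage_seed(s) for s in config.stages},
        "stages": {},
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            outputs = _STAGE_FUNCS[stage](config, run_dir)
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise StageFailure(stage, exc) from exc
        manifest["stages"][stage] = {
            "outputs": {str(f.relative_to(run_dir)): _sha256(f) for f in outputs},
            "status": "complete",
        }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return run_dir
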